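"""Inference-time simulation under freely varied conditions.

A trained generator accepts any (t, c, b) combination matching its
condition signature: the input image is encoded under its original
conditions, and decoding can use a different time (growth prediction),
a different treatment (e.g. a density change), or rescaled biomass
values — combinations never seen during training included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .conditioning import ConditionSet
from .generator import Generator, draw_noise, from_model_range, to_model_range
from .nn import tensor as T
from .traits import mae_me, plant_pixel_fraction


class SignatureMismatchError(ValueError):
    pass


@dataclass
class SimulationTarget:
    t_gen: int
    c_gen: Optional[int] = None
    b_gen: Optional[np.ndarray] = None


@dataclass
class SimulationRequest:
    """An input image with its conditions plus a list of decode targets."""

    x_in: np.ndarray  # (H, W, 3) in [0, 1]
    t_in: int
    c_in: Optional[int] = None
    b_in: Optional[np.ndarray] = None
    targets: List[SimulationTarget] = field(default_factory=list)
    n_draws: int = 10
    seed: int = 0


def _cond(signature, t, c, b, role):
    if "c" in signature and c is None:
        raise SignatureMismatchError("model expects a treatment condition c")
    if "b" in signature and b is None:
        raise SignatureMismatchError("model expects a biomass condition b")
    return ConditionSet(
        t=np.array([t]),
        c=np.array([c]) if "c" in signature else None,
        b=np.asarray(b, dtype=float)[None] if "b" in signature else None,
        role=role,
    )


def simulate(
    generator: Generator,
    request: SimulationRequest,
    trait_fn=plant_pixel_fraction,
) -> pd.DataFrame:
    """Generate ``n_draws`` images per target with distinct noise and
    summarize a trait per target (mean ± std across draws).

    Returns a table with one row per (target, draw) plus the images in
    the ``image`` column; deterministic given ``request.seed``.
    """
    sig = generator.spec.embedding.signature
    generator.eval()
    y_in = _cond(sig, request.t_in, request.c_in, request.b_in, "input")
    x_model = to_model_range(request.x_in)
    rng = np.random.default_rng(request.seed)
    rows = []
    with T.no_grad():
        xi = generator.encode(x_model, y_in)
        for ti, target in enumerate(request.targets):
            c_gen = target.c_gen if target.c_gen is not None else request.c_in
            b_gen = target.b_gen if target.b_gen is not None else request.b_in
            y_gen = _cond(sig, target.t_gen, c_gen, b_gen, "target")
            for d in range(request.n_draws):
                z = draw_noise(rng, 1, generator.spec.z_dim)
                w = generator.map_noise(z)
                img = from_model_range(
                    generator.decode(generator.inject(xi, w), y_gen)
                )[0]
                rows.append(
                    {
                        "target": ti,
                        "t_gen": target.t_gen,
                        "c_gen": c_gen,
                        "draw": d,
                        "trait": float(trait_fn(img)),
                        "image": img,
                    }
                )
    return pd.DataFrame(rows)


def summarize_simulation(table: pd.DataFrame) -> pd.DataFrame:
    """Per-target trait mean ± std across noise draws."""
    return (
        table.groupby(["target", "t_gen", "c_gen"])["trait"]
        .agg(["mean", "std"])
        .reset_index()
    )


def biomass_sweep(
    generator: Generator,
    x_in,
    t_in: int,
    c_in: Optional[int],
    b_curve: np.ndarray,
    t_gen: int,
    ratios: Sequence[Tuple[float, float]],
    trait_estimator=None,
    n_draws: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Systematically rescale the biomass condition and tabulate MAE/ME
    per species against the unscaled (100%, 100%) prediction.

    ``ratios`` are (pct_sw, pct_fb) percentages applied to the
    growth-curve value ``b_curve`` at the target date."""
    sig = generator.spec.embedding.signature
    if "b" not in sig:
        raise SignatureMismatchError(
            "biomass sweep requires a model trained with the b condition"
        )
    if len(ratios) == 0:
        return pd.DataFrame(
            columns=["pct_sw", "pct_fb", "mae_sw", "me_sw", "mae_fb", "me_fb"]
        )
    b_curve = np.asarray(b_curve, dtype=float)

    def predict(b_gen, seed_offset):
        req = SimulationRequest(
            x_in=x_in,
            t_in=t_in,
            c_in=c_in,
            b_in=b_curve,
            targets=[SimulationTarget(t_gen=t_gen, b_gen=b_gen)],
            n_draws=n_draws,
            seed=seed + seed_offset,
        )
        tab = simulate(generator, req)
        imgs = np.stack(list(tab["image"]))
        if trait_estimator is not None:
            return trait_estimator.predict(imgs)
        # fall back to per-species plant-pixel fraction
        from .traits import segment_plants

        out = []
        for img in imgs:
            m = segment_plants(img)
            out.append([m["sw"].mean(), m["fb"].mean()])
        return np.asarray(out)

    base = predict(b_curve, 0)
    rows = []
    for pct_sw, pct_fb in ratios:
        b_gen = b_curve * np.array([pct_sw, pct_fb]) / 100.0
        est = predict(b_gen, 0)  # same seed: same noise draws as baseline
        mae_sw, me_sw = mae_me(est[:, 0], base[:, 0])
        mae_fb, me_fb = mae_me(est[:, 1], base[:, 1])
        rows.append(
            {
                "pct_sw": pct_sw,
                "pct_fb": pct_fb,
                "mae_sw": mae_sw,
                "me_sw": me_sw,
                "mae_fb": mae_fb,
                "me_fb": me_fb,
            }
        )
    return pd.DataFrame(rows)
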