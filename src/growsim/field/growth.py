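"""Parametric biomass growth curves for the synthetic testbed.

Dried biomass per species follows a logistic curve
``K / (1 + exp(-r (t - t0)))`` in t/ha over days after sowing, with
multiplicative modifiers for sowing density and cultivar/entry.  The
curves stand in for the per-day output of a process-based crop model:
they only need to be monotone in time and separable by treatment, which
is what the conditioning pathway consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .design import TreatmentSpec, species_fractions

#: asymptote modifier per density level, mirroring sowing at 80% (low)
#: and 120% (high) of the recommended sole-crop density
DENSITY_FACTORS = {"low": 0.8, "high": 1.2}


@dataclass(frozen=True)
class GrowthCurveParams:
    """Logistic parameters per species plus treatment modifiers.

    K in t/ha, r in 1/day, t0 in days after sowing.  ``cultivar_factors``
    map a cultivar/entry index to a multiplicative asymptote modifier.
    """

    k_sw: float = 6.0
    r_sw: float = 0.11
    t0_sw: float = 55.0
    k_fb: float = 4.0
    r_fb: float = 0.10
    t0_fb: float = 60.0
    density_factors: Dict[str, float] = field(
        default_factory=lambda: dict(DENSITY_FACTORS)
    )
    sw_entry_factors: Tuple[float, ...] = ()
    fb_cultivar_factors: Tuple[float, ...] = ()

    def __post_init__(self):
        if self.k_sw < 0 or self.k_fb < 0:
            raise ValueError("asymptote K must be >= 0")
        if self.r_sw <= 0 or self.r_fb <= 0:
            raise ValueError("rate r must be > 0")


def default_cultivar_factors(n, rng, spread=0.15):
    """Per-cultivar asymptote modifiers drawn once per design."""
    return tuple(1.0 + spread * (2.0 * rng.random(n) - 1.0))


def _factor(factors, idx):
    if idx is None:
        return 1.0
    if idx < len(factors):
        return factors[idx]
    return 1.0


def biomass_at(params: GrowthCurveParams, trt: TreatmentSpec, t) -> np.ndarray:
    """Biomass 2-vector (SW, FB) in t/ha at day(s) ``t``.

    Monocultures carry zero biomass of the absent species; mixtures get
    each species' logistic value scaled by its seed share, density and
    cultivar modifiers.
    """
    t = np.asarray(t, dtype=float)
    dens = params.density_factors[trt.density]
    frac_sw, frac_fb = species_fractions(trt)
    sw = (
        params.k_sw
        * dens
        * frac_sw
        * _factor(params.sw_entry_factors, trt.sw_entry)
        / (1.0 + np.exp(-params.r_sw * (t - params.t0_sw)))
    )
    fb = (
        params.k_fb
        * dens
        * frac_fb
        * _factor(params.fb_cultivar_factors, trt.fb_cultivar)
        / (1.0 + np.exp(-params.r_fb * (t - params.t0_fb)))
    )
    return np.stack([sw, fb], axis=-1)
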