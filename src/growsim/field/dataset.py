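"""Synthetic dataset assembly: sequences, splits, metadata, disk I/O."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import DesignSpec, enumerate_plots, enumerate_treatments
from .growth import GrowthCurveParams, default_cultivar_factors
from .render import RenderConfig, SampleRecord, make_layout, render_plot_image

DEFAULT_SEASON = (7, 21, 28, 42, 54, 68, 82, 96)

METADATA_COLUMNS = [
    "path",
    "sequence_id",
    "t",
    "treatment_id",
    "bm_sw",
    "bm_fb",
    "split",
]


class SplitError(ValueError):
    pass


@dataclass
class FieldDataset:
    """In-memory dataset: one record per image plus a metadata table."""

    records: List[SampleRecord]
    metadata: pd.DataFrame
    design: DesignSpec
    treatments: list
    growth: GrowthCurveParams
    render_config: RenderConfig
    season: Tuple[int, ...]
    seed: int

    def indices_by_split(self, split: str) -> np.ndarray:
        return np.flatnonzero(self.metadata["split"].to_numpy() == split)

    def sequence_indices(self, split: Optional[str] = None) -> Dict[str, np.ndarray]:
        cache = getattr(self, "_seq_cache", None)
        if cache is None:
            cache = {}
            object.__setattr__(self, "_seq_cache", cache)
        if split not in cache:
            md = self.metadata
            if split is not None:
                md = md[md["split"] == split]
            cache[split] = {
                sid: grp.index.to_numpy()
                for sid, grp in md.groupby("sequence_id", sort=True)
            }
        return cache[split]

    def treatment_by_id(self, treatment_id: int):
        return self.treatments[treatment_id]

    @property
    def n_treatments(self) -> int:
        return len(self.treatments)

    def biomass_stats(self) -> Tuple[np.ndarray, np.ndarray]:
        """Training-split biomass mean/scale, used to standardize the
        continuous condition before embedding."""
        train = self.metadata[self.metadata["split"] == "train"]
        b = train[["bm_sw", "bm_fb"]].to_numpy(dtype=float)
        mean = b.mean(axis=0)
        scale = b.std(axis=0)
        scale[scale < 1e-8] = 1.0
        return mean, scale


def _assign_splits(sequence_ids: Sequence[str], fractions, rng) -> Dict[str, str]:
    if abs(sum(fractions) - 1.0) > 1e-8:
        raise SplitError(f"split fractions {fractions} do not sum to 1")
    sids = list(sequence_ids)
    order = rng.permutation(len(sids))
    n = len(sids)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_val = min(n_val, n - n_train)
    assignment = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            split = "train"
        elif rank < n_train + n_val:
            split = "val"
        else:
            split = "test"
        assignment[sids[idx]] = split
    return assignment


def generate_dataset(
    design: DesignSpec = DesignSpec(),
    season: Sequence[int] = DEFAULT_SEASON,
    image_size: int = 64,
    n_sequences: Optional[int] = None,
    split_fractions=(0.7, 0.15, 0.15),
    seed: int = 0,
    growth: Optional[GrowthCurveParams] = None,
    align_jitter_px: float = 0.0,
) -> FieldDataset:
    """Generate an aligned image time-series dataset with known design.

    Sequences are plot clippings; every sequence is assigned wholly to
    one split (spatially separated splits).  ``n_sequences`` caps the
    number of sequences (plots x clippings) for desk-scale runs.
    Deterministic given ``seed``.
    """
    root_ss = np.random.SeedSequence(seed)
    ss_design, ss_split, ss_style = root_ss.spawn(3)
    design_rng = np.random.default_rng(ss_design)
    treatments = enumerate_treatments(design)
    plots = enumerate_plots(treatments, design)
    if growth is None:
        growth = GrowthCurveParams(
            sw_entry_factors=default_cultivar_factors(design.n_sw_entries, design_rng),
            fb_cultivar_factors=default_cultivar_factors(
                design.n_fb_cultivars, design_rng
            ),
        )
    config = RenderConfig(image_size=image_size)

    # sequences = plots x clippings; subsampling strides evenly through
    # the list so every treatment (and both densities) stays covered
    all_seqs = [
        (plot, clip)
        for clip in range(design.clippings_per_plot)
        for plot in plots
    ]
    if n_sequences is not None and n_sequences < len(all_seqs):
        # round-robin over treatments so every treatment (and both
        # densities) keeps sequences at small n_sequences
        pools: Dict[int, list] = {}
        for item in all_seqs:
            pools.setdefault(item[0].treatment_id, []).append(item)
        ordered_pools = [pools[tid] for tid in sorted(pools)]
        picked, i = [], 0
        while len(picked) < n_sequences:
            pool = ordered_pools[i % len(ordered_pools)]
            if pool:
                picked.append(pool.pop(0))
            i += 1
        all_seqs = picked

    seq_ids = [f"p{plot.plot_id:04d}c{clip}" for plot, clip in all_seqs]
    split_rng = np.random.default_rng(ss_split)
    split_of = _assign_splits(seq_ids, split_fractions, split_rng)

    style_seed = int(np.random.default_rng(ss_style).integers(0, 2**31 - 1))

    records: List[SampleRecord] = []
    rows = []
    for (plot, clip), sid in zip(all_seqs, seq_ids):
        trt = treatments[plot.treatment_id]
        layout_rng = np.random.default_rng(
            np.random.SeedSequence([seed, 17, plot.plot_id, clip])
        )
        layout = make_layout(trt, config, layout_rng)
        jitter_rng = np.random.default_rng(
            np.random.SeedSequence([seed, 23, plot.plot_id, clip])
        )
        for t in season:
            rec = render_plot_image(
                trt,
                layout,
                growth,
                int(t),
                style_seed,
                config,
                align_jitter_px=align_jitter_px,
                jitter_rng=jitter_rng if align_jitter_px > 0 else None,
            )
            rec.sequence_id = sid
            rec.split = split_of[sid]
            records.append(rec)
            rows.append(
                {
                    "path": f"images/{sid}_t{t:03d}.png",
                    "sequence_id": sid,
                    "t": int(t),
                    "treatment_id": trt.treatment_id,
                    "bm_sw": float(rec.b[0]),
                    "bm_fb": float(rec.b[1]),
                    "split": split_of[sid],
                }
            )
    metadata = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    return FieldDataset(
        records=records,
        metadata=metadata,
        design=design,
        treatments=treatments,
        growth=growth,
        render_config=config,
        season=tuple(int(t) for t in season),
        seed=seed,
    )


# ---------------------------------------------------------------------
# disk round trip (PNG images + CSV metadata + JSON manifest)
# ---------------------------------------------------------------------

def save_dataset(ds: FieldDataset, root) -> None:
    from imageio.v3 import imwrite

    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    for rec, path in zip(ds.records, ds.metadata["path"]):
        imwrite(root / path, (rec.image * 255).astype(np.uint8))
        if rec.gt_masks is not None:
            mask_path = root / path.replace("images/", "masks/").replace(
                ".png", "_masks.png"
            )
            mask_path.parent.mkdir(parents=True, exist_ok=True)
            stacked = np.stack(
                [
                    rec.gt_masks["sw"].astype(np.uint8) * 255,
                    rec.gt_masks["fb"].astype(np.uint8) * 255,
                    np.zeros_like(rec.gt_masks["sw"], dtype=np.uint8),
                ],
                axis=-1,
            )
            imwrite(mask_path, stacked)
    ds.metadata.to_csv(root / "metadata.csv", index=False)
    manifest = {
        "design": asdict(ds.design),
        "season": list(ds.season),
        "image_size": ds.render_config.image_size,
        "seed": ds.seed,
        "n_treatments": ds.n_treatments,
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_dataset(root) -> FieldDataset:
    """Load a saved dataset, validating metadata against the images."""
    from imageio.v3 import imread

    root = Path(root)
    manifest = json.loads((root / "manifest.json").read_text())
    metadata = pd.read_csv(root / "metadata.csv")
    design = DesignSpec(**manifest["design"])
    treatments = enumerate_treatments(design)

    for col in METADATA_COLUMNS:
        if col not in metadata.columns:
            raise ValueError(f"metadata missing column {col!r}")
    split_per_seq = metadata.groupby("sequence_id")["split"].nunique()
    leaky = split_per_seq[split_per_seq > 1]
    if len(leaky):
        raise ValueError(
            f"split leakage: sequences in multiple splits: {list(leaky.index)[:5]}"
        )

    records = []
    for i, row in metadata.iterrows():
        img_path = root / row["path"]
        if not img_path.exists():
            raise FileNotFoundError(f"metadata row {i}: missing image {row['path']}")
        img = imread(img_path).astype(np.float32) / 255.0
        mask_path = root / str(row["path"]).replace("images/", "masks/").replace(
            ".png", "_masks.png"
        )
        masks = None
        if mask_path.exists():
            m = imread(mask_path)
            masks = {"sw": m[..., 0] > 127, "fb": m[..., 1] > 127}
        records.append(
            SampleRecord(
                image=img,
                t=int(row["t"]),
                treatment_id=int(row["treatment_id"]),
                b=np.array([row["bm_sw"], row["bm_fb"]], dtype=np.float32),
                sequence_id=str(row["sequence_id"]),
                split=str(row["split"]),
                gt_masks=masks,
            )
        )
    return FieldDataset(
        records=records,
        metadata=metadata,
        design=design,
        treatments=treatments,
        growth=GrowthCurveParams(),
        render_config=RenderConfig(image_size=manifest["image_size"]),
        season=tuple(manifest["season"]),
        seed=manifest["seed"],
    )
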