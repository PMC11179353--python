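"""Rendering of synthetic crop-mixture plot images.

Each plot image shows spring wheat (SW) as thin row-structured elements
and faba bean (FB) as rounded blobs over a textured soil background.
Element positions are fixed per sequence (plants do not move between
acquisition dates); element sizes grow monotonically with the biomass
the growth curve assigns to the date, and a per-date global style jitter
(brightness/tint) emulates varying illumination between flights.  The
two species use separated hue ranges so a hue-threshold segmenter can
recover the ground-truth masks at early growth stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .design import TreatmentSpec, species_fractions
from .growth import GrowthCurveParams, biomass_at

SOIL_RGB = np.array([0.45, 0.35, 0.25])
SW_RGB = np.array([0.50, 0.68, 0.15])  # yellow-green, hue ~ 80 deg
FB_RGB = np.array([0.10, 0.55, 0.35])  # blue-green, hue ~ 153 deg

#: biomass (t/ha) at which an element reaches ~70% of its maximum size
BIOMASS_HALF = 1.0


class DegenerateRenderError(ValueError):
    """Image too small to place any plant element."""


@dataclass(frozen=True)
class RenderConfig:
    image_size: int = 64
    sw_base_count: int = 96  # elements per species at 64 px, monoculture, density 1
    fb_base_count: int = 14
    n_rows: int = 6
    brightness_jitter: float = 0.15
    tint_jitter: float = 0.02

    def __post_init__(self):
        if self.image_size < 16:
            raise DegenerateRenderError(
                f"image_size {self.image_size} < 16: cannot place plant elements"
            )


@dataclass
class SampleRecord:
    """One aligned image with its conditions and ground truth."""

    image: np.ndarray  # (H, W, 3) float32 in [0, 1]
    t: int
    treatment_id: int
    b: np.ndarray  # (2,) biomass (SW, FB) in t/ha
    sequence_id: str
    split: str = ""
    gt_masks: Optional[Dict[str, np.ndarray]] = None
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PlotLayout:
    """Time-invariant element positions for one sequence."""

    sw_xy: np.ndarray  # (n_sw, 2) float pixel coords
    fb_xy: np.ndarray
    sw_jit: np.ndarray  # per-element size jitter factors
    fb_jit: np.ndarray
    soil_seed: int


def make_layout(trt: TreatmentSpec, config: RenderConfig, rng) -> PlotLayout:
    """Draw element positions along crop rows, counts scaled by seed
    share and sowing density."""
    size = config.image_size
    scale = (size / 64.0) ** 2
    frac_sw, frac_fb = species_fractions(trt)
    dens = {"low": 0.8, "high": 1.2}[trt.density]
    n_sw = int(round(config.sw_base_count * frac_sw * dens * scale))
    n_fb = int(round(config.fb_base_count * frac_fb * dens * scale))
    n_sw = max(n_sw, 1) if frac_sw > 0 else 0
    n_fb = max(n_fb, 1) if frac_fb > 0 else 0

    rows = (np.arange(config.n_rows) + 0.5) / config.n_rows * size

    def _place(n):
        if n == 0:
            return np.zeros((0, 2))
        row_idx = rng.integers(0, config.n_rows, size=n)
        y = rows[row_idx] + rng.normal(0.0, size / 64.0, size=n)
        x = rng.uniform(2, size - 2, size=n)
        return np.stack([x, np.clip(y, 1, size - 2)], axis=1)

    return PlotLayout(
        sw_xy=_place(n_sw),
        fb_xy=_place(n_fb),
        sw_jit=1.0 + 0.25 * (rng.random(max(n_sw, 1)) - 0.5),
        fb_jit=1.0 + 0.25 * (rng.random(max(n_fb, 1)) - 0.5),
        soil_seed=int(rng.integers(0, 2**31 - 1)),
    )


def _size_factor(b):
    """Monotone saturating map from per-species biomass to element scale."""
    return np.sqrt(b / (b + BIOMASS_HALF)) if b > 0 else 0.0


def style_params(style_seed: int, t: int, config: RenderConfig):
    """Per-acquisition-date global style jitter, shared across plots."""
    key = [style_seed, abs(int(t)) & 0x7FFFFFFF, 1 if t < 0 else 0]
    rng = np.random.default_rng(np.random.SeedSequence(key))
    brightness = 1.0 + config.brightness_jitter * (2 * rng.random() - 1)
    tint = config.tint_jitter * (2 * rng.random(3) - 1)
    return brightness, tint


def render_plot_image(
    trt: TreatmentSpec,
    layout: PlotLayout,
    params: GrowthCurveParams,
    t: int,
    style_seed: int,
    config: RenderConfig = RenderConfig(),
    align_jitter_px: float = 0.0,
    jitter_rng=None,
) -> SampleRecord:
    """Render one plot at one date; deterministic given its arguments."""
    size = config.image_size
    b = biomass_at(params, trt, t)
    b_sw, b_fb = float(b[0]), float(b[1])

    soil_rng = np.random.default_rng(layout.soil_seed)
    img = SOIL_RGB[None, None, :] + soil_rng.normal(0.0, 0.015, size=(size, size, 3))

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    mask_sw = np.zeros((size, size), dtype=bool)
    mask_fb = np.zeros((size, size), dtype=bool)

    offset = np.zeros(2)
    if align_jitter_px > 0 and jitter_rng is not None:
        offset = jitter_rng.uniform(-align_jitter_px, align_jitter_px, size=2)

    # spring wheat: thin vertical elements
    g_sw = _size_factor(b_sw)
    if g_sw > 0:
        half_len = max(size / 9.0, 2.2) * g_sw
        half_wid = max(size / 22.0, 0.9) * g_sw
        for (x, y), jit in zip(layout.sw_xy, layout.sw_jit):
            x, y = x + offset[0], y + offset[1]
            m = (np.abs(xx - x) <= half_wid * jit) & (np.abs(yy - y) <= half_len * jit)
            mask_sw |= m

    # faba bean: blob elements
    g_fb = _size_factor(b_fb)
    if g_fb > 0:
        radius = (size / 4.2) * g_fb
        for (x, y), jit in zip(layout.fb_xy, layout.fb_jit):
            x, y = x + offset[0], y + offset[1]
            r = radius * jit
            m = (xx - x) ** 2 + (yy - y) ** 2 <= r * r
            mask_fb |= m

    elem_rng = np.random.default_rng(layout.soil_seed + 1)
    sw_col = SW_RGB + elem_rng.normal(0.0, 0.02, size=3)
    fb_col = FB_RGB + elem_rng.normal(0.0, 0.02, size=3)
    img[mask_sw] = sw_col + elem_rng.normal(0.0, 0.01, size=(int(mask_sw.sum()), 3))
    img[mask_fb] = fb_col + elem_rng.normal(0.0, 0.01, size=(int(mask_fb.sum()), 3))

    brightness, tint = style_params(style_seed, t, config)
    img = np.clip(img * brightness + tint[None, None, :], 0.0, 1.0)

    return SampleRecord(
        image=img.astype(np.float32),
        t=int(t),
        treatment_id=trt.treatment_id,
        b=b.astype(np.float32),
        sequence_id="",
        gt_masks={"sw": mask_sw, "fb": mask_fb},
    )
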