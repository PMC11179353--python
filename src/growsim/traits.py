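"""Growth estimation: traits derived from (real or generated) images.

Projected leaf area (PLA) is the pixel sum of a plant segmentation
mask, optionally restricted to the instance closest to the image
center, reported as pixels, % of image and physical area via the
squared ground sample distance.  Per-species dried biomass (SW, FB in
t/ha) is regressed from the image by a small CNN whose two output
neurons are ReLU-activated (biomass is non-negative), trained with MSE
against growth-curve reference values.  ΔPLA / ΔBM and the MAE / ME
summary statistics compare traits of generated and reference images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from skimage.color import rgb2hsv
from skimage.measure import label, regionprops

from .nn import Adam, Conv2d, Linear, Module, global_avg_pool, tensor as T

#: hue windows (fractions of the hue circle) separating the two species
SW_HUE = (0.10, 0.30)  # yellow-green spring wheat
FB_HUE = (0.30, 0.60)  # blue-green faba bean
GREEN_RATIO = 1.05
GREEN_MARGIN = 0.02  # vegetation: g > 1.05 r + margin and g > b (brightness-robust)


class UnknownMethodError(ValueError):
    pass


class NotFittedError(RuntimeError):
    pass


# ---------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------

def segment_plants(image, method: str = "hue_threshold", record=None, segmenter=None):
    """Per-species binary masks for an RGB image in [0, 1].

    Methods: ``ground_truth`` (stored masks of a synthetic record),
    ``hue_threshold`` (vegetation by green dominance, species split by
    hue window), or ``external`` (any callable image -> mask dict, the
    slot where a fine-tuned instance-segmentation model plugs in).
    """
    if method == "ground_truth":
        if record is None or record.gt_masks is None:
            raise ValueError("ground_truth method needs a record with stored masks")
        return {k: v.copy() for k, v in record.gt_masks.items()}
    if method == "external":
        if segmenter is None:
            raise ValueError("external method needs a segmenter callable")
        return segmenter(image)
    if method != "hue_threshold":
        raise UnknownMethodError(f"unknown segmentation method {method!r}")

    img = np.asarray(image, dtype=float)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    veg = (g > GREEN_RATIO * r + GREEN_MARGIN) & (g > b)
    hue = rgb2hsv(img)[..., 0]
    sw = veg & (hue >= SW_HUE[0]) & (hue < SW_HUE[1])
    fb = veg & (hue >= FB_HUE[0]) & (hue <= FB_HUE[1])
    return {"sw": sw, "fb": fb}


def center_instance(mask, image_shape=None) -> np.ndarray:
    """Connected component whose centroid is nearest the image center.

    Returns an empty mask when there are no instances; ties in distance
    break toward the lowest label index."""
    mask = np.asarray(mask, dtype=bool)
    if image_shape is None:
        image_shape = mask.shape
    labeled = label(mask)
    props = regionprops(labeled)
    if not props:
        return np.zeros(image_shape, dtype=bool)
    cy, cx = (image_shape[0] - 1) / 2.0, (image_shape[1] - 1) / 2.0
    dists = [np.hypot(p.centroid[0] - cy, p.centroid[1] - cx) for p in props]
    best = props[int(np.argmin(dists))]  # argmin takes the first minimum
    return labeled == best.label


# ---------------------------------------------------------------------
# projected leaf area
# ---------------------------------------------------------------------

def pla(mask, image_shape=None, gsd: float = 1.0) -> Tuple[int, float, float]:
    """(pixel sum, % of image, physical area = px * gsd^2)."""
    if gsd <= 0:
        raise ValueError("gsd must be > 0")
    mask = np.asarray(mask, dtype=bool)
    if image_shape is None:
        image_shape = mask.shape
    px = int(mask.sum())
    pct = 100.0 * px / (image_shape[0] * image_shape[1])
    return px, pct, px * gsd * gsd


@dataclass
class TraitRecord:
    sequence_id: str
    t: int
    treatment_id: int
    source: str  # "real" | "generated"
    pla_px: int
    pla_pct: float
    pla_phys: float
    bm: Optional[np.ndarray] = None  # (2,) SW, FB in t/ha

    def __post_init__(self):
        if not (0.0 <= self.pla_pct <= 100.0):
            raise ValueError("PLA percent outside [0, 100]")
        if self.bm is not None and np.any(np.asarray(self.bm) < 0):
            raise ValueError("biomass must be >= 0")


def trait_delta(gen: float, ref: float) -> float:
    """ΔPT = PT_gen - PT_ref (antisymmetric under swapping)."""
    return gen - ref


def mae_me(pt_gen, pt_ref) -> Tuple[float, float]:
    """Mean absolute error and mean (signed) error between trait lists.

    ME < 0 flags overall underestimation, ME > 0 overestimation;
    |ME| <= MAE always."""
    g = np.asarray(pt_gen, dtype=float)
    r = np.asarray(pt_ref, dtype=float)
    if g.shape != r.shape:
        raise ValueError("trait lists must have equal length")
    if g.size == 0:
        raise ValueError("need at least one trait pair")
    d = g - r
    return float(np.abs(d).mean()), float(d.mean())


def plant_pixel_fraction(image) -> float:
    """Total vegetation fraction of an image (both species)."""
    masks = segment_plants(image)
    return float((masks["sw"] | masks["fb"]).mean())


# ---------------------------------------------------------------------
# biomass regression
# ---------------------------------------------------------------------

class BiomassRegressor(Module):
    """Small CNN regressor with a two-output ReLU head.

    The head contract (two neurons, ReLU so only non-negative biomass
    can be produced, MSE loss) matches the full-scale configuration; the
    backbone width is configurable so a desk-scale model trains on CPU
    in seconds."""

    def __init__(self, width: int = 16, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        w = width
        self.conv1 = Conv2d(3, w, 3, rng, stride=2, padding=1)
        self.conv2 = Conv2d(w, 2 * w, 3, rng, stride=2, padding=1)
        self.conv3 = Conv2d(2 * w, 4 * w, 3, rng, stride=2, padding=1)
        self.fc = Linear(4 * w, 2, rng)
        self.fc.bias.data[...] = 0.5  # start in the feasible (positive) range
        self.fitted = False

    def forward(self, x):
        h = T.relu(self.conv1(x))
        h = T.relu(self.conv2(h))
        h = T.relu(self.conv3(h))
        return T.relu(self.fc(global_avg_pool(h)))

    @staticmethod
    def _to_model(images):
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2)) * 2 - 1

    def fit(
        self,
        images,
        targets,
        epochs: int = 60,
        batch_size: int = 32,
        lr: float = 2e-3,
        seed: int = 0,
        verbose: bool = False,
    ):
        """Minimize MSE between predictions and reference biomass."""
        x = self._to_model(images)
        yt = np.asarray(targets, dtype=np.float32)
        rng = np.random.default_rng(seed)
        params = self.parameters()
        opt = Adam(params, lr=lr, betas=(0.9, 0.999))
        n = len(x)
        for epoch in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                pred = self(T.Tensor(x[idx]))
                diff = pred - T.Tensor(yt[idx])
                loss = (diff * diff).mean()
                grads = T.grad(loss, params)
                opt.step(grads)
                losses.append(loss.item())
            if verbose:  # pragma: no cover
                print(f"epoch {epoch}: mse {np.mean(losses):.4f}")
        self.fitted = True
        return self

    def predict(self, images) -> np.ndarray:
        """Non-negative (N, 2) biomass estimates (SW, FB) in t/ha."""
        if not self.fitted:
            raise NotFittedError("biomass regressor is untrained; call fit() first")
        x = self._to_model(images)
        with T.no_grad():
            out = self(T.Tensor(x))
        return out.data
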