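"""Image-quality evaluation: MS-SSIM, perceptual distance, FID,
|Δt|-stratified reporting and noise-variability images.

MS-SSIM follows the multi-scale construction of Wang et al. (contrast/
structure terms at every scale, luminance at the coarsest, standard
weights).  The perceptual distance follows the LPIPS construction —
unit-normalized channel activations compared layer-wise in a
convolutional feature space — behind a pluggable extractor interface;
the default extractor is a fixed-seed random-weight CNN, whose
identity/symmetry/non-negativity properties are extractor-independent.
FID is the Fréchet distance between Gaussian fits to two feature sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence

import numpy as np
import scipy.linalg
from scipy.ndimage import gaussian_filter


MS_SSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)
_WIN_SIGMA = 1.5
_WIN_TRUNCATE = 10.0 / 3.0  # 11-pixel Gaussian window
_C1 = 0.01**2
_C2 = 0.03**2

STRATA = ("T0", "ST", "LT")


# ---------------------------------------------------------------------
# MS-SSIM
# ---------------------------------------------------------------------

def _ssim_cs(x, y):
    """Mean SSIM and contrast-structure term for one 2-D channel."""
    mu_x = gaussian_filter(x, _WIN_SIGMA, truncate=_WIN_TRUNCATE)
    mu_y = gaussian_filter(y, _WIN_SIGMA, truncate=_WIN_TRUNCATE)
    xx = gaussian_filter(x * x, _WIN_SIGMA, truncate=_WIN_TRUNCATE) - mu_x * mu_x
    yy = gaussian_filter(y * y, _WIN_SIGMA, truncate=_WIN_TRUNCATE) - mu_y * mu_y
    xy = gaussian_filter(x * y, _WIN_SIGMA, truncate=_WIN_TRUNCATE) - mu_x * mu_y
    lum = (2 * mu_x * mu_y + _C1) / (mu_x**2 + mu_y**2 + _C1)
    cs = (2 * xy + _C2) / (xx + yy + _C2)
    return float((lum * cs).mean()), float(cs.mean())


def _downsample2(x):
    h, w = x.shape[0] // 2 * 2, x.shape[1] // 2 * 2
    x = x[:h, :w]
    return 0.25 * (x[::2, ::2] + x[1::2, ::2] + x[::2, 1::2] + x[1::2, 1::2])


def max_scales(size: int, min_size: int = 11) -> int:
    n = 1
    while size // 2 >= min_size and n < len(MS_SSIM_WEIGHTS):
        size //= 2
        n += 1
    return n


def ms_ssim(x, y, n_scales: Optional[int] = None) -> float:
    """Multi-scale SSIM of two images in [0, 1]; optimum 1, symmetric.

    Channels are averaged.  ``n_scales`` defaults to the largest pyramid
    the image supports (up to 5)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("images must share a shape")
    size = min(x.shape[0], x.shape[1])
    feasible = max_scales(size)
    if n_scales is None:
        n_scales = feasible
    elif n_scales > feasible:
        raise ValueError(
            f"image of size {size} supports at most {feasible} scales; "
            f"pass n_scales<={feasible}"
        )
    weights = np.array(MS_SSIM_WEIGHTS[:n_scales])
    weights = weights / weights.sum()

    channels = [x[..., ch] for ch in range(x.shape[2])] if x.ndim == 3 else [x]
    channels_y = [y[..., ch] for ch in range(y.shape[2])] if y.ndim == 3 else [y]

    vals = []
    for cx, cy in zip(channels, channels_y):
        mcs = []
        for s in range(n_scales):
            ssim_val, cs_val = _ssim_cs(cx, cy)
            if s == n_scales - 1:
                mcs.append(max(ssim_val, 0.0))
            else:
                mcs.append(max(cs_val, 0.0))
                cx, cy = _downsample2(cx), _downsample2(cy)
        vals.append(float(np.prod(np.array(mcs) ** weights)))
    return float(np.mean(vals))


# ---------------------------------------------------------------------
# perceptual distance (LPIPS construction)
# ---------------------------------------------------------------------

class RandomConvFeatures:
    """Fixed-seed random convolutional feature extractor.

    Serves as the desk-scale stand-in for a pretrained perceptual
    backbone behind the same interface: ``features(img)`` returns a list
    of (C, H, W) activation maps."""

    def __init__(self, seed: int = 0, widths: Sequence[int] = (16, 32, 64)):
        rng = np.random.default_rng(seed)
        self.weights = []
        in_ch = 3
        for w_ch in widths:
            fan_in = in_ch * 9
            self.weights.append(
                rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(w_ch, in_ch, 3, 3))
            )
            in_ch = w_ch

    def __call__(self, img) -> List[np.ndarray]:
        from .nn import tensor as T

        x = np.asarray(img, dtype=np.float64)
        if x.ndim == 3:
            x = x.transpose(2, 0, 1)[None]
        feats = []
        with T.no_grad():
            h = T.Tensor(x * 2.0 - 1.0)
            for w in self.weights:
                cols = T.im2col(h, 3, stride=2, pad=1)
                n, _, hh, ww = h.shape
                ho = (hh + 2 - 3) // 2 + 1
                wo = (ww + 2 - 3) // 2 + 1
                out = T.matmul(T.Tensor(w.reshape(w.shape[0], -1)), cols)
                h = T.leaky_relu(T.reshape(out, (n, w.shape[0], ho, wo)), 0.2)
                feats.append(h.data[0])
        return feats

    def pooled(self, img) -> np.ndarray:
        """Globally pooled deepest features (for FID)."""
        return self(img)[-1].mean(axis=(1, 2))


def lpips(x, y, extractor: Optional[RandomConvFeatures] = None) -> float:
    """Perceptual distance >= 0; 0 for identical inputs, any extractor."""
    if extractor is None:
        raise ValueError("a feature extractor is required")
    fx, fy = extractor(x), extractor(y)
    total = 0.0
    for ax, ay in zip(fx, fy):
        nx = ax / np.sqrt((ax**2).sum(axis=0, keepdims=True) + 1e-10)
        ny = ay / np.sqrt((ay**2).sum(axis=0, keepdims=True) + 1e-10)
        total += float(((nx - ny) ** 2).mean(axis=(1, 2)).sum())
    return total


# ---------------------------------------------------------------------
# FID
# ---------------------------------------------------------------------

def fid(features_a, features_b, reg: float = 1e-6) -> float:
    """Fréchet distance between Gaussian fits of two feature sets.

    ||mu_a - mu_b||^2 + Tr(S_a + S_b - 2 (S_a S_b)^{1/2}); unbiased
    covariance with a small diagonal regularizer for stability."""
    a = np.asarray(features_a, dtype=np.float64)
    b = np.asarray(features_b, dtype=np.float64)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    cov_a = np.atleast_2d(np.cov(a, rowvar=False)) + reg * np.eye(a.shape[1])
    cov_b = np.atleast_2d(np.cov(b, rowvar=False)) + reg * np.eye(b.shape[1])
    covmean = scipy.linalg.sqrtm(cov_a @ cov_b)
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    diff = mu_a - mu_b
    val = diff @ diff + np.trace(cov_a) + np.trace(cov_b) - 2.0 * np.trace(covmean)
    return float(max(val, 0.0))


def fid_gaussian(mu_a, var_a, mu_b, var_b) -> float:
    """Closed form for 1-D Gaussians: (mu difference)^2 + (sigma difference)^2."""
    return float((mu_a - mu_b) ** 2 + (np.sqrt(var_a) - np.sqrt(var_b)) ** 2)


# ---------------------------------------------------------------------
# Δt stratification
# ---------------------------------------------------------------------

def stratify(delta_t) -> np.ndarray:
    """T0 iff |Δt| = 0; ST iff 1 <= |Δt| <= 10; LT iff |Δt| >= 11."""
    dt = np.abs(np.atleast_1d(np.asarray(delta_t, dtype=int)))
    out = np.where(dt == 0, "T0", np.where(dt <= 10, "ST", "LT"))
    return out


@dataclass
class PredictionPair:
    x_gen: np.ndarray
    x_ref: np.ndarray
    delta_t: int

    @property
    def stratum(self) -> str:
        return str(stratify(self.delta_t)[0])


# ---------------------------------------------------------------------
# variability image
# ---------------------------------------------------------------------

def variability_image(
    generator, x_in, y_in, y_gen, n: int = 10, rng=None, overdraw: float = 4.0
) -> np.ndarray:
    """Per-pixel std over ``n`` generations with different noise draws,
    averaged over channels, scaled by ``overdraw`` and clipped to [0, 1]."""
    from .generator import draw_noise, from_model_range, to_model_range

    if n < 2:
        raise ValueError("need n >= 2 generations")
    rng = np.random.default_rng(rng)
    x_model = to_model_range(x_in)
    imgs = []
    from .nn import tensor as T

    with T.no_grad():
        for _ in range(n):
            z = draw_noise(rng, x_model.shape[0], generator.spec.z_dim)
            out = generator(x_model, y_in, y_gen, z)
            imgs.append(from_model_range(out)[0])
    std = np.stack(imgs).std(axis=0).mean(axis=-1)
    return np.clip(std * overdraw, 0.0, 1.0)


# ---------------------------------------------------------------------
# evaluation report
# ---------------------------------------------------------------------

@dataclass
class EvalReport:
    ms_ssim_by_stratum: Dict[str, Optional[float]]
    counts_by_stratum: Dict[str, int]
    lpips_mean: float
    fid_value: float
    trait_mae: Dict[str, float] = dc_field(default_factory=dict)
    trait_me: Dict[str, float] = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "ms_ssim": self.ms_ssim_by_stratum,
            "counts": self.counts_by_stratum,
            "lpips": self.lpips_mean,
            "fid": self.fid_value,
            "trait_mae": self.trait_mae,
            "trait_me": self.trait_me,
        }


def build_eval_pairs(dataset, split: str, rng) -> List[dict]:
    """Test-time pair construction mirroring training: every image of
    the split is an input once, paired with a random other growth stage
    of its sequence."""
    pairs = []
    md = dataset.metadata
    for sid, idxs in dataset.sequence_indices(split).items():
        for i in idxs:
            others = idxs[idxs != i]
            j = int(rng.choice(others)) if len(others) else int(i)
            pairs.append(
                {
                    "input_idx": int(i),
                    "ref_idx": j,
                    "delta_t": int(md["t"].iloc[j] - md["t"].iloc[i]),
                }
            )
    return pairs


def evaluate(
    generator,
    dataset,
    split: str = "test",
    trait_estimator=None,
    extractor: Optional[RandomConvFeatures] = None,
    rng=None,
    batch_size: int = 16,
    condition_builder=None,
) -> EvalReport:
    """Δt-stratified MS-SSIM, mean perceptual distance, pooled FID and
    (optionally) trait MAE/ME for one dataset split."""
    from .generator import draw_noise, from_model_range, to_model_range
    from .nn import tensor as T
    from .traits import mae_me

    rng = np.random.default_rng(rng)
    if extractor is None:
        extractor = RandomConvFeatures(seed=0)
    pairs = build_eval_pairs(dataset, split, rng)
    if not pairs:
        raise ValueError(f"no evaluation pairs in split {split!r}")

    generator.eval()
    gen_imgs, ref_imgs, strata = [], [], []
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start : start + batch_size]
        x_in = np.stack([dataset.records[p["input_idx"]].image for p in chunk])
        x_ref = np.stack([dataset.records[p["ref_idx"]].image for p in chunk])
        y_in = condition_builder(dataset, [p["input_idx"] for p in chunk], "input")
        y_gen = condition_builder(dataset, [p["ref_idx"] for p in chunk], "target")
        z = draw_noise(rng, len(chunk), generator.spec.z_dim)
        with T.no_grad():
            out = generator(to_model_range(x_in), y_in, y_gen, z)
        gen = from_model_range(out)
        for k, p in enumerate(chunk):
            gen_imgs.append(gen[k])
            ref_imgs.append(x_ref[k])
            strata.append(str(stratify(p["delta_t"])[0]))

    strata = np.array(strata)
    ms_by, counts = {}, {}
    for s in STRATA:
        mask = strata == s
        counts[s] = int(mask.sum())
        if counts[s]:
            ms_by[s] = float(
                np.mean(
                    [ms_ssim(g, r) for g, r in zip(
                        (g for g, m in zip(gen_imgs, mask) if m),
                        (r for r, m in zip(ref_imgs, mask) if m),
                    )]
                )
            )
        else:
            ms_by[s] = None

    lp = float(np.mean([lpips(g, r, extractor) for g, r in zip(gen_imgs, ref_imgs)]))
    feats_gen = np.stack([extractor.pooled(g) for g in gen_imgs])
    feats_ref = np.stack([extractor.pooled(r) for r in ref_imgs])
    fid_val = fid(feats_gen, feats_ref)

    trait_mae, trait_me = {}, {}
    if trait_estimator is not None:
        bm_gen = trait_estimator.predict(np.stack(gen_imgs))
        bm_ref = trait_estimator.predict(np.stack(ref_imgs))
        for k, name in enumerate(("sw", "fb")):
            mae, me = mae_me(bm_gen[:, k], bm_ref[:, k])
            trait_mae[name] = mae
            trait_me[name] = me

    return EvalReport(
        ms_ssim_by_stratum=ms_by,
        counts_by_stratum=counts,
        lpips_mean=lp,
        fid_value=fid_val,
        trait_mae=trait_mae,
        trait_me=trait_me,
    )
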