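"""Image-quality metrics and Δt stratification on synthetic images.

Computes MS-SSIM, the perceptual distance and FID on pairs drawn from
the synthetic testbed, without any trained model: identical images hit
each metric's optimum, images of different growth stages drift away
from it, and prediction offsets Δt fall into the T0/ST/LT strata.
"""

import numpy as np

from growsim import generate_dataset
from growsim.metrics import RandomConvFeatures, fid, lpips, ms_ssim, stratify

ds = generate_dataset(image_size=64, n_sequences=8, seed=4)
by_t = {t: [r for r in ds.records if r.t == t] for t in ds.season}
img_early = by_t[28][0].image
img_same_day = by_t[28][1].image
img_late = by_t[96][0].image

extractor = RandomConvFeatures(seed=0)
print("MS-SSIM (optimum 1):")
print(f"  image vs itself:        {ms_ssim(img_early, img_early):.6f}")
print(f"  vs another day-28 plot: {ms_ssim(img_early, img_same_day):.4f}")
print(f"  vs day 96 of same plot: {ms_ssim(img_early, img_late):.4f}")

print("perceptual distance (optimum 0):")
print(f"  image vs itself:        {lpips(img_early, img_early, extractor):.6f}")
print(f"  vs day 96 of same plot: {lpips(img_early, img_late, extractor):.4f}")

feats_early = np.stack([extractor.pooled(r.image) for r in by_t[28]])
feats_late = np.stack([extractor.pooled(r.image) for r in by_t[96]])
print("FID (optimum 0):")
print(f"  day-28 set vs itself:   {fid(feats_early, feats_early):.6f}")
print(f"  day-28 vs day-96 set:   {fid(feats_early, feats_late):.2f}")

dts = [0, 5, -10, 11, 54]
print("\nΔt strata (T0 identity, ST short-term 1-10, LT long-term >=11):")
for dt, s in zip(dts, stratify(dts)):
    print(f"  Δt={dt:+3d} -> {s}")
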