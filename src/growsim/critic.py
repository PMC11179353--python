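"""Conditional Wasserstein critic with intermediate condition fusion.

The candidate image (reference or generated) and the input image are
concatenated channel-wise (6 input channels) and passed through a conv
stem and conv/instance-norm/LeakyReLU blocks down to a 16x16 map.  Each
condition of both ``y_in`` and ``y_gen`` is embedded to 256 dimensions
by the critic's own embedding family (Psi), reshaped to 16x16 channel
planes and concatenated to that map; further conv blocks reduce to a
single unbounded scalar score.  No batch normalization anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conditioning import ConditionEmbedder, ConditionSet, EmbeddingConfig
from .nn import Conv2d, InstanceNorm2d, Module, tensor as T

FUSION_SIZE = 16
LEAKY_SLOPE = 0.2


@dataclass(frozen=True)
class CriticSpec:
    image_size: int = 256
    width: int = 64
    embedding: EmbeddingConfig = field(
        default_factory=lambda: EmbeddingConfig(dim=256)
    )

    def __post_init__(self):
        if self.image_size < 2 * FUSION_SIZE:
            raise ValueError(f"image_size must be >= {2 * FUSION_SIZE}")
        if self.image_size % FUSION_SIZE:
            raise ValueError(f"image_size must be a multiple of {FUSION_SIZE}")
        if self.embedding.dim % (FUSION_SIZE * FUSION_SIZE):
            raise ValueError(
                f"critic embedding dim must be a multiple of {FUSION_SIZE ** 2}"
            )


def reshape_condition_for_fusion(e, spatial=FUSION_SIZE):
    """Reshape an embedding batch (N, D) to (N, D/spatial^2, s, s) planes."""
    n, d = e.shape
    if d % (spatial * spatial):
        raise ValueError(
            f"embedding length {d} not reshapeable to {spatial}x{spatial} planes"
        )
    return T.reshape(e, (n, d // (spatial * spatial), spatial, spatial))


class ConvBlock(Module):
    def __init__(self, in_ch, out_ch, rng, stride=2, norm=True):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, 3, rng, stride=stride, padding=1)
        self.norm = InstanceNorm2d() if norm else None

    def forward(self, x):
        h = self.conv(x)
        if self.norm is not None:
            h = self.norm(h)
        return T.leaky_relu(h, LEAKY_SLOPE)


class Critic(Module):
    def __init__(self, spec: CriticSpec, rng):
        super().__init__()
        self.spec = spec
        self.psi = ConditionEmbedder(spec.embedding, rng)
        w = spec.width
        self.stem = Conv2d(6, w, 3, rng, stride=1, padding=1)
        n_down = int(np.log2(spec.image_size // FUSION_SIZE))
        chans = [w * min(2**i, 8) for i in range(n_down + 1)]
        self.pre = [
            ConvBlock(chans[i], chans[i + 1], rng, stride=2) for i in range(n_down)
        ]
        n_planes = 2 * len(spec.embedding.signature) * (
            spec.embedding.dim // (FUSION_SIZE * FUSION_SIZE)
        )
        fused_ch = chans[-1] + n_planes
        self.post1 = ConvBlock(fused_ch, chans[-1], rng, stride=2)
        self.post2 = ConvBlock(chans[-1], chans[-1], rng, stride=2)
        self.head = Conv2d(chans[-1], 1, 3, rng, stride=1, padding=1)

    def forward(self, x_cand, x_in, y_in: ConditionSet, y_gen: ConditionSet):
        """Scalar score per batch element (shape (N,))."""
        x_cand, x_in = _as_t(x_cand), _as_t(x_in)
        if x_cand.shape != x_in.shape:
            raise ValueError("candidate and input images must share a shape")
        h = T.leaky_relu(self.stem(T.concat([x_cand, x_in], axis=1)), LEAKY_SLOPE)
        for blk in self.pre:
            h = blk(h)
        e_in = reshape_condition_for_fusion(self.psi(y_in))
        e_gen = reshape_condition_for_fusion(self.psi(y_gen))
        h = T.concat([h, e_in, e_gen], axis=1)
        h = self.post2(self.post1(h))
        score_map = self.head(h)
        return T.reshape(T.tmean(score_map, axis=(1, 2, 3)), (-1,))

    score = forward


def _as_t(x):
    return x if isinstance(x, T.Tensor) else T.Tensor(x)
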