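"""Encoder-decoder generator with conditional batch normalization.

The generator maps ``(X_in, y_in, y_gen, z)`` to a generated image: a
residual encoder (stride product 32, every batch norm replaced by CBN
conditioned on the input-side embedding ``a_in``) compresses the image
to a latent map ``xi``; a StyleGAN-style three-layer mapping network
projects the 128-d noise ``z`` to a latent code ``w`` matching the
bottleneck channel count, which is broadcast over the spatial grid and
added to ``xi``; a mirrored decoder (nearest-neighbor x2 upsampling +
conv, CBN conditioned on the target-side embedding ``a_gen``) produces
a tanh-bounded image in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conditioning import ConditionEmbedder, ConditionSet, EmbeddingConfig
from .nn import ConditionalBatchNorm2d, Conv2d, Linear, Module, tensor as T


def to_model_range(img):
    """[0, 1] image -> [-1, 1] model range (channels-first)."""
    from .nn import tensor as _t

    img = np.asarray(img, dtype=_t.DEFAULT_DTYPE)
    if img.ndim == 3:
        img = img[None]
    return np.ascontiguousarray(img.transpose(0, 3, 1, 2)) * 2 - 1


def from_model_range(x):
    """[-1, 1] model output -> [0, 1] HWC image array."""
    data = x.data if isinstance(x, T.Tensor) else np.asarray(x)
    return np.clip(data.transpose(0, 2, 3, 1) * 0.5 + 0.5, 0.0, 1.0)


@dataclass(frozen=True)
class GeneratorSpec:
    """Architecture configuration; the default width builds the
    full-scale model (512-channel bottleneck at 256 px), small widths
    build desk-scale models."""

    image_size: int = 256
    width: int = 64
    blocks_per_stage: int = 2
    z_dim: int = 128
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)

    def __post_init__(self):
        if self.image_size % 32:
            raise ValueError("image_size must be a multiple of 32")

    @property
    def bottleneck_channels(self) -> int:
        return 8 * self.width

    @property
    def latent_spatial(self) -> int:
        return self.image_size // 32


class ResBlock(Module):
    def __init__(self, in_ch, out_ch, stride, cond_dim, rng):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng, stride=stride, padding=1, bias=False)
        self.cbn1 = ConditionalBatchNorm2d(out_ch, cond_dim, rng)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng, stride=1, padding=1, bias=False)
        self.cbn2 = ConditionalBatchNorm2d(out_ch, cond_dim, rng)
        self.proj = (
            Conv2d(in_ch, out_ch, 1, rng, stride=stride, bias=False)
            if (stride != 1 or in_ch != out_ch)
            else None
        )

    def forward(self, x, a):
        h = T.relu(self.cbn1(self.conv1(x), a))
        h = self.cbn2(self.conv2(h), a)
        skip = self.proj(x) if self.proj is not None else x
        return T.relu(h + skip)


class Encoder(Module):
    """Residual encoder; CBN everywhere, global pooling omitted."""

    def __init__(self, spec: GeneratorSpec, cond_dim, rng):
        super().__init__()
        w, n = spec.width, spec.blocks_per_stage
        self.stem = Conv2d(3, w, 3, rng, stride=2, padding=1, bias=False)
        self.stem_bn = ConditionalBatchNorm2d(w, cond_dim, rng)
        chans = [w, w, 2 * w, 4 * w, 8 * w]
        self.blocks = []
        for i in range(4):
            stage = [ResBlock(chans[i], chans[i + 1], 2, cond_dim, rng)]
            stage += [
                ResBlock(chans[i + 1], chans[i + 1], 1, cond_dim, rng)
                for _ in range(n - 1)
            ]
            self.blocks.extend(stage)

    def forward(self, x, a):
        h = T.relu(self.stem_bn(self.stem(x), a))
        for blk in self.blocks:
            h = blk(h, a)
        return h


class UpBlock(Module):
    def __init__(self, in_ch, out_ch, cond_dim, rng, n_blocks=1):
        super().__init__()
        self.blocks = [ResBlock(in_ch, out_ch, 1, cond_dim, rng)]
        self.blocks += [
            ResBlock(out_ch, out_ch, 1, cond_dim, rng) for _ in range(n_blocks - 1)
        ]

    def forward(self, x, a):
        from .nn import upsample2x

        h = upsample2x(x)
        for blk in self.blocks:
            h = blk(h, a)
        return h


class Decoder(Module):
    """Architectural mirror of the encoder with nearest x2 upsampling."""

    def __init__(self, spec: GeneratorSpec, cond_dim, rng):
        super().__init__()
        w, n = spec.width, spec.blocks_per_stage
        chans = [8 * w, 4 * w, 2 * w, w, w]
        self.ups = [
            UpBlock(chans[i], chans[i + 1], cond_dim, rng, n_blocks=n) for i in range(4)
        ]
        self.head = Conv2d(w, 3, 3, rng, stride=1, padding=1)

    def forward(self, xi, a):
        from .nn import upsample2x

        h = xi
        for up in self.ups:
            h = up(h, a)
        h = upsample2x(h)
        return T.tanh(self.head(h))


class NoiseMapper(Module):
    """Three linear layers gradually projecting z (128) to w (bottleneck
    channels), SiLU in between."""

    def __init__(self, z_dim, out_dim, rng):
        super().__init__()
        mid = int(round(np.sqrt(z_dim * out_dim)))
        self.fc1 = Linear(z_dim, mid, rng)
        self.fc2 = Linear(mid, mid, rng)
        self.fc3 = Linear(mid, out_dim, rng)
        for fc in (self.fc1, self.fc2, self.fc3):
            fc.bias.data[...] = rng.normal(0.0, 0.01, size=fc.bias.shape)

    def forward(self, z):
        if not isinstance(z, T.Tensor):
            z = T.Tensor(np.asarray(z, dtype=T.DEFAULT_DTYPE))
        return self.fc3(T.silu(self.fc2(T.silu(self.fc1(z)))))


class Generator(Module):
    def __init__(self, spec: GeneratorSpec, rng):
        super().__init__()
        self.spec = spec
        self.phi = ConditionEmbedder(spec.embedding, rng)
        cond_dim = self.phi.out_dim
        self.encoder = Encoder(spec, cond_dim, rng)
        self.decoder = Decoder(spec, cond_dim, rng)
        self.mapper = NoiseMapper(spec.z_dim, spec.bottleneck_channels, rng)

    # -- stage-wise API ------------------------------------------------
    def encode(self, x, y_in: ConditionSet):
        a_in = self.phi(y_in)
        return self.encoder(_as_t(x), a_in)

    def map_noise(self, z):
        return self.mapper(z)

    @staticmethod
    def inject(xi, w):
        if w.shape[-1] != xi.shape[1]:
            raise ValueError(
                f"latent code dim {w.shape[-1]} != bottleneck channels {xi.shape[1]}"
            )
        n, c = w.shape
        return xi + T.reshape(w, (n, c, 1, 1))

    def decode(self, xi, y_gen: ConditionSet):
        a_gen = self.phi(y_gen)
        return self.decoder(xi, a_gen)

    def forward(self, x_in, y_in: ConditionSet, y_gen: ConditionSet, z):
        """Full pass: decode(inject(encode(x, Phi(y_in)), map(z)), Phi(y_gen))."""
        xi = self.encode(x_in, y_in)
        w = self.map_noise(z)
        return self.decode(self.inject(xi, w), y_gen)

    generate = forward


def _as_t(x):
    return x if isinstance(x, T.Tensor) else T.Tensor(x)


def draw_noise(rng, n, z_dim=128):
    return rng.standard_normal((n, z_dim))
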