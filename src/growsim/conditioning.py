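"""Condition embeddings and assembly for the generator and critic.

Conditions come in three types: discrete time ``t`` (days), a
categorical treatment id ``c``, and a continuous biomass vector ``b``
(SW, FB in t/ha).  Each type gets its own embedding of a common width —
time via sinusoidal positional encoding followed by a two-layer MLP
(SiLU in between), treatment via a lookup table, biomass via a
two-layer MLP after standardization — and present embeddings are
concatenated in the fixed order (t, c, b).  The generator family (Phi)
and the critic family (Psi) share this architecture but never weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .nn import Embedding, Linear, Module, tensor as T

CONDITION_ORDER = ("t", "c", "b")


@dataclass
class ConditionSet:
    """A batch of condition triples; absent components are None."""

    t: np.ndarray  # (N,) int days
    c: Optional[np.ndarray] = None  # (N,) int treatment ids
    b: Optional[np.ndarray] = None  # (N, 2) float biomass
    role: str = "input"  # "input" | "target"

    def __post_init__(self):
        self.t = np.atleast_1d(np.asarray(self.t))
        if self.c is not None:
            self.c = np.atleast_1d(np.asarray(self.c))
        if self.b is not None:
            self.b = np.atleast_2d(np.asarray(self.b, dtype=float))
            if np.any(~np.isfinite(self.b)):
                raise ValueError("biomass condition contains non-finite values")
            if np.any(self.b < 0):
                raise ValueError("biomass condition must be >= 0")

    @property
    def signature(self) -> Tuple[str, ...]:
        sig = ["t"]
        if self.c is not None:
            sig.append("c")
        if self.b is not None:
            sig.append("b")
        return tuple(sig)

    def __len__(self):
        return len(self.t)


@dataclass(frozen=True)
class EmbeddingConfig:
    """Widths and vocabularies of the per-condition embeddings.

    All per-condition embeddings within one family share ``dim`` so no
    condition is weighted a priori.
    """

    signature: Tuple[str, ...] = ("t",)
    dim: int = 64
    vocab_size: int = 76
    b_dim: int = 2
    pe_length: int = 64
    pe_base: float = 10000.0
    time_unit: float = 1.0  # divide t by this before encoding (days vs hours)
    hidden: Optional[int] = None  # MLP hidden width; defaults to dim

    def __post_init__(self):
        for s in self.signature:
            if s not in CONDITION_ORDER:
                raise ValueError(f"unknown condition {s!r}")
        if "t" not in self.signature:
            raise ValueError("time condition is mandatory")
        if self.pe_length % 2:
            raise ValueError("pe_length must be even")


def positional_encoding(t, length=64, base=10000.0, unit=1.0) -> np.ndarray:
    """Transformer-style sin/cos encoding of scalar time points.

    Returns (N, length); column pairs are (sin, cos) at geometrically
    spaced frequencies.  Injective over any window shorter than the
    longest period (2*pi*base)."""
    t = np.atleast_1d(np.asarray(t, dtype=float)) / unit
    half = length // 2
    freqs = base ** (-np.arange(half, dtype=float) * 2.0 / length)
    ang = t[:, None] * freqs[None, :]
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1)


class TimeEmbedding(Module):
    def __init__(self, config: EmbeddingConfig, rng):
        super().__init__()
        hidden = config.hidden or config.dim
        self.config = config
        self.fc1 = Linear(config.pe_length, hidden, rng)
        self.fc2 = Linear(hidden, config.dim, rng)

    def forward(self, t):
        pe = positional_encoding(
            t, self.config.pe_length, self.config.pe_base, self.config.time_unit
        )
        return self.fc2(T.silu(self.fc1(T.Tensor(pe.astype(T.DEFAULT_DTYPE)))))


class ClassEmbedding(Module):
    def __init__(self, config: EmbeddingConfig, rng):
        super().__init__()
        self.table = Embedding(config.vocab_size, config.dim, rng)

    def forward(self, c):
        return self.table(np.asarray(c))


class ContinuousEmbedding(Module):
    """MLP embedding of the biomass vector, standardized by training-set
    mean/scale (MLP conditioning is scale-sensitive)."""

    def __init__(self, config: EmbeddingConfig, rng):
        super().__init__()
        hidden = config.hidden or config.dim
        self.fc1 = Linear(config.b_dim, hidden, rng)
        self.fc2 = Linear(hidden, config.dim, rng)
        self.b_mean = np.zeros(config.b_dim)
        self.b_scale = np.ones(config.b_dim)

    def set_standardization(self, mean, scale):
        self.b_mean[...] = mean
        self.b_scale[...] = scale

    def forward(self, b):
        b = np.atleast_2d(np.asarray(b, dtype=float))
        if np.any(~np.isfinite(b)):
            raise ValueError("biomass input contains NaN/inf")
        z = ((b - self.b_mean) / self.b_scale).astype(T.DEFAULT_DTYPE)
        return self.fc2(T.silu(self.fc1(T.Tensor(z))))


class ConditionEmbedder(Module):
    """One embedding family (Phi or Psi): type-specific embeddings
    concatenated in fixed (t, c, b) order, absent conditions omitted."""

    def __init__(self, config: EmbeddingConfig, rng):
        super().__init__()
        self.config = config
        self.time = TimeEmbedding(config, rng)
        self.cls = ClassEmbedding(config, rng) if "c" in config.signature else None
        self.cont = ContinuousEmbedding(config, rng) if "b" in config.signature else None

    @property
    def out_dim(self) -> int:
        return len(self.config.signature) * self.config.dim

    def forward(self, conditions: ConditionSet):
        if conditions.signature != self.config.signature:
            raise ValueError(
                f"condition signature {conditions.signature} does not match "
                f"model signature {self.config.signature}"
            )
        parts = [self.time(conditions.t)]
        if self.cls is not None:
            parts.append(self.cls(conditions.c))
        if self.cont is not None:
            parts.append(self.cont(conditions.b))
        if len(parts) == 1:
            return parts[0]
        return T.concat(parts, axis=1)
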