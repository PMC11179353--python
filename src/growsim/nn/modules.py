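"""Layers and parameter containers built on the autodiff engine."""

from __future__ import annotations

import warnings

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Parameter(Tensor):
    """A tensor registered for optimization."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=T.DEFAULT_DTYPE), requires_grad=True)


class Module:
    """Minimal module container: parameter discovery, state dicts, modes."""

    def __init__(self):
        self.training = True

    def modules(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix=""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, mod in self.modules():
            yield from mod.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix=""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for name, mod in self.modules():
            yield from mod.named_buffers(prefix=f"{prefix}{name}.")

    def state_dict(self):
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({f"buf::{k}": v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state):
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buf::"):
                bufs[key[5:]][...] = value
            else:
                params[key].data[...] = value

    def train(self, mode=True):
        self.training = mode
        for _, m in self.modules():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng, fan_in, shape, gain=np.sqrt(2.0)):
    std = gain / np.sqrt(fan_in)
    return rng.normal(0.0, std, size=shape)


class Linear(Module):
    def __init__(self, in_features, out_features, rng, bias=True):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, in_features, (in_features, out_features), gain=1.0))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        out = T.matmul(x, self.weight)
        if self.bias is not None:
            out = out + T.reshape(self.bias, (1, -1))
        return out


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, rng, stride=1, padding=0, bias=True):
        super().__init__()
        self.stride, self.padding, self.kernel = stride, padding, kernel
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_kaiming(rng, fan_in, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.in_ch, self.out_ch = in_ch, out_ch

    def forward(self, x):
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.padding
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        cols = T.im2col(x, k, stride=s, pad=p)
        wf = T.reshape(self.weight, (self.out_ch, -1))
        out = T.reshape(T.matmul(wf, cols), (n, self.out_ch, ho, wo))
        if self.bias is not None:
            out = out + T.reshape(self.bias, (1, -1, 1, 1))
        return out


class Embedding(Module):
    """Lookup-table embedding for categorical conditions."""

    def __init__(self, num_embeddings, dim, rng):
        super().__init__()
        self.num_embeddings = num_embeddings
        # scale comparable to the MLP-embedded conditions, so no
        # condition type dominates the concatenated embedding a priori
        self.weight = Parameter(rng.normal(0.0, 0.3, size=(num_embeddings, dim)))

    def forward(self, idx):
        idx = np.asarray(idx)
        if idx.min() < 0 or idx.max() >= self.num_embeddings:
            raise IndexError(
                f"class index out of vocabulary [0, {self.num_embeddings})"
            )
        return T.getitem(self.weight, idx)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization without learnable affine."""

    def __init__(self, eps=1e-5):
        super().__init__()
        self.eps = eps

    def forward(self, x):
        mu = T.tmean(x, axis=(2, 3), keepdims=True)
        xc = x - mu
        var = T.tmean(xc * xc, axis=(2, 3), keepdims=True)
        return xc * T.pow_const(var + T.Tensor(self.eps), -0.5)


class ConditionalBatchNorm2d(Module):
    """Batch normalization whose affine scale/shift are linear in a
    condition embedding.

    The feature map is normalized with batch statistics, then scaled by
    ``1 + gamma(a)`` and shifted by ``beta(a)`` where both are linear
    projections of the concatenated condition embedding ``a`` (one
    projection pair per layer).  With zeroed projections the layer is
    plain batch normalization.
    """

    def __init__(self, channels, cond_dim, rng, eps=1e-5, momentum=0.1):
        super().__init__()
        self.channels = channels
        self.eps, self.momentum = eps, momentum
        self.gamma_w = Parameter(rng.normal(0.0, 0.02, size=(cond_dim, channels)))
        self.gamma_b = Parameter(np.ones(channels))
        self.beta_w = Parameter(rng.normal(0.0, 0.02, size=(cond_dim, channels)))
        self.beta_b = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=T.DEFAULT_DTYPE)
        self.running_var = np.ones(channels, dtype=T.DEFAULT_DTYPE)

    def forward(self, x, a):
        if self.training:
            if x.shape[0] == 1:
                warnings.warn(
                    "batch size 1 in training mode: batch statistics are degenerate",
                    RuntimeWarning,
                    stacklevel=2,
                )
            mu = T.tmean(x, axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = T.tmean(xc * xc, axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu.data.reshape(-1)).astype(self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var.data.reshape(-1)).astype(self.running_var.dtype)
            xhat = xc * T.pow_const(var + T.Tensor(self.eps), -0.5)
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).astype(self.running_var.dtype).reshape(1, -1, 1, 1)
            xhat = (x - T.Tensor(mu)) * T.Tensor(1.0 / sd)
        gamma = T.matmul(a, self.gamma_w) + T.reshape(self.gamma_b, (1, -1))
        beta = T.matmul(a, self.beta_w) + T.reshape(self.beta_b, (1, -1))
        n = x.shape[0]
        gamma = T.reshape(gamma, (n, self.channels, 1, 1))
        beta = T.reshape(beta, (n, self.channels, 1, 1))
        return xhat * gamma + beta

    def normalize_only(self, x):
        """Expose the pre-affine normalized map (testing hook)."""
        mu = T.tmean(x, axis=(0, 2, 3), keepdims=True)
        xc = x - mu
        var = T.tmean(xc * xc, axis=(0, 2, 3), keepdims=True)
        return xc * T.pow_const(var + T.Tensor(self.eps), -0.5)


def upsample2x(x):
    """Nearest-neighbor 2x spatial upsampling."""
    n, c, h, w = x.shape
    x = T.reshape(x, (n, c, h, 1, w, 1))
    x = T.broadcast_to(x, (n, c, h, 2, w, 2))
    return T.reshape(x, (n, c, 2 * h, 2 * w))


def global_avg_pool(x):
    return T.tmean(x, axis=(2, 3))
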