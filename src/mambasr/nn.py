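"""Minimal NumPy layer library with hand-derived reverse-mode gradients.

The super-resolution network is small enough to train on a CPU, so layers
are implemented directly on ndarrays: every layer caches what its backward
pass needs and exposes ``forward``/``backward``.  Arrays are NCHW
(batch, channel, height, width) throughout; all parameters are float64,
which keeps training bit-reproducible across runs on one machine.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Tuple

import numpy as np

from .selective_ssm import silu, _silu_grad

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "DepthwiseConv3x3",
    "Conv1x1",
    "ChannelLayerNorm",
    "SiLU",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base class: children and parameters are discovered by attribute walk."""

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Parameter]]:
        for name, attr in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(attr, Parameter):
                yield full, attr
            elif isinstance(attr, Module):
                yield from attr.named_parameters(full)
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")

    def parameters(self) -> List[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {name: p.value.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            if p.value.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.value[...] = state[name]

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())


def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _windows(x: np.ndarray, k: int) -> np.ndarray:
    """Sliding k x k windows of a padded NCHW array: (B, C, H, W, k, k)."""
    return np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))


class Conv2d(Module):
    """Stride-1 'same' convolution with an odd kernel."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        fan_in = c_in * kernel * kernel
        scale = 0.0 if zero_init else np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, 1.0, (c_out, c_in, kernel, kernel)) * scale)
        self.bias = Parameter(np.zeros(c_out))

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.kernel // 2
        win = _windows(_pad_hw(x, p), self.kernel)
        self._win = win
        return np.einsum("oikl,bihwkl->bohw", self.weight.value, win, optimize=True) \
            + self.bias.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        p = self.kernel // 2
        self.weight.grad += np.einsum("bohw,bihwkl->oikl", dy, self._win, optimize=True)
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        w_flip = self.weight.value[:, :, ::-1, ::-1]
        dy_win = _windows(_pad_hw(dy, p), self.kernel)
        return np.einsum("oikl,bohwkl->bihw", w_flip, dy_win, optimize=True)


class Conv1x1(Module):
    """Pointwise channel mixing (a linear layer applied per pixel)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        self.c_in, self.c_out = c_in, c_out
        scale = 0.0 if zero_init else np.sqrt(2.0 / c_in)
        self.weight = Parameter(rng.normal(0.0, 1.0, (c_out, c_in)) * scale)
        self.bias = Parameter(np.zeros(c_out))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.einsum("oc,bchw->bohw", self.weight.value, x, optimize=True) \
            + self.bias.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += np.einsum("bohw,bchw->oc", dy, self._x, optimize=True)
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        return np.einsum("oc,bohw->bchw", self.weight.value, dy, optimize=True)


class DepthwiseConv3x3(Module):
    """Per-channel 3x3 'same' convolution for local mixing."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.channels = channels
        self.weight = Parameter(rng.normal(0.0, 1.0, (channels, 3, 3)) * np.sqrt(2.0 / 9.0))
        self.bias = Parameter(np.zeros(channels))

    def forward(self, x: np.ndarray) -> np.ndarray:
        win = _windows(_pad_hw(x, 1), 3)
        self._win = win
        return np.einsum("ckl,bchwkl->bchw", self.weight.value, win, optimize=True) \
            + self.bias.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += np.einsum("bchw,bchwkl->ckl", dy, self._win, optimize=True)
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        w_flip = self.weight.value[:, ::-1, ::-1]
        dy_win = _windows(_pad_hw(dy, 1), 3)
        return np.einsum("ckl,bchwkl->bchw", w_flip, dy_win, optimize=True)


class ChannelLayerNorm(Module):
    """Layer normalization over the channel axis at each spatial position."""

    def __init__(self, channels: int, eps: float = 1e-6):
        self.channels = channels
        self.eps = eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._xhat, self._inv = xhat, inv
        return self.gamma.value[None, :, None, None] * xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        C = self.channels
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        return inv / C * (C * dxhat - dxhat.sum(axis=1, keepdims=True)
                          - xhat * (dxhat * xhat).sum(axis=1, keepdims=True))


class SiLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return silu(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * _silu_grad(self._x)
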