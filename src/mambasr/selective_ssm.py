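"""Selective state-space recurrence with zero-order-hold discretization.

Each head runs the diagonal linear recurrence

    h_t = exp(dt_t * A) h_{t-1} + Phi(dt_t, A) B_t u_t
    y_t = C_t h_t + D u_t

with ``A = diag(-exp(a_raw))`` (strictly negative, hence stable for any
finite ``a_raw``) and ``Phi(dt, A) = (exp(dt*A) - 1) / A`` elementwise.  The
step size ``dt_t`` is predicted per token by a lightweight two-layer channel
MLP with a softplus reparameterization, making the recurrence selective
(input-dependent).  ``B_t``/``C_t`` are input-dependent linear projections of
the token by default, with a static variant switchable in configuration.

Three routes to the same recurrence live here:

* :func:`selective_scan_reference` — a literal per-timestep, per-state loop,
  kept deliberately naive to serve as an oracle;
* :func:`selective_scan` — the vectorized single-head scan;
* :class:`StackedHeadParams` with :func:`scan_heads_forward` /
  :func:`scan_heads_backward` — the batched multi-head engine with analytic
  gradients, used by the trainable network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import special

from .scan_paths import ScanSet, deserialize, serialize

PHI_SERIES_THRESHOLD = 1e-6  # |dt*A| below this uses the 2-term Taylor fallback

__all__ = [
    "SSMHeadParams",
    "DeltaPredictor",
    "DiscretizedStep",
    "StackedHeadParams",
    "MergeParams",
    "make_A",
    "softplus",
    "predict_delta",
    "discretize",
    "selective_scan",
    "selective_scan_reference",
    "scan_heads_forward",
    "scan_heads_backward",
    "multi_head_scan",
]


def make_A(a_raw: np.ndarray) -> np.ndarray:
    """Diagonal of the state matrix, ``A = -exp(a_raw)`` (always < 0)."""
    a_raw = np.asarray(a_raw, dtype=float)
    return -np.exp(a_raw)


def softplus(x: np.ndarray) -> np.ndarray:
    """Numerically stable ``log(1 + exp(x))``."""
    x = np.asarray(x, dtype=float)
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def sigmoid(x: np.ndarray) -> np.ndarray:
    return special.expit(x)


def silu(x: np.ndarray) -> np.ndarray:
    return x * special.expit(x)


def _silu_grad(x: np.ndarray) -> np.ndarray:
    s = sigmoid(x)
    return s * (1.0 + x * (1.0 - s))


@dataclass
class DeltaPredictor:
    """Two-layer channel MLP emitting one pre-softplus step size per token."""

    W1: np.ndarray  # (hidden, C)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float


@dataclass
class SSMHeadParams:
    """Parameters of one selective-scan head over ``C`` channels.

    ``B``/``C_out`` may be static vectors of length ``N`` (shared across
    tokens) or selective projection matrices of shape ``(N, C)`` applied to
    each token.  ``D`` is the per-channel skip gain (scalar broadcasts).
    ``fixed_delta`` bypasses the step-size predictor, which is convenient for
    controlled experiments and oracle checks.
    """

    a_raw: np.ndarray
    B: np.ndarray
    C_out: np.ndarray
    D: np.ndarray | float
    delta_predictor: Optional[DeltaPredictor] = None
    fixed_delta: Optional[float | np.ndarray] = None

    def __post_init__(self) -> None:
        self.a_raw = np.atleast_1d(np.asarray(self.a_raw, dtype=float))
        self.B = np.asarray(self.B, dtype=float)
        self.C_out = np.asarray(self.C_out, dtype=float)
        if self.delta_predictor is None and self.fixed_delta is None:
            raise ValueError("need either a delta_predictor or fixed_delta")

    @property
    def state_size(self) -> int:
        return self.a_raw.shape[0]


@dataclass
class DiscretizedStep:
    """ZOH-discretized coefficients for one step size."""

    Abar: np.ndarray  # exp(dt * A), in (0, 1) for dt > 0
    Phi: np.ndarray  # (exp(dt * A) - 1) / A, >= 0 for dt >= 0


def predict_delta(u_t: np.ndarray, predictor: DeltaPredictor) -> float:
    """Positive step size ``softplus(mlp(u_t))`` for one token."""
    u_t = np.asarray(u_t, dtype=float)
    hidden = silu(predictor.W1 @ u_t + predictor.b1)
    return float(softplus(np.asarray(predictor.w2 @ hidden + predictor.b2)))


def _phi(z: np.ndarray, A: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Elementwise (exp(z) - 1)/A with z = delta*A; Taylor fallback near 0.

    The fallback ``delta * (1 + z/2)`` avoids the catastrophic cancellation of
    ``expm1(z)/A`` for |z| < PHI_SERIES_THRESHOLD.
    """
    small = np.abs(z) < PHI_SERIES_THRESHOLD
    out = np.where(small, delta * (1.0 + 0.5 * z), np.expm1(z) / np.where(small, 1.0, A))
    return out


def discretize(delta: float | np.ndarray, A_diag: np.ndarray) -> DiscretizedStep:
    """ZOH discretization of a diagonal negative state matrix."""
    A_diag = np.asarray(A_diag, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("delta must be non-negative")
    if np.any(A_diag >= 0):
        raise ValueError("A diagonal must be strictly negative")
    z = delta * A_diag
    return DiscretizedStep(Abar=np.exp(z), Phi=_phi(z, A_diag, delta))


def _head_deltas(u: np.ndarray, params: SSMHeadParams) -> np.ndarray:
    """Per-token step sizes (L,) for a (C, L) sequence."""
    L = u.shape[1]
    if params.fixed_delta is not None:
        return np.broadcast_to(np.asarray(params.fixed_delta, dtype=float), (L,)).astype(float)
    p = params.delta_predictor
    hidden = silu(p.W1 @ u + p.b1[:, None])  # (r, L)
    return softplus(p.w2 @ hidden + p.b2)


def _head_BC(u: np.ndarray, mat: np.ndarray, N: int) -> np.ndarray:
    """Broadcast a static (N,) vector or apply a selective (N, C) projection."""
    L = u.shape[1]
    mat = np.asarray(mat, dtype=float)
    if mat.ndim == 1:
        return np.broadcast_to(mat[:, None], (N, L))
    return mat @ u  # (N, L)


def selective_scan_reference(u: np.ndarray, params: SSMHeadParams) -> np.ndarray:
    """Literal per-timestep loop of the recurrence — the oracle.

    Deliberately scalar-at-heart: iterates tokens one by one, discretizing at
    each step, so it is independent of the vectorized path.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 2:
        raise ValueError("u must be (channels, length)")
    C, L = u.shape
    N = params.state_size
    A = make_A(params.a_raw)
    D = np.broadcast_to(np.asarray(params.D, dtype=float), (C,))
    y = np.zeros((C, L))
    h = np.zeros((C, N))
    for t in range(L):
        u_t = u[:, t]
        if params.fixed_delta is not None:
            dt = float(np.broadcast_to(np.asarray(params.fixed_delta, dtype=float), (L,))[t])
        else:
            dt = predict_delta(u_t, params.delta_predictor)
        step = discretize(dt, A)
        B_t = _head_BC(u_t[:, None], params.B, N)[:, 0]
        C_t = _head_BC(u_t[:, None], params.C_out, N)[:, 0]
        for c in range(C):
            h[c] = step.Abar * h[c] + step.Phi * B_t * u_t[c]
        y[:, t] = h @ C_t + D * u_t
    return y


def selective_scan(u: np.ndarray, params: SSMHeadParams) -> np.ndarray:
    """Vectorized single-head scan over a ``(C, L)`` token sequence."""
    u = np.asarray(u, dtype=float)
    if u.ndim != 2:
        raise ValueError("u must be (channels, length)")
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite values in scan input")
    C, L = u.shape
    N = params.state_size
    A = make_A(params.a_raw)
    D = np.broadcast_to(np.asarray(params.D, dtype=float), (C,))
    deltas = _head_deltas(u, params)  # (L,)
    z = deltas[None, :] * A[:, None]  # (N, L)
    Abar = np.exp(z)
    Phi = _phi(z, A[:, None], deltas[None, :])
    B_all = _head_BC(u, params.B, N)  # (N, L)
    C_all = _head_BC(u, params.C_out, N)  # (N, L)
    phiB = Phi * B_all  # (N, L)
    h = np.zeros((C, N))
    y = np.empty((C, L))
    for t in range(L):
        h = Abar[:, t] * h + np.outer(u[:, t], phiB[:, t])
        y[:, t] = h @ C_all[:, t]
    return y + D[:, None] * u


# ---------------------------------------------------------------------------
# Batched multi-head engine (training path)
# ---------------------------------------------------------------------------


@dataclass
class StackedHeadParams:
    """All heads' parameters stacked on a leading head axis ``m``.

    Selective mode stores projections ``W_B``/``W_C`` of shape ``(m, N, C)``;
    static mode stores vectors ``B_static``/``C_static`` of shape ``(m, N)``.
    """

    a_raw: np.ndarray  # (m, N)
    D: np.ndarray  # (m, C)
    W1: np.ndarray  # (m, r, C) delta-MLP layer 1
    b1: np.ndarray  # (m, r)
    w2: np.ndarray  # (m, r) delta-MLP layer 2
    b2: np.ndarray  # (m,)
    W_B: Optional[np.ndarray] = None  # (m, N, C)
    W_C: Optional[np.ndarray] = None  # (m, N, C)
    B_static: Optional[np.ndarray] = None  # (m, N)
    C_static: Optional[np.ndarray] = None  # (m, N)

    @property
    def selective(self) -> bool:
        return self.W_B is not None

    @property
    def n_heads(self) -> int:
        return self.a_raw.shape[0]

    @property
    def state_size(self) -> int:
        return self.a_raw.shape[1]


@dataclass
class _ScanCache:
    u: np.ndarray
    u_T: np.ndarray
    Abar: np.ndarray
    Abar_T: np.ndarray
    Phi: np.ndarray
    z: np.ndarray
    deltas: np.ndarray
    pre2: np.ndarray
    pre1: np.ndarray
    hidden: np.ndarray
    Bsel: np.ndarray
    Csel: np.ndarray
    Csel_T: np.ndarray
    phiB_T: np.ndarray
    h_all: np.ndarray
    A: np.ndarray


# ---- fused recurrence cores (numba-jitted when available) -----------------
# Layouts are time-major per (batch, head): u_T (B, m, L, C); Abar_T, phiB_T,
# Csel_T (B, m, L, N); h_all (B, m, L, C, N).  The fused kernels make a
# single pass over the big arrays, which is what keeps CPU training viable.


def _fwd_core_numpy(u_T, Abar_T, phiB_T, Csel_T, D):
    B, m, L, C = u_T.shape
    N = Abar_T.shape[3]
    h_all = np.empty((B, m, L, C, N))
    h = np.zeros((B, m, C, N))
    for t in range(L):
        np.multiply(h, Abar_T[:, :, t, None, :], out=h)
        h += u_T[:, :, t, :, None] * phiB_T[:, :, t, None, :]
        h_all[:, :, t] = h
    y = np.einsum("bmltn,bmln->bmlt", h_all, Csel_T, optimize=True) \
        + D[None, :, None, :] * u_T
    return y, h_all


def _bwd_core_numpy(dy_T, u_T, Abar_T, phiB_T, Csel_T, h_all, D):
    B, m, L, C = u_T.shape
    N = Abar_T.shape[3]
    dD = np.einsum("bmlc,bmlc->mc", dy_T, u_T, optimize=True)
    dCsel = np.einsum("bmlcn,bmlc->bmln", h_all, dy_T, optimize=True)
    g_all = np.empty_like(h_all)
    g = dy_T[:, :, L - 1, :, None] * Csel_T[:, :, L - 1, None, :]
    g_all[:, :, L - 1] = g
    for t in range(L - 2, -1, -1):
        np.multiply(g, Abar_T[:, :, t + 1, None, :], out=g)
        g += dy_T[:, :, t, :, None] * Csel_T[:, :, t, None, :]
        g_all[:, :, t] = g
    dAbar = np.empty((B, m, L, N))
    dAbar[:, :, 0] = 0.0
    np.einsum("bmlcn,bmlcn->bmln", g_all[:, :, 1:], h_all[:, :, :-1],
              out=dAbar[:, :, 1:], optimize=True)
    dphiB = np.einsum("bmlcn,bmlc->bmln", g_all, u_T, optimize=True)
    du = np.einsum("bmlcn,bmln->bmlc", g_all, phiB_T, optimize=True) \
        + D[None, :, None, :] * dy_T
    return du, dAbar, dphiB, dCsel, dD


try:  # pragma: no cover - exercised indirectly
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None

if njit is not None:

    @njit(cache=True)
    def _fwd_core_numba(u_T, Abar_T, phiB_T, Csel_T, D):
        B, m, L, C = u_T.shape
        N = Abar_T.shape[3]
        y = np.empty((B, m, L, C))
        h_all = np.empty((B, m, L, C, N))
        for b in range(B):
            for mi in range(m):
                h = np.zeros((C, N))
                for t in range(L):
                    for c in range(C):
                        ut = u_T[b, mi, t, c]
                        acc = 0.0
                        for n in range(N):
                            hv = Abar_T[b, mi, t, n] * h[c, n] + phiB_T[b, mi, t, n] * ut
                            h[c, n] = hv
                            h_all[b, mi, t, c, n] = hv
                            acc += hv * Csel_T[b, mi, t, n]
                        y[b, mi, t, c] = acc + D[mi, c] * ut
        return y, h_all

    @njit(cache=True)
    def _bwd_core_numba(dy_T, u_T, Abar_T, phiB_T, Csel_T, h_all, D):
        B, m, L, C = u_T.shape
        N = Abar_T.shape[3]
        du = np.empty((B, m, L, C))
        dAbar = np.zeros((B, m, L, N))
        dphiB = np.zeros((B, m, L, N))
        dCsel = np.zeros((B, m, L, N))
        dD = np.zeros((m, C))
        for b in range(B):
            for mi in range(m):
                g = np.zeros((C, N))
                for t in range(L - 1, -1, -1):
                    for c in range(C):
                        dyv = dy_T[b, mi, t, c]
                        ut = u_T[b, mi, t, c]
                        dD[mi, c] += dyv * ut
                        duv = D[mi, c] * dyv
                        for n in range(N):
                            if t < L - 1:
                                gv = g[c, n] * Abar_T[b, mi, t + 1, n] \
                                    + dyv * Csel_T[b, mi, t, n]
                            else:
                                gv = dyv * Csel_T[b, mi, t, n]
                            g[c, n] = gv
                            if t > 0:
                                dAbar[b, mi, t, n] += gv * h_all[b, mi, t - 1, c, n]
                            dphiB[b, mi, t, n] += gv * ut
                            dCsel[b, mi, t, n] += h_all[b, mi, t, c, n] * dyv
                            duv += gv * phiB_T[b, mi, t, n]
                        du[b, mi, t, c] = duv
        return du, dAbar, dphiB, dCsel, dD

    _fwd_core, _bwd_core = _fwd_core_numba, _bwd_core_numba
else:  # pragma: no cover
    _fwd_core, _bwd_core = _fwd_core_numpy, _bwd_core_numpy


def scan_heads_forward(u: np.ndarray, params: StackedHeadParams) -> Tuple[np.ndarray, _ScanCache]:
    """Run all heads on ``u`` of shape ``(batch, m, C, L)``; returns ``y`` and cache."""
    Bsz, m, C, L = u.shape
    N = params.state_size
    A = make_A(params.a_raw)  # (m, N)

    pre1 = np.einsum("mrc,bmcl->bmrl", params.W1, u, optimize=True) + params.b1[None, :, :, None]
    hidden = silu(pre1)
    pre2 = np.einsum("mr,bmrl->bml", params.w2, hidden, optimize=True) + params.b2[None, :, None]
    deltas = softplus(pre2)  # (B, m, L)

    z = deltas[:, :, None, :] * A[None, :, :, None]  # (B, m, N, L)
    Abar = np.exp(z)
    Phi = _phi(z, A[None, :, :, None], deltas[:, :, None, :])

    if params.selective:
        Bsel = np.einsum("mnc,bmcl->bmnl", params.W_B, u, optimize=True)
        Csel = np.einsum("mnc,bmcl->bmnl", params.W_C, u, optimize=True)
    else:
        Bsel = np.broadcast_to(params.B_static[None, :, :, None], (Bsz, m, N, L)).copy()
        Csel = np.broadcast_to(params.C_static[None, :, :, None], (Bsz, m, N, L)).copy()

    u_T = np.ascontiguousarray(u.transpose(0, 1, 3, 2))  # (B, m, L, C)
    Abar_T = np.ascontiguousarray(Abar.transpose(0, 1, 3, 2))  # (B, m, L, N)
    phiB_T = np.ascontiguousarray((Phi * Bsel).transpose(0, 1, 3, 2))
    Csel_T = np.ascontiguousarray(Csel.transpose(0, 1, 3, 2))
    y_T, h_all = _fwd_core(u_T, Abar_T, phiB_T, Csel_T, params.D)
    y = np.ascontiguousarray(y_T.transpose(0, 1, 3, 2))  # (B, m, C, L)
    cache = _ScanCache(u=u, u_T=u_T, Abar=Abar, Abar_T=Abar_T, Phi=Phi, z=z,
                       deltas=deltas, pre2=pre2, pre1=pre1, hidden=hidden,
                       Bsel=Bsel, Csel=Csel, Csel_T=Csel_T, phiB_T=phiB_T,
                       h_all=h_all, A=A)
    return y, cache


def scan_heads_backward(dy: np.ndarray, params: StackedHeadParams, cache: _ScanCache):
    """Analytic reverse pass of :func:`scan_heads_forward`.

    Returns ``(du, grads)`` where ``grads`` maps parameter names to gradient
    arrays matching :class:`StackedHeadParams`.
    """
    u, Abar, Phi, Csel, Bsel = cache.u, cache.Abar, cache.Phi, cache.Csel, cache.Bsel
    deltas, A, z = cache.deltas, cache.A, cache.z
    Bsz, m, C, L = u.shape
    N = params.state_size

    dy_T = np.ascontiguousarray(dy.transpose(0, 1, 3, 2))  # (B, m, L, C)
    du_T, dAbar_T, dphiB_T, dCsel_T, dD = _bwd_core(
        dy_T, cache.u_T, cache.Abar_T, cache.phiB_T, cache.Csel_T,
        cache.h_all, params.D)
    du = np.ascontiguousarray(du_T.transpose(0, 1, 3, 2))  # (B, m, C, L)
    dAbar = dAbar_T.transpose(0, 1, 3, 2)
    dphiB = dphiB_T.transpose(0, 1, 3, 2)
    dCsel = dCsel_T.transpose(0, 1, 3, 2)

    dPhi = dphiB * Bsel
    dBsel = dphiB * Phi

    # Phi = (exp(z) - 1)/A:  dPhi/ddelta = Abar;  dPhi/dA = (delta*Abar - Phi)/A
    A_b = A[None, :, :, None]
    delta_b = deltas[:, :, None, :]
    small = np.abs(z) < PHI_SERIES_THRESHOLD
    dPhi_dA = np.where(small, delta_b ** 2 * (0.5 + z / 3.0),
                       (delta_b * Abar - Phi) / np.where(small, 1.0, A_b))
    ddelta = ((dAbar * Abar * A_b) + dPhi * Abar).sum(axis=2)  # (B, m, L)
    dA = np.einsum("bmnl->mn", dAbar * delta_b * Abar + dPhi * dPhi_dA, optimize=True)
    da_raw = dA * A  # chain through A = -exp(a_raw)

    grads = {"a_raw": da_raw, "D": dD}
    if params.selective:
        grads["W_B"] = np.einsum("bmnl,bmcl->mnc", dBsel, u, optimize=True)
        grads["W_C"] = np.einsum("bmnl,bmcl->mnc", dCsel, u, optimize=True)
        du += np.einsum("bmnl,mnc->bmcl", dBsel, params.W_B, optimize=True)
        du += np.einsum("bmnl,mnc->bmcl", dCsel, params.W_C, optimize=True)
    else:
        grads["B_static"] = np.einsum("bmnl->mn", dBsel, optimize=True)
        grads["C_static"] = np.einsum("bmnl->mn", dCsel, optimize=True)

    # delta-predictor MLP
    dpre2 = ddelta * sigmoid(cache.pre2)  # softplus'
    grads["w2"] = np.einsum("bml,bmrl->mr", dpre2, cache.hidden, optimize=True)
    grads["b2"] = np.einsum("bml->m", dpre2, optimize=True)
    dhidden = dpre2[:, :, None, :] * params.w2[None, :, :, None]
    dpre1 = dhidden * _silu_grad(cache.pre1)
    grads["W1"] = np.einsum("bmrl,bmcl->mrc", dpre1, u, optimize=True)
    grads["b1"] = np.einsum("bmrl->mr", dpre1, optimize=True)
    du += np.einsum("bmrl,mrc->bmcl", dpre1, params.W1, optimize=True)
    return du, grads


# ---------------------------------------------------------------------------
# Spec-level multi-head scan over a feature grid
# ---------------------------------------------------------------------------


@dataclass
class MergeParams:
    """Merge of head outputs: LayerNorm, optional SiLU gate, linear projection.

    Head outputs are concatenated channelwise (``m*C`` channels per token),
    layer-normalized across that axis, optionally multiplied by a SiLU gate
    computed from the module input, and projected back to ``C`` channels.
    """

    ln_gamma: np.ndarray  # (m*C,)
    ln_beta: np.ndarray  # (m*C,)
    W_proj: np.ndarray  # (C, m*C)
    b_proj: np.ndarray  # (C,)
    W_gate: Optional[np.ndarray] = None  # (m*C, C); None disables gating
    b_gate: Optional[np.ndarray] = None  # (m*C,)


def _layernorm_lastdim_first(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
                             eps: float = 1e-6) -> np.ndarray:
    """LayerNorm over the leading channel axis of a (C, L) array."""
    mu = x.mean(axis=0, keepdims=True)
    var = x.var(axis=0, keepdims=True)
    return gamma[:, None] * (x - mu) / np.sqrt(var + eps) + beta[:, None]


def multi_head_scan(features: np.ndarray, scan_set: ScanSet,
                    heads: List[SSMHeadParams], merge: MergeParams) -> np.ndarray:
    """Run one scan per head over a ``(C, H, W)`` grid and merge the outputs.

    Head ``i`` serializes the grid along ``scan_set.orders[i]``, runs the
    selective recurrence, and deserializes by the inverse order, so every
    head output lives on the original grid.  Outputs are concatenated
    channelwise, layer-normalized, optionally gated by
    ``silu(W_gate @ token)`` of the *input* token, and linearly projected
    back to the model dimension.
    """
    features = np.asarray(features, dtype=float)
    if len(heads) != scan_set.scan_count:
        raise ValueError(
            f"{len(heads)} heads but scan set has {scan_set.scan_count} orders")
    C, H, W = features.shape
    outs = []
    for head, order in zip(heads, scan_set.orders):
        seq = serialize(features, order)
        y = selective_scan(seq, head)
        outs.append(deserialize(y, order))
    merged = np.concatenate(outs, axis=0).reshape(len(heads) * C, H * W)
    merged = _layernorm_lastdim_first(merged, merge.ln_gamma, merge.ln_beta)
    if merge.W_gate is not None:
        gate = silu(merge.W_gate @ features.reshape(C, H * W) + merge.b_gate[:, None])
        merged = merged * gate
    out = merge.W_proj @ merged + merge.b_proj[:, None]
    return out.reshape(C, H, W)
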