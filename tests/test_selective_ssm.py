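"""Selective SSM: discretization, recurrence, oracle equivalence, gradients."""

import numpy as np
import pytest

from mambasr import selective_ssm as ss
from mambasr.scan_paths import build_scan_order, build_scan_set
from mambasr.selective_ssm import (DeltaPredictor, MergeParams, SSMHeadParams,
                                   StackedHeadParams, discretize, make_A,
                                   multi_head_scan, predict_delta,
                                   scan_heads_backward, scan_heads_forward,
                                   selective_scan, selective_scan_reference,
                                   softplus)


def test_make_A_examples():
    assert make_A(0.0) == pytest.approx(-1.0)
    assert make_A(np.log(2.0)) == pytest.approx(-2.0)
    np.testing.assert_allclose(make_A([0.0, np.log(3.0)]), [-1.0, -3.0])
    assert np.all(make_A(np.random.default_rng(0).normal(0, 3, 50)) < 0)


def test_predict_delta_softplus_reparameterization():
    # identity-ish MLP so the pre-softplus output is controllable
    p = DeltaPredictor(W1=np.zeros((2, 3)), b1=np.zeros(2), w2=np.zeros(2), b2=0.0)
    assert predict_delta(np.zeros(3), p) == pytest.approx(np.log(2.0))
    p = DeltaPredictor(W1=np.zeros((2, 3)), b1=np.zeros(2), w2=np.zeros(2), b2=5.0)
    assert predict_delta(np.zeros(3), p) == pytest.approx(5.006715348489118)
    p = DeltaPredictor(W1=np.zeros((2, 3)), b1=np.zeros(2), w2=np.zeros(2), b2=-40.0)
    assert 0.0 < predict_delta(np.zeros(3), p) < 1e-15


def test_discretize_examples():
    step = discretize(0.0, np.array([-1.0, -2.0]))
    np.testing.assert_allclose(step.Abar, 1.0)
    np.testing.assert_allclose(step.Phi, 0.0)
    step = discretize(1.0, np.array([-1.0]))
    np.testing.assert_allclose(step.Abar, np.exp(-1.0))
    np.testing.assert_allclose(step.Phi, 1.0 - np.exp(-1.0))
    step = discretize(1e-8, np.array([-1.0]))
    assert step.Phi[0] / 1e-8 == pytest.approx(1.0, abs=1e-7)


def test_discretize_bounds():
    rng = np.random.default_rng(1)
    for _ in range(20):
        a = make_A(rng.normal(0, 2, 6))
        dt = float(rng.uniform(1e-4, 3.0))
        step = discretize(dt, a)
        assert np.all((step.Abar > 0) & (step.Abar < 1))
        assert np.all(step.Phi >= 0)


@pytest.mark.parametrize("delta", [1e-3, 1e-5])
def test_small_step_phi_error_bound(delta):
    """|Phi(dt,A) - dt| <= dt^2 max|A|/2 * exp(dt max|A|), elementwise."""
    A = make_A(np.linspace(-1, 1.5, 7))
    step = discretize(delta, A)
    bound = delta ** 2 * np.abs(A).max() / 2.0 * np.exp(delta * np.abs(A).max())
    assert np.max(np.abs(step.Phi - delta)) <= bound


def test_selective_scan_hand_unrolled():
    p = SSMHeadParams(a_raw=[0.0], B=[1.0], C_out=[1.0], D=0.0, fixed_delta=1.0)
    u = np.array([[1.0, 0.0, 0.0]])
    e = np.exp(-1.0)
    expected = [[1 - e, e * (1 - e), e ** 2 * (1 - e)]]
    np.testing.assert_allclose(selective_scan(u, p), expected, atol=1e-12)
    np.testing.assert_allclose(selective_scan_reference(u, p), expected, atol=1e-12)


def test_selective_scan_pure_skip_and_zero(random_head_params):
    p = SSMHeadParams(a_raw=[0.0, 0.1], B=[1.0, 1.0], C_out=[0.0, 0.0], D=1.0,
                      fixed_delta=0.5)
    u = np.random.default_rng(2).normal(size=(3, 9))
    np.testing.assert_array_equal(selective_scan(u, p), u)
    p2 = random_head_params(3, 4)
    assert np.all(selective_scan(np.zeros((3, 9)), p2) == 0.0)


def test_selective_scan_rejects_non_finite(random_head_params):
    p = random_head_params(2, 3)
    u = np.ones((2, 5))
    u[0, 2] = np.nan
    with pytest.raises(ValueError):
        selective_scan(u, p)


def test_oracle_equivalence_randomized(random_head_params):
    """Vectorized scan equals the literal per-step loop to <= 1e-10."""
    rng = np.random.default_rng(42)
    worst = 0.0
    for trial in range(60):
        C = int(rng.integers(1, 5))
        L = int(rng.integers(1, 33))
        N = int(rng.integers(1, 9))
        p = random_head_params(C, N, seed=trial)
        u = rng.normal(0, 1, (C, L))
        err = np.max(np.abs(selective_scan(u, p) - selective_scan_reference(u, p)))
        worst = max(worst, err)
    assert worst <= 1e-10


def test_homogeneous_decay_stability(random_head_params):
    """With u = 0 the hidden state norm decays monotonically for any finite a_raw."""
    rng = np.random.default_rng(3)
    for trial in range(10):
        N = 6
        A = make_A(rng.normal(0, 1.5, N))
        dt = float(rng.uniform(0.01, 2.0))
        step = discretize(dt, A)
        h = rng.normal(0, 5, N)
        prev = np.linalg.norm(h)
        for _ in range(20):
            h = step.Abar * h
            norm = np.linalg.norm(h)
            assert norm < prev
            prev = norm


def test_engine_cores_agree():
    """numba-jitted fused kernels match the pure-NumPy reference cores."""
    rng = np.random.default_rng(7)
    B, m, L, C, N = 2, 3, 11, 4, 5
    u_T = rng.normal(size=(B, m, L, C))
    Abar_T = rng.uniform(0.1, 0.9, (B, m, L, N))
    phiB_T = rng.normal(size=(B, m, L, N))
    Csel_T = rng.normal(size=(B, m, L, N))
    D = rng.normal(size=(m, C))
    y1, h1 = ss._fwd_core(u_T, Abar_T, phiB_T, Csel_T, D)
    y2, h2 = ss._fwd_core_numpy(u_T, Abar_T, phiB_T, Csel_T, D)
    np.testing.assert_allclose(y1, y2, atol=1e-12)
    np.testing.assert_allclose(h1, h2, atol=1e-12)
    dy = rng.normal(size=(B, m, L, C))
    out1 = ss._bwd_core(dy, u_T, Abar_T, phiB_T, Csel_T, h1, D)
    out2 = ss._bwd_core_numpy(dy, u_T, Abar_T, phiB_T, Csel_T, h2, D)
    for a, b in zip(out1, out2):
        np.testing.assert_allclose(a, b, atol=1e-10)


def _stacked(rng, m, C, N, r=3, selective=True):
    kw = dict(a_raw=rng.normal(0, .5, (m, N)), D=rng.normal(0, .5, (m, C)),
              W1=rng.normal(0, .5, (m, r, C)), b1=rng.normal(0, .1, (m, r)),
              w2=rng.normal(0, .5, (m, r)), b2=rng.normal(0, .1, m))
    if selective:
        kw.update(W_B=rng.normal(0, .5, (m, N, C)), W_C=rng.normal(0, .5, (m, N, C)))
    else:
        kw.update(B_static=rng.normal(0, .5, (m, N)), C_static=rng.normal(0, .5, (m, N)))
    return StackedHeadParams(**kw)


@pytest.mark.parametrize("selective", [True, False])
def test_engine_gradients_finite_difference(selective):
    rng = np.random.default_rng(11)
    B, m, C, N, L = 2, 2, 3, 4, 7
    params = _stacked(rng, m, C, N, selective=selective)
    u = rng.normal(size=(B, m, C, L))

    def loss(u_):
        y_, _ = scan_heads_forward(u_, params)
        return 0.5 * np.sum(y_ ** 2)

    y, cache = scan_heads_forward(u, params)
    du, grads = scan_heads_backward(y, params, cache)
    eps = 1e-6
    for k in range(15):
        idx = tuple(np.random.default_rng(k).integers(0, s) for s in u.shape)
        up, um = u.copy(), u.copy()
        up[idx] += eps
        um[idx] -= eps
        num = (loss(up) - loss(um)) / (2 * eps)
        assert du[idx] == pytest.approx(num, rel=1e-4, abs=1e-7)
    names = ["a_raw", "D", "W1", "b1", "w2", "b2"]
    names += ["W_B", "W_C"] if selective else ["B_static", "C_static"]
    for name in names:
        arr = getattr(params, name)
        for k in range(3):
            idx = tuple(np.random.default_rng(100 + k).integers(0, s) for s in arr.shape)
            arr[idx] += eps
            lp = loss(u)
            arr[idx] -= 2 * eps
            lm = loss(u)
            arr[idx] += eps
            assert grads[name][idx] == pytest.approx((lp - lm) / (2 * eps),
                                                     rel=1e-4, abs=1e-7)


def _merge(rng, m, C, gated=True):
    mC = m * C
    return MergeParams(ln_gamma=np.ones(mC), ln_beta=np.zeros(mC),
                       W_proj=rng.normal(0, 0.3, (C, mC)), b_proj=np.zeros(C),
                       W_gate=rng.normal(0, 0.3, (mC, C)) if gated else None,
                       b_gate=np.zeros(mC) if gated else None)


def test_multi_head_scan_shapes_and_skip(random_head_params, rng):
    scan_set = build_scan_set(4, 4, "diagonal", 8)
    heads = [random_head_params(3, 4, seed=i) for i in range(8)]
    x = rng.normal(size=(3, 4, 4))
    out = multi_head_scan(x, scan_set, heads, _merge(rng, 8, 3))
    assert out.shape == x.shape

    # one skip-only head: scan output equals the input features, so the module
    # reduces to LN + gate + projection of the input itself
    one = build_scan_set(4, 4, "diagonal", 4)
    one = type(one)(orders=one.orders[:1], scan_type="diagonal", scan_count=1)
    skip = SSMHeadParams(a_raw=[0.0], B=[1.0], C_out=[0.0], D=1.0, fixed_delta=1.0)
    merge = _merge(rng, 1, 3)
    got = multi_head_scan(x, one, [skip], merge)
    flat = x.reshape(3, 16)
    ln = ss._layernorm_lastdim_first(flat, merge.ln_gamma, merge.ln_beta)
    gate = ss.silu(merge.W_gate @ flat + merge.b_gate[:, None])
    expected = (merge.W_proj @ (ln * gate) + merge.b_proj[:, None]).reshape(3, 4, 4)
    np.testing.assert_allclose(got, expected, atol=1e-12)


def test_multi_head_scan_head_count_mismatch(random_head_params, rng):
    scan_set = build_scan_set(4, 4, "diagonal", 8)
    with pytest.raises(ValueError):
        multi_head_scan(rng.normal(size=(2, 4, 4)), scan_set,
                        [random_head_params(2, 3)], _merge(rng, 8, 2))


def test_head_permutation_equivariance(random_head_params, rng):
    """Permuting heads together with their orders permutes the per-head scan
    outputs (the channel-concat order) and changes nothing else."""
    x = rng.normal(size=(3, 5, 4))
    orders = [build_scan_order(5, 4, k, d) for k in ("horizontal", "antidiagonal")
              for d in ("forward", "reverse")]
    heads = [random_head_params(3, 4, seed=10 + i) for i in range(4)]

    from mambasr.scan_paths import deserialize, serialize

    def head_outputs(hs, os):
        return [deserialize(selective_scan(serialize(x, o), h), o)
                for h, o in zip(hs, os)]

    base = head_outputs(heads, orders)
    perm = [2, 0, 3, 1]
    permuted = head_outputs([heads[i] for i in perm], [orders[i] for i in perm])
    for j, i in enumerate(perm):
        np.testing.assert_allclose(permuted[j], base[i], atol=1e-12)
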