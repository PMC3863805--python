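import numpy as np
import pytest
from scipy import linalg, stats

from multimarker import (
    CausalPrior,
    WeightVector,
    noncentrality_opt,
    pvalue_bonferroni,
    pvalue_linear,
    pvalue_zmax,
    weights_optimal,
    weights_prior,
)
from multimarker.combiners import mvn_cdf

from conftest import random_corr


def test_zmax_single_marker_reduces_to_normal_p():
    res = pvalue_zmax(np.array([1.959964]), np.eye(1))
    assert res.p_value == pytest.approx(0.05, abs=1e-4)


def test_zmax_perfect_correlation_collapses_to_one_marker():
    r = np.ones((5, 5))
    res = pvalue_zmax(np.full(5, 1.959964), r)
    assert res.p_value == pytest.approx(0.05, abs=2e-3)


def test_zmax_independent_closed_forms():
    """At R = I both p-value modes have exact closed forms."""
    z = np.array([2.5, -1.0, 0.3])
    phi = stats.norm.cdf(2.5)
    printed = pvalue_zmax(z, np.eye(3), mode="printed").p_value
    rect = pvalue_zmax(z, np.eye(3), mode="rectangle").p_value
    assert printed == pytest.approx(2 * (1 - phi**3), abs=2e-4)
    assert rect == pytest.approx(1 - (2 * phi - 1) ** 3, abs=2e-4)
    assert printed >= rect - 5e-4  # two-tail double counting


def test_zmax_monotone_in_statistic():
    rng = np.random.default_rng(5)
    r = random_corr(4, rng)
    ps = [pvalue_zmax(np.full(4, z), r, seed=1).p_value for z in (1.0, 2.0, 3.0)]
    assert ps[0] > ps[1] > ps[2]


def test_bonferroni_closed_forms():
    assert pvalue_bonferroni(np.array([1.959964])).p_value == pytest.approx(
        0.05, abs=1e-6
    )
    res = pvalue_bonferroni(np.full(5, 1.959964))
    assert res.p_value == pytest.approx(0.25, abs=1e-6)
    assert pvalue_bonferroni(np.array([0.1, 0.2])).p_value == 1.0


def test_bonferroni_dominates_exact_rectangle_p():
    rng = np.random.default_rng(11)
    for _ in range(25):
        k = int(rng.integers(2, 6))
        r = random_corr(k, rng)
        z = rng.normal(size=k) * 1.5
        bonf = pvalue_bonferroni(z).p_value
        rect = pvalue_zmax(z, r, mode="rectangle", maxpts=20_000, seed=2).p_value
        assert bonf >= rect - 5e-3


def test_optimal_weights_eigen_equals_closed_form():
    rng = np.random.default_rng(7)
    for _ in range(100):
        k = int(rng.integers(2, 11))
        r = random_corr(k, rng)
        delta = rng.normal(size=k)
        w1 = weights_optimal(delta, r, method="solve").weights
        w2 = weights_optimal(delta, r, method="eigen").weights
        np.testing.assert_allclose(w1, w2, atol=1e-8)
        assert w1 @ r @ w1 == pytest.approx(1.0, abs=1e-8)
        assert w1 @ delta > 0


def test_optimal_weights_special_cases():
    rng = np.random.default_rng(8)
    r = random_corr(5, rng)
    # constant Delta: L = R^{-1} 1 / sqrt(sum of R^{-1} entries)
    w = weights_optimal(np.ones(5), r).weights
    rinv1 = np.linalg.solve(r, np.ones(5))
    np.testing.assert_allclose(w, rinv1 / np.sqrt(rinv1.sum()), atol=1e-6)
    # equal MAFs: Delta proportional to the causal column -> causal indicator
    delta = r[:, 2].copy()
    w2 = weights_optimal(delta, r).weights
    e = np.zeros(5)
    e[2] = 1.0
    np.testing.assert_allclose(w2, e, atol=1e-6)


def test_optimal_weights_are_maximal():
    """No random competitor with unit null variance beats L_opt."""
    rng = np.random.default_rng(9)
    r = random_corr(5, rng)
    delta = rng.normal(size=5)
    w = weights_optimal(delta, r).weights
    best = (w @ delta) ** 2
    m = rng.normal(size=(1000, 5))
    m /= np.sqrt(np.einsum("ij,jk,ik->i", m, r, m))[:, None]
    assert ((m @ delta) ** 2 <= best + 1e-9).all()


def test_weights_invariant_to_delta_scale():
    rng = np.random.default_rng(10)
    r = random_corr(4, rng)
    delta = rng.normal(size=4)
    w1 = weights_optimal(delta, r).weights
    w2 = weights_optimal(37.5 * delta, r).weights
    np.testing.assert_allclose(w1, w2, atol=1e-10)


def test_prior_point_mass_reproduces_optimal():
    rng = np.random.default_rng(12)
    r = random_corr(6, rng)
    b = rng.uniform(5, 15, size=6)
    w_opt = weights_optimal(r[:, 3] * b, r).weights
    w_pri = weights_prior(CausalPrior.point(6, 4), r, b).weights
    np.testing.assert_allclose(w_pri, w_opt, atol=1e-8)


def test_prior_uniform_two_independent_markers():
    w = weights_prior(CausalPrior.uniform(2), np.eye(2), np.ones(2)).weights
    np.testing.assert_allclose(np.abs(w), np.full(2, 1 / np.sqrt(2)), atol=1e-10)


def test_prior_weights_match_independent_eigensolver():
    """Re-derive the agnostic weights with an independent dense eigen-route."""
    k, rho = 5, 0.4
    r = np.full((k, k), rho)
    np.fill_diagonal(r, 1.0)
    b = np.full(k, 7.0)
    w = weights_prior(CausalPrior.uniform(k), r, b).weights

    # independent construction: explicit H, scipy.linalg.eigh
    ew, ev = linalg.eigh(r)
    r_half_inv = ev @ np.diag(1 / np.sqrt(ew)) @ ev.T
    h = np.zeros((k, k))
    for j in range(k):
        d = r[:, j] * b
        v = r_half_inv @ d
        h += np.outer(v, v) / k
    lead = linalg.eigh(h)[1][:, -1]
    w_ref = r_half_inv @ lead
    w_ref /= np.sqrt(w_ref @ r @ w_ref)
    if w_ref @ (r @ b) < 0:
        w_ref = -w_ref
    np.testing.assert_allclose(w, w_ref, atol=1e-8)


def test_prior_validation():
    with pytest.raises(ValueError, match="sum"):
        CausalPrior(np.array([0.5, 0.4]))
    with pytest.raises(ValueError, match="nonnegative"):
        CausalPrior(np.array([1.5, -0.5]))


def test_linear_pvalue_and_normalization_guard():
    w = WeightVector(weights=np.array([1.0]), normalization=1.0)
    res = pvalue_linear(np.array([1.959964]), w, np.eye(1))
    assert res.p_value == pytest.approx(0.05, abs=1e-6)

    bad = WeightVector(weights=np.array([2.0, 0.0]), normalization=4.0)
    with pytest.raises(ValueError, match="renormalize|rescale"):
        pvalue_linear(np.array([1.0, 1.0]), bad, np.eye(2))


def test_noncentrality_identities():
    rng = np.random.default_rng(13)
    r = random_corr(4, rng)
    delta = rng.normal(size=4)
    assert noncentrality_opt(np.zeros(4), r) == pytest.approx(0.0)
    assert noncentrality_opt(delta, np.eye(4)) == pytest.approx(
        (delta**2).sum(), rel=1e-7
    )
    w = weights_optimal(delta, r).weights
    assert noncentrality_opt(delta, r) == pytest.approx((w @ delta) ** 2, rel=1e-7)


def test_noncentrality_matches_simulated_mean():
    """Mean of L'Z over simulated alternatives equals sqrt(Delta' R^-1 Delta)."""
    rng = np.random.default_rng(14)
    r = random_corr(3, rng)
    delta = np.array([0.8, 0.3, -0.2])
    w = weights_optimal(delta, r).weights
    chol = np.linalg.cholesky(r)
    z = delta + rng.standard_normal((50_000, 3)) @ chol.T
    ncp = noncentrality_opt(delta, r)
    assert (z @ w).mean() == pytest.approx(np.sqrt(ncp), abs=3.5 / np.sqrt(50_000))


def test_degenerate_duplicated_markers_agree_with_single():
    """With identical genotype columns every non-Bonferroni test collapses
    to the single-marker test, replicate by replicate."""
    rng = np.random.default_rng(15)
    r = np.ones((4, 4))
    b = np.full(4, 5.0)
    for _ in range(25):
        z0 = rng.normal()
        z = np.full(4, z0)
        p_single = 2 * stats.norm.sf(abs(z0))
        assert pvalue_zmax(z, r, seed=3).p_value == pytest.approx(p_single, abs=2e-3)
        w = weights_prior(CausalPrior.uniform(4), r, b).weights
        assert abs(w @ z) == pytest.approx(abs(z0), abs=1e-3)


def test_mvn_cdf_matches_independence_product():
    upper = np.array([1.0, 0.5, 2.0])
    val = mvn_cdf(upper, np.eye(3), seed=4)
    assert val == pytest.approx(stats.norm.cdf(upper).prod(), abs=2e-4)
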