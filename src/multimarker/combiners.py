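"""Multi-marker tests built from a score vector Z and correlation matrix R.

Four families are provided:

* ``pvalue_zmax`` — the correlation-calibrated maximum statistic
  Z_max = max_k |Z_k|, whose p-value comes from the multivariate normal
  N_K(0, R) null of the score vector;
* ``pvalue_bonferroni`` — K times the best single-marker two-sided p;
* ``weights_optimal`` / ``pvalue_linear`` — the optimal linear combination
  L'Z maximizing the non-centrality (E L'Z)^2 subject to L'RL = 1, which
  requires knowing (or assuming) the causal marker through Delta;
* ``weights_prior`` — prior-weighted combinations maximizing the
  pre-posterior expected non-centrality over candidate causal markers
  (uniform prior over all K markers gives the "agnostic" comb_eq; a uniform
  prior over a 2-subset gives comb_pair).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .core_stats import DeltaVector

__all__ = [
    "CombinedTest",
    "WeightVector",
    "CausalPrior",
    "mvn_cdf",
    "pvalue_zmax",
    "pvalue_bonferroni",
    "weights_optimal",
    "weights_prior",
    "pvalue_linear",
    "noncentrality_opt",
]

RIDGE = 1e-8
EIG_FLOOR = 1e-10


@dataclass(frozen=True)
class CombinedTest:
    """A single block-level test: statistic, p-value and method tag."""

    statistic: float
    p_value: float
    method_tag: str
    k: int


@dataclass(frozen=True)
class WeightVector:
    """K-vector L of combination weights normalized so that L'RL = 1."""

    weights: np.ndarray
    normalization: float
    method_tag: str = "custom"

    @property
    def k(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class CausalPrior:
    """Prior probabilities over which marker in the block is causal."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if (probs < 0).any():
            raise ValueError("prior probabilities must be nonnegative")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("prior probabilities must sum to 1")
        object.__setattr__(self, "probs", probs)

    @classmethod
    def uniform(cls, k: int) -> "CausalPrior":
        return cls(np.full(k, 1.0 / k))

    @classmethod
    def subset(cls, k: int, markers) -> "CausalPrior":
        """Uniform prior over a subset of 1-based marker indices."""
        probs = np.zeros(k)
        markers = list(markers)
        for m in markers:
            if not 1 <= m <= k:
                raise ValueError(f"marker {m} out of range 1..{k}")
            probs[m - 1] = 1.0 / len(markers)
        return cls(probs)

    @classmethod
    def point(cls, k: int, marker: int) -> "CausalPrior":
        return cls.subset(k, [marker])


def _check_R(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("R must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("R must have unit diagonal")
    return 0.5 * (R + R.T)


def _ridge_solve(R: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve (R + ridge I) x = rhs via Cholesky; never form an inverse."""
    k = R.shape[0]
    try:
        c, low = linalg.cho_factor(R + RIDGE * np.eye(k), check_finite=False)
    except linalg.LinAlgError as exc:
        raise ValueError("correlation matrix not positive definite after ridge") from exc
    return linalg.cho_solve((c, low), rhs, check_finite=False)


def _inv_sqrt(R: np.ndarray) -> np.ndarray:
    """Symmetric R^{-1/2} by eigendecomposition with floored eigenvalues."""
    w, v = np.linalg.eigh(R)
    w = np.maximum(w, EIG_FLOOR)
    return (v / np.sqrt(w)) @ v.T


def mvn_cdf(
    upper: np.ndarray,
    R: np.ndarray,
    lower: np.ndarray | None = None,
    maxpts: int | None = None,
    seed: int = 0,
) -> float:
    """P(lower <= Z <= upper) for Z ~ N_K(0, R), via randomized quadrature.

    The quasi-Monte-Carlo rule is seeded per call so repeated evaluation is
    bit-reproducible.  ``lower=None`` gives the one-sided CDF.  Correlation
    matrices with |r| = 1 pairs are nudged toward the identity by a ridge so
    the integrator accepts them; the perturbation is O(1e-9).
    """
    upper = np.atleast_1d(np.asarray(upper, dtype=float))
    k = upper.shape[0]
    if k == 0:
        raise ValueError("empty score vector")
    if k == 1:
        hi = stats.norm.cdf(upper[0])
        lo = stats.norm.cdf(lower[0]) if lower is not None else 0.0
        return float(hi - lo)
    R = _check_R(R)
    lam = 1e-9
    Rj = (1 - lam) * R + lam * np.eye(k)
    if maxpts is None:
        maxpts = 100_000 * k
    val = stats.multivariate_normal.cdf(
        upper,
        mean=np.zeros(k),
        cov=Rj,
        allow_singular=True,
        maxpts=maxpts,
        abseps=1e-7,
        releps=0,
        lower_limit=lower,
        rng=np.random.default_rng(seed),
    )
    return float(min(max(val, 0.0), 1.0))


def pvalue_zmax(
    z: np.ndarray,
    R: np.ndarray,
    mode: str = "printed",
    maxpts: int | None = None,
    seed: int = 0,
) -> CombinedTest:
    """Maximum-|Z| test with multivariate-normal calibration.

    ``mode="printed"`` computes p = 2 (1 - Phi_R(Z_max 1_K)), the form used
    throughout the power tables; ``mode="rectangle"`` computes the exact
    two-sided rejection probability 1 - P(-Z_max <= Z <= Z_max), which the
    printed form bounds from above (it double-counts the overlap of the two
    tails).  Both are clamped to [0, 1].
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if not np.isfinite(z).all():
        raise ValueError("score vector contains non-finite values")
    zmax = float(np.abs(z).max())
    k = z.shape[0]
    ones = np.full(k, zmax)
    if mode == "printed":
        p = 2.0 * (1.0 - mvn_cdf(ones, R, maxpts=maxpts, seed=seed))
    elif mode == "rectangle":
        p = 1.0 - mvn_cdf(ones, R, lower=-ones, maxpts=maxpts, seed=seed)
    else:
        raise ValueError("mode must be 'printed' or 'rectangle'")
    return CombinedTest(statistic=zmax, p_value=float(min(max(p, 0.0), 1.0)),
                        method_tag="zmax", k=k)


def pvalue_bonferroni(z: np.ndarray) -> CombinedTest:
    """K times the two-sided p-value of the most significant marker."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if z.shape[0] == 0:
        raise ValueError("empty score vector")
    zmax = float(np.abs(z).max())
    p = min(1.0, z.shape[0] * 2.0 * stats.norm.sf(zmax))
    return CombinedTest(statistic=zmax, p_value=p, method_tag="bonferroni",
                        k=z.shape[0])


def weights_optimal(
    delta: DeltaVector | np.ndarray,
    R: np.ndarray,
    method: str = "solve",
) -> WeightVector:
    """Weights of the optimal linear combination for a known Delta.

    Maximizes (E L'Z)^2 = (L'Delta)^2 subject to L'RL = 1.  The closed form
    is L = R^{-1} Delta / sqrt(Delta' R^{-1} Delta); ``method="eigen"``
    instead takes the leading eigenvector of H = R^{-1/2} Delta Delta'
    R^{-1/2} and maps it back — the two agree because H is rank one.  Only
    the direction of Delta matters: rescaling by any positive constant
    leaves the weights unchanged.  Sign is fixed so that L'Delta > 0.
    """
    d = delta.delta if isinstance(delta, DeltaVector) else np.asarray(delta, float)
    R = _check_R(R)
    if not np.any(d):
        raise ValueError("zero Delta: optimal weights are undefined under the null")
    if method == "solve":
        rinv_d = _ridge_solve(R, d)
        L = rinv_d / np.sqrt(rinv_d @ R @ rinv_d)  # exact L'RL = 1
    elif method == "eigen":
        rhalf_inv = _inv_sqrt(R)
        h = np.outer(rhalf_inv @ d, rhalf_inv @ d)
        _, vecs = np.linalg.eigh(h)
        L = rhalf_inv @ vecs[:, -1]
        nrm = L @ R @ L
        L = L / np.sqrt(nrm)
    else:
        raise ValueError("method must be 'solve' or 'eigen'")
    if L @ d < 0:
        L = -L
    return WeightVector(weights=L, normalization=float(L @ R @ L),
                        method_tag="optimal")


def weights_prior(
    prior: CausalPrior,
    R: np.ndarray,
    b: np.ndarray,
) -> WeightVector:
    """Prior-weighted combination maximizing pre-posterior non-centrality.

    For each candidate causal marker k, Delta^(k) is the k-th column of R
    scaled component-wise by the B factors; H averages the outer products
    Delta^(k) Delta^(k)' under the prior (whitened by R^{-1/2}) and the
    weights are the leading eigenvector mapped back through R^{-1/2}.  The
    eigenvector sign is chosen so that L' (prior-mean Delta) > 0.
    """
    R = _check_R(R)
    b = np.asarray(b, dtype=float)
    k = R.shape[0]
    if prior.probs.shape[0] != k or b.shape[0] != k:
        raise ValueError("prior, b and R dimensions must agree")
    # Delta^(j) as columns: entry (i, j) = R[i, j] * b[i]
    deltas = R * b[:, None]
    m = deltas * np.sqrt(prior.probs)[None, :]
    rhalf_inv = _inv_sqrt(R)
    w = rhalf_inv @ m
    h = w @ w.T
    vals, vecs = np.linalg.eigh(h)
    mean_delta = deltas @ prior.probs
    lead = vecs[:, -1]
    # degenerate leading eigenspace (e.g. independent markers under a
    # symmetric prior): every direction in it is equally optimal; break the
    # tie by projecting the prior-mean Delta onto the eigenspace
    top = vals >= vals[-1] * (1 - 1e-10) - 1e-12
    if top.sum() > 1:
        basis = vecs[:, top]
        proj = basis @ (basis.T @ (rhalf_inv @ mean_delta))
        if np.linalg.norm(proj) > 1e-12:
            lead = proj / np.linalg.norm(proj)
    L = rhalf_inv @ lead
    L = L / np.sqrt(L @ R @ L)
    if L @ mean_delta < 0:
        L = -L
    tag = "agnostic" if np.allclose(prior.probs, 1.0 / k) else "prior"
    return WeightVector(weights=L, normalization=float(L @ R @ L), method_tag=tag)


def pvalue_linear(
    z: np.ndarray,
    weights: WeightVector,
    R: np.ndarray,
) -> CombinedTest:
    """Two-sided test of the linear combination L'Z against N(0, 1).

    L must satisfy L'RL = 1 (checked), so the combined statistic has unit
    variance under the null and needs no further calibration.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    R = _check_R(R)
    L = weights.weights
    norm = float(L @ R @ L)
    if abs(norm - 1.0) > 1e-6:
        raise ValueError(
            f"weights not normalized against this R (L'RL = {norm:.6f}); "
            "rescale by 1/sqrt(L'RL) before testing"
        )
    statistic = float(L @ z)
    p = 2.0 * stats.norm.sf(abs(statistic))
    return CombinedTest(statistic=statistic, p_value=float(p),
                        method_tag="linear", k=z.shape[0])


def noncentrality_opt(delta: DeltaVector | np.ndarray, R: np.ndarray) -> float:
    """Non-centrality Delta' R^{-1} Delta of the optimal combination.

    Evaluated as (L_opt' Delta)^2 with L_opt normalized exactly to
    L'RL = 1, which coincides with Delta' R^{-1} Delta and keeps the two
    routes consistent to machine precision despite the stabilizing ridge.
    """
    d = delta.delta if isinstance(delta, DeltaVector) else np.asarray(delta, float)
    R = _check_R(R)
    if not np.any(d):
        return 0.0
    rinv_d = _ridge_solve(R, d)
    return float((d @ rinv_d) ** 2 / (rinv_d @ R @ rinv_d))
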