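"""Correlated-binary genotype simulation and retrospective case-control sampling.

Haplotype blocks are generated by one of two calibrated engines: an exact
maximum-entropy joint Bernoulli distribution over the 2^K marker patterns
(default for small blocks), or the dichotomized-Gaussian construction — a
latent multivariate normal with unit marginals thresholded at
Phi^{-1}(1 - p_k), its latent correlations calibrated by root-finding on
the bivariate normal orthant probability so the *binary* pairwise
correlations hit their targets.  Case-control samples are drawn by
prospective rejection sampling
against a logistic risk model at one causal marker, at either of two
resolutions: haplotypes as the sampling units (G = allele indicator, risk
on the allele), or diploid subjects (two independent haplotypes paired and
dominant-coded into a carrier indicator, risk on carrier status).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, stats
from scipy.special import expit, ndtri

from .blocks import BlockSpec, pair_prob_from_corr
from .data import CaseControlData

__all__ = [
    "LatentGaussianModel",
    "JointBernoulliModel",
    "DiseaseModel",
    "bvn_upper",
    "latent_correlation",
    "calibrate_latent",
    "fit_joint_bernoulli",
    "build_generator",
    "sample_haplotypes",
    "sample_genotypes",
    "dominant_genotypes",
    "sample_case_control",
    "causal_unit_freq",
]

_PD_CLIP = 1e-8
_MAXENT_K_LIMIT = 12


def bvn_upper(h: float, k: float, rho: float) -> float:
    """P(X > h, Y > k) for standard bivariate normal with correlation rho.

    Uses the identity d/dr P = phi2(h, k; r) (Plackett), integrating the
    bivariate density from independence; deterministic and accurate to
    ~1e-12 away from |rho| = 1.
    """
    base = stats.norm.sf(h) * stats.norm.sf(k)
    if rho == 0.0:
        return float(base)

    def dens(r: float) -> float:
        om = 1.0 - r * r
        return np.exp(-(h * h - 2 * r * h * k + k * k) / (2 * om)) / (
            2 * np.pi * np.sqrt(om)
        )

    val, _ = integrate.quad(dens, 0.0, rho, epsabs=1e-12, epsrel=1e-10, limit=200)
    return float(base + val)


def latent_correlation(p1: float, p2: float, target: float) -> float:
    """Latent Gaussian correlation reproducing a target binary correlation.

    Solves P(X > t1, Y > t2; rho) = p11(target) for rho, where t_k are the
    dichotomization thresholds of the two marginals.  Targets on the Fréchet
    boundary map to rho = +/-1.
    """
    if target == 0.0:
        return 0.0
    p11 = pair_prob_from_corr(p1, p2, target)  # validates feasibility
    t1, t2 = ndtri(1 - p1), ndtri(1 - p2)
    lo, hi = -1.0 + 1e-12, 1.0 - 1e-12
    f_lo = bvn_upper(t1, t2, lo) - p11
    f_hi = bvn_upper(t1, t2, hi) - p11
    if f_hi <= 0:
        return 1.0
    if f_lo >= 0:
        return -1.0
    return float(optimize.brentq(
        lambda r: bvn_upper(t1, t2, r) - p11, lo, hi, xtol=1e-10, rtol=1e-12
    ))


@dataclass(frozen=True)
class LatentGaussianModel:
    """Calibrated dichotomized-Gaussian generator for one binary block.

    ``thresholds[k] = Phi^{-1}(1 - freq_k)``; a latent draw above the
    threshold yields a 1 (minor-allele / carrier indicator).  If the
    pairwise-calibrated latent matrix is not positive definite it is
    repaired by eigenvalue clipping and rescaled to unit diagonal;
    ``max_abs_repair`` records the largest entrywise change so downstream
    fidelity checks can widen their tolerance accordingly.
    """

    block: BlockSpec
    thresholds: np.ndarray
    latent_corr: np.ndarray
    repaired: bool
    max_abs_repair: float
    _chol: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self._chol is None:
            object.__setattr__(self, "_chol", np.linalg.cholesky(self.latent_corr))

    @property
    def k(self) -> int:
        return self.thresholds.shape[0]


def calibrate_latent(block: BlockSpec) -> LatentGaussianModel:
    """Calibrate the latent Gaussian so dichotomized draws match the block.

    Each pair's latent correlation is solved independently on the bivariate
    normal; the assembled matrix is then nearest-PD repaired (eigenvalues
    clipped at 1e-8, rescaled to unit diagonal) since pairwise-feasible
    targets need not form a jointly PD latent matrix.  ``max_abs_repair``
    reports, on the *binary* correlation scale, the largest gap between the
    correlation the repaired model actually induces and the target — this
    covers both PD repair and any Fréchet clipping of rounded targets.
    """
    p = block.freq
    k = block.k
    thresholds = ndtri(1 - p)
    latent = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            latent[i, j] = latent[j, i] = latent_correlation(
                p[i], p[j], block.corr[i, j]
            )
    w, v = np.linalg.eigh(latent)
    pd_repaired = bool(w.min() < _PD_CLIP)
    if pd_repaired:
        w = np.maximum(w, _PD_CLIP)
        fixed = (v * w) @ v.T
        d = np.sqrt(np.diag(fixed))
        fixed = fixed / np.outer(d, d)
        np.fill_diagonal(fixed, 1.0)
        latent = 0.5 * (fixed + fixed.T)

    # achieved binary correlation of the final latent model, pair by pair
    max_gap = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            p11 = bvn_upper(thresholds[i], thresholds[j],
                            float(np.clip(latent[i, j], -1.0, 1.0)))
            achieved = (p11 - p[i] * p[j]) / np.sqrt(
                p[i] * (1 - p[i]) * p[j] * (1 - p[j])
            )
            max_gap = max(max_gap, abs(achieved - block.corr[i, j]))
    return LatentGaussianModel(
        block=block,
        thresholds=thresholds,
        latent_corr=latent,
        repaired=pd_repaired or max_gap > 1e-6,
        max_abs_repair=float(max_gap),
    )


@dataclass(frozen=True)
class JointBernoulliModel:
    """Maximum-entropy joint Bernoulli distribution over the 2^K patterns.

    Fitted so that every marginal frequency and pairwise product moment
    matches the block's targets; exact where the (rounded) targets admit a
    joint distribution at all.  Strong LD blocks printed in the literature
    routinely sit on or beyond pairwise Fréchet bounds, where the Gaussian
    copula cannot represent them jointly — the explicit pattern
    distribution can, so this engine is preferred for small K.
    ``max_abs_repair`` has the same meaning as for the latent model: the
    largest gap between an achieved pairwise correlation and its target.
    """

    block: BlockSpec
    patterns: np.ndarray  # (2^K, K) int8
    probs: np.ndarray     # (2^K,)
    repaired: bool
    max_abs_repair: float

    @property
    def k(self) -> int:
        return self.patterns.shape[1]


def fit_joint_bernoulli(
    block: BlockSpec,
    interior_eps: float = 1e-3,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> JointBernoulliModel:
    """Fit the max-entropy distribution matching marginals and pair moments.

    The natural parameters of the exponential family over {0,1}^K with
    singleton and pair sufficient statistics are found by Newton iteration
    (the Hessian is the feature covariance).  Pairwise targets are pulled a
    relative ``interior_eps`` toward independence so boundary targets
    (correlations at the Fréchet bound, i.e. a zero haplotype cell) keep
    the parameters finite; the bias this introduces is far below sampling
    noise at any realistic study size and is included in the reported
    ``max_abs_repair``.
    """
    p = block.freq
    k = block.k
    if k > _MAXENT_K_LIMIT:
        raise ValueError(
            f"joint Bernoulli fit enumerates 2^K patterns; K={k} exceeds the "
            f"limit {_MAXENT_K_LIMIT} — use calibrate_latent instead"
        )
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    targets = list(p)
    for i, j in pairs:
        p11 = pair_prob_from_corr(p[i], p[j], block.corr[i, j])
        targets.append((1 - interior_eps) * p11 + interior_eps * p[i] * p[j])
    t = np.array(targets)
    patterns = ((np.arange(2**k)[:, None] >> np.arange(k)) & 1).astype(np.int8)
    x = patterns.astype(float)
    feats = np.hstack([x] + [x[:, [i]] * x[:, [j]] for i, j in pairs])

    from scipy.special import logsumexp

    theta = np.zeros(feats.shape[1])
    theta[:k] = np.log(p / (1 - p))
    for _ in range(max_iter):
        eta = feats @ theta
        q = np.exp(eta - logsumexp(eta))
        mu = feats.T @ q
        grad = mu - t
        if np.abs(grad).max() < tol:
            break
        hess = (feats.T * q) @ feats - np.outer(mu, mu)
        hess[np.diag_indices_from(hess)] += 1e-12
        step = np.linalg.solve(hess, grad)
        f0 = logsumexp(eta) - t @ theta
        s = 1.0
        for _ in range(60):
            cand = theta - s * step
            if logsumexp(feats @ cand) - t @ cand <= f0 - 1e-4 * s * (grad @ step):
                break
            s *= 0.5
        theta = cand
    eta = feats @ theta
    q = np.exp(eta - logsumexp(eta))

    achieved = feats.T @ q
    am = achieved[:k]
    max_gap = float(np.abs(am - p).max())
    for idx, (i, j) in enumerate(pairs):
        corr = (achieved[k + idx] - am[i] * am[j]) / np.sqrt(
            am[i] * (1 - am[i]) * am[j] * (1 - am[j])
        )
        max_gap = max(max_gap, abs(corr - block.corr[i, j]))
    return JointBernoulliModel(
        block=block,
        patterns=patterns,
        probs=q,
        repaired=max_gap > 1e-6,
        max_abs_repair=max_gap,
    )


def build_generator(block: BlockSpec, engine: str = "auto"):
    """Generator for a block: max-entropy joint fit or dichotomized Gaussian.

    ``"auto"`` picks the exact joint Bernoulli fit when the pattern space is
    enumerable (K <= 12) and falls back to the latent Gaussian otherwise.
    """
    if engine == "auto":
        engine = "maxent" if block.k <= _MAXENT_K_LIMIT else "latent"
    if engine == "maxent":
        return fit_joint_bernoulli(block)
    if engine == "latent":
        return calibrate_latent(block)
    raise ValueError("engine must be 'auto', 'maxent' or 'latent'")


def sample_haplotypes(model, m: int, rng: np.random.Generator) -> np.ndarray:
    """m iid binary K-vectors from a calibrated block generator."""
    if m < 1:
        raise ValueError("m must be positive")
    if isinstance(model, JointBernoulliModel):
        idx = rng.choice(model.patterns.shape[0], size=m, p=model.probs)
        return model.patterns[idx]
    z = rng.standard_normal((m, model.k)) @ model._chol.T
    return (z > model.thresholds).astype(np.int8)


def dominant_genotypes(model, n: int, rng: np.random.Generator) -> np.ndarray:
    """Pair two independent haplotypes per subject, dominant-coded.

    G_k = 1 iff either haplotype carries the minor allele at marker k, so
    the carrier frequency is 1 - (1 - maf_k)^2.
    """
    h = sample_haplotypes(model, 2 * n, rng)
    return h[0::2] | h[1::2]


def sample_genotypes(model, n: int, rng: np.random.Generator) -> np.ndarray:
    """Genotype matrix for n subjects, honouring the block's level.

    Allele-level blocks go through haplotype pairing; genotype-level blocks
    are drawn directly as the correlated carrier indicators.
    """
    if model.block.level == "allele":
        return dominant_genotypes(model, n, rng)
    return sample_haplotypes(model, n, rng)


@dataclass(frozen=True)
class DiseaseModel:
    """Dominant logistic risk model: logit P(case | G) = mu + theta * G_causal."""

    causal_marker: int  # 1-based, matching printed block tables
    odds_ratio: float
    baseline_log_odds: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.odds_ratio) and self.odds_ratio > 0):
            raise ValueError("odds ratio must be positive and finite")

    @property
    def theta(self) -> float:
        return float(np.log(self.odds_ratio))

    @classmethod
    def from_prevalence(
        cls,
        causal_marker: int,
        odds_ratio: float,
        causal_freq: float,
        prevalence: float = 0.1,
    ) -> "DiseaseModel":
        """Choose the baseline so the population disease prevalence is hit.

        Solves (1-f) expit(mu) + f expit(mu + theta) = prevalence where f is
        the frequency of G = 1 at the causal marker for the analysis unit
        (carrier frequency for diploid subjects, MAF for haplotype units).
        """
        if not 0 < prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        theta = np.log(odds_ratio)

        def gap(mu: float) -> float:
            return (
                (1 - causal_freq) * expit(mu)
                + causal_freq * expit(mu + theta)
                - prevalence
            )

        mu = optimize.brentq(gap, -40.0, 40.0, xtol=1e-12)
        return cls(causal_marker=causal_marker, odds_ratio=float(odds_ratio),
                   baseline_log_odds=float(mu))

    def case_probability(self, g_causal: np.ndarray) -> np.ndarray:
        return expit(self.baseline_log_odds + self.theta * g_causal)


def causal_unit_freq(model, causal_marker: int,
                     units: str = "subject") -> float:
    """Frequency of G = 1 at the causal marker for the chosen analysis unit."""
    c = causal_marker - 1
    if units == "subject" and model.block.level == "allele":
        return float(1.0 - (1.0 - model.block.freq[c]) ** 2)
    return float(model.block.freq[c])


def sample_case_control(
    model,
    disease: DiseaseModel,
    n_case: int,
    n_control: int,
    rng: np.random.Generator,
    units: str = "subject",
) -> CaseControlData:
    """Prospective rejection sampling until both quotas are filled.

    Units are drawn from the population genotype distribution, assigned
    case status with probability expit(mu + theta * G_causal), and retained
    as cases or controls until n_case and n_control are reached.  Cases are
    stacked first in the returned data set.

    ``units="subject"`` draws diploid subjects (two haplotypes paired into a
    dominant carrier indicator when the block is allele-level).
    ``units="haplotype"`` treats each haplotype as its own sampling unit
    with G the allele indicator and the risk model acting on the allele —
    the resolution at which haplotype-based association analyses operate;
    quotas then count haplotypes.
    """
    if n_case < 1 or n_control < 1:
        raise ValueError("need at least one case and one control")
    if units not in ("subject", "haplotype"):
        raise ValueError("units must be 'subject' or 'haplotype'")
    if units == "haplotype" and model.block.level != "allele":
        raise ValueError("haplotype units require an allele-level block")
    k = model.k
    if not 1 <= disease.causal_marker <= k:
        raise ValueError(f"causal marker {disease.causal_marker} out of range 1..{k}")
    c = disease.causal_marker - 1

    f = causal_unit_freq(model, disease.causal_marker, units)
    p_case = float((1 - f) * expit(disease.baseline_log_odds)
                   + f * expit(disease.baseline_log_odds + disease.theta))
    batch = int(1.2 * max(n_case / max(p_case, 1e-6),
                          n_control / max(1 - p_case, 1e-6))) + 64

    max_draws = 10_000 * (n_case + n_control)
    drawn = 0
    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    need_case, need_control = n_case, n_control
    while need_case > 0 or need_control > 0:
        if drawn >= max_draws:
            raise RuntimeError(
                f"case-control sampling exceeded {max_draws} draws; "
                "check prevalence and quota settings"
            )
        m = min(batch, max_draws - drawn)
        if units == "haplotype":
            g = sample_haplotypes(model, m, rng)
        else:
            g = sample_genotypes(model, m, rng)
        drawn += m
        is_case = rng.random(m) < disease.case_probability(g[:, c])
        if need_case > 0:
            got = g[is_case][:need_case]
            cases.append(got)
            need_case -= got.shape[0]
        if need_control > 0:
            got = g[~is_case][:need_control]
            controls.append(got)
            need_control -= got.shape[0]
    genotypes = np.vstack([np.vstack(cases), np.vstack(controls)])
    phenotype = np.concatenate([np.ones(n_case, dtype=np.int8),
                                np.zeros(n_control, dtype=np.int8)])
    return CaseControlData(phenotype=phenotype, genotypes=genotypes,
                           marker_ids=model.block.marker_ids)
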