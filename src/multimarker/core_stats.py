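"""Per-marker score tests and the LD-driven moments of the score vector.

For a binary disease indicator x and a dominant-coded genotype G, the score
test of no association at one marker is

    Z = sum_i (x_i - xbar)(g_i - pihat) / sqrt(n xbar(1-xbar) pihat(1-pihat)),

asymptotically N(0, 1) under the null.  Across the K markers of an LD block
the score vector Z is asymptotically N_K(0, R) where R is, to first order,
the Pearson correlation matrix of the genotypes themselves — so R can be
estimated directly from the pooled sample.  Under a local alternative with
log odds ratio theta at a causal marker, each component is shifted by a
non-centrality Delta_j = theta * R[j, causal] * B_j with
B_j = sqrt(n xbar(1-xbar) pi_j(1-pi_j)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .blocks import BlockSpec
from .data import CaseControlData

__all__ = [
    "ScoreResult",
    "DeltaVector",
    "score_statistics",
    "estimate_R",
    "delta_vector",
    "b_factors",
    "write_score_table",
]


@dataclass(frozen=True)
class ScoreResult:
    """Per-marker score statistics Z_k with their building blocks."""

    z: np.ndarray
    numerator: np.ndarray
    denominator: np.ndarray
    freq: np.ndarray          # pooled carrier frequency pihat
    case_freq: np.ndarray     # pihat_1
    control_freq: np.ndarray  # pihat_0
    marker_ids: tuple[str, ...]

    @property
    def k(self) -> int:
        return self.z.shape[0]

    def p_single(self) -> np.ndarray:
        """Two-sided normal p-value per marker."""
        return 2.0 * stats.norm.sf(np.abs(self.z))


@dataclass(frozen=True)
class DeltaVector:
    """Expected score vector Delta = E(Z) under a local alternative.

    ``delta[j] = theta * R[j, causal] * b[j]`` where b are the B_k scale
    factors; ``causal_marker`` is 1-based, matching printed block tables.
    """

    delta: np.ndarray
    b: np.ndarray
    theta: float
    causal_marker: int | None

    @property
    def k(self) -> int:
        return self.delta.shape[0]


def _check_polymorphic(freq: np.ndarray, marker_ids) -> None:
    bad = np.flatnonzero((freq <= 0) | (freq >= 1))
    if bad.size:
        names = ", ".join(marker_ids[j] for j in bad)
        raise ValueError(
            f"monomorphic marker(s) {names}: carrier frequency 0 or 1 makes the "
            "score statistic undefined; drop these markers upstream"
        )


def score_statistics(data: CaseControlData) -> ScoreResult:
    """Score test statistic per marker of a case-control data set.

    Raises for monomorphic markers (pooled carrier frequency of 0 or 1):
    they would silently propagate NaN into any maximum over |Z|.
    """
    x = data.phenotype.astype(float)
    g = data.genotypes.astype(float)
    n = data.n
    xbar = x.mean()
    pihat = g.mean(axis=0)
    _check_polymorphic(pihat, data.marker_ids)
    numerator = (x - xbar) @ (g - pihat)
    denominator = np.sqrt(n * xbar * (1 - xbar) * pihat * (1 - pihat))
    case = x == 1
    return ScoreResult(
        z=numerator / denominator,
        numerator=numerator,
        denominator=denominator,
        freq=pihat,
        case_freq=g[case].mean(axis=0),
        control_freq=g[~case].mean(axis=0),
        marker_ids=data.marker_ids,
    )


def estimate_R(data: CaseControlData) -> np.ndarray:
    """Pearson correlation matrix of the genotype columns, pooled sample.

    Under the null (and local alternatives) the correlation of the score
    statistics equals the genotype correlation, so the pooled estimate
    calibrates the multi-marker tests.  No shrinkage is applied; numerical
    safeguards (ridge before inversion) live with the consumers.
    """
    if data.n < 2:
        raise ValueError("need at least two subjects to estimate correlations")
    g = data.genotypes.astype(float)
    _check_polymorphic(g.mean(axis=0), data.marker_ids)
    if data.k == 1:
        return np.ones((1, 1))
    r = np.corrcoef(g, rowvar=False)
    r = np.clip(0.5 * (r + r.T), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def b_factors(freq: np.ndarray, n: int, case_fraction: float) -> np.ndarray:
    """Scale factors B_k = sqrt(n xbar(1-xbar) pi_k(1-pi_k)).

    ``freq`` must be genotype-level (carrier) frequencies.
    """
    freq = np.asarray(freq, dtype=float)
    return np.sqrt(n * case_fraction * (1 - case_fraction) * freq * (1 - freq))


def delta_vector(
    block: BlockSpec,
    theta: float,
    causal_marker: int,
    n: int,
    case_fraction: float = 0.5,
) -> DeltaVector:
    """Non-centrality vector induced by a causal marker in LD with the block.

    The causal marker contributes Delta = theta * B there; every other marker
    picks up an induced shift scaled by its correlation with the causal
    marker, vanishing under linkage equilibrium.

    Parameters
    ----------
    block
        Block describing the binary coding of the analysis units: carrier
        frequencies/correlations (``genotype_level``) when subjects are the
        units under dominant coding, or the allele-level block itself when
        haplotypes are the units.
    theta
        Log odds ratio at the causal marker; must be finite.
    causal_marker
        1-based index of the causal marker, as printed in block tables.
    n, case_fraction
        Number of analysis units and case proportion xbar of the design.
    """
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    if not 0 < case_fraction < 1:
        raise ValueError("case_fraction must lie in (0, 1)")
    if not 1 <= causal_marker <= block.k:
        raise ValueError(f"causal_marker {causal_marker} out of range 1..{block.k}")
    b = b_factors(block.freq, n, case_fraction)
    delta = theta * block.corr[:, causal_marker - 1] * b
    return DeltaVector(delta=delta, b=b, theta=float(theta), causal_marker=causal_marker)


def write_score_table(result: ScoreResult, path) -> None:
    """TSV with per-marker Z, two-sided p and frequency estimates."""
    pd.DataFrame(
        {
            "marker": list(result.marker_ids),
            "Z": result.z,
            "p_single": result.p_single(),
            "pi_hat": result.freq,
            "pi1_hat": result.case_freq,
            "pi0_hat": result.control_freq,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
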