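"""LD-block specifications: MAFs plus a pairwise Pearson correlation matrix.

A :class:`BlockSpec` describes a block of K biallelic markers either at the
haplotype (allele) level — the frequency of the minor allele and the
correlation of the binary allele indicators along a haplotype — or at the
genotype level, where the frequency is that of the dominant-coded carrier
indicator G = 1{at least one minor allele} and the correlation is between
carrier indicators.  Two fixture blocks mirror LD structure observed on
chromosome 10 in a smoking-cohort genome scan; parametric compound-symmetry
and AR(1) builders cover the designed simulation settings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BlockSpec",
    "build_cs",
    "build_ar1",
    "chr10_block8",
    "chr10_block7",
    "genotype_level",
    "pair_prob_from_corr",
    "read_block_json",
    "write_block_json",
    "read_block_tsv",
    "write_block_tsv",
]


@dataclass(frozen=True)
class BlockSpec:
    """Marker frequencies and target pairwise correlations for one LD block.

    ``freq`` holds the minor allele frequency when ``level == "allele"`` and
    the dominant-coded carrier frequency when ``level == "genotype"``.
    """

    freq: np.ndarray
    corr: np.ndarray
    level: str = "allele"
    marker_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        freq = np.atleast_1d(np.asarray(self.freq, dtype=float))
        corr = np.asarray(self.corr, dtype=float)
        k = freq.shape[0]
        if corr.shape != (k, k):
            raise ValueError(f"corr must be {k}x{k}, got {corr.shape}")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ValueError("corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ValueError("corr must have unit diagonal")
        if np.abs(corr).max() > 1 + 1e-12:
            raise ValueError("corr entries must lie in [-1, 1]")
        if ((freq <= 0) | (freq >= 1)).any():
            raise ValueError("frequencies must lie strictly in (0, 1)")
        if self.level not in ("allele", "genotype"):
            raise ValueError("level must be 'allele' or 'genotype'")
        corr = 0.5 * (corr + corr.T)
        np.fill_diagonal(corr, 1.0)
        ids = tuple(self.marker_ids) or tuple(f"m{j + 1}" for j in range(k))
        if len(ids) != k:
            raise ValueError("marker_ids length mismatch")
        object.__setattr__(self, "freq", freq)
        object.__setattr__(self, "corr", corr)
        object.__setattr__(self, "marker_ids", ids)

    @property
    def k(self) -> int:
        return self.freq.shape[0]


def build_cs(k: int, rho: float, freq=0.25, level: str = "allele") -> BlockSpec:
    """Compound-symmetry (exchangeable) block: every off-diagonal equals rho."""
    if k < 2:
        raise ValueError("need at least two markers")
    if not (-1.0 / (k - 1) < rho <= 1.0):
        raise ValueError(f"CS correlation {rho} outside PD range (-1/(K-1), 1]")
    corr = np.full((k, k), float(rho))
    np.fill_diagonal(corr, 1.0)
    return BlockSpec(freq=np.broadcast_to(np.asarray(freq, float), (k,)).copy(),
                     corr=corr, level=level)


def build_ar1(k: int, rho: float, freq=0.25, level: str = "allele") -> BlockSpec:
    """AR(1) block: correlation rho^|j-k| decaying with marker distance."""
    if k < 2:
        raise ValueError("need at least two markers")
    if not (-1.0 < rho < 1.0):
        raise ValueError(f"AR(1) correlation {rho} outside (-1, 1)")
    idx = np.arange(k)
    corr = float(rho) ** np.abs(idx[:, None] - idx[None, :])
    np.fill_diagonal(corr, 1.0)
    return BlockSpec(freq=np.broadcast_to(np.asarray(freq, float), (k,)).copy(),
                     corr=corr, level=level)


def _symmetric_from_upper(upper_rows: list[list[float]], k: int) -> np.ndarray:
    corr = np.eye(k)
    for i, row in enumerate(upper_rows):
        corr[i, i + 1:] = row
        corr[i + 1:, i] = row
    return corr


def chr10_block8() -> BlockSpec:
    """Eight-marker chromosome-10 LD block: modest MAFs, weak-to-moderate LD."""
    upper = [
        [0.93, 0.57, 0.78, 0.47, 0.45, 0.07, 0.43],
        [0.61, 0.81, 0.46, 0.49, 0.08, 0.47],
        [0.50, -0.14, -0.13, 0.29, 0.29],
        [0.68, 0.67, 0.14, 0.53],
        [0.96, -0.09, 0.38],
        [-0.07, 0.39],
        [0.59],
    ]
    maf = np.array([0.25, 0.22, 0.10, 0.28, 0.17, 0.16, 0.21, 0.43])
    return BlockSpec(freq=maf, corr=_symmetric_from_upper(upper, 8), level="allele")


def chr10_block7() -> BlockSpec:
    """Seven-marker chromosome-10 LD block: common alleles, strong (signed) LD."""
    upper = [
        [0.99, -0.96, -0.83, -0.83, 0.76, -0.69],
        [-0.97, -0.84, -0.84, 0.77, -0.69],
        [0.81, 0.81, -0.74, 0.69],
        [0.95, -0.84, 0.76],
        [-0.87, 0.77],
        [-0.67],
    ]
    maf = np.array([0.49, 0.49, 0.49, 0.44, 0.45, 0.49, 0.44])
    return BlockSpec(freq=maf, corr=_symmetric_from_upper(upper, 7), level="allele")


def pair_prob_from_corr(p1: float, p2: float, r: float,
                        infeasible_tol: float = 0.05) -> float:
    """Joint success probability P(A=1, B=1) of two Bernoullis with correlation r.

    Published LD tables round MAFs and correlations independently, so a
    printed r can overshoot the Fréchet bound of the printed marginals by a
    rounding-sized margin.  Targets within ``infeasible_tol`` of the bound
    (correlation scale) are clipped to it; larger violations raise with the
    bound printed.  Pass ``infeasible_tol=0`` for strict checking.
    """
    s = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    p11 = p1 * p2 + r * s
    lo, hi = max(0.0, p1 + p2 - 1.0), min(p1, p2)
    r_lo = (lo - p1 * p2) / s
    r_hi = (hi - p1 * p2) / s
    if r > r_hi + infeasible_tol + 1e-12 or r < r_lo - infeasible_tol - 1e-12:
        raise ValueError(
            f"correlation {r} infeasible for marginals ({p1}, {p2}); "
            f"Fréchet bounds give r in [{r_lo:.4f}, {r_hi:.4f}]"
        )
    return float(min(max(p11, lo), hi))


def genotype_level(block: BlockSpec) -> BlockSpec:
    """Induced genotype-level block under random pairing of two haplotypes.

    With two independent haplotypes per subject and dominant coding, the
    carrier indicator at marker j is zero iff both haplotypes carry the major
    allele, so P(G_j = 0) = (1 - p_j)^2 and the pairwise carrier joint
    probabilities follow from the allele-level pair probabilities by squaring
    the double-zero cell.  Returns the carrier frequencies and carrier-level
    Pearson correlations in closed form.
    """
    if block.level == "genotype":
        return block
    p = block.freq
    q = 1.0 - p
    g_freq = 1.0 - q**2
    k = block.k
    corr = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            p11a = pair_prob_from_corr(p[i], p[j], block.corr[i, j])
            q00a = 1.0 - p[i] - p[j] + p11a  # both haplo alleles major
            p00g = q00a**2
            p11g = 1.0 - q[i] ** 2 - q[j] ** 2 + p00g
            cov = p11g - g_freq[i] * g_freq[j]
            corr[i, j] = corr[j, i] = cov / np.sqrt(
                g_freq[i] * (1 - g_freq[i]) * g_freq[j] * (1 - g_freq[j])
            )
    return BlockSpec(freq=g_freq, corr=corr, level="genotype",
                     marker_ids=block.marker_ids)


def write_block_json(block: BlockSpec, path) -> None:
    payload = {
        "freq": block.freq.tolist(),
        "corr": block.corr.tolist(),
        "level": block.level,
        "marker_ids": list(block.marker_ids),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_block_json(path) -> BlockSpec:
    with open(path) as fh:
        payload = json.load(fh)
    return BlockSpec(
        freq=np.asarray(payload["freq"], dtype=float),
        corr=np.asarray(payload["corr"], dtype=float),
        level=payload.get("level", "allele"),
        marker_ids=tuple(payload.get("marker_ids", ())),
    )


def write_block_tsv(block: BlockSpec, path) -> None:
    """Square correlation matrix with a trailing MAF row, tab separated."""
    with open(path, "w") as fh:
        fh.write("\t".join(block.marker_ids) + "\n")
        for row in block.corr:
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")
        fh.write("\t".join(f"{v:.10g}" for v in block.freq) + "\n")


def read_block_tsv(path, level: str = "allele") -> BlockSpec:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    ids = tuple(lines[0].split("\t"))
    k = len(ids)
    if len(lines) != k + 2:
        raise ValueError(f"block TSV must have header, {k} matrix rows and a MAF row")
    corr = np.array([[float(v) for v in ln.split("\t")] for ln in lines[1:k + 1]])
    freq = np.array([float(v) for v in lines[k + 1].split("\t")])
    return BlockSpec(freq=freq, corr=corr, level=level, marker_ids=ids)
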