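"""Case-control genotype containers and file I/O.

The unit of analysis is a rectangular data set: one binary disease-status
indicator per subject plus a dominant-coded (carrier/non-carrier) binary
genotype per subject and marker.  All downstream statistics operate on this
container; missing-data handling and genotype recoding are resolved here,
at ingestion time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CaseControlData",
    "read_genotype_table",
    "write_genotype_table",
    "read_vcf_dominant",
]

STATUS_COLUMN = "status"


@dataclass(frozen=True)
class CaseControlData:
    """Binary phenotype vector plus an n x K dominant-coded genotype matrix.

    Parameters
    ----------
    phenotype
        Length-n integer vector of 0 (control) / 1 (case).
    genotypes
        n x K matrix with entries in {0, 1}; column k is the carrier
        indicator for marker k under dominant coding.
    marker_ids
        K marker labels; generated as ``m1..mK`` when not supplied.
    """

    phenotype: np.ndarray
    genotypes: np.ndarray
    marker_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        phen = np.asarray(self.phenotype)
        geno = np.asarray(self.genotypes)
        if geno.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        if phen.ndim != 1 or phen.shape[0] != geno.shape[0]:
            raise ValueError(
                f"phenotype length {phen.shape} does not match genotype rows {geno.shape}"
            )
        if not np.isin(phen, (0, 1)).all():
            raise ValueError("phenotype entries must be 0 (control) or 1 (case)")
        if not np.isin(geno, (0, 1)).all():
            raise ValueError(
                "genotype entries must be 0/1 under dominant coding; "
                "additive (0/1/2) or missing codes are not accepted"
            )
        n_case = int(phen.sum())
        if n_case == 0 or n_case == phen.shape[0]:
            raise ValueError("need at least one case and one control")
        ids = tuple(self.marker_ids) or tuple(f"m{k + 1}" for k in range(geno.shape[1]))
        if len(ids) != geno.shape[1]:
            raise ValueError("marker_ids length does not match number of genotype columns")
        object.__setattr__(self, "phenotype", phen.astype(np.int8))
        object.__setattr__(self, "genotypes", geno.astype(np.int8))
        object.__setattr__(self, "marker_ids", ids)

    @property
    def n(self) -> int:
        return self.phenotype.shape[0]

    @property
    def k(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_case(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_control(self) -> int:
        return self.n - self.n_case

    @property
    def case_fraction(self) -> float:
        return self.n_case / self.n

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.genotypes, columns=list(self.marker_ids))
        df.insert(0, STATUS_COLUMN, self.phenotype)
        return df


def read_genotype_table(path) -> CaseControlData:
    """Read a delimited genotype table (whitespace or comma separated).

    The file must have a header row naming each marker column plus a
    ``status`` column carrying the 0/1 disease indicator.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if STATUS_COLUMN not in df.columns:
        raise ValueError(f"genotype table must contain a '{STATUS_COLUMN}' column")
    markers = [c for c in df.columns if c != STATUS_COLUMN]
    if not markers:
        raise ValueError("genotype table contains no marker columns")
    if df.isna().any().any():
        raise ValueError("missing values in genotype table; resolve missingness upstream")
    return CaseControlData(
        phenotype=df[STATUS_COLUMN].to_numpy(),
        genotypes=df[markers].to_numpy(),
        marker_ids=tuple(markers),
    )


def write_genotype_table(data: CaseControlData, path, sep: str = "\t") -> None:
    data.to_frame().to_csv(path, sep=sep, index=False)


def read_vcf_dominant(vcf_path, status: np.ndarray) -> CaseControlData:
    """Read a VCF and recode each biallelic site to a dominant 0/1 indicator.

    A subject is coded 1 at a site when either allele is ALT (ALT-carrier).
    Multiallelic sites are rejected; supply a normalized, biallelic VCF.

    Parameters
    ----------
    vcf_path
        Path to an (optionally compressed) VCF with genotype calls.
    status
        Disease indicator per VCF sample, in VCF sample order.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF ingestion requires the cyvcf2 package") from exc

    vcf = VCF(str(vcf_path))
    columns: list[np.ndarray] = []
    ids: list[str] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"multiallelic site {variant.CHROM}:{variant.POS} not supported; "
                "split/normalize the VCF first"
            )
        gt = np.asarray(variant.genotype.array())[:, :2]
        if (gt < 0).any():
            raise ValueError(
                f"missing genotype call at {variant.CHROM}:{variant.POS}; "
                "resolve missingness upstream"
            )
        columns.append((gt > 0).any(axis=1).astype(np.int8))
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
    if not columns:
        raise ValueError("VCF contains no variants")
    return CaseControlData(
        phenotype=np.asarray(status),
        genotypes=np.column_stack(columns),
        marker_ids=tuple(ids),
    )
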