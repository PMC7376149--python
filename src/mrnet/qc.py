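"""Instrument selection and strength statistics.

Candidate instruments are genome-wide significant index SNPs for the
exposure.  Pleiotropy-prone candidates are removed conservatively: SNPs
within 1 Mb of a known outcome-associated locus, and SNPs whose own
outcome association survives a Bonferroni correction over the candidate
set.  Per-instrument strength is summarized by the proportion of exposure
variance explained (PVE) and the F statistic; F > 10 is the conventional
weak-instrument threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .sumstats import AssociationRecord

GENOME_WIDE_P = 5e-8
DEFAULT_WINDOW_BP = 1_000_000


@dataclass(frozen=True)
class InstrumentQCRow:
    snp_id: str
    pve: float
    f_stat: float

    def __post_init__(self):
        if not (0 <= self.pve < 1):
            raise ValueError(f"pve out of [0,1): {self.pve}")
        if self.f_stat < 0:
            raise ValueError(f"negative f_stat: {self.f_stat}")


def select_by_pvalue(records: Sequence[AssociationRecord],
                     threshold: float = GENOME_WIDE_P) -> list[AssociationRecord]:
    """Keep records with p strictly below the significance threshold."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    kept = [r for r in records if r.p < threshold]
    if records and not kept:
        warnings.warn(f"no records pass p < {threshold}", stacklevel=2)
    return kept


def exclude_near_loci(records: Sequence[AssociationRecord],
                      loci: Sequence[tuple[str, int]],
                      window_bp: int = DEFAULT_WINDOW_BP) -> list[AssociationRecord]:
    """Drop records within ``window_bp`` (inclusive) of any listed locus."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    loci = [(str(c), int(p)) for c, p in loci]

    def near(rec: AssociationRecord) -> bool:
        return any(
            str(rec.chrom) == c and abs(rec.pos - p) <= window_bp for c, p in loci
        )

    return [r for r in records if not near(r)]


def prune_outcome_associated(exposure_records: Sequence[AssociationRecord],
                             outcome_records: Sequence[AssociationRecord],
                             alpha: float = 0.05) -> list[AssociationRecord]:
    """Drop candidates whose outcome p-value is Bonferroni-significant.

    The multiplicity m is the number of candidate instruments entering this
    step, not the genome-wide SNP count.  A candidate missing from the
    outcome set cannot be tested and is kept with a warning.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    m = len(exposure_records)
    outcome_p = {r.snp_id: r.p for r in outcome_records}
    survivors = []
    for rec in exposure_records:
        p = outcome_p.get(rec.snp_id)
        if p is None:
            warnings.warn(
                f"{rec.snp_id}: absent from outcome file, kept untested",
                stacklevel=2,
            )
            survivors.append(rec)
        elif p * m < alpha:
            continue
        else:
            survivors.append(rec)
    return survivors


def compute_pve(beta: float, se: float, n: int) -> float:
    """Proportion of exposure variance explained by one instrument.

    PVE = beta^2 / (beta^2 + se^2 * n).
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if n < 2:
        raise ValueError("n must be >= 2")
    b2 = beta * beta
    return b2 / (b2 + se * se * n)


def compute_f(pve: float, n: int, k: int = 1) -> float:
    """Instrument-strength F statistic, F = PVE (n - 1 - k) / (k (1 - PVE)).

    ``k`` is the number of instruments in the model.  The default k=1 is the
    single-instrument (per-SNP) form, which is how published per-row F
    columns are normally computed even when several instruments are used
    jointly.
    """
    if not (0 <= pve < 1):
        raise ValueError("pve must be in [0, 1)")
    if n <= 1 + k:
        raise ValueError(f"n must exceed 1 + k (got n={n}, k={k})")
    return pve * (n - 1 - k) / (k * (1 - pve))


def qc_table(records: Sequence[AssociationRecord], k: int = 1) -> pd.DataFrame:
    """Per-instrument PVE and F in input order (one row per record)."""
    rows = []
    for r in records:
        pve = compute_pve(r.beta, r.se, r.n)
        rows.append(InstrumentQCRow(r.snp_id, pve, compute_f(pve, r.n, k)))
    return pd.DataFrame(
        {"snp_id": [r.snp_id for r in rows],
         "pve": [r.pve for r in rows],
         "f_stat": [r.f_stat for r in rows]}
    )
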