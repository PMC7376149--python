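"""Reading, validation and harmonization of GWAS summary statistics.

Two-sample Mendelian randomization combines SNP-exposure and SNP-outcome
association estimates that come from different studies.  Before any causal
estimator can run, the two sets of associations must be joined per SNP and
expressed relative to the *same* effect allele; this module owns that
plumbing plus the bundled instrument tables used throughout the test suite.

The orientation convention follows telomere-length epidemiology: effect
sizes may be re-signed so that the causal contrast is "per SD *decrease* of
the exposure" (the effect allele becomes the exposure-lowering allele).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: conventional GWAS column names, auto-detected case-insensitively
DEFAULT_COLUMNS = {
    "snp_id": ("SNP", "RSID", "SNP_ID", "MARKERNAME", "VARIANT_ID"),
    "chrom": ("CHR", "CHROM", "CHROMOSOME"),
    "pos": ("BP", "POS", "POSITION", "BASE_PAIR_LOCATION"),
    "effect_allele": ("A1", "EA", "EFFECT_ALLELE", "ALLELE1"),
    "other_allele": ("A2", "OA", "NEA", "OTHER_ALLELE", "ALLELE2"),
    "beta": ("BETA", "B", "EFFECT"),
    "se": ("SE", "STDERR", "STANDARD_ERROR"),
    "p": ("P", "PVAL", "PVALUE", "P_VALUE"),
    "n": ("N", "NMISS", "SAMPLESIZE", "SAMPLE_SIZE"),
}

_VALID_BASES = set("ACGT")
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class SumstatsError(ValueError):
    """Malformed or inconsistent summary-statistics input."""


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP-trait association row from a GWAS summary-statistics file.

    ``beta`` is the per-effect-allele change in the trait: SD units for a
    quantitative trait, log-odds for a binary one.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    p: float
    n: int
    trait: str = ""

    def __post_init__(self):
        if not self.effect_allele or not self.other_allele:
            raise SumstatsError(f"{self.snp_id}: empty allele")
        if self.effect_allele == self.other_allele:
            raise SumstatsError(f"{self.snp_id}: identical alleles")
        if not np.isfinite(self.beta):
            raise SumstatsError(f"{self.snp_id}: non-finite beta")
        if not (self.se > 0):
            raise SumstatsError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0 < self.p <= 1):
            raise SumstatsError(f"{self.snp_id}: p must be in (0, 1], got {self.p}")
        if self.n < 1:
            raise SumstatsError(f"{self.snp_id}: n must be >= 1, got {self.n}")

    def flip_alleles(self) -> "AssociationRecord":
        """Re-express the effect relative to the other allele (involution)."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
        )

    @property
    def is_palindromic(self) -> bool:
        return (self.effect_allele, self.other_allele) in _PALINDROMIC


@dataclass(frozen=True)
class HarmonizedRecord:
    snp_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float


@dataclass
class HarmonizedSet:
    """Per-SNP aligned exposure/outcome effect pairs.

    ``orientation`` records whether ``beta_x`` is expressed per SD increase
    or per SD decrease of the exposure; estimators consume either but report
    effects in the stated direction.
    """

    exposure_label: str
    outcome_label: str
    records: list[HarmonizedRecord] = field(default_factory=list)
    orientation: str = "increase"

    def __post_init__(self):
        if self.orientation not in ("increase", "decrease"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        ids = [r.snp_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_id in HarmonizedSet")
        if not self.records:
            raise ValueError("HarmonizedSet needs at least one record")
        if self.orientation == "decrease" and any(r.beta_x < 0 for r in self.records):
            raise ValueError("orientation 'decrease' requires all beta_x >= 0")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    @property
    def beta_x(self) -> np.ndarray:
        return np.array([r.beta_x for r in self.records])

    @property
    def se_x(self) -> np.ndarray:
        return np.array([r.se_x for r in self.records])

    @property
    def beta_y(self) -> np.ndarray:
        return np.array([r.beta_y for r in self.records])

    @property
    def se_y(self) -> np.ndarray:
        return np.array([r.se_y for r in self.records])

    @classmethod
    def from_arrays(cls, snp_ids, beta_x, se_x, beta_y, se_y,
                    exposure_label="exposure", outcome_label="outcome",
                    orientation="increase") -> "HarmonizedSet":
        recs = [
            HarmonizedRecord(s, float(bx), float(sx), float(by), float(sy))
            for s, bx, sx, by, sy in zip(snp_ids, beta_x, se_x, beta_y, se_y)
        ]
        return cls(exposure_label, outcome_label, recs, orientation)

    def subset(self, keep: Sequence[int] | Sequence[bool]) -> "HarmonizedSet":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        recs = [self.records[i] for i in keep]
        return HarmonizedSet(self.exposure_label, self.outcome_label, recs,
                             self.orientation)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "beta_x": self.beta_x,
                "se_x": self.se_x,
                "beta_y": self.beta_y,
                "se_y": self.se_y,
            }
        )

    def to_tsv(self, path) -> None:
        """Audit serialization with the fixed column order."""
        self.to_frame().to_csv(path, sep="\t", index=False)


def _parse_number(value, row: int, column: str) -> float:
    """Parse a numeric cell tolerating U+2212 minus and any-case exponents."""
    if isinstance(value, (int, float, np.integer, np.floating)):
        return float(value)
    text = str(value).strip().replace("−", "-").replace(" ", "")
    try:
        return float(text)
    except ValueError as exc:
        raise SumstatsError(
            f"row {row}: non-numeric value {value!r} in column {column!r}"
        ) from exc


def _resolve_columns(header: Iterable[str], column_map: dict | None) -> dict:
    header = list(header)
    upper = {h.upper(): h for h in header}
    resolved = {}
    column_map = column_map or {}
    for field_name, aliases in DEFAULT_COLUMNS.items():
        if field_name in column_map:
            col = column_map[field_name]
            if col not in header:
                raise SumstatsError(f"mapped column {col!r} not in header {header}")
            resolved[field_name] = col
            continue
        for alias in aliases:
            if alias in upper:
                resolved[field_name] = upper[alias]
                break
        else:
            raise SumstatsError(
                f"cannot locate a column for {field_name!r}; "
                f"provide a column_map entry (header: {header})"
            )
    return resolved


def read_sumstats(path, column_map: dict | None = None, delimiter: str | None = None,
                  trait: str = "") -> list[AssociationRecord]:
    """Read a delimited summary-statistics table into association records.

    Rows violating record invariants (non-positive SE, p outside (0,1], ...)
    are dropped with a row-indexed warning; non-numeric beta/se cells raise.
    Duplicate SNP ids raise: upstream clumping guarantees uniqueness, so a
    duplicate signals corrupt input.
    """
    df = pd.read_csv(path, sep=delimiter, engine="python", dtype=str)
    if df.columns.size == 1 and delimiter is None:
        df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(df.columns, column_map)

    records: list[AssociationRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        try:
            rec = AssociationRecord(
                snp_id=str(row[cols["snp_id"]]).strip(),
                chrom=str(row[cols["chrom"]]).strip(),
                pos=int(_parse_number(row[cols["pos"]], i, cols["pos"])),
                effect_allele=str(row[cols["effect_allele"]]).strip().upper(),
                other_allele=str(row[cols["other_allele"]]).strip().upper(),
                beta=_parse_number(row[cols["beta"]], i, cols["beta"]),
                se=_parse_number(row[cols["se"]], i, cols["se"]),
                p=_parse_number(row[cols["p"]], i, cols["p"]),
                n=int(_parse_number(row[cols["n"]], i, cols["n"])),
                trait=trait,
            )
        except SumstatsError as exc:
            if "non-numeric" in str(exc):
                raise
            warnings.warn(f"row {i} rejected: {exc}", stacklevel=2)
            continue
        records.append(rec)
    if not records:
        warnings.warn(f"{path}: no valid data rows", stacklevel=2)
    ids = [r.snp_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise SumstatsError(f"duplicate snp_id in {path}: {dupes}")
    return records


def harmonize(exposure: Sequence[AssociationRecord],
              outcome: Sequence[AssociationRecord],
              strict_palindromic: bool = False) -> HarmonizedSet:
    """Inner-join exposure and outcome records on snp_id, aligning alleles.

    When the outcome file reports the effect for the opposite allele, the
    outcome beta sign is flipped.  SNPs whose allele pairs do not match at
    all are dropped with a warning.  Palindromic (A/T, C/G) SNPs are kept
    under a same-strand assumption (warned) unless ``strict_palindromic``.
    """
    if not exposure or not outcome:
        raise SumstatsError("harmonize requires non-empty exposure and outcome lists")
    out_by_id = {r.snp_id: r for r in outcome}
    records: list[HarmonizedRecord] = []
    exposure_label = exposure[0].trait or "exposure"
    outcome_label = next(iter(out_by_id.values())).trait or "outcome"
    for ex in exposure:
        oc = out_by_id.get(ex.snp_id)
        if oc is None:
            continue
        if ex.is_palindromic:
            if strict_palindromic:
                warnings.warn(f"{ex.snp_id}: palindromic SNP dropped (strict mode)",
                              stacklevel=2)
                continue
            warnings.warn(f"{ex.snp_id}: palindromic SNP kept, assumed same-strand",
                          stacklevel=2)
        if (oc.effect_allele, oc.other_allele) == (ex.effect_allele, ex.other_allele):
            pass
        elif (oc.effect_allele, oc.other_allele) == (ex.other_allele, ex.effect_allele):
            oc = oc.flip_alleles()
        else:
            warnings.warn(
                f"{ex.snp_id}: allele mismatch "
                f"({ex.effect_allele}/{ex.other_allele} vs "
                f"{oc.effect_allele}/{oc.other_allele}), dropped",
                stacklevel=2,
            )
            continue
        records.append(
            HarmonizedRecord(ex.snp_id, ex.beta, ex.se, oc.beta, oc.se)
        )
    if not records:
        raise SumstatsError("no SNPs shared between exposure and outcome")
    return HarmonizedSet(exposure_label, outcome_label, records, "increase")


def orient_to_decrease(hs: HarmonizedSet) -> HarmonizedSet:
    """Re-sign effects so the causal contrast is per SD *decrease* of exposure.

    Records whose beta_x is already negative follow the shorter-exposure
    allele convention (the effect allele lowers the exposure): beta_x becomes
    its magnitude and beta_y is untouched.  Records entered per the
    exposure-raising allele are first allele-flipped (both betas negated) and
    then magnitude-expressed, which nets out to negating beta_y only.
    Idempotent: an already decrease-oriented set is returned unchanged.
    """
    if hs.orientation == "decrease":
        return hs
    records = []
    for r in hs.records:
        if r.beta_x == 0:
            raise ValueError(f"{r.snp_id}: beta_x = 0, orientation undefined")
        if r.beta_x < 0:
            records.append(replace(r, beta_x=abs(r.beta_x)))
        else:
            records.append(replace(r, beta_y=-r.beta_y))
    return HarmonizedSet(hs.exposure_label, hs.outcome_label, records, "decrease")


def _data_path(name: str):
    return resources.files("mrnet.data").joinpath(name)


def load_instrument_table() -> pd.DataFrame:
    """Full bundled European LTL/ALS instrument table.

    Columns include the published per-instrument PVE and F statistic so QC
    recomputation can be checked against them.  Gene labels are annotations
    only; coordinates are 1-based.
    """
    with resources.as_file(_data_path("eur_ltl_als.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_fixture(name: str):
    """Load a bundled dataset.

    ``eur_ltl_als`` -- the 7 European LTL instruments with their ALS effects,
    as a :class:`HarmonizedSet` (orientation ``increase``: betas as published,
    per the LTL-shortening allele).
    ``eur_paths_table5`` -- the exposure->mediator, mediator->outcome and
    exposure->outcome path coefficient table (a/b/c with SEs and p values)
    for all population x mediator x outcome triples, as a DataFrame.
    """
    if name == "eur_ltl_als":
        df = load_instrument_table()
        return HarmonizedSet.from_arrays(
            df["snp_id"], df["beta_ltl"], df["se_ltl"],
            df["beta_als"], df["se_als"],
            exposure_label="LTL", outcome_label="ALS",
            orientation="increase",
        )
    if name == "eur_paths_table5":
        with resources.as_file(_data_path("eur_paths_table5.tsv")) as p:
            return pd.read_csv(p, sep="\t")
    raise KeyError(f"unknown fixture {name!r}")


def records_from_instrument_table(df: pd.DataFrame, trait: str = "LTL"
                                  ) -> list[AssociationRecord]:
    """Exposure-side AssociationRecords from the bundled instrument table."""
    side = "ltl" if trait.upper() == "LTL" else "als"
    return [
        AssociationRecord(
            snp_id=row.snp_id, chrom=str(row.chrom), pos=int(row.pos),
            effect_allele=row.a1, other_allele=row.a2,
            beta=float(getattr(row, f"beta_{side}")),
            se=float(getattr(row, f"se_{side}")),
            p=float(getattr(row, f"p_{side}")),
            n=int(getattr(row, f"n_{side}")),
            trait=trait.upper(),
        )
        for row in df.itertuples(index=False)
    ]
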