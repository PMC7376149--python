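"""Network-MR mediation analysis with Sobel inference.

Decomposes an exposure->outcome causal effect into an indirect path through
a mediator: path a (exposure->mediator), path b (mediator->outcome) and the
total effect c (exposure->outcome), each estimated by univariable IVW from
its own harmonized instrument set.  The mediation (indirect) effect is the
product of coefficients ab with the first-order delta-method (Sobel)
standard error

    S_ab = sqrt(a^2 SE(b)^2 + b^2 SE(a)^2),  Z = ab / S_ab.

Note the interpretive caveat: b is a standalone univariable mediator->
outcome estimate, not a multivariable estimate adjusted for the exposure,
so ab is an approximation to the indirect effect that is exact only when
the exposure->mediator->outcome paths are linear and non-interacting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, Z95, ivw
from .sumstats import AssociationRecord, HarmonizedSet

#: two-sided p below which a mediated path is labelled suggestive
SUGGESTIVE_P = 0.1


@dataclass
class MediationResult:
    """Path coefficients and the product-of-coefficients mediation effect."""

    exposure: str
    mediator: str
    outcome: str
    a: float
    se_a: float
    b: float
    se_b: float
    ab: float
    s_ab: float
    z: float
    p: float
    ci_low: float
    ci_high: float
    c: float = float("nan")
    se_c: float = float("nan")
    suggestive: bool = False

    @property
    def direct_effect(self) -> float:
        """c' = c - ab (derived output, not part of the published tables)."""
        return self.c - self.ab


def sobel(a: float, se_a: float, b: float, se_b: float,
          exposure: str = "exposure", mediator: str = "mediator",
          outcome: str = "outcome", second_order: bool = False
          ) -> MediationResult:
    """Product-of-coefficients mediation effect with Sobel standard error.

    ``second_order`` adds the se_a^2 * se_b^2 cross term to the variance
    (Aroian variant); the default first-order form is the classical Sobel
    test.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("path standard errors must be positive")
    ab = a * b
    var = a * a * se_b * se_b + b * b * se_a * se_a
    if second_order:
        var += se_a * se_a * se_b * se_b
    s_ab = float(np.sqrt(var))
    if s_ab == 0:
        warnings.warn("a = b = 0: Sobel Z undefined, reported as 0 with p = 1",
                      stacklevel=2)
        z, p = 0.0, 1.0
        s_ab = float(np.sqrt(se_a**2 * se_b**2))  # Aroian floor for the CI
    else:
        z = float(ab / s_ab)
        p = float(2 * stats.norm.sf(abs(z)))
    return MediationResult(
        exposure=exposure, mediator=mediator, outcome=outcome,
        a=a, se_a=se_a, b=b, se_b=se_b,
        ab=float(ab), s_ab=s_ab, z=z, p=p,
        ci_low=float(ab - Z95 * s_ab), ci_high=float(ab + Z95 * s_ab),
        suggestive=p < SUGGESTIVE_P,
    )


def estimate_paths(exp_med: HarmonizedSet, med_out: HarmonizedSet,
                   exp_out: HarmonizedSet, mode: str = "fixed",
                   order: str = "first") -> tuple[MREstimate, MREstimate, MREstimate]:
    """Estimate paths a, b and c by univariable IVW on three harmonized sets.

    Instruments shared between the exposure and mediator sets are allowed
    (each path uses its own set); overlap is reported as a warning because
    it weakens the independence of the a and b estimates.
    """
    overlap = set(exp_med.snp_ids) & set(med_out.snp_ids)
    if overlap:
        warnings.warn(
            f"{len(overlap)} instrument(s) shared between exposure and "
            f"mediator sets: {sorted(overlap)}",
            stacklevel=2,
        )
    a = ivw(exp_med, mode=mode, order=order)
    b = ivw(med_out, mode=mode, order=order)
    c = ivw(exp_out, mode=mode, order=order)
    return a, b, c


def mediation_table(paths: pd.DataFrame, second_order: bool = False
                    ) -> list[MediationResult]:
    """Sobel mediation results for every (exposure, mediator, outcome) row.

    ``paths`` needs columns exposure, mediator, outcome, a, se_a, b, se_b
    (optionally c, se_c).  Rows are returned sorted by (exposure, outcome,
    mediator) so input order never changes the output; rows with p below
    0.1 carry ``suggestive=True``.
    """
    if paths.empty:
        raise ValueError("mediation_table needs at least one mediator row")
    results = []
    for row in paths.itertuples(index=False):
        res = sobel(
            float(row.a), float(row.se_a), float(row.b), float(row.se_b),
            exposure=row.exposure, mediator=row.mediator, outcome=row.outcome,
            second_order=second_order,
        )
        if hasattr(row, "c"):
            res = _dc_replace(res, c=float(row.c), se_c=float(row.se_c))
        results.append(res)
    results.sort(key=lambda r: (r.exposure, r.outcome, r.mediator))
    return results


def mediation_frame(results: list[MediationResult]) -> pd.DataFrame:
    """Publication-layout table: one row per triple with ab (S_ab), CI, Z, p."""
    return pd.DataFrame(
        {
            "exposure": [r.exposure for r in results],
            "mediator": [r.mediator for r in results],
            "outcome": [r.outcome for r in results],
            "ab": [r.ab for r in results],
            "s_ab": [r.s_ab for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "z": [r.z for r in results],
            "p": [r.p for r in results],
            "suggestive": [r.suggestive for r in results],
        }
    )


def rescale_units(records: list[AssociationRecord], factor: float
                  ) -> list[AssociationRecord]:
    """Multiply betas and SEs by a unit-conversion factor (p, n unchanged).

    Used to put mediator GWAS from different populations on a common unit
    (e.g. mmol/L to mg/dL for lipids) before path estimation.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    return [_dc_replace(r, beta=r.beta * factor, se=r.se * factor) for r in records]
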