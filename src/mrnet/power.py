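"""Analytic power for two-sample MR with a binary outcome.

Uses the non-centrality approximation for an IVW-type estimate: the test
statistic for the causal log odds ratio is approximately normal with
non-centrality

    lambda = log(OR) * sqrt(n * R^2 * K * (1 - K)),

where n is the outcome-GWAS sample size, R^2 the exposure variance
explained by the instruments jointly, and K the case fraction.  Two-sided
power at level alpha is Phi(-z_{1-alpha/2} + lambda) +
Phi(-z_{1-alpha/2} - lambda), which equals alpha exactly at OR = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PowerQuery:
    """One cell of a power grid for a binary-outcome MR design."""

    n: int
    r2: float
    case_fraction: float
    odds_ratio: float
    alpha: float = 0.05

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be positive")
        if not (0 < self.r2 < 1):
            raise ValueError("r2 must be in (0, 1)")
        if not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must be in (0, 1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


def mr_power_binary(q: PowerQuery) -> float:
    """Two-sided power to detect the hypothesized odds ratio per SD exposure."""
    lam = np.log(q.odds_ratio) * np.sqrt(
        q.n * q.r2 * q.case_fraction * (1 - q.case_fraction)
    )
    z = stats.norm.ppf(1 - q.alpha / 2)
    return float(stats.norm.cdf(-z + lam) + stats.norm.cdf(-z - lam))


def power_grid(ns, case_fractions, ors, r2: float, alpha: float = 0.05
               ) -> pd.DataFrame:
    """Power over the full Cartesian grid of designs (one row per cell)."""
    if not (len(ns) and len(case_fractions) and len(ors)):
        raise ValueError("all grid axes must be non-empty")
    rows = [
        {
            "n": n,
            "case_fraction": k,
            "odds_ratio": o,
            "r2": r2,
            "alpha": alpha,
            "power": mr_power_binary(PowerQuery(n, r2, k, o, alpha)),
        }
        for n, o, k in product(ns, ors, case_fractions)
    ]
    return pd.DataFrame(rows)
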