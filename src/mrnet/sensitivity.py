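"""Heterogeneity, outlier and pleiotropy diagnostics.

Complements the point estimators with the checks an MR analyst runs before
trusting them: Cochran's Q for ratio heterogeneity, leave-one-out refits,
the simulation-based MR-PRESSO residual test, and a GSMR-style generalized
least squares estimate with HEIDI-outlier filtering that can absorb
linkage disequilibrium between instruments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import ESTIMATORS, MREstimate, _normal_p, ivw, wald_ratio
from .sumstats import HarmonizedSet


@dataclass
class LDMatrix:
    """Pairwise LD correlations between instruments, unit diagonal."""

    snp_ids: list[str]
    r: np.ndarray

    PSD_TOL = 1e-8

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.snp_ids)
        if self.r.shape != (k, k):
            raise ValueError("LD matrix shape does not match snp_ids")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("LD matrix not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-12):
            raise ValueError("LD matrix diagonal must be exactly 1")
        if np.linalg.eigvalsh(self.r).min() < -self.PSD_TOL:
            raise ValueError("LD matrix not positive semi-definite")

    @classmethod
    def identity(cls, snp_ids) -> "LDMatrix":
        snp_ids = list(snp_ids)
        return cls(snp_ids, np.eye(len(snp_ids)))

    @classmethod
    def from_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy())


@dataclass
class OutlierReport:
    """MR-PRESSO output: global test plus per-SNP outlier p-values."""

    global_p: float
    per_snp: pd.DataFrame  # snp_id, rss_contribution, outlier_p, flagged
    n_sim: int
    seed: int

    @property
    def n_flagged(self) -> int:
        return int(self.per_snp["flagged"].sum())


def cochran_q(hs: HarmonizedSet, beta: float, order: str = "first"
              ) -> tuple[float, int, float]:
    """Cochran's Q for ratio heterogeneity about a given causal effect.

    Q = sum_i w_i (r_i - beta)^2, df = k - 1, chi-square upper tail.
    """
    k = len(hs)
    if k < 2:
        raise ValueError("Q needs at least 2 instruments")
    est = [wald_ratio(r.beta_x, r.se_x, r.beta_y, r.se_y, order, r.snp_id)
           for r in hs.records]
    q = float(sum(e.weight * (e.ratio - beta) ** 2 for e in est))
    return q, k - 1, float(stats.chi2.sf(q, k - 1))


def leave_one_out(hs: HarmonizedSet, estimator: str = "ivw-fixed", **kwargs
                  ) -> pd.DataFrame:
    """Refit the estimator k times, each excluding one SNP.

    A row is flagged when the exclusion flips the sign of the causal
    estimate or moves it by more than one full-sample SE — the usual
    single-instrument-dependence screen.
    """
    k = len(hs)
    if k < 3:
        raise ValueError("leave-one-out needs at least 3 instruments")
    fit = ESTIMATORS[estimator]
    full = fit(hs, **kwargs)
    rows = []
    for i in range(k):
        sub = hs.subset([j for j in range(k) if j != i])
        est = fit(sub, **kwargs)
        rows.append(
            {
                "excluded": hs.records[i].snp_id,
                "beta": est.beta,
                "se": est.se,
                "p": est.p,
                "sign_flip": est.beta * full.beta < 0,
                "flagged": est.beta * full.beta < 0
                or abs(est.beta - full.beta) > full.se,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["full_beta"] = full.beta
    df.attrs["full_se"] = full.se
    return df


def _loo_slopes(bx, by, w):
    """Leave-one-out IVW slopes for rows of (bx, by); vectorized over sims.

    bx, by, w have shape (..., k); returns shape (..., k) where entry i is
    the slope fit without SNP i.
    """
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(hs: HarmonizedSet, n_sim: int = 10_000, seed: int = 0,
              threshold: float = 0.05) -> OutlierReport:
    """MR-PRESSO global and per-SNP outlier test.

    The observed statistic is the weighted leave-one-out residual sum of
    squares of the outcome effects about the IVW-fitted slope.  The null
    distribution is simulated by regenerating (beta_x, beta_y) from their
    sampling normals under the fitted (leave-one-out) slopes.  Per-SNP
    outlier p-values compare each observed residual to its simulated
    distribution and are Bonferroni-corrected; a SNP is flagged when the
    corrected p falls below ``threshold``.
    """
    k = len(hs)
    if k < 4:
        raise ValueError("MR-PRESSO needs at least 4 instruments")
    if n_sim < 1000:
        raise ValueError("n_sim must be at least 1000")
    bx, sx, by, sy = hs.beta_x, hs.se_x, hs.beta_y, hs.se_y
    w = 1.0 / sy**2

    slopes = _loo_slopes(bx, by, w)
    obs_res = w * (by - slopes * bx) ** 2
    obs_rss = float(obs_res.sum())

    rng = np.random.default_rng(seed)
    bx_s = rng.normal(bx, sx, size=(n_sim, k))
    by_s = rng.normal(slopes * bx, sy, size=(n_sim, k))
    slopes_s = _loo_slopes(bx_s, by_s, w)
    sim_res = w * (by_s - slopes_s * bx_s) ** 2
    sim_rss = sim_res.sum(axis=1)

    global_p = float((np.sum(sim_rss >= obs_rss) + 1) / (n_sim + 1))
    outlier_p = (np.sum(sim_res >= obs_res, axis=0) + 1) / (n_sim + 1)
    adj_p = np.minimum(1.0, outlier_p * k)
    per_snp = pd.DataFrame(
        {
            "snp_id": hs.snp_ids,
            "rss_contribution": obs_res,
            "outlier_p": outlier_p,
            "flagged": adj_p < threshold,
        }
    )
    return OutlierReport(global_p=global_p, per_snp=per_snp, n_sim=n_sim, seed=seed)


def heidi_outlier(hs: HarmonizedSet, threshold: float = 0.01,
                  reference: str | None = None) -> tuple[HarmonizedSet, list[str]]:
    """HEIDI-style outlier screen against the strongest instrument's ratio.

    The reference SNP (largest |beta_x|/se_x unless named) defines the
    consensus ratio; any other SNP whose ratio deviates from it with
    p < threshold is removed as pleiotropic.
    """
    bx, sx, by, sy = hs.beta_x, hs.se_x, hs.beta_y, hs.se_y
    if reference is None:
        ref = int(np.argmax(np.abs(bx) / sx))
    else:
        ref = hs.snp_ids.index(reference)
    r = by / bx
    var_r = sy**2 / bx**2  # first-order ratio variances
    d = r - r[ref]
    var_d = var_r + var_r[ref]
    var_d[ref] = np.inf  # reference never tests against itself
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 2 * stats.norm.sf(np.abs(d) / np.sqrt(var_d))
    p[ref] = 1.0
    keep = p >= threshold
    keep[ref] = True
    removed = [s for s, k_ in zip(hs.snp_ids, keep) if not k_]
    return hs.subset(keep), removed


def gsmr(hs: HarmonizedSet, ld: LDMatrix | None = None,
         heidi_threshold: float = 0.01, reference: str | None = None,
         level: float = 0.95) -> MREstimate:
    """GSMR: generalized least squares over Wald ratios with LD covariance.

    HEIDI-outlier filtering runs first; the surviving ratios are combined
    by GLS with covariance Sigma_ij = rho_ij * se_i * se_j, where rho is
    the LD correlation.  With identity LD and no removals this reduces
    exactly to fixed-effects IVW.
    """
    if ld is None:
        ld = LDMatrix.identity(hs.snp_ids)
    missing = set(hs.snp_ids) - set(ld.snp_ids)
    if missing:
        raise ValueError(f"LD matrix missing instruments: {sorted(missing)}")

    kept, removed = heidi_outlier(hs, heidi_threshold, reference)
    if len(kept) == 1:
        r0 = kept.records[0]
        w = wald_ratio(r0.beta_x, r0.se_x, r0.beta_y, r0.se_y, "first", r0.snp_id)
        return MREstimate(
            method="gsmr", beta=w.ratio, se=w.se_ratio,
            p=_normal_p(w.ratio / w.se_ratio), n_snps=1, level=level,
            diagnostics={"heidi_removed": removed, "fallback": "wald_ratio"},
        )

    idx = [ld.snp_ids.index(s) for s in kept.snp_ids]
    rho = ld.r[np.ix_(idx, idx)]
    r = kept.beta_y / kept.beta_x
    se_r = kept.se_y / np.abs(kept.beta_x)
    sigma = rho * np.outer(se_r, se_r)
    sigma_inv = np.linalg.pinv(sigma)
    one = np.ones(len(kept))
    denom = float(one @ sigma_inv @ one)
    beta = float(one @ sigma_inv @ r / denom)
    se = float(1.0 / np.sqrt(denom))
    return MREstimate(
        method="gsmr",
        beta=beta,
        se=se,
        p=_normal_p(beta / se),
        n_snps=len(kept),
        level=level,
        diagnostics={"heidi_removed": removed,
                     "heidi_threshold": heidi_threshold},
    )


__all__ = [
    "LDMatrix", "OutlierReport", "cochran_q", "leave_one_out", "mr_presso",
    "heidi_outlier", "gsmr", "ivw",
]
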