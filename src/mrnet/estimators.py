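"""Two-sample MR causal-effect estimators.

All estimators consume a :class:`~mrnet.sumstats.HarmonizedSet` and return
an :class:`MREstimate` with the causal effect on the outcome scale per 1-SD
change of the exposure in the set's stated orientation.  For a binary
outcome the effect is a log odds ratio; :func:`to_odds_ratio` exponentiates.

Implemented methods:

* per-SNP Wald ratio (the building block),
* inverse-variance weighted (IVW), fixed- and multiplicative random-effects,
* MR-Egger weighted regression with a free pleiotropy intercept,
* weighted median (consistent when >= 50% of weight is valid),
* maximum likelihood under the joint normal measurement model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .sumstats import HarmonizedSet

#: normal quantile used for 95% confidence intervals
Z95 = 1.959964


class EstimationError(RuntimeError):
    pass


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio with its standard error and IVW weight."""

    snp_id: str
    ratio: float
    se_ratio: float

    @property
    def weight(self) -> float:
        return 1.0 / self.se_ratio**2


@dataclass
class MREstimate:
    """A causal-effect estimate with normal-theory CI and p-value."""

    method: str
    beta: float
    se: float
    p: float
    n_snps: int
    level: float = 0.95
    ci_low: float = field(default=None)  # type: ignore[assignment]
    ci_high: float = field(default=None)  # type: ignore[assignment]
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.se <= 0:
            raise EstimationError(f"{self.method}: non-positive SE")
        z = stats.norm.ppf(0.5 + self.level / 2)
        if self.ci_low is None:
            self.ci_low = self.beta - z * self.se
        if self.ci_high is None:
            self.ci_high = self.beta + z * self.se

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "n_snps": self.n_snps,
        }
        d.update({f"diag_{k}": v for k, v in self.diagnostics.items()})
        return d


def _normal_p(z: float) -> float:
    return float(2 * stats.norm.sf(abs(z)))


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float,
               order: str = "first", snp_id: str = "") -> RatioEstimate:
    """Single-SNP causal estimate beta_y / beta_x.

    ``order`` selects the delta-method expansion for the SE: first-order
    ignores uncertainty in beta_x (se_y / |beta_x|); second-order adds the
    beta_x sampling term and is never smaller.
    """
    if beta_x == 0:
        raise EstimationError(f"{snp_id or 'record'}: beta_x = 0, ratio undefined")
    ratio = beta_y / beta_x
    if order == "first":
        se = se_y / abs(beta_x)
    elif order == "second":
        se = np.sqrt(se_y**2 / beta_x**2 + beta_y**2 * se_x**2 / beta_x**4)
    else:
        raise ValueError(f"unknown SE order {order!r}")
    return RatioEstimate(snp_id, float(ratio), float(se))


def ratio_estimates(hs: HarmonizedSet, order: str = "first") -> list[RatioEstimate]:
    return [
        wald_ratio(r.beta_x, r.se_x, r.beta_y, r.se_y, order=order, snp_id=r.snp_id)
        for r in hs.records
    ]


def _ratio_arrays(hs: HarmonizedSet, order: str):
    est = ratio_estimates(hs, order)
    r = np.array([e.ratio for e in est])
    w = np.array([e.weight for e in est])
    return r, w


def ivw(hs: HarmonizedSet, mode: str = "fixed", order: str = "first",
        level: float = 0.95) -> MREstimate:
    """Inverse-variance weighted meta-analysis of the per-SNP Wald ratios.

    The point estimate is identical in fixed and random mode; the
    multiplicative random-effects model inflates the SE by
    max(1, sqrt(Q / (k - 1))) so random-effects intervals never undercut
    fixed-effects ones.
    """
    if mode not in ("fixed", "random"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    k = len(hs)
    if k == 1:
        warnings.warn("single instrument: IVW degenerates to the Wald ratio",
                      stacklevel=2)
    r, w = _ratio_arrays(hs, order)
    beta = float(np.sum(w * r) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (r - beta) ** 2))
    re_scale = 1.0
    if mode == "random" and k > 1:
        re_scale = max(1.0, np.sqrt(q / (k - 1)))
        se *= re_scale
    q_p = float(stats.chi2.sf(q, k - 1)) if k > 1 else float("nan")
    return MREstimate(
        method=f"ivw-{mode}",
        beta=beta,
        se=se,
        p=_normal_p(beta / se),
        n_snps=k,
        level=level,
        diagnostics={"Q": q, "Q_df": k - 1, "Q_p": q_p, "re_scale": re_scale,
                     "se_order": order},
    )


def egger(hs: HarmonizedSet, level: float = 0.95,
          use_t: bool = False) -> MREstimate:
    """MR-Egger: WLS of beta_y on beta_x with a free intercept.

    The slope estimates the causal effect under the InSIDE assumption; a
    non-zero intercept indicates directional pleiotropy.  Weights are
    1/se_y^2 and SEs carry a multiplicative residual scale floored at 1.
    Requires all beta_x oriented to the same (non-negative) sign so the
    intercept is interpretable.
    """
    k = len(hs)
    if k < 3:
        raise EstimationError("MR-Egger needs at least 3 instruments")
    bx, by, sy = hs.beta_x, hs.beta_y, hs.se_y
    if np.any(bx < 0) and np.any(bx > 0):
        raise EstimationError(
            "MR-Egger requires consistently oriented beta_x; call "
            "orient_to_decrease() first"
        )
    bx = np.abs(bx)
    by = np.where(hs.beta_x < 0, -by, by)  # keep ratio signs intact
    if np.ptp(bx) == 0:
        raise EstimationError("all beta_x identical: Egger slope unidentified")
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    scale = max(1.0, np.sqrt(fit.scale))
    # statsmodels bse already include sqrt(fit.scale); refloor at 1
    bse = fit.bse / np.sqrt(fit.scale) * scale
    slope, slope_se = float(fit.params[1]), float(bse[1])
    icpt, icpt_se = float(fit.params[0]), float(bse[0])
    if use_t:
        df = k - 2
        pfun = lambda z: float(2 * stats.t.sf(abs(z), df))
        q = stats.t.ppf(0.5 + level / 2, df)
    else:
        pfun = _normal_p
        q = stats.norm.ppf(0.5 + level / 2)
    return MREstimate(
        method="egger",
        beta=slope,
        se=slope_se,
        p=pfun(slope / slope_se),
        n_snps=k,
        level=level,
        ci_low=slope - q * slope_se,
        ci_high=slope + q * slope_se,
        diagnostics={
            "egger_intercept": icpt,
            "intercept_se": icpt_se,
            "intercept_p": pfun(icpt / icpt_se),
            "residual_scale": float(scale),
        },
    )


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weight-interpolated median of the per-SNP ratios.

    Sort ratios, form standardized cumulative weights
    s_i = (cum_i - w_i/2) / sum(w), and linearly interpolate at s = 0.5.
    """
    order = np.argsort(ratios)
    r, w = np.asarray(ratios)[order], np.asarray(weights)[order]
    cw = np.cumsum(w)
    s = (cw - w / 2) / cw[-1]
    return float(np.interp(0.5, s, r))


def weighted_median(hs: HarmonizedSet, n_boot: int = 10_000, seed: int = 0,
                    order: str = "first", level: float = 0.95) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap standard error.

    Consistent when instruments carrying at least half the total weight are
    valid.  The SE resamples (beta_x, beta_y) from their sampling normals,
    recomputes the weighted median, and takes the SD across replicates.
    """
    k = len(hs)
    if k < 3:
        raise EstimationError("weighted median needs at least 3 instruments")
    r, w = _ratio_arrays(hs, order)
    point = weighted_median_point(r, w)

    rng = np.random.default_rng(seed)
    bx = rng.normal(hs.beta_x, hs.se_x, size=(n_boot, k))
    by = rng.normal(hs.beta_y, hs.se_y, size=(n_boot, k))
    bad = bx == 0
    if bad.any():  # measure-zero guard
        bx[bad] = np.finfo(float).tiny
    rb = by / bx
    if order == "first":
        seb = hs.se_y / np.abs(bx)
    else:
        seb = np.sqrt(hs.se_y**2 / bx**2 + by**2 * hs.se_x**2 / bx**4)
    wb = 1.0 / seb**2
    boots = np.array([weighted_median_point(rb[i], wb[i]) for i in range(n_boot)])
    se = float(np.std(boots, ddof=1))
    return MREstimate(
        method="weighted-median",
        beta=point,
        se=se,
        p=_normal_p(point / se),
        n_snps=k,
        level=level,
        diagnostics={"n_boot": n_boot, "seed": seed, "se_order": order},
    )


def _profile_negloglik(theta: float, bx, sx, by, sy) -> float:
    """-log L profiled over the per-SNP true exposure effects xi_i.

    Model: beta_x_i ~ N(xi_i, se_x_i^2), beta_y_i ~ N(theta xi_i, se_y_i^2),
    independent across SNPs.  For fixed theta the xi_i maximizer is the
    precision-weighted combination below, so theta can be optimized in 1-D.
    """
    xi = (bx / sx**2 + theta * by / sy**2) / (1.0 / sx**2 + theta**2 / sy**2)
    return float(0.5 * np.sum((bx - xi) ** 2 / sx**2 + (by - theta * xi) ** 2 / sy**2))


def max_likelihood(hs: HarmonizedSet, tol: float = 1e-10, max_iter: int = 200,
                   level: float = 0.95) -> MREstimate:
    """Maximum-likelihood causal estimate under the joint normal model.

    The per-SNP true exposure effects are profiled out analytically, leaving
    a one-dimensional profile likelihood that is minimized by Brent's method
    bracketed around the IVW starting value (tolerance ``tol`` on theta);
    the SE comes from the numerical curvature of the profile log-likelihood
    (which equals the observed information for theta).
    """
    bx, sx, by, sy = hs.beta_x, hs.se_x, hs.beta_y, hs.se_y
    if len(hs) == 1:
        theta0 = by[0] / bx[0]
    else:
        theta0 = ivw(hs).beta
    spread = max(1.0, abs(theta0))
    res = optimize.minimize_scalar(
        lambda t: _profile_negloglik(t, bx, sx, by, sy),
        bracket=(theta0, theta0 + spread),
        method="brent",
        options={"xtol": tol, "maxiter": max_iter},
    )
    if not res.success:
        raise EstimationError(f"likelihood optimization failed: {res}")
    theta = float(res.x)
    h = 1e-5 * max(1.0, abs(theta))
    d2 = (
        _profile_negloglik(theta + h, bx, sx, by, sy)
        - 2 * _profile_negloglik(theta, bx, sx, by, sy)
        + _profile_negloglik(theta - h, bx, sx, by, sy)
    ) / h**2
    if d2 <= 0:
        raise EstimationError("non-positive observed information at optimum")
    se = float(1.0 / np.sqrt(d2))
    return MREstimate(
        method="likelihood",
        beta=theta,
        se=se,
        p=_normal_p(theta / se),
        n_snps=len(hs),
        level=level,
        diagnostics={"n_iter": int(res.nit), "converged": bool(res.success),
                     "theta0": float(theta0)},
    )


def to_odds_ratio(est: MREstimate) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate and its CI endpoints."""
    return (float(np.exp(est.beta)), float(np.exp(est.ci_low)),
            float(np.exp(est.ci_high)))


#: estimator registry used by leave-one-out and the pipeline
ESTIMATORS = {
    "ivw-fixed": lambda hs, **kw: ivw(hs, mode="fixed", **kw),
    "ivw-random": lambda hs, **kw: ivw(hs, mode="random", **kw),
    "egger": lambda hs, **kw: egger(hs, **kw),
    "weighted-median": lambda hs, **kw: weighted_median(hs, **kw),
    "likelihood": lambda hs, **kw: max_likelihood(hs, **kw),
}
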