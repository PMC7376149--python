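"""Synthetic two-sample GWAS summary statistics with known ground truth.

Generates the statistical structure the estimators assume: per-SNP true
exposure effects xi_i, observed exposure effects beta_x_i ~ N(xi_i,
se_x^2), and observed outcome effects beta_y_i ~ N(theta xi_i + pleio_i +
outlier_i, se_y^2).  Standard errors follow the simplest model consistent
with the binary-outcome power calculation: se_x = 1/sqrt(n_exp) for the
quantitative exposure and se_y = 1/sqrt(n_out K (1 - K)) for the binary
outcome (K = case fraction).

Defaults emulate the telomere-length -> ALS design this package was
validated on: 7 instruments with exposure effects near 0.066 SD, an
exposure GWAS of ~37,700 and an outcome GWAS of ~80,600 with 25.8% cases.

One global seed spawns independent child streams (true effects, exposure
noise, outcome noise, pleiotropy, mediator noise) so that changing one
source of randomness never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .sumstats import HarmonizedSet


@dataclass
class SyntheticTruth:
    """Generative parameters for one synthetic two-sample dataset."""

    k: int = 7
    theta: float = 0.1
    xi_mean: float = 0.066
    xi_sd: float = 0.011
    n_exp: int = 37_684
    n_out: int = 80_610
    case_fraction: float = 0.258
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    n_outliers: int = 0
    outlier_shift: float = 0.0
    mediation: tuple[float, float, float] | None = None  # (a, b, direct)
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.xi_sd < 0 or self.pleiotropy_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0 <= self.n_outliers <= self.k:
            raise ValueError("n_outliers must be in [0, k]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"bad pleiotropy mode {self.pleiotropy_mode!r}")

    @property
    def se_x(self) -> float:
        return 1.0 / np.sqrt(self.n_exp)

    @property
    def se_y(self) -> float:
        kk = self.case_fraction
        return 1.0 / np.sqrt(self.n_out * kk * (1 - kk))

    def streams(self, n: int = 5) -> list[np.random.Generator]:
        seqs = np.random.SeedSequence(self.seed).spawn(n)
        return [np.random.default_rng(s) for s in seqs]


def _pleiotropy(truth: SyntheticTruth, rng: np.random.Generator) -> np.ndarray:
    if truth.pleiotropy_mode == "none":
        return np.zeros(truth.k)
    mean = truth.pleiotropy_mean if truth.pleiotropy_mode == "directional" else 0.0
    return rng.normal(mean, truth.pleiotropy_sd, truth.k)


def simulate_two_sample(truth: SyntheticTruth
                        ) -> tuple[HarmonizedSet, SyntheticTruth]:
    """Draw one synthetic harmonized exposure/outcome dataset.

    Outlier contamination shifts the outcome effect of the first
    ``n_outliers`` SNPs by ``outlier_shift`` units of the first-order ratio
    SE (on the beta_y scale), mimicking gross horizontal pleiotropy.
    """
    rng_xi, rng_x, rng_y, rng_pl, _ = truth.streams()
    xi = rng_xi.normal(truth.xi_mean, truth.xi_sd, truth.k)
    se_x = np.full(truth.k, truth.se_x)
    se_y = np.full(truth.k, truth.se_y)
    pleio = _pleiotropy(truth, rng_pl)
    mean_y = truth.theta * xi + pleio
    if truth.n_outliers:
        mean_y[: truth.n_outliers] += truth.outlier_shift * se_y[: truth.n_outliers]
    beta_x = rng_x.normal(xi, se_x) if truth.xi_sd or truth.se_x else xi.copy()
    beta_y = rng_y.normal(mean_y, se_y)
    hs = HarmonizedSet.from_arrays(
        [f"snp{i + 1}" for i in range(truth.k)],
        beta_x, se_x, beta_y, se_y,
        exposure_label="sim_exposure", outcome_label="sim_outcome",
        orientation="increase",
    )
    return hs, truth


def simulate_noiseless(truth: SyntheticTruth) -> HarmonizedSet:
    """Degenerate noise-free draw: beta_y = theta * beta_x exactly.

    SEs are kept at a tiny positive floor so estimator preconditions hold.
    """
    rng_xi, *_ = truth.streams()
    xi = rng_xi.normal(truth.xi_mean, truth.xi_sd, truth.k)
    eps = 1e-8
    return HarmonizedSet.from_arrays(
        [f"snp{i + 1}" for i in range(truth.k)],
        xi, np.full(truth.k, eps), truth.theta * xi, np.full(truth.k, eps),
        exposure_label="sim_exposure", outcome_label="sim_outcome",
        orientation="increase",
    )


def simulate_mediation(truth: SyntheticTruth
                       ) -> tuple[HarmonizedSet, HarmonizedSet, HarmonizedSet,
                                  SyntheticTruth]:
    """Synthetic exposure->mediator->outcome triplet of harmonized sets.

    With mediation = (a, b, direct): the exposure instruments' mediator
    effects are a * xi_i, the mediator has its own instrument set with
    effects zeta_j whose outcome effects are b * zeta_j, and the exposure->
    outcome effects are (direct + a * b) * xi_i, so the total effect equals
    direct + ab in expectation.
    """
    if truth.mediation is None:
        raise ValueError("truth.mediation must be set")
    a, b, direct = truth.mediation
    rng_xi, rng_x, rng_y, rng_pl, rng_med = truth.streams()
    xi = rng_xi.normal(truth.xi_mean, truth.xi_sd, truth.k)
    zeta = rng_med.normal(truth.xi_mean, truth.xi_sd, truth.k)
    se_x = np.full(truth.k, truth.se_x)
    se_m = np.full(truth.k, truth.se_x)  # mediator treated as quantitative
    se_y = np.full(truth.k, truth.se_y)

    exp_ids = [f"esnp{i + 1}" for i in range(truth.k)]
    med_ids = [f"msnp{i + 1}" for i in range(truth.k)]

    exp_med = HarmonizedSet.from_arrays(
        exp_ids,
        rng_x.normal(xi, se_x), se_x,
        rng_y.normal(a * xi, se_m), se_m,
        exposure_label="sim_exposure", outcome_label="sim_mediator",
        orientation="increase",
    )
    med_out = HarmonizedSet.from_arrays(
        med_ids,
        rng_med.normal(zeta, se_m), se_m,
        rng_pl.normal(b * zeta, se_y), se_y,
        exposure_label="sim_mediator", outcome_label="sim_outcome",
        orientation="increase",
    )
    exp_out = HarmonizedSet.from_arrays(
        exp_ids,
        rng_x.normal(xi, se_x), se_x,
        rng_y.normal((direct + a * b) * xi, se_y), se_y,
        exposure_label="sim_exposure", outcome_label="sim_outcome",
        orientation="increase",
    )
    return exp_med, med_out, exp_out, truth


def inject_outlier(hs: HarmonizedSet, index: int, shift: float) -> HarmonizedSet:
    """Displace one SNP's outcome effect by ``shift`` ratio-SE units.

    Adds shift * (se_y_i / |beta_x_i|) * beta_x_i to beta_y at ``index``;
    additive, so successive shifts compose.
    """
    if not 0 <= index < len(hs):
        raise IndexError(f"index {index} out of range for k={len(hs)}")
    rec = hs.records[index]
    delta = shift * (rec.se_y / abs(rec.beta_x)) * rec.beta_x
    records = list(hs.records)
    records[index] = replace(rec, beta_y=rec.beta_y + delta)
    return HarmonizedSet(hs.exposure_label, hs.outcome_label, records,
                         hs.orientation)
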