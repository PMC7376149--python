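"""End-to-end orchestration of a two-sample / network MR study.

A single config document drives instrument selection, harmonization,
orientation, QC, every estimator, the sensitivity suite and (optionally)
mediation and power, writing a deterministic bundle of TSV/JSON results
plus a markdown report.  Every threshold, seed and dropped SNP is logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimators as est
from . import mediation as med
from . import power as pw
from . import qc, sensitivity
from .sumstats import HarmonizedSet, harmonize, orient_to_decrease, read_sumstats

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated study configuration (paths, thresholds, seeds)."""

    exposure_path: str
    outcome_path: str
    out_dir: str
    exposure_columns: dict | None = None
    outcome_columns: dict | None = None
    p_threshold: float = qc.GENOME_WIDE_P
    window_bp: int = qc.DEFAULT_WINDOW_BP
    bonferroni_alpha: float = 0.05
    loci: list = field(default_factory=list)
    orient: str = "decrease"
    se_order: str = "first"
    n_boot: int = 10_000
    n_sim: int = 10_000
    heidi_threshold: float = 0.01
    ld_matrix_path: str | None = None
    seed: int = 0
    level: float = 0.95
    mediators: list = field(default_factory=list)
    power: dict | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        try:
            cfg = cls(**doc)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in (self.exposure_path, self.outcome_path):
            if not Path(p).exists():
                raise ConfigError(f"missing input file: {p}")
        if self.ld_matrix_path and not Path(self.ld_matrix_path).exists():
            raise ConfigError(f"missing LD matrix: {self.ld_matrix_path}")
        if self.orient not in ("increase", "decrease"):
            raise ConfigError(f"bad orientation {self.orient!r}")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _select_instruments(config: RunConfig):
    exposure = read_sumstats(config.exposure_path, config.exposure_columns,
                             trait="exposure")
    outcome = read_sumstats(config.outcome_path, config.outcome_columns,
                            trait="outcome")
    selected = qc.select_by_pvalue(exposure, config.p_threshold)
    for r in set(r.snp_id for r in exposure) - set(r.snp_id for r in selected):
        logger.info("dropped %s: p >= %g", r, config.p_threshold)
    if config.loci:
        kept = qc.exclude_near_loci(selected, [tuple(l) for l in config.loci],
                                    config.window_bp)
        for r in set(x.snp_id for x in selected) - set(x.snp_id for x in kept):
            logger.info("dropped %s: within %d bp of outcome locus",
                        r, config.window_bp)
        selected = kept
    pruned = qc.prune_outcome_associated(selected, outcome,
                                         config.bonferroni_alpha)
    for r in set(x.snp_id for x in selected) - set(x.snp_id for x in pruned):
        logger.info("dropped %s: Bonferroni-significant outcome association", r)
    if not pruned:
        raise StageError("selection", ValueError("no instruments survive selection"))
    return pruned, outcome


def analyze_harmonized(hs: HarmonizedSet, config: RunConfig) -> dict:
    """Run every estimator and sensitivity analysis on one harmonized set."""
    results: dict = {"n_snps": len(hs), "orientation": hs.orientation}
    estimates = {}
    estimates["ivw-fixed"] = est.ivw(hs, "fixed", config.se_order, config.level)
    estimates["ivw-random"] = est.ivw(hs, "random", config.se_order, config.level)
    if len(hs) >= 3:
        estimates["egger"] = est.egger(hs, config.level)
        estimates["weighted-median"] = est.weighted_median(
            hs, config.n_boot, config.seed, config.se_order, config.level)
    estimates["likelihood"] = est.max_likelihood(hs, level=config.level)
    if config.ld_matrix_path:
        ld = sensitivity.LDMatrix.from_tsv(config.ld_matrix_path)
    else:
        ld = None
    estimates["gsmr"] = sensitivity.gsmr(hs, ld, config.heidi_threshold,
                                         level=config.level)
    rows = []
    for name, e in estimates.items():
        or_, lo, hi = est.to_odds_ratio(e)
        d = e.to_dict()
        d.update({"odds_ratio": or_, "or_ci_low": lo, "or_ci_high": hi})
        rows.append(d)
    results["estimates"] = rows

    q, df, qp = sensitivity.cochran_q(hs, estimates["ivw-fixed"].beta,
                                      config.se_order)
    results["cochran_q"] = {"Q": q, "df": df, "p": qp}
    if len(hs) >= 4:
        loo = sensitivity.leave_one_out(hs, "ivw-fixed", order=config.se_order)
        results["leave_one_out"] = loo.to_dict(orient="records")
        presso = sensitivity.mr_presso(hs, config.n_sim, config.seed)
        results["mr_presso"] = {
            "global_p": presso.global_p,
            "n_flagged": presso.n_flagged,
            "n_sim": presso.n_sim,
            "seed": presso.seed,
            "per_snp": presso.per_snp.to_dict(orient="records"),
        }
    return results


def run_mr(config: RunConfig) -> dict:
    """Full pipeline: select -> exclude -> prune -> harmonize -> orient ->
    QC -> estimators -> sensitivity.  Writes the result bundle to out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        instruments, outcome = _select_instruments(config)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("selection", exc) from exc

    try:
        hs = harmonize(instruments, outcome)
        if config.orient == "decrease":
            hs = orient_to_decrease(hs)
    except Exception as exc:
        raise StageError("harmonization", exc) from exc

    try:
        qc_df = qc.qc_table(instruments)
    except Exception as exc:
        raise StageError("qc", exc) from exc

    try:
        results = analyze_harmonized(hs, config)
    except Exception as exc:
        raise StageError("estimation", exc) from exc

    results["qc"] = qc_df.to_dict(orient="records")
    results["config"] = {
        k: v for k, v in vars(config).items() if not k.startswith("_")
    }

    if config.power:
        grid = pw.power_grid(**config.power)
        grid.to_csv(out / "power_grid.tsv", sep="\t", index=False)
        results["power"] = grid.to_dict(orient="records")

    hs.to_tsv(out / "harmonized.tsv")
    qc_df.to_csv(out / "instrument_qc.tsv", sep="\t", index=False)
    pd.DataFrame(results["estimates"]).to_csv(out / "estimates.tsv", sep="\t",
                                              index=False)
    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=_json_default)
    (out / "report.md").write_text(render_report(results))
    return results


def run_mediation(config: RunConfig) -> dict:
    """Per-mediator a/b/c path estimation plus the Sobel mediation table.

    Each mediator block names the exposure->mediator and mediator->outcome
    summary files (sharing the study's exposure->outcome set).
    """
    if not config.mediators:
        raise ConfigError("run_mediation needs at least one mediator block")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for block in config.mediators:
        name = block.get("name", "mediator")
        try:
            em = _read_pair(block["exposure_mediator"])
            mo = _read_pair(block["mediator_outcome"])
            eo = _read_pair(block["exposure_outcome"])
            a, b, c = med.estimate_paths(em, mo, eo, order=config.se_order)
        except KeyError as exc:
            raise ConfigError(f"mediator {name!r}: missing key {exc}") from exc
        except FileNotFoundError as exc:
            raise StageError(f"mediation[{name}]", exc) from exc
        rows.append(
            {"exposure": em.exposure_label, "mediator": name,
             "outcome": eo.outcome_label,
             "a": a.beta, "se_a": a.se, "b": b.beta, "se_b": b.se,
             "c": c.beta, "se_c": c.se}
        )
    paths = pd.DataFrame(rows)
    results = med.mediation_table(paths)
    frame = med.mediation_frame(results)
    paths.to_csv(out / "paths.tsv", sep="\t", index=False)
    frame.to_csv(out / "mediation.tsv", sep="\t", index=False)
    bundle = {"paths": paths.to_dict(orient="records"),
              "mediation": frame.to_dict(orient="records")}
    with open(out / "mediation.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True, default=_json_default)
    return bundle


def _read_pair(spec: dict) -> HarmonizedSet:
    """Harmonized set from a {exposure: path, outcome: path} file pair
    or directly from a harmonized TSV ({harmonized: path})."""
    if "harmonized" in spec:
        df = pd.read_csv(spec["harmonized"], sep="\t")
        return HarmonizedSet.from_arrays(
            df["snp_id"], df["beta_x"], df["se_x"], df["beta_y"], df["se_y"],
            exposure_label=spec.get("exposure_label", "exposure"),
            outcome_label=spec.get("outcome_label", "outcome"),
        )
    exposure = read_sumstats(spec["exposure"], trait=spec.get("exposure_label", ""))
    outcome = read_sumstats(spec["outcome"], trait=spec.get("outcome_label", ""))
    hs = harmonize(exposure, outcome)
    if spec.get("orient", "decrease") == "decrease":
        hs = orient_to_decrease(hs)
    return hs


def _fmt_or(or_, lo, hi, p):
    return f"{or_:.2f} ({lo:.2f}–{hi:.2f}, {p:.3f})"


def render_report(results: dict) -> str:
    """Deterministic markdown report; every number comes from the bundle."""
    lines = ["# Two-sample MR report", ""]
    orient = results.get("orientation", "increase")
    direction = "per SD decrease" if orient == "decrease" else "per SD increase"
    lines += [
        f"Causal effects are expressed {direction} of the exposure; "
        f"{results['n_snps']} instruments.",
        "",
    ]
    if results.get("qc"):
        lines += ["## Instrument strength", "",
                  "| SNP | PVE | F |", "|---|---|---|"]
        for row in results["qc"]:
            lines.append(f"| {row['snp_id']} | {row['pve']:.3g} | "
                         f"{row['f_stat']:.1f} |")
        lines.append("")
    lines += ["## Causal estimates", "",
              "| Method | OR (95% CI, p) | beta | SE |", "|---|---|---|---|"]
    for row in results["estimates"]:
        lines.append(
            f"| {row['method']} | "
            f"{_fmt_or(row['odds_ratio'], row['or_ci_low'], row['or_ci_high'], row['p'])} | "
            f"{row['beta']:.4f} | {row['se']:.4f} |"
        )
    lines.append("")
    sens = []
    if "cochran_q" in results:
        cq = results["cochran_q"]
        sens.append(f"Cochran's Q = {cq['Q']:.3f} (df {cq['df']}, p = {cq['p']:.3f}).")
    if "mr_presso" in results:
        mp = results["mr_presso"]
        sens.append(
            f"MR-PRESSO global p = {mp['global_p']:.4f}; "
            f"{mp['n_flagged']} outlier(s) flagged "
            f"({mp['n_sim']} simulations, seed {mp['seed']})."
        )
    if "leave_one_out" in results:
        flips = sum(r["sign_flip"] for r in results["leave_one_out"])
        sens.append(f"Leave-one-out: {len(results['leave_one_out'])} refits, "
                    f"{flips} sign flip(s).")
    if sens:
        lines += ["## Sensitivity", ""] + sens + [""]
    else:
        lines += ["## Sensitivity", "", "No sensitivity analyses were run "
                  "(fewer than 4 instruments).", ""]
    return "\n".join(lines)
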