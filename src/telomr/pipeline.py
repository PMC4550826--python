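"""End-to-end per-outcome MR analysis and report tables.

For each outcome the pipeline builds the harmonized instrument set, tabulates
per-SNP odds ratios, runs both causal estimators on three instrument-set
variants — "all" (every instrument), "strict" (questionable exposure
associations removed), and "goodness-of-fit based" (after stepwise Q_rs
pruning) — and records the heterogeneity test before and after pruning plus
scatter-plot-ready data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import TelomrError
from .estimators import (
    MrEstimate,
    Z95,
    ivw_estimate,
    likelihood_estimate,
    per_snp_odds_ratios,
)
from .heterogeneity import (
    GofReport,
    PruneHistory,
    gof_statistic,
    stepwise_prune,
    strict_subset,
)
from .summary_io import (
    InstrumentSet,
    build_instrument_set,
    read_exposure_table,
    read_outcome_table,
)

logger = logging.getLogger("telomr")

DEFAULT_STRICT_DROP = ("rs6772228",)


@dataclass
class AnalysisConfig:
    """Inputs and knobs for a full multi-outcome analysis run."""

    exposure_path: str | Path
    outcome_paths: dict[str, str | Path]
    exposure_dialect: Mapping[str, str] | str | None = None
    outcome_dialect: Mapping[str, str] | str | None = None
    exclusions: dict[str, str] = field(default_factory=dict)
    proxy_map: dict[str, str] = field(default_factory=dict)
    strict_drop: tuple[str, ...] = DEFAULT_STRICT_DROP
    alpha_gof: float = 0.05
    prune_floor: int = 3
    allow_palindromic: bool = False
    rho: float = 0.0
    seed: int = 0
    output_dir: str | Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise TelomrError(f"unknown config keys: {sorted(unknown)}")
        for req in ("exposure_path", "outcome_paths"):
            if req not in raw:
                raise TelomrError(f"config is missing required key {req!r}")
        if "strict_drop" in raw:
            raw["strict_drop"] = tuple(raw["strict_drop"])
        return cls(**raw)


@dataclass
class ScatterData:
    """Plot-ready per-SNP effects with CIs, the fitted slope and the
    correlation r between |x| and |y| magnitudes."""

    table: pd.DataFrame
    slope: float
    r: float


@dataclass
class OutcomeReport:
    outcome_label: str
    instruments: InstrumentSet
    per_snp: pd.DataFrame
    estimates: list[MrEstimate]
    gof_before: GofReport
    prune_history: PruneHistory
    gof_after: GofReport
    scatter: ScatterData
    analysis_snp_ids: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class RunReport:
    outcomes: dict[str, OutcomeReport]
    errors: dict[str, str] = field(default_factory=dict)

    def estimates_frame(self) -> pd.DataFrame:
        rows = []
        for label, rep in self.outcomes.items():
            for est in rep.estimates:
                rows.append({"outcome": label, **est.to_row()})
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        out: dict = {"errors": dict(self.errors), "outcomes": {}}
        for label, rep in self.outcomes.items():
            out["outcomes"][label] = {
                "estimates": [e.to_row() | {"beta": e.beta, "se": e.se}
                              for e in rep.estimates],
                "gof_before": dataclasses.asdict(rep.gof_before),
                "gof_after": dataclasses.asdict(rep.gof_after),
                "prune_steps": rep.prune_history.to_frame()
                                  .to_dict("records"),
                "floor_reached": rep.prune_history.floor_reached,
                "analysis_snp_ids": rep.analysis_snp_ids,
                "excluded": list(map(list, rep.instruments.excluded)),
                "scatter_r": rep.scatter.r,
            }
        return out


def scatter_table(instruments: InstrumentSet,
                  estimate: MrEstimate) -> ScatterData:
    """Per-SNP effects with 95% CIs for a scatter plot of y against x,
    overlaid with the MR slope.  ``r`` is the Pearson correlation between
    the magnitudes of the TL and outcome associations."""
    rows = []
    for v in instruments:
        rows.append({
            "snp_id": v.snp_id,
            "x": v.x, "x_ci_low": v.x - Z95 * v.sigma_x,
            "x_ci_high": v.x + Z95 * v.sigma_x,
            "y": v.y, "y_ci_low": v.y - Z95 * v.sigma_y,
            "y_ci_high": v.y + Z95 * v.sigma_y,
            "flipped": v.flipped,
        })
    table = pd.DataFrame(rows)
    ax, ay = np.abs(instruments.x), np.abs(instruments.y)
    if len(instruments) >= 2 and ax.std() > 0 and ay.std() > 0:
        r = float(np.corrcoef(ax, ay)[0, 1])
    else:
        r = float("nan")
    return ScatterData(table=table, slope=estimate.beta, r=r)


def _estimate_pair(instruments: InstrumentSet, analysis: str,
                   rho: float, seed: int) -> list[MrEstimate]:
    ests: list[MrEstimate] = [ivw_estimate(instruments, analysis=analysis)]
    if len(instruments) >= 2:
        ests.append(likelihood_estimate(instruments, rho=rho,
                                        analysis=analysis))
    else:
        logger.warning("%s: <2 instruments, likelihood method skipped",
                       analysis)
    return ests


def _analyse_outcome(label: str, exposures, outcomes,
                     config: AnalysisConfig) -> OutcomeReport:
    instruments = build_instrument_set(
        exposures, outcomes,
        exclusions=config.exclusions, proxy_map=config.proxy_map,
        allow_palindromic=config.allow_palindromic)

    estimates = _estimate_pair(instruments, "all", config.rho, config.seed)
    snp_ids = {"all": instruments.snp_ids}

    strict = strict_subset(instruments, drop=config.strict_drop)
    if strict.snp_ids != instruments.snp_ids:
        estimates += _estimate_pair(strict, "strict", config.rho, config.seed)
        snp_ids["strict"] = strict.snp_ids

    gof_before = gof_statistic(instruments)
    history = stepwise_prune(instruments, alpha=config.alpha_gof,
                             floor=config.prune_floor)
    gof_after = history.final_report
    estimates += _estimate_pair(history.final_set, "goodness-of-fit based",
                                config.rho, config.seed)
    snp_ids["goodness-of-fit based"] = history.final_set.snp_ids

    ivw_all = estimates[0]
    return OutcomeReport(
        outcome_label=label, instruments=instruments,
        per_snp=per_snp_odds_ratios(instruments), estimates=estimates,
        gof_before=gof_before, prune_history=history, gof_after=gof_after,
        scatter=scatter_table(instruments, ivw_all),
        analysis_snp_ids=snp_ids)


def run_analysis(config: AnalysisConfig) -> RunReport:
    """Run the full analysis for every configured outcome.

    Failures are isolated per outcome and recorded (naming the outcome);
    the run only raises if no outcome could be analysed at all.
    """
    exposures = read_exposure_table(config.exposure_path,
                                    config.exposure_dialect)
    outcomes_reports: dict[str, OutcomeReport] = {}
    errors: dict[str, str] = {}
    for label, path in config.outcome_paths.items():
        try:
            outcome_records = read_outcome_table(
                path, config.outcome_dialect, outcome_label=label)
            outcomes_reports[label] = _analyse_outcome(
                label, exposures, outcome_records, config)
        except Exception as exc:
            errors[label] = f"outcome {label!r}: {exc}"
            logger.error("outcome %r failed: %s", label, exc)
    if not outcomes_reports:
        raise TelomrError("every outcome failed: " + "; ".join(errors.values()))
    report = RunReport(outcomes=outcomes_reports, errors=errors)
    if config.output_dir is not None:
        write_report(report, config.output_dir)
    return report


def stratified_runs(config: AnalysisConfig,
                    strata: Mapping[str, str | Path]) -> dict[str, RunReport]:
    """Independent analysis per stratum (e.g. sex or age bands), sharing
    the instrument table, proxy map and settings of ``config``."""
    reports = {}
    for label, path in strata.items():
        sub = dataclasses.replace(
            config, outcome_paths={label: path},
            output_dir=(Path(config.output_dir) / f"stratum_{label}"
                        if config.output_dir else None))
        reports[label] = run_analysis(sub)
    return reports


def write_report(report: RunReport, outdir: str | Path) -> dict[str, Path]:
    """Serialize a run report to TSV/JSON files under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    est = report.estimates_frame()
    n_tests = max(len(report.outcomes), 1)
    if not est.empty:
        # convenience Bonferroni column; flagging still uses raw P
        est["p_bonferroni"] = np.minimum(est["p_value"] * n_tests, 1.0)
    paths["estimates"] = outdir / "estimates.tsv"
    est.to_csv(paths["estimates"], sep="\t", index=False)

    per_snp = pd.concat(
        [rep.per_snp.assign(outcome=label)
         for label, rep in report.outcomes.items()], ignore_index=True)
    paths["per_snp"] = outdir / "per_snp.tsv"
    per_snp.to_csv(paths["per_snp"], sep="\t", index=False)

    gof_rows, prune_frames = [], []
    for label, rep in report.outcomes.items():
        gof_rows.append({"outcome": label, "stage": "before",
                         **dataclasses.asdict(rep.gof_before)})
        gof_rows.append({"outcome": label, "stage": "after",
                         **dataclasses.asdict(rep.gof_after)})
        prune_frames.append(rep.prune_history.to_frame().assign(outcome=label))
        scat = outdir / f"scatter_{label.replace(' ', '_')}.tsv"
        rep.scatter.table.to_csv(scat, sep="\t", index=False)
        paths[f"scatter_{label}"] = scat
    paths["gof"] = outdir / "gof.tsv"
    pd.DataFrame(gof_rows).to_csv(paths["gof"], sep="\t", index=False)
    paths["prune_history"] = outdir / "prune_history.tsv"
    pd.concat(prune_frames, ignore_index=True).to_csv(
        paths["prune_history"], sep="\t", index=False)

    paths["report"] = outdir / "report.json"
    with open(paths["report"], "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
    return paths
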