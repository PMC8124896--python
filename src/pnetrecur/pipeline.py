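"""End-to-end orchestration: filter → scan → classify → models → report.

A run is described by a :class:`PipelineConfig` (input CSV or a simulation
block, scan settings, model settings, one seed) and produces a
:class:`RunReport` plus a directory of plot-ready TSV tables and a YAML
metadata file.  All randomness (simulation, permutation null) flows from the
single seed through independent substreams, so identical configurations
yield identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import logistic as lg
from .cutpoint import (
    DEFAULT_GRID,
    DEFAULT_MIN_PER_ARM,
    CutpointScan,
    permutation_adjusted_p,
    scan_cutoffs,
    select_optimal,
)
from .records import (
    ExclusionLog,
    PatientRecord,
    apply_eligibility_filters,
    classify_er_status,
    classify_recurrence_pattern,
    read_cohort_csv,
)
from .simulate import SyntheticConfig, generate_cohort
from .summary import CohortSummary, percent, summarize_cohort
from .survival import km_fit, km_median_ci

logger = logging.getLogger("pnetrecur")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one analysis run needs; exactly one input source."""

    input_csv: Optional[str] = None
    simulate: Optional[SyntheticConfig] = None
    grid: Sequence[float] = DEFAULT_GRID
    min_per_arm: int = DEFAULT_MIN_PER_ARM
    n_perm: int = 0          # 0 disables the permutation correction
    alpha: float = 0.05
    screen_threshold: float = 0.10
    seed: int = 0
    output_dir: Optional[str] = None

    def validate(self) -> None:
        if (self.input_csv is None) == (self.simulate is None):
            raise ValueError("provide exactly one of input_csv or simulate")
        if not (0 < self.alpha < 1) or not (0 < self.screen_threshold < 1):
            raise ValueError("alpha and screen_threshold must lie in (0, 1)")
        if len(list(self.grid)) == 0:
            raise ValueError("cutoff grid must be nonempty")


@dataclass
class RunReport:
    config: PipelineConfig
    n_input: int
    exclusion_log: ExclusionLog
    n_eligible: int
    scan: CutpointScan
    cutoff: float
    min_p: float
    adjusted_p: Optional[float]
    table1: CohortSummary
    table2: CohortSummary
    pattern_table: pd.DataFrame
    risk_tables: dict            # outcome tag -> DataFrame
    km_tables: dict              # label -> DataFrame
    medians: dict                # label -> MedianEstimate
    output_files: dict = field(default_factory=dict)


def _atomic_write(frame_or_text, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    if isinstance(frame_or_text, pd.DataFrame):
        frame_or_text.to_csv(tmp, sep="\t", index=False)
    else:
        tmp.write_text(frame_or_text)
    os.replace(tmp, path)


def _risk_table(
    records: Sequence[PatientRecord],
    outcome_tag: str,
    cutoff: float,
    threshold: float,
) -> pd.DataFrame:
    """Combined univariable + multivariable odds-ratio table per outcome."""
    screen = lg.univariable_screen(
        records, outcome_tag=outcome_tag, cutoff_months=cutoff, threshold=threshold
    )
    table = screen.table.copy()
    table = table.rename(
        columns={c: f"uni_{c}" for c in ("odds_ratio", "ci_low", "ci_high", "p", "n")}
    )
    for col in ("multi_odds_ratio", "multi_ci_low", "multi_ci_high", "multi_p"):
        table[col] = np.nan
    included = screen.included
    if included:
        try:
            fit = lg.multivariable_model(
                records, included, outcome_tag=outcome_tag, cutoff_months=cutoff
            )
            for factor in fit.table.index:
                table.loc[factor, "multi_odds_ratio"] = fit.table.loc[factor, "odds_ratio"]
                table.loc[factor, "multi_ci_low"] = fit.table.loc[factor, "ci_low"]
                table.loc[factor, "multi_ci_high"] = fit.table.loc[factor, "ci_high"]
                table.loc[factor, "multi_p"] = fit.table.loc[factor, "p"]
        except (lg.SeparationError, lg.ConvergenceError, ValueError) as exc:
            logger.warning("multivariable %s model failed: %s", outcome_tag, exc)
    return table.reset_index().rename(columns={"index": "factor"})


def _pattern_by_er(records: Sequence[PatientRecord], cutoff: float) -> pd.DataFrame:
    rows = []
    counts: dict = {}
    for rec in records:
        if not rec.recurrence:
            continue
        status = classify_er_status(rec, cutoff).value
        pattern = classify_recurrence_pattern(rec.recurrence_sites)
        counts.setdefault(status, {}).setdefault(pattern, 0)
        counts[status][pattern] += 1
    for status, pats in sorted(counts.items()):
        denom = sum(pats.values())
        for pattern, cnt in sorted(pats.items()):
            rows.append(
                {
                    "er_status": status,
                    "pattern": pattern,
                    "count": cnt,
                    "denominator": denom,
                    "pct": percent(cnt, denom),
                }
            )
    return pd.DataFrame(rows, columns=["er_status", "pattern", "count", "denominator", "pct"])


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis in fixed stage order.

    Stages: load or simulate the cohort; apply eligibility filters; scan the
    cut-off grid on the recurred patients; classify early/late at the
    selected cut-off; build grouped summary tables, the recurrence-pattern
    breakdown, per-outcome risk-factor tables and PRS survival-curve
    exports; write everything to ``output_dir`` when set.
    """
    config.validate()
    master = np.random.default_rng(config.seed)
    sim_seed = int(master.integers(0, 2**31 - 1))
    perm_seed = int(master.integers(0, 2**31 - 1))

    if config.simulate is not None:
        sim_cfg = dataclasses.replace(config.simulate, seed=sim_seed)
        records, _truth = generate_cohort(sim_cfg)
        logger.info("simulated cohort: n=%d (seed %d)", len(records), sim_seed)
    else:
        records = read_cohort_csv(config.input_csv)
        logger.info("loaded cohort: n=%d from %s", len(records), config.input_csv)

    n_input = len(records)
    eligible, log = apply_eligibility_filters(records)
    logger.info("eligibility: %d eligible, %d excluded", len(eligible), len(log))
    if not eligible:
        raise ValueError("no eligible patients after filtering")

    recurred = [r for r in eligible if r.recurrence]
    logger.info("recurred patients entering the scan: %d", len(recurred))
    scan = scan_cutoffs(recurred, grid=config.grid, min_per_arm=config.min_per_arm)
    cutoff, min_p = select_optimal(scan)
    adjusted = None
    if config.n_perm > 0:
        adjusted = permutation_adjusted_p(
            recurred,
            grid=config.grid,
            min_per_arm=config.min_per_arm,
            n_perm=config.n_perm,
            seed=perm_seed,
        )
        scan.adjusted_p = adjusted
    logger.info(
        "selected cutoff %.1f months (min p = %.4g%s)",
        cutoff,
        min_p,
        "" if adjusted is None else f", permutation-adjusted p = {adjusted:.4g}",
    )

    table1 = summarize_cohort(eligible, grouping="recurrence")
    table2 = summarize_cohort(eligible, grouping="er", cutoff_months=cutoff)
    patterns = _pattern_by_er(eligible, cutoff)

    risk_tables = {
        tag: _risk_table(eligible, tag, cutoff, config.screen_threshold)
        for tag in lg.OUTCOME_TAGS
    }

    km_tables, medians = {}, {}
    arms = {
        "prs_early": [r for r in recurred if r.rfs_months <= cutoff],
        "prs_late": [r for r in recurred if r.rfs_months > cutoff],
    }
    for label, arm in arms.items():
        if not arm:
            continue
        curve = km_fit(
            [r.prs_months for r in arm], [r.prs_event for r in arm], label=label
        )
        km_tables[label] = curve.to_frame()
        medians[label] = km_median_ci(curve)

    report = RunReport(
        config=config,
        n_input=n_input,
        exclusion_log=log,
        n_eligible=len(eligible),
        scan=scan,
        cutoff=cutoff,
        min_p=min_p,
        adjusted_p=adjusted,
        table1=table1,
        table2=table2,
        pattern_table=patterns,
        risk_tables=risk_tables,
        km_tables=km_tables,
        medians=medians,
    )

    if config.output_dir is not None:
        _write_outputs(report, Path(config.output_dir))
    return report


def _write_outputs(report: RunReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}

    excl = pd.DataFrame(
        [{"patient_id": pid, "reason": reason}
         for pid, reason in sorted(report.exclusion_log.reasons.items())],
        columns=["patient_id", "reason"],
    )
    for name, frame in {
        "exclusions.tsv": excl,
        "table1.tsv": report.table1.table,
        "table1_tests.tsv": report.table1.tests,
        "table2.tsv": report.table2.table,
        "table2_tests.tsv": report.table2.tests,
        "scan_profile.tsv": report.scan.to_frame(),
        "patterns_by_er.tsv": report.pattern_table,
        **{f"riskfactors_{tag}.tsv": t for tag, t in report.risk_tables.items()},
        **{f"km_{label}.tsv": t for label, t in report.km_tables.items()},
    }.items():
        path = outdir / name
        _atomic_write(frame, path)
        files[name] = str(path)

    meta = {
        "seed": report.config.seed,
        "n_input": report.n_input,
        "n_eligible": report.n_eligible,
        "n_excluded": len(report.exclusion_log),
        "exclusion_counts": report.exclusion_log.counts,
        "n_recurred": report.scan.n_recurred,
        "selected_cutoff_months": report.cutoff,
        "min_p": float(report.min_p),
        "adjusted_p": None if report.adjusted_p is None else float(report.adjusted_p),
        "alpha": report.config.alpha,
        "screen_threshold": report.config.screen_threshold,
        "min_per_arm": report.config.min_per_arm,
        "grid": [float(g) for g in report.config.grid],
        "prs_medians": {
            label: {
                "median": est.median,
                "lower95": est.lower95,
                "upper95": est.upper95,
            }
            for label, est in report.medians.items()
        },
    }
    path = outdir / "run.yaml"
    _atomic_write(yaml.safe_dump(meta, sort_keys=True), path)
    files["run.yaml"] = str(path)
    report.output_files = files
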