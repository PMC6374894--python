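"""Experiment orchestration: simulation sweeps, null-split runs, comparator.

A sweep executes, per design and repeat: generate (or load) a baseline
cohort, pick spike-in DEGs, multiply their counts, rescale the disease
cohort to the common grand total, call the rank-based method (and
optionally the count-based comparator), and score both against the truth.
Per-repeat seeds are ``base_seed + repeat_index`` so every repeat is
auditable; the truth seed adds a fixed offset so gene selection and the
baseline noise are independent streams.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .comparator import ComparatorUnavailableError, run_edger
from .evaluate import MetricsReport, aggregate_repeats, confusion_metrics
from .rankcomp import call_degs
from .simulate import (
    BaselineParams,
    apply_fc,
    assign_fc_groups,
    generate_baseline,
    make_null_split,
    rescale_to_common_total,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Design",
    "ExperimentConfig",
    "SweepReport",
    "run_sweep",
    "run_null_experiment",
    "wrap_count_comparator",
    "render_sweep_table",
]

_TRUTH_SEED_OFFSET = 100003  # distinct stream for DEG selection


@dataclass(frozen=True)
class Design:
    n_up: int
    n_down: int
    scheme: str = "four_group"

    @property
    def label(self) -> str:
        return f"{self.n_up}/{self.n_down} {self.scheme}"


@dataclass
class ExperimentConfig:
    designs: list[Design]
    repeats: int = 5
    base_seed: int = 0
    n_genes: int = 2000
    n_samples: int = 20
    mean_log: float = 4.0
    sigma_log: float = 1.5
    dispersion: float = 0.1
    stable_fdr: float = 0.05
    deg_fdr: float = 0.05
    comparator: bool = False
    comparator_rounding: str = "nearest"

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not self.designs:
            raise ValueError("need at least one design")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        designs = [Design(**d) for d in raw.pop("designs")]
        return cls(designs=designs, **raw)


@dataclass
class SweepReport:
    """Long-format per-(design, method) table plus per-repeat detail."""

    table: pd.DataFrame
    per_repeat: pd.DataFrame
    comparator_missing: bool = False


def _metrics_row(design: Design, method: str, repeat: int, seed: int,
                 factor: float, report: MetricsReport) -> dict:
    return {
        "design": design.label,
        "n_up": design.n_up,
        "n_down": design.n_down,
        "scheme": design.scheme,
        "method": method,
        "repeat": repeat,
        "seed": seed,
        "factor": factor,
        **report.to_dict(),
    }


def run_sweep(config: ExperimentConfig) -> SweepReport:
    """Execute all (design, repeat) cells and aggregate the metrics."""
    per_repeat_rows: list[dict] = []
    comparator_missing = False
    for design in config.designs:
        for rep in range(config.repeats):
            seed = config.base_seed + rep
            baseline = generate_baseline(BaselineParams(
                n_genes=config.n_genes, n_samples=config.n_samples, seed=seed,
                mean_log=config.mean_log, sigma_log=config.sigma_log,
                dispersion=config.dispersion,
            ))
            truth = assign_fc_groups(baseline.index, design.n_up, design.n_down,
                                     design.scheme, seed=seed + _TRUTH_SEED_OFFSET)
            disease, factor = rescale_to_common_total(baseline, apply_fc(baseline, truth))
            result = call_degs(baseline, disease,
                               stable_fdr=config.stable_fdr, deg_fdr=config.deg_fdr)
            per_repeat_rows.append(_metrics_row(
                design, "rankcompv2", rep, seed, factor,
                confusion_metrics(result.degs, truth),
            ))
            if config.comparator:
                try:
                    comp_degs = wrap_count_comparator(
                        baseline, disease, fdr=config.deg_fdr,
                        rounding=config.comparator_rounding,
                    )
                except ComparatorUnavailableError as exc:
                    logger.warning("comparator unavailable: %s", exc)
                    comparator_missing = True
                else:
                    per_repeat_rows.append(_metrics_row(
                        design, "comparator", rep, seed, factor,
                        confusion_metrics(comp_degs, truth),
                    ))
    per_repeat = pd.DataFrame(per_repeat_rows)
    agg_rows = []
    for (label, method), grp in per_repeat.groupby(["design", "method"], sort=False):
        reports = [MetricsReport(r.sensitivity, r.specificity, r.f_score, r.fdr,
                                 int(r.tp), int(r.fp), int(r.tn), int(r.fn))
                   for r in grp.itertuples()]
        mean = aggregate_repeats(reports)
        agg_rows.append({
            "design": label,
            "method": method,
            "n_repeats": len(reports),
            "factor": float(grp["factor"].mean()),
            **mean.to_dict(),
        })
    return SweepReport(table=pd.DataFrame(agg_rows), per_repeat=per_repeat,
                       comparator_missing=comparator_missing)


def render_sweep_table(report: SweepReport) -> str:
    """Plain-text table mirroring the design / factor / per-method metric layout."""
    lines = [f"{'Design':<24}{'Method':<12}{'Factor':>8}{'Sen':>9}{'Spe':>9}"
             f"{'F':>9}{'FDR':>9}"]
    for row in report.table.itertuples():
        def pct(x):
            return "   --" if not np.isfinite(x) else f"{100 * x:7.2f}%"
        lines.append(
            f"{row.design:<24}{row.method:<12}{row.factor:8.4f}"
            f"{pct(row.sensitivity):>9}{pct(row.specificity):>9}"
            f"{pct(row.f_score):>9}{pct(row.fdr):>9}"
        )
    if report.comparator_missing:
        lines.append("note: comparator unavailable; its cells are missing")
    return "\n".join(lines)


def run_null_experiment(
    normal: pd.DataFrame,
    repeats: int = 20,
    seed: int = 0,
    stable_fdr: float = 0.05,
    deg_fdr: float = 0.05,
) -> pd.DataFrame:
    """Half-split the cohort against itself ``repeats`` times; count null DEGs.

    With no phenotype signal the DEG count distribution should concentrate
    at zero; the returned frame has one row per repeat (seed, n_degs) and
    carries summary quantiles in ``.attrs['summary']``.
    """
    rows = []
    for rep in range(repeats):
        rep_seed = seed + rep
        group_a, group_b = make_null_split(normal, seed=rep_seed)
        result = call_degs(group_a, group_b, stable_fdr=stable_fdr, deg_fdr=deg_fdr)
        rows.append({"repeat": rep, "seed": rep_seed, "n_degs": len(result.degs)})
    out = pd.DataFrame(rows)
    counts = out["n_degs"].to_numpy()
    out.attrs["summary"] = {
        "median": float(np.median(counts)),
        "p95": float(np.quantile(counts, 0.95)),
        "max": int(counts.max()),
        "mean": float(counts.mean()),
    }
    return out


def wrap_count_comparator(
    baseline: pd.DataFrame,
    disease_rescaled: pd.DataFrame,
    fdr: float = 0.05,
    rounding: str = "nearest",
) -> pd.DataFrame:
    """Call the external count-based caller; raises ComparatorUnavailableError."""
    return run_edger(baseline, disease_rescaled, fdr=fdr, rounding=rounding)
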