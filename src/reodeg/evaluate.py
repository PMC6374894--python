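"""Scoring DEG calls against simulation truth, and cross-list overlap scores.

Conventions follow the benchmark definitions: sensitivity is the fraction
of true DEGs correctly identified, specificity the fraction of true
non-DEGs correctly left uncalled, the F-score the harmonic mean of
sensitivity and specificity, and the (empirical) FDR the fraction of calls
that are not true DEGs.  A call with the wrong direction counts as a false
positive by default, since a reversed direction is not a correct call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pairs import binomial_reo_pvalue
from .simulate import SimulationTruth

__all__ = [
    "MetricsReport",
    "OverlapReport",
    "f_score",
    "confusion_metrics",
    "pog_scores",
    "aggregate_repeats",
]


def f_score(sensitivity: float, specificity: float) -> float:
    """Harmonic mean of sensitivity and specificity (0 when both are 0)."""
    total = sensitivity + specificity
    if total == 0:
        return 0.0
    return 2.0 * sensitivity * specificity / total


@dataclass
class MetricsReport:
    sensitivity: float  # NaN when the design has no true DEGs
    specificity: float
    f_score: float
    fdr: float
    tp: int
    fp: int
    tn: int
    fn: int

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f_score": self.f_score,
            "fdr": self.fdr,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
        }


def _as_direction_map(called) -> dict[str, str]:
    if isinstance(called, pd.DataFrame):
        return dict(zip(called["gene"].astype(str), called["direction"].astype(str)))
    return {str(k): str(v) for k, v in dict(called).items()}


def confusion_metrics(called, truth: SimulationTruth | pd.Series,
                      require_direction: bool = True) -> MetricsReport:
    """Score a directed DEG list against per-gene true fold changes.

    ``called`` is a DataFrame with ``gene``/``direction`` columns (or a
    gene -> direction mapping).  A true DEG called with the wrong direction
    counts as a false positive when ``require_direction`` is set.
    """
    fc = truth.fc if isinstance(truth, SimulationTruth) else truth
    calls = _as_direction_map(called)
    unknown = set(calls) - set(fc.index.astype(str))
    if unknown:
        raise ValueError(f"called gene(s) absent from truth: {sorted(unknown)[:5]}")
    true_dir = pd.Series(np.where(fc > 1, "up", np.where(fc < 1, "down", "none")),
                         index=fc.index.astype(str))
    n_true = int((true_dir != "none").sum())
    n_null = len(fc) - n_true
    tp = fp = 0
    for gene, direction in calls.items():
        t = true_dir[gene]
        if t == "none" or (require_direction and direction != t):
            fp += 1
        else:
            tp += 1
    fn = n_true - tp
    called_null = sum(1 for gene in calls if true_dir[gene] == "none")
    tn = n_null - called_null
    sensitivity = tp / n_true if n_true else float("nan")
    specificity = tn / n_null if n_null else float("nan")
    fdr = fp / (tp + fp) if (tp + fp) else 0.0
    fs = (f_score(sensitivity, specificity)
          if np.isfinite(sensitivity) and np.isfinite(specificity) else float("nan"))
    return MetricsReport(sensitivity, specificity, fs, fdr, tp, fp, tn, fn)


@dataclass
class OverlapReport:
    """Cross-list overlap: POG scores and directional concordance.

    With list lengths L1, L2, n overlapping genes and s of them sharing the
    dysregulation direction: POG12 = s/L1, POG21 = s/L2, concordance = s/n.
    ``concordance_p`` is the upper-tail binomial probability of at least s
    same-direction genes among n under a 50/50 chance null.
    """

    l1: int
    l2: int
    n: int
    s: int
    pog12: float
    pog21: float
    concordance: float  # NaN when the overlap is empty
    concordance_p: float

    def to_dict(self) -> dict:
        return {
            "L1": self.l1, "L2": self.l2, "n": self.n, "s": self.s,
            "pog12": self.pog12, "pog21": self.pog21,
            "concordance": self.concordance, "concordance_p": self.concordance_p,
        }


def pog_scores(list1, list2) -> OverlapReport:
    """Percentage-of-overlapping-genes and concordance between two DEG lists."""
    d1 = _as_direction_map(list1)
    d2 = _as_direction_map(list2)
    if not d1 or not d2:
        raise ValueError("DEG lists must be non-empty")
    for d in (d1, d2):
        bad = {v for v in d.values()} - {"up", "down"}
        if bad:
            raise ValueError(f"directions must be 'up' or 'down', got {sorted(bad)}")
    overlap = set(d1) & set(d2)
    n = len(overlap)
    s = sum(1 for gene in overlap if d1[gene] == d2[gene])
    if n:
        concordance = s / n
        concordance_p = binomial_reo_pvalue(s, n, 0.5) if s > 0 else 1.0
    else:
        concordance = float("nan")
        concordance_p = 1.0
    return OverlapReport(
        l1=len(d1), l2=len(d2), n=n, s=s,
        pog12=s / len(d1), pog21=s / len(d2),
        concordance=concordance, concordance_p=concordance_p,
    )


def aggregate_repeats(reports: list[MetricsReport]) -> MetricsReport:
    """Mean of each rate across repeats (NaN-aware); raw counts are summed."""
    if not reports:
        raise ValueError("need at least one report")
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rate columns
        return MetricsReport(
            sensitivity=float(np.nanmean([r.sensitivity for r in reports])),
            specificity=float(np.nanmean([r.specificity for r in reports])),
            f_score=float(np.nanmean([r.f_score for r in reports])),
            fdr=float(np.nanmean([r.fdr for r in reports])),
            tp=sum(r.tp for r in reports),
            fp=sum(r.fp for r in reports),
            tn=sum(r.tn for r in reports),
            fn=sum(r.fn for r in reports),
        )
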