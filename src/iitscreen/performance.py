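"""Confusion matrices, diagnostic metrics, eGFR-stratified reports and the
RDW-by-eGFR quadrant table.

Percentages in reports are rounded half-away-from-zero to integers; unrounded
fractions are always carried alongside.  Exact binomial (Clopper-Pearson) 95%
intervals accompany each proportion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .cohort import CohortTable, EgfrStratum, STRATA_BEST_TO_WORST, assign_egfr_stratum
from .cutoff import apply_cutoff
from .roc import GREATER

__all__ = [
    "ConfusionMatrix",
    "DiagnosticMetrics",
    "StratifiedReport",
    "confusion",
    "metrics",
    "stratified_metrics",
    "quadrant_table",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (0.5 -> 1), the convention of clinical tables."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class DiagnosticMetrics:
    """Sens/spec/PPV/NPV/prevalence with exact binomial 95% intervals.

    Ratios with a zero denominator are None and listed in ``undefined``.
    """

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    prevalence: float
    n: int
    ci: dict = field(default_factory=dict)
    undefined: list = field(default_factory=list)

    def as_percent(self, rounded: bool = True) -> dict:
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv", "prevalence"):
            v = getattr(self, name)
            out[name] = None if v is None else (
                round_half_away(100.0 * v) if rounded else 100.0 * v
            )
        return out


def confusion(predicted, truth) -> ConfusionMatrix:
    """2x2 cross-tabulation of predicted vs true binary status."""
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if predicted.shape != truth.shape or predicted.ndim != 1:
        raise ValueError("predicted and truth must be equal-length 1-D vectors")
    if predicted.size < 1:
        raise ValueError("need at least one record")
    return ConfusionMatrix(
        tp=int((predicted & truth).sum()),
        fp=int((predicted & ~truth).sum()),
        fn=int((~predicted & truth).sum()),
        tn=int((~predicted & ~truth).sum()),
    )


def _ratio(num: int, den: int):
    return None if den == 0 else num / den


def metrics(cm: ConfusionMatrix) -> DiagnosticMetrics:
    """Derive sensitivity, specificity, PPV, NPV and prevalence from counts."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    pairs = {
        "sensitivity": (cm.tp, cm.tp + cm.fn),
        "specificity": (cm.tn, cm.tn + cm.fp),
        "ppv": (cm.tp, cm.tp + cm.fp),
        "npv": (cm.tn, cm.tn + cm.fn),
        "prevalence": (cm.tp + cm.fn, cm.n),
    }
    values, ci, undefined = {}, {}, []
    for name, (num, den) in pairs.items():
        v = _ratio(num, den)
        values[name] = v
        if v is None:
            undefined.append(name)
            warnings.warn(f"{name} undefined (zero denominator)", stacklevel=2)
            ci[name] = (None, None)
        else:
            lo, hi = proportion_confint(num, den, alpha=0.05, method="beta")
            ci[name] = (float(lo), float(hi))
    return DiagnosticMetrics(
        sensitivity=values["sensitivity"],
        specificity=values["specificity"],
        ppv=values["ppv"],
        npv=values["npv"],
        prevalence=values["prevalence"],
        n=cm.n,
        ci=ci,
        undefined=undefined,
    )


@dataclass
class StratifiedReport:
    """Per-eGFR-stratum diagnostic metrics plus marker mean +/- SD."""

    per_stratum: dict  # EgfrStratum -> DiagnosticMetrics | None
    marker_summary: dict  # EgfrStratum -> (n, mean, sd)
    overall: DiagnosticMetrics
    marker: str
    cutoff: float

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for stratum in STRATA_BEST_TO_WORST:
            m = self.per_stratum.get(stratum)
            n, mean, sd = self.marker_summary.get(stratum, (0, np.nan, np.nan))
            row = {"stratum": stratum.name, "n": n,
                   f"{self.marker}_mean": mean, f"{self.marker}_sd": sd}
            if m is None:
                row.update({k: np.nan for k in
                            ("sensitivity", "specificity", "ppv", "npv", "prevalence")})
            else:
                row.update({k: (np.nan if v is None else v)
                            for k, v in m.as_percent(rounded=False).items()})
            rows.append(row)
        return pd.DataFrame(rows)


def _strata_of(egfr: np.ndarray) -> list[EgfrStratum]:
    return [assign_egfr_stratum(float(v)) for v in egfr]


def stratified_metrics(
    cohort: CohortTable,
    marker: str,
    cutoff: float,
    labels,
    direction: str = GREATER,
) -> StratifiedReport:
    """Diagnostic performance of ``marker >= cutoff`` overall and per eGFR stratum."""
    df = cohort.df
    scores = df[marker].to_numpy(dtype=float)
    egfr = df["egfr"].to_numpy(dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if np.isnan(scores).any() or np.isnan(egfr).any():
        raise ValueError("marker and egfr must be complete; filter the cohort first")
    pred = apply_cutoff(scores, cutoff, direction)
    strata = np.array([s.name for s in _strata_of(egfr)])
    per, summary = {}, {}
    for stratum in STRATA_BEST_TO_WORST:
        mask = strata == stratum.name
        vals = scores[mask]
        summary[stratum] = (
            int(mask.sum()),
            float(vals.mean()) if mask.any() else float("nan"),
            float(vals.std(ddof=1)) if mask.sum() > 1 else float("nan"),
        )
        if not mask.any():
            per[stratum] = None
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per[stratum] = metrics(confusion(pred[mask], labels[mask]))
    overall = metrics(confusion(pred, labels))
    return StratifiedReport(per, summary, overall, marker, cutoff)


def quadrant_table(
    cohort: CohortTable,
    marker: str,
    cutoff: float,
    labels,
    egfr_split: tuple[float, ...] = (60.0,),
) -> pd.DataFrame:
    """Cross-tabulate marker </>= cutoff against eGFR groups.

    Each cell reports its share of the cohort (percent) and the IIT prevalence
    within the cell; cell percentages sum to 100.
    """
    df = cohort.df
    scores = df[marker].to_numpy(dtype=float)
    egfr = df["egfr"].to_numpy(dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if np.isnan(scores).any() or np.isnan(egfr).any():
        raise ValueError("marker and egfr must be complete")
    edges = (0.0,) + tuple(sorted(egfr_split)) + (math.inf,)
    n = len(df)
    above = scores >= cutoff
    rows = []
    for row_name, row_mask in ((f"{marker} >= {cutoff:g}", above),
                               (f"{marker} < {cutoff:g}", ~above)):
        for lo, hi in zip(edges[:-1], edges[1:]):
            cell = row_mask & (egfr >= lo) & (egfr < hi)
            k = int(cell.sum())
            rows.append(
                {
                    "marker_group": row_name,
                    "egfr_group": f"[{lo:g}, {hi:g})",
                    "n": k,
                    "percent_of_cohort": 100.0 * k / n,
                    "iit_prevalence": float(labels[cell].mean()) if k else float("nan"),
                }
            )
    return pd.DataFrame(rows)
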