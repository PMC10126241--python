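"""Empirical ROC curves, AUC, and logistic marker combinations.

Candidate thresholds are midpoints between adjacent distinct score values,
plus sentinels below the minimum and above the maximum, so every achievable
(sensitivity, specificity) operating point appears exactly once and tied
scores share a threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GREATER",
    "LESSER",
    "RocCurve",
    "roc_curve",
    "auc_trapezoid",
    "auc_concordance",
    "combine_markers",
    "marker_direction",
]

GREATER = "greater_is_positive"
LESSER = "lesser_is_positive"

#: Conventional test directions: RDW rises with iron-transport impairment,
#: while MCV and MCHC fall with it.
MARKER_DIRECTIONS = {"rdw": GREATER, "mcv": LESSER, "mchc": LESSER}


def marker_direction(marker: str) -> str:
    return MARKER_DIRECTIONS.get(marker, GREATER)


def _validate(scores, labels, direction):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D vectors")
    if scores.size < 2:
        raise ValueError("need at least 2 observations")
    if np.isnan(scores).any():
        raise ValueError("missing scores are not allowed; drop incomplete cases first")
    if labels.all() or not labels.any():
        raise ValueError("degenerate labels: both classes must be present")
    if direction not in (GREATER, LESSER):
        raise ValueError(f"unknown direction {direction!r}")
    return scores, labels


@dataclass
class RocCurve:
    """Ordered (threshold, sensitivity, specificity) triples for one marker."""

    marker_name: str
    direction: str
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_pos: int
    n_neg: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct values plus sentinels outside the range."""
    uniq = np.unique(np.asarray(scores, dtype=float))
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))


def roc_curve(scores, labels, direction: str = GREATER, marker_name: str = "") -> RocCurve:
    """Empirical ROC curve over all candidate thresholds.

    Under ``greater_is_positive`` a record is called positive when its score is
    >= the threshold (and <= under ``lesser_is_positive``), matching how the
    final cutoff is applied clinically.
    """
    scores, labels = _validate(scores, labels, direction)
    thr = candidate_thresholds(scores)
    pos = np.sort(scores[labels])
    neg = np.sort(scores[~labels])
    n_pos, n_neg = pos.size, neg.size
    if direction == GREATER:
        sens = (n_pos - np.searchsorted(pos, thr, side="left")) / n_pos
        spec = np.searchsorted(neg, thr, side="left") / n_neg
    else:
        sens = np.searchsorted(pos, thr, side="right") / n_pos
        spec = (n_neg - np.searchsorted(neg, thr, side="right")) / n_neg
    return RocCurve(marker_name, direction, thr, sens, spec, n_pos, n_neg)


def auc_trapezoid(curve: RocCurve) -> float:
    """Trapezoidal area under (1 - specificity, sensitivity), in [0, 1]."""
    fpr = 1.0 - curve.specificity
    order = np.argsort(fpr, kind="stable")
    fpr, tpr = fpr[order], curve.sensitivity[order]
    # within equal-fpr runs sensitivity must be ordered for a proper staircase
    order2 = np.lexsort((tpr, fpr))
    fpr, tpr = fpr[order2], tpr[order2]
    return float(np.trapezoid(tpr, fpr))


def auc_concordance(scores, labels, direction: str = GREATER) -> float:
    """Pairwise-concordance AUC: P(score separates a random +/- pair correctly).

    Concordant pairs count 1, ties 0.5, discordant 0; computed through the
    rank-sum identity, which is exact including ties.
    """
    scores, labels = _validate(scores, labels, direction)
    if direction == LESSER:
        scores = -scores
    ranks = stats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    r_pos = ranks[labels].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def combine_markers(
    cohort_df: pd.DataFrame,
    markers: list[str],
    labels,
) -> tuple[np.ndarray, dict]:
    """Additive logistic score over several markers, fitted by maximum likelihood.

    Returns the per-record linear predictor (higher = more likely positive,
    so downstream ROC uses ``greater_is_positive``) and a metadata dict with
    the fitted coefficients and a perfect-separation flag.
    """
    if len(markers) < 2:
        raise ValueError("need at least 2 markers to combine")
    X = cohort_df.loc[:, list(markers)].to_numpy(dtype=float)
    y = np.asarray(labels, dtype=float)
    complete = ~np.isnan(X).any(axis=1)
    if complete.sum() < 10:
        raise ValueError("fewer than 10 complete cases")
    if not (0 < y[complete].sum() < complete.sum()):
        raise ValueError("degenerate labels among complete cases")
    import statsmodels.api as sm

    Xc = sm.add_constant(X[complete], has_constant="add")
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y[complete], Xc).fit(disp=0, maxiter=200, method="lbfgs")
            coef = fit.params
            if not fit.mle_retvals.get("converged", True):
                separated = True
        except Exception:  # perfect separation aborts Newton/LBFGS
            separated = True
            coef, _ = _logistic_ridge(Xc, y[complete])
    prob = Xc @ coef
    fitted = 1.0 / (1.0 + np.exp(-prob))
    if np.all((fitted > 0.5) == (y[complete] > 0.5)) and (
        np.min(np.abs(fitted - y[complete])) < 1e-6
    ):
        separated = True
    score = np.full(len(cohort_df), np.nan)
    score[complete] = prob
    meta = {
        "markers": list(markers),
        "intercept": float(coef[0]),
        "coefficients": {m: float(c) for m, c in zip(markers, coef[1:])},
        "perfect_separation": bool(separated),
        "n_complete": int(complete.sum()),
    }
    return score, meta


def _logistic_ridge(X: np.ndarray, y: np.ndarray, alpha: float = 1e-4,
                    n_iter: int = 100) -> tuple[np.ndarray, bool]:
    """Weakly ridge-penalized IRLS fallback so a score exists under separation."""
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-10)
        H = X.T @ (X * w[:, None]) + alpha * np.eye(X.shape[1])
        g = X.T @ (y - mu) - alpha * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta, True
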