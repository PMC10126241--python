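"""Euclidean-distance-optimal cutoff selection with split-half cross-validation.

The optimal cutoff minimizes the Euclidean distance between the operating
point (sensitivity, specificity) and the ideal corner (1, 1) of ROC space.
To guard against optimism, the cohort is randomly split in half many times
(200 by default): the cutoff is fitted on the training half, its sensitivity
and specificity are measured on the held-out half, and the final reported
cutoff is the arithmetic mean of the training cutoffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .roc import GREATER, LESSER, roc_curve, _validate

__all__ = [
    "CutoffResult",
    "CrossValResult",
    "euclidean_distance",
    "best_cutoff",
    "crossval_cutoff",
    "apply_cutoff",
]


def euclidean_distance(sensitivity, specificity):
    """Distance from (sensitivity, specificity) to the ideal point (1, 1).

    0 for a perfect classifier, sqrt(2) at the worst corner.
    """
    sens = np.asarray(sensitivity, dtype=float)
    spec = np.asarray(specificity, dtype=float)
    if np.any((sens < 0) | (sens > 1) | (spec < 0) | (spec > 1)):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    out = np.sqrt((1.0 - sens) ** 2 + (1.0 - spec) ** 2)
    return float(out) if out.ndim == 0 else out


@dataclass
class CutoffResult:
    """A fitted cutoff with its on-data operating point."""

    cutoff: float
    sensitivity: float
    specificity: float
    distance: float
    direction: str = GREATER


@dataclass
class CrossValResult:
    """Per-replicate training cutoffs and test-half performance."""

    replicates: list[tuple[int, float, float, float]]  # (id, train_cutoff, test_sens, test_spec)
    mean_cutoff: float
    sd_cutoff: float
    mean_test_sensitivity: float
    mean_test_specificity: float
    n_replicates: int
    seed: int
    skipped: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mean_cutoff": self.mean_cutoff,
            "sd_cutoff": self.sd_cutoff,
            "mean_test_sensitivity": self.mean_test_sensitivity,
            "mean_test_specificity": self.mean_test_specificity,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "skipped_replicates": list(self.skipped),
            "replicates": [
                {
                    "replicate_id": r,
                    "train_cutoff": c,
                    "test_sensitivity": s,
                    "test_specificity": p,
                }
                for r, c, s, p in self.replicates
            ],
        }


def best_cutoff(scores, labels, direction: str = GREATER) -> CutoffResult:
    """Cutoff minimizing the Euclidean distance over all candidate thresholds.

    Ties are broken toward the larger threshold — the more specific rule under
    ``greater_is_positive``.
    """
    curve = roc_curve(scores, labels, direction)
    dist = euclidean_distance(curve.sensitivity, curve.specificity)
    tied = np.flatnonzero(dist <= dist.min() + 1e-12)
    idx = tied[np.argmax(curve.thresholds[tied])]
    return CutoffResult(
        cutoff=float(curve.thresholds[idx]),
        sensitivity=float(curve.sensitivity[idx]),
        specificity=float(curve.specificity[idx]),
        distance=float(dist[idx]),
        direction=direction,
    )


def apply_cutoff(scores, cutoff: float, direction: str = GREATER) -> np.ndarray:
    """Dichotomize scores at the cutoff, inclusive: >= cutoff is positive under
    ``greater_is_positive`` (<= under ``lesser_is_positive``)."""
    scores = np.asarray(scores, dtype=float)
    if np.isnan(scores).any():
        raise ValueError("missing scores are not allowed")
    return scores >= cutoff if direction == GREATER else scores <= cutoff


def _sens_spec(scores, labels, cutoff, direction):
    pred = apply_cutoff(scores, cutoff, direction)
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    sens = float((pred & labels).sum() / n_pos)
    spec = float((~pred & ~labels).sum() / n_neg)
    return sens, spec


def crossval_cutoff(
    scores,
    labels,
    direction: str = GREATER,
    n_replicates: int = 200,
    seed: int = 0,
) -> CrossValResult:
    """Repeated split-half cross-validation of the Euclidean-optimal cutoff.

    For each replicate the cohort is permuted, the first ceil(n/2) records form
    the training half, the optimal cutoff is fitted there and its sensitivity
    and specificity are evaluated on the other half.  Replicates where either
    half is single-class are skipped and logged.  Deterministic given the seed.
    """
    scores, labels = _validate(scores, labels, direction)
    n = scores.size
    if n < 4:
        raise ValueError("need at least 4 records to split in half")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    n_train = math.ceil(n / 2)
    rows: list[tuple[int, float, float, float]] = []
    skipped: list[int] = []
    for rep in range(n_replicates):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        y_tr, y_te = labels[tr], labels[te]
        if y_tr.all() or not y_tr.any() or y_te.all() or not y_te.any():
            skipped.append(rep)
            continue
        fit = best_cutoff(scores[tr], y_tr, direction)
        sens, spec = _sens_spec(scores[te], y_te, fit.cutoff, direction)
        rows.append((rep, fit.cutoff, sens, spec))
    if len(rows) < 10:
        raise ValueError("insufficient valid splits (fewer than 10 completed replicates)")
    cuts = np.array([r[1] for r in rows])
    return CrossValResult(
        replicates=rows,
        mean_cutoff=float(cuts.mean()),
        sd_cutoff=float(cuts.std(ddof=1)) if cuts.size > 1 else 0.0,
        mean_test_sensitivity=float(np.mean([r[2] for r in rows])),
        mean_test_specificity=float(np.mean([r[3] for r in rows])),
        n_replicates=len(rows),
        seed=seed,
        skipped=skipped,
    )
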