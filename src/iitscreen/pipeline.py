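"""End-to-end orchestration: simulate/load -> filter -> ROC -> cutoff -> reports.

``run_pipeline`` executes the whole screening analysis and writes every table
under an output directory, returning (and serializing) a manifest with content
hashes so a config + seed pair is verifiably reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortTable, apply_eligibility, iit_labels, read_cohort, write_cohort
from .cutoff import crossval_cutoff, best_cutoff
from .performance import quadrant_table, stratified_metrics
from .roc import GREATER, auc_trapezoid, combine_markers, marker_direction, roc_curve
from .simulate import GeneratorParams, generate_cohort

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("iitscreen")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``input_path`` and ``generator`` must be set.
    """

    input_path: str | None = None
    generator: GeneratorParams | None = None
    markers: tuple[str, ...] = ("rdw", "mcv", "mchc")
    label: str = "iit"
    cutoff_override: float | None = None
    n_replicates: int = 200
    seed: int = 0
    egfr_split: tuple[float, ...] = (60.0,)
    out_dir: str = "results"

    def validate(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ValueError("set exactly one of input_path and generator params")
        if self.n_replicates < 10:
            raise ValueError("n_replicates must be >= 10")
        if self.label != "iit":
            raise ValueError("only the IIT label is supported")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict:
    """Run eligibility -> ROC (single markers + combinations) -> cross-validated
    cutoff for the best marker -> overall, stratified and quadrant reports.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save_tsv(name: str, df: pd.DataFrame) -> None:
        path = out / name
        _write_tsv(df, path)
        artifacts[name] = _sha256(path)

    # --- stage: cohort -----------------------------------------------------
    if config.generator is not None:
        cohort = generate_cohort(config.generator)
        raw_path = out / "cohort.csv"
        write_cohort(cohort, raw_path)
        artifacts["cohort.csv"] = _sha256(raw_path)
    else:
        cohort = read_cohort(config.input_path)
    n_in = cohort.n
    log.info("stage cohort: %d records in", n_in)

    # --- stage: eligibility ------------------------------------------------
    filtered = apply_eligibility(cohort)
    if filtered.n == 0:
        raise RuntimeError("eligibility stage produced an empty cohort")
    n_excluded = n_in - filtered.n
    log.info("stage eligibility: %d retained, %d excluded", filtered.n, n_excluded)
    write_cohort(filtered, out / "cohort_filtered.csv")
    artifacts["cohort_filtered.csv"] = _sha256(out / "cohort_filtered.csv")
    pd.DataFrame(filtered.exclusion_log, columns=["patient_id", "reason"]).to_csv(
        out / "exclusions.csv", index=False
    )
    artifacts["exclusions.csv"] = _sha256(out / "exclusions.csv")

    # complete cases for the marker analysis
    df = filtered.df
    complete = ~df[list(config.markers)].isna().any(axis=1) & ~df["egfr"].isna()
    analysis = CohortTable(
        df=df.loc[complete].reset_index(drop=True),
        provenance=filtered.provenance + " | complete cases",
        exclusion_log=filtered.exclusion_log
        + [(str(pid), "incomplete marker data") for pid in df.loc[~complete, "patient_id"]],
    )
    labels = iit_labels(analysis)
    if labels.all() or not labels.any():
        raise RuntimeError("ROC stage requires both IIT classes present")

    # --- stage: ROC --------------------------------------------------------
    auc_rows = []
    for marker in config.markers:
        direction = marker_direction(marker)
        curve = roc_curve(analysis.df[marker].to_numpy(float), labels, direction, marker)
        auc_rows.append({"marker": marker, "direction": direction,
                         "auc": auc_trapezoid(curve), "kind": "single"})
    best_marker = max(
        (r for r in auc_rows), key=lambda r: (r["auc"], -list(config.markers).index(r["marker"]))
    )["marker"]
    for other in config.markers:
        if other == best_marker:
            continue
        score, meta = combine_markers(analysis.df, [best_marker, other], labels)
        curve = roc_curve(score, labels, GREATER, f"{best_marker}+{other}")
        auc_rows.append(
            {"marker": f"{best_marker}+{other}", "direction": GREATER,
             "auc": auc_trapezoid(curve), "kind": "combination",
             "perfect_separation": meta["perfect_separation"]}
        )
    save_tsv("aucs.tsv", pd.DataFrame(auc_rows))
    log.info("stage roc: best single marker %s", best_marker)

    # --- stage: cutoff -----------------------------------------------------
    direction = marker_direction(best_marker)
    scores = analysis.df[best_marker].to_numpy(float)
    cv = crossval_cutoff(scores, labels, direction,
                         n_replicates=config.n_replicates, seed=config.seed)
    full = best_cutoff(scores, labels, direction)
    (out / "cv.json").write_text(json.dumps(
        {**cv.to_dict(), "full_data_cutoff": full.cutoff}, indent=2))
    artifacts["cv.json"] = _sha256(out / "cv.json")
    cutoff = config.cutoff_override if config.cutoff_override is not None else cv.mean_cutoff
    log.info("stage cutoff: mean CV cutoff %.3f (using %.3f)", cv.mean_cutoff, cutoff)

    # --- stage: reports ----------------------------------------------------
    report = stratified_metrics(analysis, best_marker, cutoff, labels, direction)
    overall = report.overall.as_percent(rounded=False)
    save_tsv("overall_metrics.tsv", pd.DataFrame([{"marker": best_marker,
                                                   "cutoff": cutoff, **overall,
                                                   "n": report.overall.n}]))
    save_tsv("stratified_metrics.tsv", report.as_frame())
    save_tsv("quadrant.tsv",
             quadrant_table(analysis, best_marker, cutoff, labels, config.egfr_split))

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            "input_path": config.input_path,
            "generator": config.generator.to_dict() if config.generator else None,
            "markers": list(config.markers),
            "label": config.label,
            "cutoff_override": config.cutoff_override,
            "n_replicates": config.n_replicates,
            "egfr_split": list(config.egfr_split),
        },
        "counts": {
            "records_in": n_in,
            "records_retained": filtered.n,
            "records_excluded": n_excluded,
            "records_analyzed": int(complete.sum()),
        },
        "summary": {
            "best_marker": best_marker,
            "aucs": {r["marker"]: r["auc"] for r in auc_rows},
            "mean_cv_cutoff": cv.mean_cutoff,
            "full_data_cutoff": full.cutoff,
            "cutoff_used": cutoff,
            "overall_metrics_pct": report.overall.as_percent(rounded=True),
        },
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
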