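"""Diagnostic performance of the RDW cutoff, overall and by eGFR stratum.

Applies the cross-validated cutoff (from step 04, or --cutoff) to the cohort
and reports sensitivity, specificity, PPV and NPV overall, per renal-function
stratum, and as the RDW-by-eGFR quadrant table used to judge in whom a normal
RDW safely excludes impaired iron transport.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from iitscreen import apply_eligibility, quadrant_table, read_cohort, stratified_metrics
from iitscreen.cohort import iit_labels


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    parser.add_argument("--cv", type=Path, default=Path("results/cv.json"))
    parser.add_argument("--cutoff", type=float, default=None,
                        help="override the cross-validated cutoff")
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    cohort = apply_eligibility(read_cohort(args.cohort))
    labels = iit_labels(cohort)
    cutoff = args.cutoff if args.cutoff is not None \
        else json.loads(args.cv.read_text())["mean_cutoff"]

    report = stratified_metrics(cohort, "rdw", cutoff, labels)
    overall = report.overall.as_percent(rounded=True)
    print(f"RDW >= {cutoff:.1f}% vs IIT, n={report.overall.n}:")
    print("  overall  sens {sensitivity:.0f}%  spec {specificity:.0f}%  "
          "PPV {ppv:.0f}%  NPV {npv:.0f}%".format(**overall))

    frame = report.as_frame()
    args.out_dir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(args.out_dir / "stratified.tsv", sep="\t", index=False,
                 float_format="%.4g")
    print(frame.to_string(index=False))

    quad = quadrant_table(cohort, "rdw", cutoff, labels, egfr_split=(60.0,))
    quad.to_csv(args.out_dir / "quadrant.tsv", sep="\t", index=False,
                float_format="%.4g")
    print(quad.to_string(index=False))
    print(f"\nwrote {args.out_dir / 'stratified.tsv'} and {args.out_dir / 'quadrant.tsv'}")


if __name__ == "__main__":
    main()
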