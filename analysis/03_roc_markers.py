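"""ROC comparison of RDW, MCV and MCHC (and RDW-based combinations) for IIT.

RDW is read as higher-is-positive; MCV and MCHC as lower-is-positive.  The
best single marker is then combined with each remaining marker through an
additive logistic score to ask whether the combination adds discrimination.
"""

import argparse
from pathlib import Path

import pandas as pd

from iitscreen import apply_eligibility, read_cohort
from iitscreen.cohort import iit_labels
from iitscreen.roc import GREATER, auc_trapezoid, combine_markers, marker_direction, roc_curve

MARKERS = ["rdw", "mcv", "mchc"]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    parser.add_argument("--out", type=Path, default=Path("results/aucs.tsv"))
    args = parser.parse_args()

    cohort = apply_eligibility(read_cohort(args.cohort))
    labels = iit_labels(cohort)

    rows = []
    for marker in MARKERS:
        direction = marker_direction(marker)
        auc = auc_trapezoid(roc_curve(cohort.df[marker].to_numpy(), labels,
                                      direction, marker))
        rows.append({"marker": marker, "direction": direction, "auc": auc})
    best = max(rows, key=lambda r: r["auc"])["marker"]
    print(f"best single marker: {best}")
    for other in MARKERS:
        if other == best:
            continue
        score, meta = combine_markers(cohort.df, [best, other], labels)
        auc = auc_trapezoid(roc_curve(score, labels, GREATER))
        rows.append({"marker": f"{best}+{other}", "direction": GREATER, "auc": auc})

    table = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, sep="\t", index=False, float_format="%.4f")
    print(table.to_string(index=False))
    print(f"\nwrote {args.out}")


if __name__ == "__main__":
    main()
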