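"""Eligibility filtering and the IIT-present vs IIT-absent characteristics table.

Reads the cohort CSV from step 01, applies the study filter (adults,
non-anaemic, resolvable TSAT), and writes a two-group comparison of
demographics, haematology, iron panel and renal function.
"""

import argparse
from pathlib import Path

from iitscreen import apply_eligibility, read_cohort, table_one
from iitscreen.cohort import iit_labels

VARIABLES = ["age", "weight_kg", "height_m", "hb", "hct", "rdw", "mcv", "mchc",
             "serum_iron", "ferritin", "transferrin", "tsat", "tibc",
             "creatinine", "egfr", "lvef"]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    parser.add_argument("--out", type=Path, default=Path("results/table1.tsv"))
    args = parser.parse_args()

    cohort = apply_eligibility(read_cohort(args.cohort))
    print(f"{cohort.n} eligible patients ({len(cohort.exclusion_log)} excluded)")

    labels = iit_labels(cohort)
    table = table_one(cohort.df, labels, VARIABLES,
                      group_names=("IIT absent", "IIT present"))
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, sep="\t", index=False, float_format="%.4g")
    print(table.to_string(index=False))
    print(f"\nwrote {args.out}")


if __name__ == "__main__":
    main()
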