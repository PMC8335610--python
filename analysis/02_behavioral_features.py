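"""Circadian and calendar posting statistics per user.

Computes STTR/DTTR, weekday/weekend ratios, year-quarter ratios, the
median inter-tweet gap and total counts, and prints the group medians —
the night-activity ordering (AN highest) is the headline behavioral
signal.
"""

import argparse
from pathlib import Path

import pandas as pd

from anstages.behavior import behavioral_table
from anstages.corpus import read_cohort

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--out", type=Path,
                    default=ROOT / "results" / "behavioral_features.csv")
    args = ap.parse_args()

    cohort = read_cohort(args.cohort)
    table = behavioral_table(cohort)
    table.to_csv(args.out)

    groups = pd.Series({uid: u.group for uid, u in cohort.users.items()})
    med = table.groupby(groups)[["sttr", "weekend_ratio",
                                 "median_gap_seconds"]].median()
    print("group medians:")
    print(med.round(4).to_string())
    print(f"table written to {args.out}")


if __name__ == "__main__":
    main()
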