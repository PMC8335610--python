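"""Nonparametric comparison of the five user groups.

Joins the text and behavioral feature tables, screens every feature with
Kruskal–Wallis at alpha=.05, then runs pairwise Mann–Whitney U tests for
the five pairs of interest and reports medians with significance tiers.
"""

import argparse
from pathlib import Path

import pandas as pd

from anstages.corpus import read_cohort
from anstages.stats import compare_table, comparison_frame

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--features", type=Path, nargs="+",
                    default=[ROOT / "results" / "text_features.csv",
                             ROOT / "results" / "behavioral_features.csv"])
    ap.add_argument("--out", type=Path,
                    default=ROOT / "results" / "group_comparison.csv")
    args = ap.parse_args()

    cohort = read_cohort(args.cohort)
    groups = pd.Series({uid: u.group for uid, u in cohort.users.items()})
    table = pd.concat(
        [pd.read_csv(f, index_col="user_id") for f in args.features], axis=1)

    rows = compare_table(table, groups)
    frame = comparison_frame(rows)
    frame.to_csv(args.out)

    passed = frame[frame["kw_p"] < 0.05]
    print(f"{len(passed)}/{len(frame)} features pass the Kruskal-Wallis screen")
    tier_cols = [c for c in frame.columns if c.startswith("tier_")]
    strong = (passed[tier_cols] == "<.001").sum().sum()
    print(f"{strong} pairwise contrasts at P<.001")
    print(passed[["median_AN", "median_focused_control",
                  "p_AN_vs_focused_control"]].head(12).round(4).to_string())
    print(f"table written to {args.out}")


if __name__ == "__main__":
    main()
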