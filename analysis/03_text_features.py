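"""Lexicon-category rate features per user.

Concatenates each user's tweets and scores every lexicon category
(linguistic dimensions, the eight basic emotions with positive/negative,
personal concerns, anorexia-related vocabulary) as phrase matches per
token, plus median tweet length and median polarity.
"""

import argparse
from pathlib import Path

import pandas as pd

from anstages.corpus import read_cohort
from anstages.lexfeat import build_feature_table
from anstages.synth import default_lexicons

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--out", type=Path,
                    default=ROOT / "results" / "text_features.csv")
    args = ap.parse_args()

    cohort = read_cohort(args.cohort)
    table = build_feature_table(cohort, default_lexicons())
    table.to_csv(args.out)

    groups = pd.Series({uid: u.group for uid, u in cohort.users.items()})
    show = ["first_person_singular", "negative", "sadness", "an_vocab",
            "polarity_median"]
    print("group medians (selected categories):")
    print(table.groupby(groups)[show].median().round(4).to_string())
    print(f"table written to {args.out}")


if __name__ == "__main__":
    main()
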