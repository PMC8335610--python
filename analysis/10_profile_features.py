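"""Demographics and profile-picture features per group.

Applies the organization/gender/age decision rules to the externally
supplied scores, builds the boolean picture-object bag (support >= 5
users), assigns dominant emotions where faces are present, and reports
ratio-of-users summaries per group with pairwise proportion z-tests on
selected features.
"""

import argparse
from pathlib import Path

import pandas as pd

from anstages.corpus import read_cohort
from anstages.profiles import (
    assign_demographics, dominant_emotion, group_user_ratios, object_bow,
)
from anstages.stats import proportion_ztest

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--out", type=Path,
                    default=ROOT / "results" / "profile_ratios.csv")
    args = ap.parse_args()

    cohort = read_cohort(args.cohort)
    groups = {uid: u.group for uid, u in cohort.users.items()}

    demo = {uid: assign_demographics(u.demo_scores).gender
            for uid, u in cohort.users.items() if u.demo_scores}
    gender_ratios = group_user_ratios(demo, groups)
    print("gender/organization ratios per group:")
    print(gender_ratios.round(3).to_string())

    emotions = {uid: dominant_emotion(u.picture)
                for uid, u in cohort.users.items() if u.picture}
    emo_ratios = group_user_ratios(emotions, groups)

    has_text = {uid: u.picture.has_text
                for uid, u in cohort.users.items() if u.picture}
    text_ratios = group_user_ratios(has_text, groups)

    bow = object_bow(cohort.users.values(), min_images=5)
    print(f"picture-object vocabulary (support >= 5): {list(bow.columns)}")

    def count(group, mapping):
        vals = [v for uid, v in mapping.items() if groups[uid] == group]
        return sum(vals), len(vals)

    s_an, n_an = count("AN", has_text)
    s_fc, n_fc = count("focused_control", has_text)
    z, p = proportion_ztest(s_an, n_an, s_fc, n_fc)
    print(f"has_text AN {s_an}/{n_an} vs focused {s_fc}/{n_fc}: "
          f"z={z:.2f}, p={p:.4f}")

    combined = pd.concat({"gender": gender_ratios, "emotion": emo_ratios,
                          "has_text": text_ratios}, axis=1)
    combined.to_csv(args.out)
    print(f"ratio tables written to {args.out}")


if __name__ == "__main__":
    main()
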