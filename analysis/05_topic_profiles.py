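"""Topic-interest profiles per group and the user-vs-followee correlation.

Scores every user's sampled texts (own tweets, likes, followee bios)
against the topic lexicons, aggregates to group medians (displayed x1000),
computes followee-level profiles through the three-level aggregation, and
reports Spearman correlations between the profiles.
"""

import argparse
from pathlib import Path

import pandas as pd

from anstages.corpus import read_cohort
from anstages.synth import default_config
from anstages.topics import (
    SamplingPlan, followee_group_profile, group_profile, profile_spearman,
    top_topics, user_interest_profile,
)

ROOT = Path(__file__).resolve().parents[1]
GROUPS = ("AN", "treatment", "recovered", "focused_control", "random_control")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path,
                    default=ROOT / "results" / "topic_profiles.csv")
    args = ap.parse_args()

    cohort = read_cohort(args.cohort)
    topics = {t: set(v) for t, v in default_config(args.seed).topic_terms.items()}
    plan = SamplingPlan(seed=args.seed)

    gp = {}
    for g in GROUPS:
        profs = [user_interest_profile(u, cohort, topics, plan)
                 for u in cohort.by_group(g)]
        gp[g] = group_profile(profs, display_scale=1000)
    fw_an = followee_group_profile(cohort.by_group("AN"), cohort, topics, plan)

    pd.DataFrame({g: gp[g].display() for g in GROUPS}).rename_axis("topic") \
        .to_csv(args.out)

    print("top 5 topics per group (median score x1000):")
    for g in GROUPS:
        tops = ", ".join(f"{t}={v:.1f}" for t, v in top_topics(gp[g], 5))
        print(f"  {g}: {tops}")
    print("Spearman rho, group vs group:")
    for a, b in (("AN", "focused_control"), ("treatment", "focused_control"),
                 ("recovered", "focused_control"), ("AN", "random_control")):
        print(f"  {a} vs {b}: {profile_spearman(gp[a], gp[b]):.3f}")
    print(f"AN users vs their followees: "
          f"{profile_spearman(gp['AN'], fw_an):.3f}")
    print(f"profiles written to {args.out}")


if __name__ == "__main__":
    main()
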