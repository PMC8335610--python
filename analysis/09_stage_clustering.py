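"""Precontemplation / contemplation clustering of the AN group.

k=2 k-means over the eight emotion rates plus median polarity
(z-standardized), labeled by the positivity-vs-negativity rule, with
per-cluster medians and between-cluster Mann-Whitney p-values.  Since the
cohort is synthetic, the assignments are also checked against the
generator's true mixture memberships.
"""

import argparse
from pathlib import Path

import pandas as pd

from anstages.corpus import read_cohort
from anstages.lexfeat import build_feature_table
from anstages.stages import cluster_report, run_stage_clustering
from anstages.synth import default_lexicons

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path,
                    default=ROOT / "results" / "stage_clusters.csv")
    args = ap.parse_args()

    cohort = read_cohort(args.cohort)
    groups = pd.Series({uid: u.group for uid, u in cohort.users.items()})
    features = build_feature_table(cohort, default_lexicons())
    an = features.loc[groups == "AN"]

    res = run_stage_clustering(an, seed=args.seed)
    predicted = res.assignments.map(res.stage_labels)
    sizes = predicted.value_counts()
    print(f"clusters: precontemplation={sizes.get('precontemplation', 0)}, "
          f"contemplation={sizes.get('contemplation', 0)}")

    truth = pd.Series({uid: cohort.users[uid].true_stage
                       for uid in predicted.index})
    acc = (predicted == truth).mean()
    print(f"agreement with generator mixtures: {acc:.1%}")

    report = cluster_report(res)
    report.to_csv(args.out)
    print(report.round(4).to_string())
    print(f"report written to {args.out}")


if __name__ == "__main__":
    main()
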