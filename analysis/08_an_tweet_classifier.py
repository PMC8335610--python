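"""Anorexia-related tweet classifier and per-user median scores.

Trains the tf-idf / PCA-300 / logistic-regression pipeline on a balanced
corpus of AN-group vs random-control tweets, reports fold-wise
cross-validated precision/recall/F1, and compares the per-user median
scores across groups (expected ordering: AN > treatment > recovered >
random control).
"""

import argparse
from pathlib import Path

import numpy as np

from anstages.antweet import NEGATIVE_CLASS, POSITIVE_CLASS, fit, user_median_score
from anstages.corpus import read_cohort
from anstages.stats import mann_whitney
from anstages.synth import substream

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--per-class", type=int, default=1500)
    args = ap.parse_args()

    cohort = read_cohort(args.cohort)
    rng = substream(args.seed, "classifier_corpus")
    texts, labels = [], []
    for g, lab in (("AN", POSITIVE_CLASS), ("random_control", NEGATIVE_CLASS)):
        pool = [t.text for u in cohort.by_group(g) for t in u.tweets]
        idx = rng.choice(len(pool), size=min(args.per_class, len(pool)),
                         replace=False)
        texts += [pool[i] for i in idx]
        labels += [lab] * len(idx)

    model = fit(texts, labels, folds=10, seed=args.seed)
    m = model.cv_metrics
    print(f"10-fold CV (anorexia class): precision={m['precision']:.3f} "
          f"recall={m['recall']:.3f} F1={m['f1']:.3f}")

    med = {}
    for g in ("AN", "treatment", "recovered", "random_control"):
        users = cohort.by_group(g)
        med[g] = [user_median_score(model, u) for u in users]
        print(f"median user score {g}: {np.median(med[g]):.3f} (n={len(users)})")
    _, p = mann_whitney(med["AN"], med["random_control"])
    print(f"AN vs random control Mann-Whitney p = {p:.2e}")


if __name__ == "__main__":
    main()
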