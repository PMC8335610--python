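"""Generate the synthetic study cohort and write it to results/cohort/.

Five user groups with the study's structure: night-skewed posting for the
AN group, group-specific vocabulary emission rates, homophilous follow
edges (AN / focused-control polarization), per-group topic interests, an
emotion-mixture split of the AN group, and picture/demographic scores.
"""

import argparse
from pathlib import Path

from anstages.corpus import write_cohort
from anstages.synth import default_config, generate_cohort

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "cohort")
    args = ap.parse_args()

    cfg = default_config(seed=args.seed)
    cohort = generate_cohort(cfg)
    write_cohort(cohort, args.out)

    n_tweets = sum(len(u.tweets) for u in cohort.users.values())
    n_edges = len(cohort.edges())
    print(f"cohort: {len(cohort)} users, {n_tweets} tweets, {n_edges} follow edges")
    for g in sorted(cfg.group_sizes):
        print(f"  {g}: {len(cohort.by_group(g))} users")
    print(f"written to {args.out}")


if __name__ == "__main__":
    main()
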