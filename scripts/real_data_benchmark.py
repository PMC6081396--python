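#!/usr/bin/env python
"""Optional benchmark on a user-supplied real DDI dataset.

Runs new-drug hold-out cross-validation (default: 85% of drugs withheld,
10 repetitions) for one method on interaction/similarity matrices given
as drug-ID-headed TSV files, and prints the mean and per-repetition
AUPR.  Useful for comparing against published figures on curated DDI
networks; not part of the test suite (no dataset ships with the
package).

Usage::

    python scripts/real_data_benchmark.py \
        --interactions interactions.tsv --similarity similarity.tsv \
        --method svm --ratio 0.85 --repetitions 10 --seed 1
"""

from __future__ import annotations

import argparse

from lcmds.evaluation import HoldoutPlan, holdout_cv
from lcmds.io import read_interaction_matrix, read_similarity_matrix


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--interactions", required=True)
    parser.add_argument("--similarity", required=True)
    parser.add_argument("--method", default="svm")
    parser.add_argument("--ratio", type=float, default=0.85)
    parser.add_argument("--repetitions", type=int, default=10)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    A = read_interaction_matrix(args.interactions)
    S = read_similarity_matrix(args.similarity)
    plan = HoldoutPlan(
        ratio=args.ratio,
        repetitions=args.repetitions,
        seeds=tuple(range(args.seed, args.seed + args.repetitions)),
    )
    report = holdout_cv(A, S, plan, args.method)
    for seed, value in zip(plan.seeds, report.auprs):
        print(f"repetition seed={seed}\taupr={value:.4f}")
    print(f"mean_aupr\t{report.mean:.4f}")
    print(f"std_aupr\t{report.std:.4f}")


if __name__ == "__main__":
    main()
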