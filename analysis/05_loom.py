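"""Subject-level leave-one-out (LOOM) evaluation of fingerprinting stability.

Each subject is excluded from both the training and the test set once; the
rs1 -> rs2 metrics of every reduced cohort are collected and summarized as
mean +/- sd, quantifying how much a single subject's data sways the model.
Run on a 10-subject cohort for desk-scale runtime.
"""

import argparse
from pathlib import Path

from neurofp import CohortConfig, TransformConfig, generate_cohort, loom_evaluate
from neurofp.io import RunConfig, write_report

N_FEATURES = 840
N_TRIALS = 15
DURATION = 1.5


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    cohort = generate_cohort(CohortConfig(n_subjects=10, seed=args.seed))
    result = loom_evaluate(
        cohort, TransformConfig("minirocket", N_FEATURES),
        duration=DURATION, n_trials_per_subject=N_TRIALS, seed=args.seed,
    )
    run_cfg = RunConfig(num_kernels_or_features=N_FEATURES, n_trials_per_subject=N_TRIALS,
                        trial_duration=DURATION, seed=args.seed)
    write_report(result, args.out, "loom", seed=args.seed, config=run_cfg)
    for metric, stats in result.summary.items():
        print(f"{metric}: {stats['mean']:.4f} +/- {stats['sd']:.4f}")


if __name__ == "__main__":
    main()
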