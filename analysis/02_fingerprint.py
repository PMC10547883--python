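"""Headline experiment: identify subjects across resting-state sessions.

Trains the ridge classifier on MiniRocket features of 15 trials x 1.5 s per
subject from rs1 and identifies the subject of each rs2 trial, then repeats
with the roles reversed.  Writes both metric reports under results/.
"""

import argparse
from pathlib import Path

from neurofp import CohortConfig, TransformConfig, generate_cohort, run_fingerprint, trials_from_cohort
from neurofp.io import RunConfig, write_report
from neurofp.seeding import derive_seed

N_FEATURES = 840
N_TRIALS = 15
DURATION = 1.5


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    cohort = generate_cohort(CohortConfig(seed=args.seed))
    tc = TransformConfig("minirocket", N_FEATURES)
    run_cfg = RunConfig(num_kernels_or_features=N_FEATURES, n_trials_per_subject=N_TRIALS,
                        trial_duration=DURATION, seed=args.seed)
    sessions = {"rs1": trials_from_cohort(cohort, "rs1", DURATION, N_TRIALS,
                                          derive_seed(args.seed, "trials", 0)),
                "rs2": trials_from_cohort(cohort, "rs2", DURATION, N_TRIALS,
                                          derive_seed(args.seed, "trials", 1))}
    for train_s, test_s in (("rs1", "rs2"), ("rs2", "rs1")):
        rep = run_fingerprint(sessions[train_s], sessions[test_s], tc, args.seed)
        write_report(rep, args.out, f"fingerprint_{train_s}_to_{test_s}",
                     seed=args.seed, config=run_cfg)
        print(
            f"{train_s} -> {test_s}: accuracy {rep.accuracy:.4f}, "
            f"macro precision {rep.macro_precision:.4f}, "
            f"macro recall {rep.macro_recall:.4f}, macro F1 {rep.macro_f1:.4f} "
            f"({rep.n_test} test trials, {len(rep.per_class)} subjects)"
        )


if __name__ == "__main__":
    main()
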