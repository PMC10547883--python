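"""Parameter sweeps: accuracy vs kernel count, trial count, trial duration.

One axis varies while the other two stay at the defaults (840 features,
15 trials, 1.5 s); each grid point is repeated with fresh trial selections
and kernel seeds and summarized as mean/min/max, mirroring a
rise-then-saturate accuracy curve on each axis.  Uses a 10-subject cohort
and 5 repeats to stay desk-scale.
"""

import argparse
from pathlib import Path

from neurofp import CohortConfig, generate_cohort, parameter_sweep
from neurofp.io import RunConfig, write_report
from neurofp.seeding import derive_seed

FIXED = {"num_kernels": 840, "num_trials": 15, "duration": 1.5}
GRIDS = {
    "num_kernels": [100, 200, 500, 840, 2000],
    "num_trials": [3, 5, 8, 15],
    "duration": [0.2, 0.5, 1.0, 1.5],
}
N_REPEATS = 5


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    cohort = generate_cohort(CohortConfig(n_subjects=10, seed=args.seed))
    run_cfg = RunConfig(num_kernels_or_features=FIXED["num_kernels"],
                        n_trials_per_subject=FIXED["num_trials"],
                        trial_duration=FIXED["duration"],
                        n_repeats=N_REPEATS, seed=args.seed)
    for gi, (axis, grid) in enumerate(GRIDS.items()):
        res = parameter_sweep(cohort, axis, grid, FIXED, n_repeats=N_REPEATS,
                              seed=derive_seed(args.seed, "sweep", gi))
        write_report(res, args.out, f"sweep_{axis}", seed=args.seed, config=run_cfg)
        cells = ", ".join(
            f"{v}: {m:.3f} [{lo:.3f}, {hi:.3f}]"
            for v, m, lo, hi in zip(res.grid, res.mean, res.min, res.max)
        )
        print(f"{axis}: {cells}")


if __name__ == "__main__":
    main()
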