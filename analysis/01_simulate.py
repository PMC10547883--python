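"""Generate the default synthetic cohort and store it with its manifest.

25 subjects x (rs1, rs2, empty), 68 regions at 250 Hz, 60 s per session:
subject-specific oscillator signatures in 1/f noise, plus noise-only empty
sessions.  The container goes under scratch/ (it is a large binary file);
every later driver can either reload it or regenerate it from the seed.
"""

import argparse
import json
from pathlib import Path

from neurofp import CohortConfig, generate_cohort
from neurofp.io import config_hash, save_cohort


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("scratch/cohort.h5"))
    args = parser.parse_args()

    config = CohortConfig(seed=args.seed)
    cohort = generate_cohort(config)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    save_cohort(cohort, args.out)
    manifest = {"config": config.as_dict(), "config_hash": config_hash(config)}
    Path(str(args.out) + ".manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    n_samples = cohort.recordings[cohort.subjects[0]]["rs1"].n_samples
    print(
        f"cohort: {config.n_subjects} subjects x 3 sessions, "
        f"{config.n_regions} regions x {n_samples} samples at {config.sampling_rate:g} Hz"
    )
    print(f"wrote {args.out} (config hash {manifest['config_hash']})")


if __name__ == "__main__":
    main()
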