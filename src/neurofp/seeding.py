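"""Deterministic seed derivation.

One global integer seed expands into per-stage seeds through a fixed
(stage-code, counter) scheme, so trial selection, kernel initialization,
noise generation etc. are independently reproducible.
"""

from __future__ import annotations

import numpy as np

# Stage codes are part of the reproducibility contract: changing them
# changes every derived stream.
_STAGE_CODES = {
    "cohort": 1,
    "signature": 2,
    "noise": 3,
    "day": 4,
    "session": 5,
    "kernels": 6,
    "channels": 7,
    "bias": 8,
    "classifier": 9,
    "trials": 10,
    "loom": 11,
    "sweep": 12,
    "crossover": 13,
    "permutation": 14,
}


def seed_sequence(seed: int, stage: str, index: int = 0) -> np.random.SeedSequence:
    """SeedSequence for a (seed, stage, counter) triple."""
    if stage not in _STAGE_CODES:
        raise KeyError(f"unknown seeding stage {stage!r}")
    return np.random.SeedSequence([int(seed), _STAGE_CODES[stage], int(index)])


def derive_seed(seed: int, stage: str, index: int = 0) -> int:
    """A derived integer seed in [0, 2**31), stable across runs."""
    return int(seed_sequence(seed, stage, index).generate_state(1, np.uint32)[0] % (2**31))


def rng_for(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Generator seeded from the derived (stage, counter) stream."""
    return np.random.default_rng(seed_sequence(seed, stage, index))
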