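"""MiniRocket: a fixed, data-fitted variant of the random-kernel transform.

Instead of fully random kernels, MiniRocket uses the deterministic set of
length-9 weight vectors over {-1, 2} with exactly three 2s (84 patterns,
each summing to zero), a small set of geometrically spaced dilations per
pattern (at most 32), and biases fitted as quantiles of the convolution
output on training trials.  Pooling is ppv only, but each convolution is
used twice: the proportion of strictly positive values of (C - b) for the
kernel itself and the proportion of strictly negative values for the
inverted kernel (-w, -b), which equals 1 - ppv whenever no output value
ties the bias.  This doubles the features without a second convolution.

Feature layout: combos in (pattern, dilation) order; within a combo the
budgeted features come as (ppv, pnv) pairs sharing one fitted bias, with an
odd remainder emitted as a lone ppv feature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .containers import FeatureMatrix, TrialSet
from .seeding import rng_for

KERNEL_LENGTH = 9
N_HIGH_TAPS = 3
N_PATTERNS = 84  # C(9, 3)
MAX_DILATIONS = 32
#: golden-ratio increment for the low-discrepancy quantile-level sequence
_PHI = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class MiniRocketPattern:
    """One fixed weight vector: -1 everywhere, 2 at three tap positions."""

    pattern_id: int
    positions: tuple

    @property
    def weights(self) -> np.ndarray:
        w = np.full(KERNEL_LENGTH, -1.0)
        w[list(self.positions)] = 2.0
        return w


def enumerate_patterns() -> list:
    """All 84 patterns, in lexicographic order of the positions of the 2s."""
    return [
        MiniRocketPattern(pattern_id=i, positions=pos)
        for i, pos in enumerate(combinations(range(KERNEL_LENGTH), N_HIGH_TAPS))
    ]


@dataclass(frozen=True)
class Combo:
    """A (pattern, dilation) pairing with its fixed padding flag and channel subset."""

    pattern_id: int
    dilation: int
    padding: bool
    channels: tuple


@dataclass
class MiniRocketConfig:
    num_features: int = 3500
    max_dilations_per_kernel: int = MAX_DILATIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_features < N_PATTERNS:
            raise ValueError(
                f"num_features must be >= {N_PATTERNS} (the pattern-set size)"
            )
        if not 1 <= self.max_dilations_per_kernel <= MAX_DILATIONS:
            raise ValueError(f"max_dilations_per_kernel must be in [1, {MAX_DILATIONS}]")


@dataclass
class FittedMiniRocket:
    """Fitted transform: combos, per-combo feature counts and quantile biases."""

    combos: list
    features_per_combo: np.ndarray
    biases: list  # per combo, array of len ceil(n_features_combo / 2)
    input_length: int
    n_channels: int
    seed: int
    patterns: list = field(default_factory=enumerate_patterns)

    @property
    def num_features(self) -> int:
        return int(self.features_per_combo.sum())

    def to_json(self, path) -> None:
        payload = {
            "input_length": self.input_length,
            "n_channels": self.n_channels,
            "seed": self.seed,
            "combos": [
                {
                    "pattern_id": c.pattern_id,
                    "dilation": c.dilation,
                    "padding": c.padding,
                    "channels": list(c.channels),
                }
                for c in self.combos
            ],
            "features_per_combo": self.features_per_combo.tolist(),
            "biases": [b.tolist() for b in self.biases],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "FittedMiniRocket":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        combos = [
            Combo(
                pattern_id=c["pattern_id"],
                dilation=c["dilation"],
                padding=c["padding"],
                channels=tuple(c["channels"]),
            )
            for c in payload["combos"]
        ]
        return cls(
            combos=combos,
            features_per_combo=np.asarray(payload["features_per_combo"], dtype=int),
            biases=[np.asarray(b, dtype=float) for b in payload["biases"]],
            input_length=payload["input_length"],
            n_channels=payload["n_channels"],
            seed=payload["seed"],
        )


def _dilation_values(input_length: int, n_dilations: int) -> np.ndarray:
    """Geometrically spaced dilations with receptive field inside the trial."""
    a_max = np.log2((input_length - 1) / (KERNEL_LENGTH - 1))
    exponents = np.linspace(0.0, a_max, n_dilations)
    return np.unique(np.floor(2.0**exponents).astype(int))


def _combo_convolve(data: np.ndarray, combo: Combo, weights: np.ndarray) -> np.ndarray:
    """Convolve a (n_trials, channels, samples) stack with one combo's kernel.

    The pattern weights are shared across the selected channels, so the
    multivariate convolution reduces to the univariate convolution of the
    channel sum.
    """
    x = data[:, list(combo.channels), :].sum(axis=1)
    span = (KERNEL_LENGTH - 1) * combo.dilation
    if combo.padding:
        pad = span // 2
        x = np.pad(x, ((0, 0), (pad, pad)))
    n_out = x.shape[1] - span
    if n_out < 1:
        raise ValueError("trial too short for this combo's receptive field")
    out = np.zeros((data.shape[0], n_out), dtype=float)
    d = combo.dilation
    for j in range(KERNEL_LENGTH):
        out += weights[j] * x[:, j * d : j * d + n_out]
    return out


def fit(training: TrialSet, config: MiniRocketConfig) -> FittedMiniRocket:
    """Fit the deterministic kernel set to a training TrialSet.

    Dilations per pattern: min(budget // 84, max_dilations_per_kernel),
    geometrically spaced (duplicates merged).  The feature budget is spread
    as evenly as possible over (pattern, dilation) combos.  Padding
    alternates deterministically over combos; channel subsets are drawn
    from the seed.  Each bias is the quantile - at a golden-ratio
    low-discrepancy level - of the combo's convolution output on one
    training trial drawn uniformly at random.
    """
    if training.n_trials < 1:
        raise ValueError("training set must contain at least one trial")
    length = training.samples_per_trial
    if length < KERNEL_LENGTH:
        raise ValueError(
            f"trial length {length} does not admit the length-{KERNEL_LENGTH} kernel"
        )
    patterns = enumerate_patterns()
    n_dil = int(np.clip(config.num_features // N_PATTERNS, 1, config.max_dilations_per_kernel))
    dilations = _dilation_values(length, n_dil)

    chan_rng = rng_for(config.seed, "channels")
    max_sub = min(KERNEL_LENGTH, training.n_regions)
    combos = []
    ci = 0
    for pattern in patterns:
        for d in dilations:
            u = chan_rng.uniform(0.0, np.log2(max_sub + 1))
            size = min(int(2**u), max_sub)
            chans = np.sort(chan_rng.choice(training.n_regions, size=size, replace=False))
            combos.append(
                Combo(
                    pattern_id=pattern.pattern_id,
                    dilation=int(d),
                    padding=(ci % 2 == 0),
                    channels=tuple(int(c) for c in chans),
                )
            )
            ci += 1

    n_combos = len(combos)
    base, rem = divmod(config.num_features, n_combos)
    features_per_combo = np.full(n_combos, base, dtype=int)
    features_per_combo[:rem] += 1

    bias_rng = rng_for(config.seed, "bias")
    biases = []
    level_counter = 0
    for combo, n_f in zip(combos, features_per_combo):
        n_b = (int(n_f) + 1) // 2
        combo_biases = np.empty(n_b, dtype=float)
        if n_b:
            weights = patterns[combo.pattern_id].weights
            for k in range(n_b):
                trial_idx = int(bias_rng.integers(training.n_trials))
                conv = _combo_convolve(
                    training.data[trial_idx : trial_idx + 1], combo, weights
                )[0]
                level = ((level_counter + 1) * _PHI) % 1.0
                combo_biases[k] = np.quantile(conv, level)
                level_counter += 1
        biases.append(combo_biases)

    return FittedMiniRocket(
        combos=combos,
        features_per_combo=features_per_combo,
        biases=biases,
        input_length=length,
        n_channels=training.n_regions,
        seed=config.seed,
        patterns=patterns,
    )


def minirocket_features(trials: TrialSet, fitted: FittedMiniRocket) -> FeatureMatrix:
    """Transform trials with a fitted MiniRocket.

    Each (combo, bias) yields ppv(C - b); its inverted-kernel partner is
    the proportion of strictly negative values of (C - b), read off the
    same convolution (pnv = 1 - ppv on tie-free outputs).
    """
    if trials.samples_per_trial != fitted.input_length:
        raise ValueError(
            f"trial length {trials.samples_per_trial} does not match fitted "
            f"input_length {fitted.input_length}"
        )
    if trials.n_regions != fitted.n_channels:
        raise ValueError(
            f"trial channel count {trials.n_regions} does not match fitted "
            f"n_channels {fitted.n_channels}"
        )
    n = trials.n_trials
    values = np.empty((n, fitted.num_features), dtype=float)
    names = []
    col = 0
    for ci, (combo, n_f) in enumerate(zip(fitted.combos, fitted.features_per_combo)):
        n_f = int(n_f)
        if n_f == 0:
            continue
        weights = fitted.patterns[combo.pattern_id].weights
        conv = _combo_convolve(trials.data, combo, weights)
        inv_n = conv.shape[1]
        for k in range(n_f):
            b = fitted.biases[ci][k // 2]
            if k % 2 == 0:
                values[:, col] = (conv > b).mean(axis=1)
                names.append(f"c{ci:04d}_b{k // 2}_ppv")
            else:
                values[:, col] = (conv < b).sum(axis=1) / inv_n
                names.append(f"c{ci:04d}_b{k // 2}_pnv")
            col += 1
    return FeatureMatrix(values=values, feature_names=names, transform_tag="minirocket")
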