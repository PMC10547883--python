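"""ROCKET: random convolutional kernels with max / ppv pooling.

A kernel is characterised by its length (7, 9 or 11 taps), a dilation
(spacing between taps, sampled on an exponential scale so different kernels
see different time scales / frequencies), mean-centred Gaussian weights, a
uniform bias on [-1, 1], an even-chance padding flag, and - for multivariate
input - the subset of channels it is applied to.  Each kernel is slid over a
trial as a dilated dot product

    C_t = sum_ch sum_j X[ch, t + j*d] * w[ch, j] + b

and pooled into two features: the global maximum of C and the proportion of
strictly positive values (ppv).  A large bank of such kernels turns each
trial into a feature vector for a linear classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .containers import FeatureMatrix, TrialSet
from .seeding import rng_for

LENGTH_CHOICES = (7, 9, 11)
#: minimum input length such that every kernel length admits dilation >= 1
MIN_INPUT_LENGTH = 12


@dataclass(frozen=True)
class RocketKernel:
    """One random convolutional kernel.

    ``weights`` has shape (len(channels), length): independent mean-centred
    weights per selected channel.  ``channels`` is the ordered channel
    subset the kernel is applied to.
    """

    length: int
    dilation: int
    weights: np.ndarray
    bias: float
    padding: bool
    channels: tuple

    def receptive_field(self) -> int:
        """Span of the dilated kernel in samples."""
        return (self.length - 1) * self.dilation + 1


@dataclass
class KernelBank:
    kernels: list
    input_length: int
    n_channels: int
    seed: int

    def __len__(self) -> int:
        return len(self.kernels)

    def to_json(self, path) -> None:
        payload = {
            "input_length": self.input_length,
            "n_channels": self.n_channels,
            "seed": self.seed,
            "kernels": [
                {
                    "length": k.length,
                    "dilation": k.dilation,
                    "weights": k.weights.tolist(),
                    "bias": k.bias,
                    "padding": k.padding,
                    "channels": list(k.channels),
                }
                for k in self.kernels
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "KernelBank":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        kernels = [
            RocketKernel(
                length=k["length"],
                dilation=k["dilation"],
                weights=np.asarray(k["weights"], dtype=float),
                bias=k["bias"],
                padding=k["padding"],
                channels=tuple(k["channels"]),
            )
            for k in payload["kernels"]
        ]
        return cls(
            kernels=kernels,
            input_length=payload["input_length"],
            n_channels=payload["n_channels"],
            seed=payload["seed"],
        )


def _draw_channel_subset(rng: np.random.Generator, n_channels: int) -> tuple:
    """Log-uniform subset size (favouring small subsets), distinct channels."""
    u = rng.uniform(0.0, np.log2(n_channels + 1))
    size = min(int(2**u), n_channels)
    chans = rng.choice(n_channels, size=size, replace=False)
    return tuple(int(c) for c in np.sort(chans))


def sample_kernel_bank(
    num_kernels: int, input_length: int, n_channels: int, seed: int
) -> KernelBank:
    """Draw a reproducible bank of random kernels.

    Lengths are uniform over {7, 9, 11}; weights standard normal then
    mean-centred per channel; bias uniform on [-1, 1]; dilation
    d = floor(2^x) with x ~ U(0, A) and A = log2((L-1)/(l_k-1)) so the
    dilated kernel always fits inside the input; padding is a fair coin.
    """
    if num_kernels < 1:
        raise ValueError("num_kernels must be >= 1")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if input_length < MIN_INPUT_LENGTH:
        raise ValueError(
            f"input_length must be >= {MIN_INPUT_LENGTH} so every kernel length "
            f"admits at least dilation 1; got {input_length}"
        )
    rng = rng_for(seed, "kernels")
    kernels = []
    for _ in range(num_kernels):
        length = int(rng.choice(LENGTH_CHOICES))
        a_max = np.log2((input_length - 1) / (length - 1))
        dilation = int(2 ** rng.uniform(0.0, a_max))
        channels = _draw_channel_subset(rng, n_channels)
        weights = rng.standard_normal((len(channels), length))
        weights -= weights.mean(axis=1, keepdims=True)
        bias = float(rng.uniform(-1.0, 1.0))
        padding = bool(rng.random() < 0.5)
        kernels.append(
            RocketKernel(
                length=length,
                dilation=dilation,
                weights=weights,
                bias=bias,
                padding=padding,
                channels=channels,
            )
        )
    return KernelBank(
        kernels=kernels, input_length=input_length, n_channels=n_channels, seed=seed
    )


def _batch_convolve(data: np.ndarray, kernel: RocketKernel) -> np.ndarray:
    """Convolve a (n_trials, n_channels, n_samples) stack with one kernel.

    Returns (n_trials, n_out).  With padding on, ((l-1)*d)/2 zeros are
    implicitly added on each side, so n_out equals the input length
    ((l-1)*d is even for all admissible lengths).
    """
    span = (kernel.length - 1) * kernel.dilation
    x = data[:, list(kernel.channels), :]
    if kernel.padding:
        pad = span // 2
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    n_out = x.shape[2] - span
    if n_out < 1:
        raise ValueError(
            f"input of length {data.shape[2]} too short for kernel span {span + 1} "
            "without padding"
        )
    out = np.full((data.shape[0], n_out), kernel.bias, dtype=float)
    d = kernel.dilation
    for j in range(kernel.length):
        out += np.einsum("ncs,c->ns", x[:, :, j * d : j * d + n_out], kernel.weights[:, j])
    return out


def convolve(trial: np.ndarray, kernel: RocketKernel) -> np.ndarray:
    """Dilated sliding dot product of one trial (channels x samples) with a kernel.

    A single bias is added once per output sample, shared across channels.
    """
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2:
        raise ValueError("trial must be a (channels, samples) matrix")
    if max(kernel.channels) >= trial.shape[0]:
        raise ValueError("kernel channel index out of range for this trial")
    return _batch_convolve(trial[None, :, :], kernel)[0]


def global_max(output: np.ndarray) -> float:
    """Global max pooling of a convolution output."""
    output = np.asarray(output, dtype=float)
    if output.size == 0:
        raise ValueError("cannot pool an empty convolution output")
    return float(output.max())


def ppv(output: np.ndarray) -> float:
    """Proportion of strictly positive values; zeros do not count."""
    output = np.asarray(output, dtype=float)
    if output.size == 0:
        raise ValueError("cannot pool an empty convolution output")
    return float((output > 0).mean())


def rocket_transform(trials: TrialSet, bank: KernelBank) -> FeatureMatrix:
    """Transform trials into 2 features per kernel, ordered [ppv, max] per kernel."""
    if trials.samples_per_trial != bank.input_length:
        raise ValueError(
            f"trial length {trials.samples_per_trial} does not match bank "
            f"input_length {bank.input_length}"
        )
    if trials.n_regions != bank.n_channels:
        raise ValueError(
            f"trial channel count {trials.n_regions} does not match bank "
            f"n_channels {bank.n_channels}"
        )
    n = trials.n_trials
    values = np.empty((n, 2 * len(bank)), dtype=float)
    names = []
    for i, kernel in enumerate(bank.kernels):
        out = _batch_convolve(trials.data, kernel)
        values[:, 2 * i] = (out > 0).mean(axis=1)
        values[:, 2 * i + 1] = out.max(axis=1)
        names.extend([f"k{i:05d}_ppv", f"k{i:05d}_max"])
    return FeatureMatrix(values=values, feature_names=names, transform_tag="rocket")
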