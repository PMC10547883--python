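"""Synthetic multi-subject, multi-session source-level cohort.

Emulates the statistical structure that subject identification from MEG
label time courses relies on, without any real data: each subject carries a
stable spectral/spatial signature (a small set of band-limited oscillators
mixed into the regions through a subject-specific matrix) that largely
persists from session rs1 to rs2, embedded in session-specific broadband
1/f noise.  "Empty-room" sessions contain no signature at all - only 1/f
noise plus an optional day-specific component shared by all subjects
recorded on the same simulated day, which carries day but not subject
information (its strength is the dial for the above-chance empty-vs-empty
diagonal seen with real empty-room data).

The generator targets statistical, not physiological, fidelity: no forward
model, sensor covariance or head movement.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .containers import Recording
from .seeding import rng_for

_SESSION_CODE = {"rs1": 0, "rs2": 1, "empty": 2}


@dataclass
class CohortConfig:
    """Generator settings; defaults give a high-SNR desk-scale cohort."""

    n_subjects: int = 25
    n_regions: int = 68
    sampling_rate: float = 250.0
    duration_rs1: float = 60.0
    duration_rs2: float = 60.0
    duration_empty: float = 60.0
    #: ratio of signature power to 1/f-noise power in resting sessions;
    #: 0 switches the signature off entirely (null cohort)
    snr: float = 4.0
    #: fraction of oscillators re-drawn between rs1 and rs2
    session_perturbation: float = 0.1
    #: spectral slope of the broadband noise, S(f) ~ f**-noise_exponent
    noise_exponent: float = 1.0
    #: amplitude (relative to unit noise power) of the day-specific,
    #: subject-shared component in empty sessions; 0 = no day structure
    empty_day_structure: float = 0.5
    #: subjects recorded per simulated day (groups sharing day structure)
    subjects_per_day: int = 5
    n_oscillators: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if not 0 <= self.session_perturbation <= 1:
            raise ValueError("session_perturbation must be in [0, 1]")
        if min(self.duration_rs1, self.duration_rs2, self.duration_empty) <= 0:
            raise ValueError("session durations must be positive")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class SubjectSignature:
    """Stable per-subject spectral/spatial structure."""

    subject_index: int
    frequencies: np.ndarray  # Hz, within [1, 40]
    amplitudes: np.ndarray
    mixing: np.ndarray  # (n_regions, n_oscillators)
    phases: np.ndarray
    seed: int


@dataclass
class Cohort:
    """recordings[subject_id][session] -> Recording."""

    recordings: dict
    config: CohortConfig

    @property
    def subjects(self) -> list:
        return sorted(self.recordings)


def subject_label(index: int) -> str:
    return f"sub-{index:03d}"


def make_signature(config: CohortConfig, subject_index: int) -> SubjectSignature:
    """Draw one subject's signature, deterministic in (seed, subject_index)."""
    rng = rng_for(config.seed, "signature", subject_index)
    k = config.n_oscillators
    return SubjectSignature(
        subject_index=subject_index,
        frequencies=rng.uniform(1.0, 40.0, k),
        amplitudes=rng.uniform(0.5, 1.5, k),
        mixing=rng.standard_normal((config.n_regions, k)) / np.sqrt(k),
        phases=rng.uniform(0.0, 2 * np.pi, k),
        seed=config.seed,
    )


def _pink_noise(
    rng: np.random.Generator, n_regions: int, n_samples: int, exponent: float, fs: float
) -> np.ndarray:
    """Per-region independent 1/f**exponent noise, unit variance per region."""
    white = rng.standard_normal((n_regions, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    noise = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    std = noise.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return noise / std


def _session_signature(
    signature: SubjectSignature, session: str, config: CohortConfig
) -> SubjectSignature:
    """Signature as expressed in a given resting session.

    rs1 uses the signature as drawn; rs2 re-draws a
    ``session_perturbation`` fraction of the oscillators (frequency, phase
    and spatial mixing column) to model between-session drift.
    """
    if session == "rs1" or config.session_perturbation == 0:
        return signature
    k = config.n_oscillators
    n_redraw = int(round(config.session_perturbation * k))
    if n_redraw == 0:
        return signature
    rng = rng_for(config.seed, "session", signature.subject_index)
    idx = rng.choice(k, size=n_redraw, replace=False)
    freqs = signature.frequencies.copy()
    phases = signature.phases.copy()
    mixing = signature.mixing.copy()
    freqs[idx] = rng.uniform(1.0, 40.0, n_redraw)
    phases[idx] = rng.uniform(0.0, 2 * np.pi, n_redraw)
    mixing[:, idx] = rng.standard_normal((config.n_regions, n_redraw)) / np.sqrt(k)
    return SubjectSignature(
        subject_index=signature.subject_index,
        frequencies=freqs,
        amplitudes=signature.amplitudes,
        mixing=mixing,
        phases=phases,
        seed=signature.seed,
    )


def make_recording(
    signature: SubjectSignature, session: str, config: CohortConfig
) -> Recording:
    """One session's continuous recording for one subject.

    Resting sessions: mixed oscillators scaled against fresh 1/f noise so
    that signature power / noise power = ``snr``.  Empty sessions: 1/f
    noise plus ``empty_day_structure`` times a day-shared 1/f component.
    """
    fs = config.sampling_rate
    duration = {
        "rs1": config.duration_rs1,
        "rs2": config.duration_rs2,
        "empty": config.duration_empty,
    }[session]
    n = int(round(duration * fs))
    noise_rng = rng_for(
        config.seed, "noise", signature.subject_index * 3 + _SESSION_CODE[session]
    )
    noise = _pink_noise(noise_rng, config.n_regions, n, config.noise_exponent, fs)
    if session == "empty":
        data = noise
        if config.empty_day_structure > 0:
            day = signature.subject_index // config.subjects_per_day
            day_rng = rng_for(config.seed, "day", day)
            day_comp = _pink_noise(day_rng, config.n_regions, n, config.noise_exponent, fs)
            data = noise + config.empty_day_structure * day_comp
    elif config.snr == 0:
        data = noise
    else:
        sig = _session_signature(signature, session, config)
        t = np.arange(n) / fs
        osc = sig.amplitudes[:, None] * np.sin(
            2 * np.pi * sig.frequencies[:, None] * t[None, :] + sig.phases[:, None]
        )
        signal = sig.mixing @ osc
        p_signal = float(np.mean(signal**2))
        p_noise = float(np.mean(noise**2))
        data = signal + noise * np.sqrt(p_signal / (config.snr * p_noise))
    return Recording(
        subject_id=subject_label(signature.subject_index),
        session=session,
        data=data,
        sampling_rate=fs,
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Full cohort: every subject gets rs1, rs2 and an empty session."""
    recordings = {}
    for i in range(config.n_subjects):
        signature = make_signature(config, i)
        recordings[subject_label(i)] = {
            session: make_recording(signature, session, config)
            for session in ("rs1", "rs2", "empty")
        }
    return Cohort(recordings=recordings, config=config)
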