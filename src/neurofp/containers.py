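"""Core in-memory containers shared across the package.

A *Recording* is one subject-session continuous multichannel source time
course (regions x samples).  A *TrialSet* is a stack of fixed-duration
windows cut from recordings, each labelled with the subject it came from;
trials are the unit of classification.  A *FeatureMatrix* holds the pooled
kernel features a transform produced, and a *MetricsReport* the
classification scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SESSIONS = ("rs1", "rs2", "empty")


@dataclass
class Recording:
    """One continuous subject-session time course, shape (n_regions, n_samples)."""

    subject_id: str
    session: str
    data: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("recording data must be a non-empty (regions, samples) matrix")
        if self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}, got {self.session!r}")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass
class TrialSet:
    """Labelled trials, shape (n_trials, n_regions, samples_per_trial)."""

    data: np.ndarray
    labels: np.ndarray
    duration: float
    sampling_rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("trial data must have shape (n_trials, n_regions, n_samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels must align one-to-one with trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    @property
    def samples_per_trial(self) -> int:
        return self.data.shape[2]

    @property
    def subject_ids(self) -> list:
        """Sorted unique labels."""
        return sorted(set(self.labels.tolist()))


@dataclass
class FeatureMatrix:
    """Pooled kernel features, one row per trial."""

    values: np.ndarray
    feature_names: list = field(default_factory=list)
    transform_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D (trials x features)")
        if self.feature_names and len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names must match the number of columns")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class MetricsReport:
    """Accuracy plus macro precision/recall/F1 with per-class detail."""

    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class: dict
    n_test: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "n_test": self.n_test,
        }
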