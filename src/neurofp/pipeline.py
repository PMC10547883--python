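"""Fingerprinting pipeline: trials, ridge classification, experiments.

The pipeline turns continuous per-subject recordings into balanced labelled
trial sets, transforms them with ROCKET or MiniRocket, fits a ridge
classifier (cross-validated regularization) on the training features and
scores identification on held-out features.  On top of that sit the three
experiment designs: subject-level leave-one-out evaluation (LOOM),
parameter sweeps over kernel count / trial count / trial duration, and the
rs1/rs2/empty cross-over matrix with a half-split rule on the diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.linear_model import RidgeClassifierCV

from . import minirocket as mr
from . import rocket as rk
from .containers import SESSIONS, FeatureMatrix, MetricsReport, Recording, TrialSet
from .seeding import derive_seed, rng_for

#: regularization grid for the ridge classifier
ALPHA_GRID = np.logspace(-3, 3, 10)


# ---------------------------------------------------------------------------
# trial construction


def znormalize(recording: Recording) -> Recording:
    """Z-score each region's continuous course (before any segmentation).

    A zero-variance region is centred to all zeros and a warning recorded
    rather than raising.
    """
    data = recording.data
    mean = data.mean(axis=1, keepdims=True)
    std = data.std(axis=1, keepdims=True)
    flat = std[:, 0] == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance region(s) in "
            f"{recording.subject_id}/{recording.session}; left at 0",
            stacklevel=2,
        )
        std[flat] = 1.0
    return Recording(
        subject_id=recording.subject_id,
        session=recording.session,
        data=(data - mean) / std,
        sampling_rate=recording.sampling_rate,
    )


def segment(recording: Recording, duration: float) -> TrialSet:
    """Cut consecutive non-overlapping trials of ``duration`` seconds.

    The trailing remainder shorter than one trial is dropped.
    """
    spt = int(round(duration * recording.sampling_rate))
    if spt < 2:
        raise ValueError("trial duration must span at least 2 samples")
    n_trials = recording.n_samples // spt
    if n_trials < 1:
        raise ValueError(
            f"recording of {recording.n_samples} samples shorter than one "
            f"{spt}-sample trial"
        )
    data = recording.data[:, : n_trials * spt].reshape(
        recording.n_regions, n_trials, spt
    )
    return TrialSet(
        data=np.ascontiguousarray(data.transpose(1, 0, 2)),
        labels=np.array([recording.subject_id] * n_trials, dtype=object),
        duration=duration,
        sampling_rate=recording.sampling_rate,
    )


def concatenate_trials(trialsets: list) -> TrialSet:
    """Stack TrialSets with identical trial shape into one."""
    first = trialsets[0]
    return TrialSet(
        data=np.concatenate([t.data for t in trialsets], axis=0),
        labels=np.concatenate([t.labels for t in trialsets]),
        duration=first.duration,
        sampling_rate=first.sampling_rate,
    )


def sample_trials(trials: TrialSet, n_per_subject: int, seed: int) -> TrialSet:
    """Draw a balanced random-but-fixed subset: n trials per subject.

    Drawn without replacement, deterministically from ``seed``; subjects
    processed in sorted order.
    """
    rng = rng_for(seed, "trials")
    labels = trials.labels
    keep = []
    for subject in trials.subject_ids:
        idx = np.flatnonzero(labels == subject)
        if len(idx) < n_per_subject:
            raise ValueError(
                f"subject {subject!r} has only {len(idx)} trials, "
                f"need {n_per_subject}"
            )
        keep.append(rng.choice(idx, size=n_per_subject, replace=False))
    keep = np.concatenate(keep)
    return TrialSet(
        data=trials.data[keep],
        labels=labels[keep],
        duration=trials.duration,
        sampling_rate=trials.sampling_rate,
    )


def split_halves(recording: Recording):
    """First floor(n/2) samples and the rest, as two recordings."""
    n = recording.n_samples
    if n < 4:
        raise ValueError("recording too short to split into halves")
    half = n // 2
    make = lambda d: Recording(
        subject_id=recording.subject_id,
        session=recording.session,
        data=d,
        sampling_rate=recording.sampling_rate,
    )
    return make(recording.data[:, :half]), make(recording.data[:, half:])


def trials_from_cohort(
    cohort,
    session: str,
    duration: float,
    n_per_subject: int,
    seed: int,
    half: int | None = None,
    subjects: list | None = None,
) -> TrialSet:
    """Balanced labelled trials for one session across a cohort.

    Each recording is z-scored on its own continuous course, segmented, and
    then ``n_per_subject`` trials are sampled per subject.  ``half`` selects
    the first (0) or second (1) half of each recording (cross-over diagonal
    rule).
    """
    if subjects is None:
        subjects = sorted(cohort.recordings)
    sets = []
    for subject in subjects:
        rec = cohort.recordings[subject][session]
        if half is not None:
            rec = split_halves(rec)[half]
        sets.append(segment(znormalize(rec), duration))
    return sample_trials(concatenate_trials(sets), n_per_subject, seed)


# ---------------------------------------------------------------------------
# classifier


@dataclass
class ClassifierModel:
    """Standardized one-vs-all ridge scores over a fixed class list."""

    class_list: list
    coef: np.ndarray
    intercept: np.ndarray
    alpha: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray


def fit_classifier(features: FeatureMatrix, labels, seed: int = 0) -> ClassifierModel:
    """Fit a ridge classifier with cross-validated regularization.

    Features are standardized with training statistics only; the
    regularization strength is selected over 10 log-spaced values in
    [1e-3, 1e3] by efficient generalized leave-one-out cross-validation,
    which is deterministic (``seed`` is accepted for interface uniformity).
    """
    labels = np.asarray(labels, dtype=object)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to fit a classifier")
    x = features.values
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    clf = RidgeClassifierCV(alphas=ALPHA_GRID)
    clf.fit((x - mean) / scale, labels.astype(str))
    coef = np.atleast_2d(clf.coef_)
    intercept = np.atleast_1d(clf.intercept_)
    if len(clf.classes_) == 2 and coef.shape[0] == 1:
        # binary: one decision row; expand to one score row per class
        coef = np.vstack([-coef[0], coef[0]])
        intercept = np.array([-intercept[0], intercept[0]])
    return ClassifierModel(
        class_list=[str(c) for c in clf.classes_],
        coef=coef,
        intercept=intercept,
        alpha=float(clf.alpha_),
        feature_mean=mean,
        feature_scale=scale,
    )


def predict(model: ClassifierModel, features: FeatureMatrix) -> list:
    """Highest-scoring class per trial; ties go to the earlier class."""
    x = features.values
    if x.shape[1] != model.coef.shape[1]:
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match model "
            f"({model.coef.shape[1]})"
        )
    if x.shape[0] == 0:
        return []
    scores = (x - model.feature_mean) / model.feature_scale @ model.coef.T
    scores = scores + model.intercept
    # np.argmax returns the first maximum: earlier class wins ties
    return [model.class_list[i] for i in np.argmax(scores, axis=1)]


def compute_metrics(y_true, y_pred, class_list) -> MetricsReport:
    """Accuracy plus per-class and macro precision/recall/F1.

    Precision = TP/(TP+FP), Recall = TP/(TP+FN), F1 = 2PR/(P+R); any 0/0 is
    defined as 0, so a never-predicted class drags the macro average down.
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    per_class = {}
    for c in class_list:
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[c] = {
            "tp": tp, "fp": fp, "fn": fn,
            "precision": prec, "recall": rec, "f1": f1,
        }
    macro = lambda key: float(np.mean([per_class[c][key] for c in class_list]))
    return MetricsReport(
        accuracy=float(np.mean(y_true == y_pred)) if len(y_true) else 0.0,
        macro_precision=macro("precision"),
        macro_recall=macro("recall"),
        macro_f1=macro("f1"),
        per_class=per_class,
        n_test=len(y_true),
    )


# ---------------------------------------------------------------------------
# experiments


@dataclass
class TransformConfig:
    """Which transform to apply and how large to make it."""

    transform: str = "minirocket"  # or "rocket"
    num_kernels_or_features: int = 3500
    max_dilations_per_kernel: int = mr.MAX_DILATIONS

    def __post_init__(self) -> None:
        if self.transform not in ("rocket", "minirocket"):
            raise ValueError("transform must be 'rocket' or 'minirocket'")


def _transform_pair(train: TrialSet, test: TrialSet, config: TransformConfig, seed: int):
    """Fit the transform on training trials only; apply to both sets."""
    kseed = derive_seed(seed, "kernels")
    if config.transform == "rocket":
        bank = rk.sample_kernel_bank(
            config.num_kernels_or_features,
            train.samples_per_trial,
            train.n_regions,
            kseed,
        )
        return rk.rocket_transform(train, bank), rk.rocket_transform(test, bank)
    fitted = mr.fit(
        train,
        mr.MiniRocketConfig(
            num_features=config.num_kernels_or_features,
            max_dilations_per_kernel=config.max_dilations_per_kernel,
            seed=kseed,
        ),
    )
    return mr.minirocket_features(train, fitted), mr.minirocket_features(test, fitted)


def run_fingerprint(
    train: TrialSet, test: TrialSet, transform_config: TransformConfig, seed: int = 0
) -> MetricsReport:
    """Train on one session's trials, identify subjects in another's.

    The transform (including MiniRocket bias fitting) and the feature
    standardization see training data only.
    """
    if train.n_regions != test.n_regions or train.samples_per_trial != test.samples_per_trial:
        raise ValueError("train and test trials must share shape")
    if not set(train.subject_ids) & set(test.subject_ids):
        raise ValueError("train and test label sets do not overlap")
    f_train, f_test = _transform_pair(train, test, transform_config, seed)
    model = fit_classifier(f_train, train.labels, derive_seed(seed, "classifier"))
    preds = predict(model, f_test)
    return compute_metrics(test.labels, preds, model.class_list)


@dataclass
class LoomResult:
    """Per-left-out-subject reports plus mean/sd summaries."""

    reports: dict
    summary: dict


def loom_evaluate(
    cohort,
    transform_config: TransformConfig,
    duration: float = 1.5,
    n_trials_per_subject: int = 15,
    seed: int = 0,
    train_session: str = "rs1",
    test_session: str = "rs2",
) -> LoomResult:
    """Subject-level leave-one-out: each subject excluded from train and test once."""
    subjects = sorted(cohort.recordings)
    if len(subjects) < 3:
        raise ValueError("LOOM needs at least 3 subjects")
    reports = {}
    for i, left_out in enumerate(subjects):
        keep = [s for s in subjects if s != left_out]
        run_seed = derive_seed(seed, "loom", i)
        train = trials_from_cohort(
            cohort, train_session, duration, n_trials_per_subject,
            derive_seed(run_seed, "trials", 0), subjects=keep,
        )
        test = trials_from_cohort(
            cohort, test_session, duration, n_trials_per_subject,
            derive_seed(run_seed, "trials", 1), subjects=keep,
        )
        reports[left_out] = run_fingerprint(train, test, transform_config, run_seed)
    summary = {}
    for key in ("accuracy", "macro_precision", "macro_recall", "macro_f1"):
        vals = np.array([getattr(r, key) for r in reports.values()])
        summary[key] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))}
    return LoomResult(reports=reports, summary=summary)


@dataclass
class SweepResult:
    """Mean/min/max accuracy over repeats, per grid value of one swept axis."""

    axis: str
    grid: list
    mean: np.ndarray
    min: np.ndarray
    max: np.ndarray
    n_repeats: int
    accuracies: np.ndarray = field(default=None)  # (grid, repeats)


SWEEP_AXES = ("num_kernels", "num_trials", "duration")


def parameter_sweep(
    cohort,
    axis: str,
    grid: list,
    fixed_settings: dict,
    n_repeats: int = 10,
    seed: int = 0,
    transform: str = "minirocket",
) -> SweepResult:
    """Sweep one axis (kernel count, trial count or trial duration).

    ``fixed_settings`` supplies the two non-swept parameters (keys from
    ``SWEEP_AXES``).  Each repeat uses a fresh trial selection and kernel
    seed; accuracy is from training on rs1 and testing on rs2.
    """
    if axis not in SWEEP_AXES:
        raise ValueError(f"axis must be one of {SWEEP_AXES}")
    if not grid:
        raise ValueError("grid must be non-empty")
    accs = np.empty((len(grid), n_repeats), dtype=float)
    for gi, value in enumerate(grid):
        settings = dict(fixed_settings)
        settings[axis] = value
        tc = TransformConfig(
            transform=transform,
            num_kernels_or_features=int(settings["num_kernels"]),
        )
        for rep in range(n_repeats):
            run_seed = derive_seed(seed, "sweep", gi * n_repeats + rep)
            train = trials_from_cohort(
                cohort, "rs1", float(settings["duration"]),
                int(settings["num_trials"]), derive_seed(run_seed, "trials", 0),
            )
            test = trials_from_cohort(
                cohort, "rs2", float(settings["duration"]),
                int(settings["num_trials"]), derive_seed(run_seed, "trials", 1),
            )
            accs[gi, rep] = run_fingerprint(train, test, tc, run_seed).accuracy
    return SweepResult(
        axis=axis,
        grid=list(grid),
        mean=accs.mean(axis=1),
        min=accs.min(axis=1),
        max=accs.max(axis=1),
        n_repeats=n_repeats,
        accuracies=accs,
    )


@dataclass
class CrossoverMatrix:
    """Mean accuracy for every train-session x test-session combination."""

    conditions: tuple
    mean: np.ndarray  # (3, 3)
    accuracies: np.ndarray  # (3, 3, n_repeats)
    n_repeats: int

    def cell(self, train_session: str, test_session: str) -> float:
        i = self.conditions.index(train_session)
        j = self.conditions.index(test_session)
        return float(self.mean[i, j])


def crossover_experiment(
    cohort,
    transform_config: TransformConfig,
    duration: float = 1.5,
    n_trials_per_subject: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
) -> CrossoverMatrix:
    """Train/test on every (rs1, rs2, empty) combination.

    Off-diagonal cells train on one session and test on another; diagonal
    cells split the continuous recording into halves and sample training
    trials from the first half, test trials from the second.
    """
    for subject, sessions in cohort.recordings.items():
        missing = [s for s in SESSIONS if s not in sessions]
        if missing:
            raise ValueError(f"subject {subject!r} missing session(s) {missing}")
    accs = np.empty((3, 3, n_repeats), dtype=float)
    for (i, tr_sess), (j, te_sess) in product(enumerate(SESSIONS), repeat=2):
        for rep in range(n_repeats):
            run_seed = derive_seed(seed, "crossover", (i * 3 + j) * n_repeats + rep)
            halves = (0, 1) if tr_sess == te_sess else (None, None)
            train = trials_from_cohort(
                cohort, tr_sess, duration, n_trials_per_subject,
                derive_seed(run_seed, "trials", 0), half=halves[0],
            )
            test = trials_from_cohort(
                cohort, te_sess, duration, n_trials_per_subject,
                derive_seed(run_seed, "trials", 1), half=halves[1],
            )
            accs[i, j, rep] = run_fingerprint(train, test, transform_config, run_seed).accuracy
    return CrossoverMatrix(
        conditions=SESSIONS, mean=accs.mean(axis=2), accuracies=accs, n_repeats=n_repeats
    )
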