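"""Configuration, serialization and reporting glue.

Run configurations load from JSON or YAML with validated defaults; cohorts
persist to an HDF5 container (one group per subject, one dataset per
session, sampling rate as an attribute) with a JSON manifest of generator
parameters; results are written as tidy tab-delimited tables plus a JSON
summary, each traceable to the seed and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import Recording
from .pipeline import CrossoverMatrix, LoomResult, MetricsReport, SweepResult
from .simulate import Cohort, CohortConfig


class ConfigError(ValueError):
    """Raised with the full list of offending fields."""

    def __init__(self, problems: list):
        self.problems = problems
        super().__init__("invalid configuration: " + "; ".join(problems))


@dataclass
class RunConfig:
    """Experiment settings; defaults are 3500 features, 15 trials of 1.5 s, 10 repeats."""

    transform: str = "minirocket"
    num_kernels_or_features: int = 3500
    n_trials_per_subject: int = 15
    trial_duration: float = 1.5
    n_repeats: int = 10
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        problems = []
        if self.transform not in ("rocket", "minirocket"):
            problems.append(f"transform: must be 'rocket' or 'minirocket', got {self.transform!r}")
        for name in ("num_kernels_or_features", "n_trials_per_subject", "n_repeats"):
            if not isinstance(getattr(self, name), int) or getattr(self, name) <= 0:
                problems.append(f"{name}: must be a positive integer")
        if not self.trial_duration > 0:
            problems.append("trial_duration: must be positive")
        if not isinstance(self.seed, int):
            problems.append("seed: must be an integer")
        if problems:
            raise ConfigError(problems)
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Read a JSON or YAML run configuration, filling defaults."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(text) or {}
    else:
        raw = json.loads(text) if text.strip() else {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError([f"{k}: unknown field" for k in unknown])
    if "trial_duration" in raw:
        raw["trial_duration"] = float(raw["trial_duration"])
    return RunConfig(**raw).validate()


def save_config(config: RunConfig, path) -> None:
    path = Path(path)
    payload = config.to_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=True), encoding="utf-8")
    else:
        path.write_text(json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")


def config_hash(config) -> str:
    """Short stable hash of a configuration (RunConfig, CohortConfig or dict)."""
    if hasattr(config, "to_dict"):
        payload = config.to_dict()
    elif hasattr(config, "as_dict"):
        payload = config.as_dict()
    else:
        payload = dict(config)
    canon = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# cohort container


def save_cohort(cohort: Cohort, path) -> None:
    """HDF5: one group per subject, one dataset per session."""
    with h5py.File(path, "w") as fh:
        fh.attrs["config"] = json.dumps(cohort.config.as_dict(), sort_keys=True)
        for subject, sessions in cohort.recordings.items():
            grp = fh.create_group(subject)
            for session, rec in sessions.items():
                ds = grp.create_dataset(session, data=rec.data)
                ds.attrs["sampling_rate"] = rec.sampling_rate


def load_cohort(path) -> Cohort:
    with h5py.File(path, "r") as fh:
        config = CohortConfig(**json.loads(fh.attrs["config"]))
        recordings = {}
        for subject in fh:
            recordings[subject] = {}
            for session in fh[subject]:
                ds = fh[subject][session]
                recordings[subject][session] = Recording(
                    subject_id=subject,
                    session=session,
                    data=ds[()],
                    sampling_rate=float(ds.attrs["sampling_rate"]),
                )
    return Cohort(recordings=recordings, config=config)


def load_recording_text(path, subject_id: str, session: str, sampling_rate: float) -> Recording:
    """Import one recording from a delimited text matrix (regions x samples)."""
    data = np.loadtxt(path, delimiter="\t")
    return Recording(
        subject_id=subject_id, session=session,
        data=np.atleast_2d(data), sampling_rate=sampling_rate,
    )


# ---------------------------------------------------------------------------
# reports


def _result_rows(results) -> pd.DataFrame:
    if isinstance(results, MetricsReport):
        return pd.DataFrame([results.as_dict()])
    if isinstance(results, LoomResult):
        rows = [
            {"left_out": s, **r.as_dict()} for s, r in sorted(results.reports.items())
        ]
        return pd.DataFrame(rows)
    if isinstance(results, SweepResult):
        return pd.DataFrame(
            {
                "axis": results.axis,
                "value": results.grid,
                "mean_accuracy": results.mean,
                "min_accuracy": results.min,
                "max_accuracy": results.max,
                "n_repeats": results.n_repeats,
            }
        )
    if isinstance(results, CrossoverMatrix):
        rows = []
        for i, tr in enumerate(results.conditions):
            for j, te in enumerate(results.conditions):
                rows.append(
                    {
                        "train_session": tr,
                        "test_session": te,
                        "mean_accuracy": results.mean[i, j],
                        "min_accuracy": results.accuracies[i, j].min(),
                        "max_accuracy": results.accuracies[i, j].max(),
                        "n_repeats": results.n_repeats,
                    }
                )
        return pd.DataFrame(rows)
    raise TypeError(f"cannot write report for {type(results).__name__}")


def _summary(results) -> dict:
    if isinstance(results, MetricsReport):
        return results.as_dict()
    if isinstance(results, LoomResult):
        return results.summary
    if isinstance(results, SweepResult):
        return {
            "axis": results.axis,
            "grid": list(results.grid),
            "mean": results.mean.tolist(),
            "min": results.min.tolist(),
            "max": results.max.tolist(),
            "n_repeats": results.n_repeats,
        }
    if isinstance(results, CrossoverMatrix):
        return {
            "conditions": list(results.conditions),
            "mean": results.mean.tolist(),
            "n_repeats": results.n_repeats,
        }
    raise TypeError(f"cannot summarize {type(results).__name__}")


def write_report(results, out_dir, name: str, seed: int, config=None) -> dict:
    """Write ``<name>.tsv`` and ``<name>_summary.json`` under ``out_dir``.

    Both files embed the seed and the configuration hash, so every artifact
    is traceable; re-running with the same seed reproduces them
    byte-identically (no timestamps).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config) if config is not None else ""
    table = _result_rows(results)
    table.insert(0, "seed", seed)
    table.insert(1, "config_hash", chash)
    tsv_path = out_dir / f"{name}.tsv"
    table.to_csv(tsv_path, sep="\t", index=False)
    summary = {"seed": seed, "config_hash": chash, "results": _summary(results)}
    json_path = out_dir / f"{name}_summary.json"
    json_path.write_text(json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8")
    return {"table": tsv_path, "summary": json_path}
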