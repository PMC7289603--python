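"""Shared tabular IO, run configuration, and the optional real-data loader.

All on-disk formats are flat text tables (CSV with header) or YAML/JSON,
so every artifact the pipeline reads or writes is human-inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .pupil import PupilRecording
from .task import TaskConfig, TrialSequence

__all__ = [
    "RunConfig",
    "read_session",
    "write_session",
    "read_task_config",
    "write_task_config",
    "load_osf_export",
]

#: Config blocks every run must provide (defaults exist for all keys,
#: but a block present with unknown keys, or a missing block in a
#: strict load, is a validation error naming the block).
REQUIRED_BLOCKS = ("paths", "task", "learner", "pupil", "regression")

_DEFAULTS: dict[str, dict] = {
    "paths": {"out_dir": "results"},
    "task": {
        "hazard_values": [0.01, 0.30, 0.99],
        "p": 0.8,
        "n_trials": 1000,
        "session_index": 1,
    },
    "learner": {"n_grid": 100, "reference_k": 0.0, "n_starts": 8},
    "pupil": {
        "filter_cutoff_hz": 4.0,
        "baseline_window_ms": 100.0,
        "evoked_window_s": 2.0,
        "exclude_interp_fraction": 0.5,
        "zscore": True,
    },
    "regression": {
        "fwe_method": "max_stat_sign_flip",
        "n_permutations": 1000,
        "group_test": "ttest",
    },
}


@dataclass
class RunConfig:
    """Full pipeline configuration with one block per stage."""

    seed: int = 0
    n_subjects: int = 10
    paths: dict = field(default_factory=lambda: dict(_DEFAULTS["paths"]))
    task: dict = field(default_factory=lambda: dict(_DEFAULTS["task"]))
    learner: dict = field(default_factory=lambda: dict(_DEFAULTS["learner"]))
    pupil: dict = field(default_factory=lambda: dict(_DEFAULTS["pupil"]))
    regression: dict = field(default_factory=lambda: dict(_DEFAULTS["regression"]))

    @classmethod
    def from_yaml(cls, path, strict: bool = True) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if strict:
            for block in REQUIRED_BLOCKS:
                if block not in raw:
                    raise ValueError(f"config is missing required block {block!r}")
        kwargs: dict = {
            "seed": int(raw.get("seed", 0)),
            "n_subjects": int(raw.get("n_subjects", 10)),
        }
        for block in REQUIRED_BLOCKS:
            merged = dict(_DEFAULTS[block])
            user = raw.get(block, {}) or {}
            unknown = set(user) - set(merged)
            if unknown:
                raise ValueError(
                    f"unknown keys {sorted(unknown)} in config block {block!r}"
                )
            merged.update(user)
            kwargs[block] = merged
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        data = {
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            **{b: getattr(self, b) for b in REQUIRED_BLOCKS},
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_session(sequence: TrialSequence, path) -> None:
    sequence.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_session(path, p: float = 0.8) -> TrialSequence:
    return TrialSequence.from_frame(pd.read_csv(path, float_precision="round_trip"), p=p)


def write_task_config(config: TaskConfig, path) -> None:
    data = {
        "hazard_values": list(config.hazard_values),
        "p": config.p,
        "n_trials": config.n_trials,
        "block_schedule": (
            [[h, n] for h, n in config.block_schedule]
            if config.block_schedule is not None
            else None
        ),
        "block_length_range": list(config.block_length_range),
        "seed": config.seed,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_task_config(path) -> TaskConfig:
    data = yaml.safe_load(Path(path).read_text())
    if data.get("block_schedule") is not None:
        data["block_schedule"] = [(float(h), int(n)) for h, n in data["block_schedule"]]
    data["hazard_values"] = tuple(data.get("hazard_values", (0.01, 0.30, 0.99)))
    data["block_length_range"] = tuple(data.get("block_length_range", (100, 400)))
    return TaskConfig(**data)


def load_osf_export(directory) -> dict:
    """Load a user-downloaded session/pupil export into cohort tables.

    Expected layout: per subject, ``<id>_session.csv`` with per-trial
    columns (trial, tone, prediction, rt, hazard) and, optionally,
    ``<id>_pupil.csv`` with per-sample columns (time_ms, diameter,
    gaze_x, gaze_y) plus ``<id>_events.csv`` (trial, onset_ms).
    Returns {subject_id: {"trials": DataFrame, "pupil": PupilRecording
    | None, "onsets_ms": array | None}}.  Missing pupil files yield a
    behavioral-only subject; a malformed column raises with a
    per-column diagnostic.
    """
    directory = Path(directory)
    session_files = sorted(directory.glob("*_session.csv"))
    if not session_files:
        raise FileNotFoundError(f"no *_session.csv files found in {directory}")
    required = {"trial", "tone", "prediction", "rt", "hazard"}
    cohort: dict = {}
    for f in session_files:
        sid = f.name[: -len("_session.csv")]
        trials = pd.read_csv(f)
        missing = required - set(trials.columns)
        if missing:
            raise ValueError(f"{f.name}: missing columns {sorted(missing)}")
        diagnostics = []
        for col, kind in [
            ("tone", "binary"),
            ("prediction", "binary"),
            ("rt", "positive"),
            ("hazard", "probability"),
        ]:
            vals = pd.to_numeric(trials[col], errors="coerce")
            if vals.isna().any():
                diagnostics.append(f"column {col!r} has non-numeric entries")
            elif kind == "binary" and not set(vals.dropna().unique()) <= {0, 1}:
                diagnostics.append(f"column {col!r} must be 0/1")
            elif kind == "probability" and ((vals < 0) | (vals > 1)).any():
                diagnostics.append(f"column {col!r} must lie in [0, 1]")
        if diagnostics:
            raise ValueError(f"{f.name}: " + "; ".join(diagnostics))
        entry: dict = {"trials": trials, "pupil": None, "onsets_ms": None}
        pupil_file = directory / f"{sid}_pupil.csv"
        events_file = directory / f"{sid}_events.csv"
        if pupil_file.exists() and events_file.exists():
            entry["pupil"] = PupilRecording.from_frame(pd.read_csv(pupil_file))
            entry["onsets_ms"] = pd.read_csv(events_file)["onset_ms"].to_numpy(float)
        cohort[sid] = entry
    return cohort
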