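"""Shared domain types and on-disk formats.

Time is always seconds (float) on disk; indices are 0-based half-open in
memory.  A recording is a set of equally long channels at a single sampling
rate; channel *roles* tie arbitrary channel names to the five standard
signals of the protocol (zygomaticus / corrugator / trapezius EMG, skin
conductance level, ECG).

Formats
-------
signals CSV   ``time_s,<channel>,...`` one row per sample
meta JSON     ``{"subject_id": ..., "fs": ..., "roles": {channel: role}}``
events CSV    ``level,onset_s,plateau_s`` (level ``B`` rows are baseline
              window onsets; their plateau column is ignored)
features TSV  header row, first two columns ``subject_id`` and
              ``class_label``, remaining columns the named features
report JSON   confusion matrix, metrics, selected features, SVM parameters
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: the five signal roles of the standard montage
CHANNEL_ROLES = ("emg_zyg", "emg_cor", "emg_tra", "scl", "ecg")

#: class labels: baseline plus the four calibrated pain levels
CLASS_LABELS = ("B", "T1", "T2", "T3", "T4")

#: pain levels only (stimulus events)
PAIN_LEVELS = ("T1", "T2", "T3", "T4")


class FormatError(ValueError):
    """Malformed on-disk data (ragged columns, bad header, ...)."""


class ConfigError(ValueError):
    """Invalid or inconsistent configuration / metadata."""


class ScheduleError(ValueError):
    """Stimulus schedule violates protocol invariants."""


@dataclass
class Recording:
    """Multichannel biopotential recording of one subject.

    Parameters
    ----------
    subject_id : str
        Opaque identifier.
    fs : float
        Sampling rate in Hz, strictly positive.
    channels : dict[str, np.ndarray]
        Ordered mapping channel name -> samples.  All channels must have the
        same length.
    channel_role : dict[str, str]
        Mapping channel name -> one of :data:`CHANNEL_ROLES`.
    """

    subject_id: str
    fs: float
    channels: dict[str, np.ndarray]
    channel_role: dict[str, str]

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigError(f"sampling rate must be positive, got {self.fs}")
        lengths = {name: len(x) for name, x in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise FormatError(f"channels have unequal lengths: {lengths}")
        for name, role in self.channel_role.items():
            if role not in CHANNEL_ROLES:
                raise ConfigError(f"unknown channel role {role!r} for {name!r}")
            if name not in self.channels:
                raise ConfigError(f"role given for unknown channel {name!r}")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values()))) if self.channels else 0

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def by_role(self, role: str) -> np.ndarray:
        """Samples of the (unique) channel with the given role."""
        for name, r in self.channel_role.items():
            if r == role:
                return self.channels[name]
        raise ConfigError(f"no channel with role {role!r}")

    def validate_standard(self) -> None:
        """Require exactly the five standard roles."""
        roles = sorted(self.channel_role.values())
        if roles != sorted(CHANNEL_ROLES):
            raise ConfigError(
                f"standard configuration needs roles {CHANNEL_ROLES}, got {roles}"
            )


@dataclass(frozen=True)
class StimulusEvent:
    """A single heat stimulus: pain level, onset and plateau duration."""

    level: str
    onset_s: float
    plateau_s: float = 4.0

    def __post_init__(self) -> None:
        if self.level not in PAIN_LEVELS:
            raise ScheduleError(f"stimulus level must be one of {PAIN_LEVELS}, got {self.level!r}")
        if self.onset_s < 0:
            raise ScheduleError(f"onset must be >= 0, got {self.onset_s}")
        if self.plateau_s <= 0:
            raise ScheduleError("plateau duration must be positive")


@dataclass
class StimulusSchedule:
    """Ordered stimulus events plus baseline ("non-pain") window onsets.

    The standard protocol applies each of four calibrated temperature levels
    20 times in randomized order (80 stimuli, 4 s plateaus, pauses uniform on
    8-12 s, 32 degC between stimuli) and provides 20 stimulus-free baseline
    windows for the no-pain class.
    """

    events: list[StimulusEvent] = field(default_factory=list)
    baseline_windows: list[float] = field(default_factory=list)
    baseline_temp_C: float = 32.0
    pause_range_s: tuple[float, float] = (8.0, 12.0)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.onset_s)
        prev_end = -np.inf
        for ev in self.events:
            if ev.onset_s < prev_end:
                raise ScheduleError(
                    f"events overlap: stimulus at {ev.onset_s} s starts before "
                    f"the previous plateau ends at {prev_end} s"
                )
            prev_end = ev.onset_s + ev.plateau_s

    def level_counts(self) -> dict[str, int]:
        counts = {lv: 0 for lv in PAIN_LEVELS}
        for ev in self.events:
            counts[ev.level] += 1
        return counts

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass
class LabeledWindow:
    """A labelled per-channel signal segment (the classification unit).

    ``class_label`` is ``B`` for non-pain windows or ``T1``..``T4``; the
    segments of all channels cover the same ``window_s`` seconds.
    """

    subject_id: str
    class_label: str
    segments: dict[str, np.ndarray]  # role -> samples
    fs: float
    onset_s: float
    window_s: float = 5.5

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ConfigError(f"class label must be in {CLASS_LABELS}, got {self.class_label!r}")
        lengths = {len(v) for v in self.segments.values()}
        if len(lengths) > 1:
            raise FormatError("window segments have unequal lengths")


@dataclass
class EvalReport:
    """Classification evaluation: confusion matrix and derived metrics.

    ``confusion`` is a square DataFrame with true classes on the rows and
    predicted classes on the columns.  ``accuracy`` is the trace over the
    total; sensitivity and specificity are per class, one-vs-others.
    """

    confusion: pd.DataFrame
    accuracy: float
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    cramers_v: float
    association_band: str
    selected_features: list[str] = field(default_factory=list)
    svm_params: tuple[float, float] | None = None  # (C, gamma)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.confusion.index),
            "confusion": self.confusion.values.tolist(),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "cramers_v": self.cramers_v,
            "association_band": self.association_band,
            "selected_features": self.selected_features,
            "svm_params": list(self.svm_params) if self.svm_params else None,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path_signals: str | Path, path_meta: str | Path) -> None:
    """Write a recording as signals CSV plus metadata JSON."""
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time_s": t})
    for name, x in rec.channels.items():
        df[name] = x
    df.to_csv(path_signals, index=False, float_format="%.17g")
    meta = {"subject_id": rec.subject_id, "fs": rec.fs, "roles": rec.channel_role}
    Path(path_meta).write_text(json.dumps(meta, indent=2))


def read_recording(path_signals: str | Path, path_meta: str | Path) -> Recording:
    """Read a recording from signals CSV + metadata JSON and validate it."""
    meta = json.loads(Path(path_meta).read_text())
    try:
        df = pd.read_csv(path_signals, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise FormatError(f"malformed signals CSV {path_signals}: {exc}") from exc
    if "time_s" not in df.columns:
        raise FormatError("signals CSV must have a 'time_s' column")
    channels = {c: df[c].to_numpy(dtype=float) for c in df.columns if c != "time_s"}
    rec = Recording(
        subject_id=str(meta["subject_id"]),
        fs=float(meta["fs"]),
        channels=channels,
        channel_role={str(k): str(v) for k, v in meta["roles"].items()},
    )
    rec.validate_standard()
    return rec


def write_schedule(schedule: StimulusSchedule, path: str | Path) -> None:
    rows = [{"level": ev.level, "onset_s": ev.onset_s, "plateau_s": ev.plateau_s}
            for ev in schedule.events]
    rows += [{"level": "B", "onset_s": b, "plateau_s": np.nan}
             for b in schedule.baseline_windows]
    pd.DataFrame(rows, columns=["level", "onset_s", "plateau_s"]).to_csv(
        path, index=False, float_format="%.17g")


def read_schedule(path: str | Path) -> StimulusSchedule:
    """Read an events CSV into a validated schedule.

    ``B`` rows denote baseline-window onsets.  An empty file (header only or
    zero bytes) yields an empty schedule.
    """
    p = Path(path)
    if p.stat().st_size == 0:
        return StimulusSchedule()
    df = pd.read_csv(p)
    if df.empty:
        return StimulusSchedule()
    events, baselines = [], []
    for _, row in df.iterrows():
        level = str(row["level"])
        if level == "B":
            baselines.append(float(row["onset_s"]))
        else:
            plateau = row.get("plateau_s", 4.0)
            plateau = 4.0 if pd.isna(plateau) else float(plateau)
            events.append(StimulusEvent(level=level, onset_s=float(row["onset_s"]),
                                        plateau_s=plateau))
    return StimulusSchedule(events=events, baseline_windows=sorted(baselines))


def write_feature_matrix(m: pd.DataFrame, path: str | Path) -> None:
    """Write a feature matrix as TSV (full float precision).

    First two columns must be ``subject_id`` and ``class_label``.
    """
    _validate_feature_matrix(m)
    m.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed features TSV {path}: {exc}") from exc
    _validate_feature_matrix(df)
    return df


def _validate_feature_matrix(m: pd.DataFrame) -> None:
    if list(m.columns[:2]) != ["subject_id", "class_label"]:
        raise FormatError(
            "feature matrix must start with columns 'subject_id', 'class_label'")
    bad = set(m["class_label"].astype(str)) - set(CLASS_LABELS)
    if bad:
        raise FormatError(f"unknown class labels {sorted(bad)}; expected {CLASS_LABELS}")


def feature_columns(m: pd.DataFrame) -> list[str]:
    """Names of the feature columns (everything after the two id columns)."""
    return [c for c in m.columns if c not in ("subject_id", "class_label")]
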