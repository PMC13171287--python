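"""Domain types and tabular I/O for laminar spike-train sessions.

A session directory holds plain-text tables::

    units.tsv       unit_id, channel_index, kind
    spikes.tsv      unit_id, time_ms
    trials.tsv      trial_id, fixation_onset_ms, cue_onset_ms, first_dimming_ms, condition
    session.json    session_id, monkey_profile, probe geometry, area label per channel
    continuous.tsv  optional channels x samples matrix (sampling rate in session.json)

All times are floating milliseconds relative to session start.  Intervals are
half-open ``[start, end)``; a spike at exactly ``end`` is excluded.  Channel
indices are 0-based and increase with depth (contact 0 most superficial).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrain",
    "TrialEpochs",
    "AnalysisWindow",
    "SpikeSession",
    "WINDOWS",
    "read_session",
    "write_session",
    "resolve_window",
    "SessionValidationError",
    "SessionLoadError",
]

CONDITIONS = ("attend_RF", "attend_away")
UNIT_KINDS = ("single_unit", "multi_unit")
AREAS = ("V1", "V4")
MONKEY_PROFILES = ("M1", "M2")


class SessionValidationError(ValueError):
    """An invariant of the session data model is violated."""


class SessionLoadError(IOError):
    """A session directory is missing a required table or is malformed."""


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times of one unit (single- or multi-unit) on one probe contact."""

    unit_id: str
    channel_index: int
    kind: str
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        if self.kind not in UNIT_KINDS:
            raise SessionValidationError(
                f"unit {self.unit_id}: kind must be one of {UNIT_KINDS}, got {self.kind!r}"
            )
        if self.channel_index < 0:
            raise SessionValidationError(
                f"unit {self.unit_id}: channel_index must be >= 0"
            )
        if times.size and np.any(np.diff(times) < 0):
            raise SessionValidationError(
                f"unit {self.unit_id}: spike_times must be nondecreasing"
            )
        if times.size and times[0] < 0:
            raise SessionValidationError(
                f"unit {self.unit_id}: spike time {times[0]} before session start"
            )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeTrain):
            return NotImplemented
        return (
            self.unit_id == other.unit_id
            and self.channel_index == other.channel_index
            and self.kind == other.kind
            and np.array_equal(self.spike_times, other.spike_times)
        )


@dataclass(frozen=True)
class TrialEpochs:
    """Event times and attention condition of one trial.

    The two non-RF cue locations are pooled into ``attend_away``.
    """

    trial_id: str
    fixation_onset_ms: float
    cue_onset_ms: float
    first_dimming_ms: float
    condition: str

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise SessionValidationError(
                f"trial {self.trial_id}: condition must be one of {CONDITIONS}, "
                f"got {self.condition!r}"
            )
        if not (
            self.fixation_onset_ms < self.cue_onset_ms < self.first_dimming_ms
        ):
            raise SessionValidationError(
                f"trial {self.trial_id}: events must be ordered "
                "fixation_onset < cue_onset < first_dimming"
            )

    def event_time(self, event: str) -> float:
        try:
            return float(getattr(self, f"{event}_ms"))
        except AttributeError:
            raise SessionValidationError(
                f"trial {self.trial_id}: unknown anchoring event {event!r}"
            ) from None


@dataclass(frozen=True)
class AnalysisWindow:
    """A named window given as offsets to a per-trial anchoring event.

    ``end_anchor``/``end_ms`` allow windows spanning two events (the
    cue-to-dimming window ends relative to the first dimming, not the cue).
    """

    name: str
    anchor: str
    start_ms: float
    end_ms: float
    end_anchor: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end_anchor is None and self.end_ms <= self.start_ms:
            raise SessionValidationError(
                f"window {self.name}: end offset must exceed start offset"
            )


def _standard_windows(monkey_profile: str) -> dict[str, AnalysisWindow]:
    if monkey_profile not in MONKEY_PROFILES:
        raise SessionValidationError(
            f"monkey_profile must be one of {MONKEY_PROFILES}, got {monkey_profile!r}"
        )
    spont = (200.0, 500.0) if monkey_profile == "M1" else (100.0, 400.0)
    return {
        "spontaneous": AnalysisWindow("spontaneous", "fixation_onset", *spont),
        "cue_to_dimming": AnalysisWindow(
            "cue_to_dimming", "cue_onset", 400.0, 30.0, end_anchor="first_dimming"
        ),
        "pre_dimming": AnalysisWindow("pre_dimming", "first_dimming", -500.0, 0.0),
        "baseline": AnalysisWindow("baseline", "cue_onset", -250.0, 0.0),
        "onset_response": AnalysisWindow("onset_response", "cue_onset", 50.0, 300.0),
    }


def WINDOWS(monkey_profile: str, name: Optional[str] = None):
    """Standard analysis windows for a monkey profile.

    With ``name`` returns a single :class:`AnalysisWindow`, otherwise a dict.
    """
    table = _standard_windows(monkey_profile)
    if name is None:
        return table
    try:
        return table[name]
    except KeyError:
        raise SessionValidationError(f"unknown window name {name!r}") from None


def resolve_window(window: AnalysisWindow, trial: TrialEpochs) -> tuple[float, float]:
    """Resolve a window to an absolute half-open ``[start, end)`` interval in ms."""
    start = trial.event_time(window.anchor) + window.start_ms
    end_anchor = window.end_anchor or window.anchor
    end = trial.event_time(end_anchor) + window.end_ms
    if end <= start:
        raise SessionValidationError(
            f"window {window.name} on trial {trial.trial_id}: "
            f"resolved interval [{start}, {end}) is empty"
        )
    return (start, end)


@dataclass(frozen=True)
class SpikeSession:
    """One penetration: units, trials, probe geometry, optional continuous data."""

    session_id: str
    monkey_profile: str
    spike_trains: tuple[SpikeTrain, ...]
    trials: tuple[TrialEpochs, ...]
    area_labels: tuple[str, ...]
    probe_spacing_um: float = 150.0
    continuous_signals: Optional[np.ndarray] = None  # channels x samples
    continuous_sampling_hz: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "spike_trains", tuple(self.spike_trains))
        object.__setattr__(self, "trials", tuple(self.trials))
        object.__setattr__(self, "area_labels", tuple(self.area_labels))
        if self.monkey_profile not in MONKEY_PROFILES:
            raise SessionValidationError(
                f"session {self.session_id}: monkey_profile must be one of "
                f"{MONKEY_PROFILES}"
            )
        if not self.spike_trains:
            raise SessionValidationError(
                f"session {self.session_id}: session has no units"
            )
        if not self.area_labels:
            raise SessionValidationError(
                f"session {self.session_id}: no channel area labels"
            )
        for label in self.area_labels:
            if label not in AREAS:
                raise SessionValidationError(
                    f"session {self.session_id}: bad area label {label!r}"
                )
        n_channels = self.n_channels
        for train in self.spike_trains:
            if train.channel_index >= n_channels:
                raise SessionValidationError(
                    f"unit {train.unit_id}: channel_index {train.channel_index} "
                    f"outside probe of {n_channels} channels"
                )
        seen: set[str] = set()
        for train in self.spike_trains:
            if train.unit_id in seen:
                raise SessionValidationError(
                    f"duplicate unit_id {train.unit_id!r}"
                )
            seen.add(train.unit_id)
        by_condition = {c: 0 for c in CONDITIONS}
        for trial in self.trials:
            by_condition[trial.condition] += 1
        for condition, count in by_condition.items():
            if count == 0:
                raise SessionValidationError(
                    f"session {self.session_id}: no trials in condition {condition}"
                )
        if self.continuous_signals is not None:
            sig = np.asarray(self.continuous_signals, dtype=float)
            object.__setattr__(self, "continuous_signals", sig)
            if sig.ndim != 2 or sig.shape[0] != n_channels:
                raise SessionValidationError(
                    f"session {self.session_id}: continuous matrix must be "
                    f"(n_channels={n_channels}) x samples"
                )
            if not self.continuous_sampling_hz or self.continuous_sampling_hz <= 0:
                raise SessionValidationError(
                    f"session {self.session_id}: continuous data needs a "
                    "positive sampling rate"
                )

    @property
    def n_channels(self) -> int:
        return len(self.area_labels)

    def unit(self, unit_id: str) -> SpikeTrain:
        for train in self.spike_trains:
            if train.unit_id == unit_id:
                return train
        raise KeyError(unit_id)

    def single_units(self) -> tuple[SpikeTrain, ...]:
        return tuple(t for t in self.spike_trains if t.kind == "single_unit")

    def multi_units(self) -> tuple[SpikeTrain, ...]:
        return tuple(t for t in self.spike_trains if t.kind == "multi_unit")

    def trials_in(self, condition: str) -> tuple[TrialEpochs, ...]:
        if condition not in CONDITIONS:
            raise SessionValidationError(f"unknown condition {condition!r}")
        return tuple(t for t in self.trials if t.condition == condition)

    def channel_depth_um(self, channel_index: int) -> float:
        return channel_index * self.probe_spacing_um

    def windows(self) -> dict[str, AnalysisWindow]:
        return _standard_windows(self.monkey_profile)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeSession):
            return NotImplemented
        cont_equal = (self.continuous_signals is None) == (
            other.continuous_signals is None
        )
        if cont_equal and self.continuous_signals is not None:
            cont_equal = np.allclose(
                self.continuous_signals, other.continuous_signals
            ) and self.continuous_sampling_hz == other.continuous_sampling_hz
        return (
            cont_equal
            and self.session_id == other.session_id
            and self.monkey_profile == other.monkey_profile
            and self.probe_spacing_um == other.probe_spacing_um
            and self.area_labels == other.area_labels
            and self.spike_trains == other.spike_trains
            and self.trials == other.trials
        )


def write_session(session: SpikeSession, path: str | Path) -> None:
    """Write a session directory readable by :func:`read_session`."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    units = pd.DataFrame(
        {
            "unit_id": [t.unit_id for t in session.spike_trains],
            "channel_index": [t.channel_index for t in session.spike_trains],
            "kind": [t.kind for t in session.spike_trains],
        }
    )
    units.to_csv(path / "units.tsv", sep="\t", index=False)

    spike_frames = [
        pd.DataFrame({"unit_id": t.unit_id, "time_ms": t.spike_times})
        for t in session.spike_trains
        if t.n_spikes
    ]
    spikes = (
        pd.concat(spike_frames, ignore_index=True)
        if spike_frames
        else pd.DataFrame(columns=["unit_id", "time_ms"])
    )
    # %.17g keeps doubles exact so read(write(s)) round-trips bit-for-bit
    spikes.to_csv(path / "spikes.tsv", sep="\t", index=False, float_format="%.17g")

    trials = pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in session.trials],
            "fixation_onset_ms": [t.fixation_onset_ms for t in session.trials],
            "cue_onset_ms": [t.cue_onset_ms for t in session.trials],
            "first_dimming_ms": [t.first_dimming_ms for t in session.trials],
            "condition": [t.condition for t in session.trials],
        }
    )
    trials.to_csv(path / "trials.tsv", sep="\t", index=False, float_format="%.17g")

    meta = {
        "session_id": session.session_id,
        "monkey_profile": session.monkey_profile,
        "probe_spacing_um": session.probe_spacing_um,
        "area_labels": list(session.area_labels),
    }
    if session.continuous_signals is not None:
        meta["continuous_sampling_hz"] = session.continuous_sampling_hz
        np.savetxt(path / "continuous.tsv", session.continuous_signals, delimiter="\t")
    with open(path / "session.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_session(path: str | Path) -> SpikeSession:
    """Read and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    for name in ("units.tsv", "spikes.tsv", "trials.tsv", "session.json"):
        if not (path / name).exists():
            raise SessionLoadError(f"missing table {name} in {path}")

    with open(path / "session.json") as fh:
        meta = json.load(fh)
    units = pd.read_csv(path / "units.tsv", sep="\t")
    # round_trip parsing keeps read(write(s)) exactly equal to s
    spikes = pd.read_csv(path / "spikes.tsv", sep="\t", float_precision="round_trip")
    trials = pd.read_csv(path / "trials.tsv", sep="\t", float_precision="round_trip")

    spikes_by_unit = (
        {k: g["time_ms"].to_numpy(dtype=float) for k, g in spikes.groupby("unit_id")}
        if len(spikes)
        else {}
    )
    trains = tuple(
        SpikeTrain(
            unit_id=str(row.unit_id),
            channel_index=int(row.channel_index),
            kind=str(row.kind),
            spike_times=np.sort(spikes_by_unit.get(str(row.unit_id), np.empty(0))),
        )
        for row in units.itertuples()
    )
    trial_records = tuple(
        TrialEpochs(
            trial_id=str(row.trial_id),
            fixation_onset_ms=float(row.fixation_onset_ms),
            cue_onset_ms=float(row.cue_onset_ms),
            first_dimming_ms=float(row.first_dimming_ms),
            condition=str(row.condition),
        )
        for row in trials.itertuples()
    )

    continuous = None
    sampling = meta.get("continuous_sampling_hz")
    if (path / "continuous.tsv").exists():
        continuous = np.atleast_2d(np.loadtxt(path / "continuous.tsv", delimiter="\t"))

    return SpikeSession(
        session_id=str(meta["session_id"]),
        monkey_profile=str(meta["monkey_profile"]),
        spike_trains=trains,
        trials=trial_records,
        area_labels=tuple(meta["area_labels"]),
        probe_spacing_um=float(meta.get("probe_spacing_um", 150.0)),
        continuous_signals=continuous,
        continuous_sampling_hz=float(sampling) if sampling else None,
    )
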