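"""Session container, on-disk format, and firing-rate binning.

A *session* is one recording day: a trial table (instructed target
number 1-5, stimulus protocol, stimulus condition, timing arrangement,
behavioral outcome, produced peck count, event times) plus per-unit
spike times.  All times are in milliseconds with zero at instruction
stimulus onset; windows are half-open ``[a, b)``.

On disk a session is a directory of plain-text tables::

    trials.csv     one row per trial
    spikes.csv     unit_id, trial_id, time_ms (long format)
    metadata.json  session_id, crow_id, free-form metadata

chosen over binary containers for inspectability and diff-ability.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TaskConfig",
    "DEFAULT_TASK",
    "TrialRecord",
    "Session",
    "BinnedRates",
    "SessionFormatError",
    "SessionValidationError",
    "read_session",
    "write_session",
    "read_sessions",
    "bin_rates",
]

PROTOCOLS = ("dot", "sign")
CONDITIONS = ("standard", "control")
ARRANGEMENTS = ("standard", "control1", "control2")
OUTCOMES = ("correct", "error_minus", "error_plus", "aborted")


class SessionFormatError(ValueError):
    """A session table does not conform to the documented dialect."""


class SessionValidationError(ValueError):
    """A session table parses but violates a trial/spike invariant."""


@dataclass(frozen=True)
class TaskConfig:
    """Timing and design constants of the instructed number-production task.

    The trial runs baseline (300 ms) -> instruction stimulus (600 ms) ->
    motor planning delay (1000 ms) -> motor execution.  The planning
    analysis window [800, 1700] ms relative to instruction onset shifts
    the nominal planning period by the visual response latency and spans
    900 ms.
    """

    baseline_duration: float = 300.0
    instruction_duration: float = 600.0
    planning_duration: float = 1000.0
    response_epoch_duration: float = 600.0
    target_numbers: tuple[int, ...] = (1, 2, 3, 4, 5)
    protocols: tuple[str, ...] = PROTOCOLS
    conditions: tuple[str, ...] = CONDITIONS
    timing_arrangements: tuple[str, ...] = ARRANGEMENTS
    planning_analysis_window: tuple[float, float] = (800.0, 1700.0)
    anova_window: tuple[float, float] = (200.0, 10.0)  # width, step (ms)
    pev_window: tuple[float, float] = (200.0, 20.0)

    @property
    def trial_start(self) -> float:
        return -self.baseline_duration

    @property
    def planning_onset(self) -> float:
        return self.instruction_duration

    @property
    def planning_offset(self) -> float:
        return self.instruction_duration + self.planning_duration

    @property
    def execution_onset(self) -> float:
        return self.planning_offset

    @property
    def analysis_span(self) -> tuple[float, float]:
        """Baseline onset through planning offset plus the response-latency
        carry-over covered by the planning analysis window."""
        return (self.trial_start, self.planning_analysis_window[1])

    @classmethod
    def from_yaml(cls, path) -> "TaskConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in cls.__dataclass_fields__:
            if f in raw:
                v = raw[f]
                kwargs[f] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


DEFAULT_TASK = TaskConfig()


@dataclass
class TrialRecord:
    """One trial's design factors, outcome, and event times (ms, 0 = instruction onset)."""

    trial_id: int
    target_number: int
    protocol: str
    condition: str
    timing_arrangement: str
    outcome: str
    produced_count: int
    instruction_onset: float = 0.0
    peck_times: list[float] = field(default_factory=list)
    confirmation_time: float | None = None
    first_response_rt: float | None = None

    @property
    def is_scored(self) -> bool:
        """Counted in behavior/neural analyses (aborted trials are stored but excluded)."""
        return self.outcome != "aborted"

    @property
    def is_correct(self) -> bool:
        return self.outcome == "correct"

    def problems(self) -> list[str]:
        """Invariant violations as human-readable strings (empty if valid)."""
        out = []
        if self.target_number < 1:
            out.append(f"trial {self.trial_id}: target_number {self.target_number} < 1")
        if self.protocol not in PROTOCOLS:
            out.append(f"trial {self.trial_id}: unknown protocol {self.protocol!r}")
        if self.condition not in CONDITIONS:
            out.append(f"trial {self.trial_id}: unknown condition {self.condition!r}")
        if self.timing_arrangement not in ARRANGEMENTS:
            out.append(
                f"trial {self.trial_id}: unknown timing_arrangement {self.timing_arrangement!r}"
            )
        if self.outcome not in OUTCOMES:
            out.append(f"trial {self.trial_id}: unknown outcome {self.outcome!r}")
        if self.produced_count < 0:
            out.append(f"trial {self.trial_id}: negative produced_count")
        n, k = self.target_number, self.produced_count
        if self.outcome == "correct" and k != n:
            out.append(f"trial {self.trial_id}: outcome correct but produced {k} != target {n}")
        if self.outcome == "error_plus" and k != n + 1:
            out.append(
                f"trial {self.trial_id}: outcome error_plus but produced {k} != target+1"
                f" (trials abort at {n + 1} pecks)"
            )
        if self.outcome == "error_minus" and not k < n:
            out.append(f"trial {self.trial_id}: outcome error_minus but produced {k} >= target {n}")
        if self.outcome != "aborted" and k > n + 1:
            out.append(
                f"trial {self.trial_id}: produced_count {k} exceeds abort cap {n + 1}"
            )
        if any(b <= a for a, b in zip(self.peck_times, self.peck_times[1:])):
            out.append(f"trial {self.trial_id}: peck_times not strictly increasing")
        return out


@dataclass
class Session:
    """Trial table plus per-unit, per-trial spike trains.

    ``units`` maps unit_id -> {trial_id -> sorted float array of spike
    times (ms, aligned to that trial's instruction onset)}.
    """

    session_id: str
    crow_id: str
    trials: list[TrialRecord]
    units: dict[str, dict[int, np.ndarray]]
    metadata: dict = field(default_factory=dict)

    @property
    def trial_ids(self) -> list[int]:
        return [t.trial_id for t in self.trials]

    @property
    def unit_ids(self) -> list[str]:
        return list(self.units)

    def trial(self, trial_id: int) -> TrialRecord:
        return self._index()[trial_id]

    def _index(self) -> dict[int, TrialRecord]:
        return {t.trial_id: t for t in self.trials}

    def scored_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.is_scored]

    def correct_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.is_correct]

    def spikes(self, unit_id: str, trial_id: int) -> np.ndarray:
        return self.units.get(unit_id, {}).get(trial_id, np.empty(0))

    def validate(self) -> None:
        """Raise :class:`SessionValidationError` on any invariant violation."""
        problems = []
        seen = set()
        for t in self.trials:
            if t.trial_id in seen:
                problems.append(f"duplicate trial_id {t.trial_id}")
            seen.add(t.trial_id)
            problems.extend(t.problems())
        for uid, by_trial in self.units.items():
            for tid, times in by_trial.items():
                if tid not in seen:
                    problems.append(f"unit {uid}: spikes reference unknown trial {tid}")
                times = np.asarray(times)
                if times.size > 1 and np.any(np.diff(times) < 0):
                    problems.append(f"unit {uid} trial {tid}: spike times not sorted")
        if problems:
            raise SessionValidationError(
                "invalid session: " + "; ".join(problems[:20])
                + ("" if len(problems) <= 20 else f"; ... ({len(problems)} problems)")
            )


# ----------------------------------------------------------------------
# On-disk format

_TRIAL_COLUMNS = [
    "trial_id",
    "target_number",
    "protocol",
    "condition",
    "timing_arrangement",
    "outcome",
    "produced_count",
    "instruction_onset",
    "peck_times",
    "confirmation_time",
    "first_response_rt",
]
_SPIKE_COLUMNS = ["unit_id", "trial_id", "time_ms"]


def _fmt(x: float | None) -> str:
    return "" if x is None else repr(float(x))


def _parse_float(s: str) -> float | None:
    return None if s == "" else float(s)


def write_session(session: Session, path) -> None:
    """Write a session as ``trials.csv``, ``spikes.csv``, ``metadata.json``.

    Deterministic column order and float formatting: writing the result
    of :func:`read_session` reproduces byte-identical tables.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "trials.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_TRIAL_COLUMNS)
        for t in session.trials:
            w.writerow(
                [
                    t.trial_id,
                    t.target_number,
                    t.protocol,
                    t.condition,
                    t.timing_arrangement,
                    t.outcome,
                    t.produced_count,
                    _fmt(t.instruction_onset),
                    ";".join(_fmt(p) for p in t.peck_times),
                    _fmt(t.confirmation_time),
                    _fmt(t.first_response_rt),
                ]
            )
    with open(path / "spikes.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_SPIKE_COLUMNS)
        for uid in sorted(session.units):
            by_trial = session.units[uid]
            for tid in sorted(by_trial):
                for ts in np.sort(np.asarray(by_trial[tid], dtype=float)):
                    w.writerow([uid, tid, _fmt(ts)])
    meta = {
        "session_id": session.session_id,
        "crow_id": session.crow_id,
        "metadata": session.metadata,
    }
    with open(path / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, ensure_ascii=False)
        fh.write("\n")


def read_session(path) -> Session:
    """Read and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    trials_path = path / "trials.csv"
    spikes_path = path / "spikes.csv"
    for p in (trials_path, spikes_path):
        if not p.exists():
            raise SessionFormatError(f"missing table: {p}")

    with open(trials_path, newline="") as fh:
        reader = csv.DictReader(fh)
        cols = reader.fieldnames or []
        for col in _TRIAL_COLUMNS:
            if col not in cols:
                raise SessionFormatError(f"trials.csv is missing required column '{col}'")
        trials = []
        for row in reader:
            pecks = [float(x) for x in row["peck_times"].split(";") if x != ""]
            trials.append(
                TrialRecord(
                    trial_id=int(row["trial_id"]),
                    target_number=int(row["target_number"]),
                    protocol=row["protocol"],
                    condition=row["condition"],
                    timing_arrangement=row["timing_arrangement"],
                    outcome=row["outcome"],
                    produced_count=int(row["produced_count"]),
                    instruction_onset=float(row["instruction_onset"] or 0.0),
                    peck_times=pecks,
                    confirmation_time=_parse_float(row["confirmation_time"]),
                    first_response_rt=_parse_float(row["first_response_rt"]),
                )
            )

    units: dict[str, dict[int, list[float]]] = {}
    with open(spikes_path, newline="") as fh:
        reader = csv.DictReader(fh)
        cols = reader.fieldnames or []
        for col in _SPIKE_COLUMNS:
            if col not in cols:
                raise SessionFormatError(f"spikes.csv is missing required column '{col}'")
        for row in reader:
            units.setdefault(row["unit_id"], {}).setdefault(int(row["trial_id"]), []).append(
                float(row["time_ms"])
            )
    unit_arrays = {
        uid: {tid: np.sort(np.asarray(ts, dtype=float)) for tid, ts in by_trial.items()}
        for uid, by_trial in units.items()
    }

    meta_path = path / "metadata.json"
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
    else:
        meta = {"session_id": path.name, "crow_id": "", "metadata": {}}

    session = Session(
        session_id=meta.get("session_id", path.name),
        crow_id=meta.get("crow_id", ""),
        trials=trials,
        units=unit_arrays,
        metadata=meta.get("metadata", {}),
    )
    session.validate()
    return session


def read_sessions(path) -> list[Session]:
    """Read every session directory (one containing trials.csv) under ``path``."""
    path = Path(path)
    if (path / "trials.csv").exists():
        return [read_session(path)]
    out = [read_session(p.parent) for p in sorted(path.glob("*/trials.csv"))]
    if not out:
        raise SessionFormatError(f"no session directories found under {path}")
    return out


# ----------------------------------------------------------------------
# Binning


@dataclass
class BinnedRates:
    """Sliding-window firing rates: ``rates[u, t, b]`` in spikes/s.

    Bin ``b`` covers ``[span0 + b*step, span0 + b*step + width)``.
    """

    rates: np.ndarray
    unit_ids: list[str]
    trial_ids: list[int]
    bin_starts: np.ndarray
    width: float
    step: float

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_starts + self.width / 2.0

    @property
    def n_bins(self) -> int:
        return self.bin_starts.size


def bin_rates(
    session: Session,
    width: float,
    step: float,
    span: tuple[float, float],
    unit_ids=None,
    trial_ids=None,
) -> BinnedRates:
    """Count spikes in half-open sliding windows and convert to spikes/s.

    The number of bins is ``floor((t1 - t0 - width) / step) + 1``; a
    partial terminal window is dropped.  Raises if the span is shorter
    than one window or extends beyond the session's recorded range
    (``metadata['recorded_span']``, when present).
    """
    t0, t1 = span
    if t1 - t0 < width:
        raise ValueError(f"span {span} shorter than window width {width}")
    recorded = session.metadata.get("recorded_span")
    if recorded is not None and (t0 < recorded[0] or t1 > recorded[1]):
        raise ValueError(f"span {span} outside recorded range {tuple(recorded)}")
    unit_ids = list(session.units) if unit_ids is None else list(unit_ids)
    trial_ids = session.trial_ids if trial_ids is None else list(trial_ids)
    n_bins = int(math.floor((t1 - t0 - width) / step)) + 1
    starts = t0 + step * np.arange(n_bins)
    ends = starts + width
    rates = np.zeros((len(unit_ids), len(trial_ids), n_bins))
    for i, uid in enumerate(unit_ids):
        by_trial = session.units.get(uid, {})
        for j, tid in enumerate(trial_ids):
            sp = np.asarray(by_trial.get(tid, ()), dtype=float)
            if sp.size:
                counts = np.searchsorted(sp, ends, side="left") - np.searchsorted(
                    sp, starts, side="left"
                )
                rates[i, j] = counts
    rates /= width / 1000.0
    return BinnedRates(rates, unit_ids, trial_ids, starts, float(width), float(step))
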