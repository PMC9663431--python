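"""Task-faithful synthetic sessions with ground truth.

Behavior follows the approximate-number system: the internal estimate of
a target number ``n`` is log-normally distributed around ``log n`` with
a constant Weber fraction ``w``, which produces both the numerical
distance effect (errors cluster next to the target) and the size effect
(precision worsens with magnitude).  Spikes come from tuned
inhomogeneous-Poisson units whose gain is a Gaussian on the
log-number axis centred on a preferred number.

Two deliberate mechanisms tie the neural code to behavior so that
error-trial analyses have something real to recover:

* units are tuned to the *planned* (i.e. actually produced) count, not
  the instructed one, and
* the tuned gain is further damped by ``error_gain`` on error trials.

The generator returns a :class:`GroundTruth` carrying every unit's true
parameters and each trial's planned count, for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import product
from pathlib import Path

import numpy as np

from .session import (
    ARRANGEMENTS,
    DEFAULT_TASK,
    Session,
    TaskConfig,
    TrialRecord,
)

__all__ = [
    "BehaviorParams",
    "UnitParams",
    "PopulationSpec",
    "GroundTruth",
    "simulate_behavior",
    "unit_rate_profile",
    "sample_population",
    "generate_session",
]

# Spikes are simulated from baseline onset through the first response
# epoch; analyses never look later than 1700 ms.
RECORDED_SPAN = (-300.0, 1800.0)

# Wait intervals between enumeration pecks, by timing arrangement.
# standard: pseudo-random 300..1200 ms; control1: fixed 300 ms;
# control2: per-numerosity durations that roughly equalize the total
# response-period duration across numerosities.
_STANDARD_WAITS = (300.0, 600.0, 900.0, 1200.0)
_CONTROL2_WAITS = {1: [], 2: [2800.0], 3: [1200.0, 1200.0], 4: [600.0] * 3, 5: [300.0] * 4}


@dataclass
class BehaviorParams:
    """Approximate-number response model.

    ``weber_fraction`` is the SD of the internal estimate on the
    log-number axis; 0.16 yields ~73% correct over targets 1-5, matching
    well-trained birds.  ``lapse_rate`` mixes in uniform guesses over
    the feasible counts {0..n+1}.  ``motor_delay_ms`` sets the latency
    from each enumeration-stimulus onset to the peck.
    """

    weber_fraction: float = 0.16
    lapse_rate: float = 0.02
    trials_per_cell: int = 20
    motor_delay_ms: float = 420.0
    motor_delay_sd_ms: float = 60.0
    abort_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.weber_fraction < 0:
            raise ValueError("weber_fraction must be >= 0")
        if not 0 <= self.lapse_rate <= 1:
            raise ValueError("lapse_rate must be in [0, 1]")


@dataclass
class UnitParams:
    """Ground-truth parameters of one synthetic unit.

    ``temporal_profile`` is ``"sustained"``, ``"ramping"``, or
    ``("transient", t_on, t_off)``.  ``protocol_effect`` multiplies the
    tuned gain in the sign protocol (1 = protocol-invariant coding).
    ``error_gain`` multiplies the tuned gain on error trials.
    """

    preferred_number: int | None
    baseline_rate: float = 5.0
    peak_gain: float = 15.0
    tuning_sigma_log: float = 0.4
    temporal_profile: str | tuple = "sustained"
    error_gain: float = 0.8
    protocol_effect: float = 1.0

    def __post_init__(self):
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.baseline_rate + min(0.0, self.peak_gain) < 0:
            raise ValueError("suppressive gain would drive rates negative")


@dataclass
class PopulationSpec:
    """Population composition for the generator.

    Defaults mirror the recorded population: roughly a quarter of units
    number-tuned, preferred values covering 1-5 with an under-
    representation of 3, and a mix of sustained, transient, and ramping
    temporal profiles.
    """

    n_units: int = 60
    tuned_fraction: float = 0.24
    preferred_number_distribution: tuple[float, ...] = (0.25, 0.1875, 0.10, 0.225, 0.2375)
    baseline_range: tuple[float, float] = (2.0, 8.0)
    peak_gain_range: tuple[float, float] = (8.0, 20.0)
    sigma_log_range: tuple[float, float] = (0.3, 0.6)
    profile_probs: dict = field(
        default_factory=lambda: {"sustained": 0.4, "transient": 0.3, "ramping": 0.3}
    )
    error_gain: float = 0.8
    protocol_effect: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if not 0 <= self.tuned_fraction <= 1:
            raise ValueError("tuned_fraction must be in [0, 1]")
        w = np.asarray(self.preferred_number_distribution, dtype=float)
        if w.size != 5 or abs(w.sum() - 1) > 1e-9 or np.any(w < 0):
            raise ValueError("preferred_number_distribution must be 5 weights summing to 1")


@dataclass
class GroundTruth:
    """True generator state: unit parameters and per-trial planned counts."""

    units: dict[str, UnitParams]
    planned_counts: dict[int, int]
    behavior: BehaviorParams
    spec: PopulationSpec

    def to_json(self, path) -> None:
        payload = {
            "units": {uid: asdict(u) for uid, u in self.units.items()},
            "planned_counts": {str(k): v for k, v in self.planned_counts.items()},
            "behavior": asdict(self.behavior),
            "spec": asdict(self.spec),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=list)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)

        def _unit(d):
            tp = d["temporal_profile"]
            if isinstance(tp, list):
                d = dict(d, temporal_profile=tuple(tp))
            return UnitParams(**d)

        spec_raw = dict(raw["spec"])
        for key in ("preferred_number_distribution", "baseline_range", "peak_gain_range",
                    "sigma_log_range"):
            spec_raw[key] = tuple(spec_raw[key])
        return cls(
            units={uid: _unit(d) for uid, d in raw["units"].items()},
            planned_counts={int(k): v for k, v in raw["planned_counts"].items()},
            behavior=BehaviorParams(**raw["behavior"]),
            spec=PopulationSpec(**spec_raw),
        )


# ----------------------------------------------------------------------
# Behavior


def simulate_behavior(target_number: int, params: BehaviorParams, rng: np.random.Generator) -> int:
    """Draw the produced peck count for one trial.

    Internal estimate ``x ~ Normal(log n, w)``; the produced count is
    ``round(exp(x))`` clipped to the feasible range ``[0, n+1]`` (the
    task aborts at n+1 pecks).  With probability ``lapse_rate`` the
    count is instead uniform over ``{0..n+1}``.
    """
    n = int(target_number)
    if n < 1:
        raise ValueError("target_number must be >= 1")
    if params.lapse_rate > 0 and rng.uniform() < params.lapse_rate:
        return int(rng.integers(0, n + 2))
    x = rng.normal(np.log(n), params.weber_fraction)
    k = int(np.round(np.exp(x)))
    return min(max(k, 0), n + 1)


# ----------------------------------------------------------------------
# Unit rate model


def _envelope(profile, t: np.ndarray, task: TaskConfig) -> np.ndarray:
    tuned_end = task.planning_analysis_window[1]  # 1700 ms
    if profile == "sustained":
        return ((t >= 0) & (t < tuned_end)).astype(float)
    if profile == "ramping":
        on, off = task.planning_onset, task.planning_offset
        env = np.clip((t - on) / (off - on), 0.0, 1.0)
        return np.where((t >= on) & (t < tuned_end), env, 0.0)
    if isinstance(profile, tuple) and len(profile) == 3 and profile[0] == "transient":
        _, t_on, t_off = profile
        return ((t >= t_on) & (t < t_off)).astype(float)
    raise ValueError(f"unknown temporal_profile {profile!r}")


def unit_rate_profile(
    unit: UnitParams,
    planned_number: int,
    t,
    *,
    protocol: str = "dot",
    is_error: bool = False,
    task: TaskConfig = DEFAULT_TASK,
    span: tuple[float, float] = RECORDED_SPAN,
):
    """Instantaneous firing rate (spikes/s) of a unit at time(s) ``t``.

    rate = baseline + peak_gain * exp(-(log max(planned,1) - log pref)^2
    / (2 sigma^2)) * envelope(t) * protocol_mult * error_mult.
    Untuned units sit at baseline.  ``planned_number`` is the count the
    synthetic animal will produce; ``max(planned, 1)`` keeps the log
    defined for zero-peck trials.
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if np.any(t_arr < span[0]) or np.any(t_arr > span[1]):
        raise ValueError(f"time outside trial span {span}")
    if unit.preferred_number is None:
        rate = np.full(t_arr.shape, unit.baseline_rate)
    else:
        d = np.log(max(int(planned_number), 1)) - np.log(unit.preferred_number)
        gain = np.exp(-(d**2) / (2.0 * unit.tuning_sigma_log**2))
        if protocol == "sign":
            gain *= unit.protocol_effect
        if is_error:
            gain *= unit.error_gain
        rate = unit.baseline_rate + unit.peak_gain * gain * _envelope(
            unit.temporal_profile, t_arr, task
        )
    rate = np.maximum(rate, 0.0)
    return float(rate[0]) if scalar else rate


def _simulate_spike_train(
    unit: UnitParams,
    planned: int,
    protocol: str,
    is_error: bool,
    rng: np.random.Generator,
    task: TaskConfig,
) -> np.ndarray:
    """Inhomogeneous Poisson spikes over RECORDED_SPAN by thinning."""
    lo, hi = RECORDED_SPAN
    rate_max = unit.baseline_rate + max(unit.peak_gain, 0.0) * max(1.0, unit.protocol_effect)
    if rate_max <= 0:
        return np.empty(0)
    n = rng.poisson(rate_max * (hi - lo) / 1000.0)
    t = rng.uniform(lo, hi, n)
    r = unit_rate_profile(unit, planned, t, protocol=protocol, is_error=is_error, task=task)
    return np.sort(t[rng.uniform(0.0, rate_max, n) < r])


# ----------------------------------------------------------------------
# Population and session assembly


def sample_population(spec: PopulationSpec, rng: np.random.Generator) -> dict[str, UnitParams]:
    """Draw unit parameters; unit ids are ``u000`` ... zero-padded."""
    task = DEFAULT_TASK
    units = {}
    n_tuned = int(round(spec.n_units * spec.tuned_fraction))
    profiles = list(spec.profile_probs)
    probs = np.asarray([spec.profile_probs[k] for k in profiles], dtype=float)
    probs /= probs.sum()
    for i in range(spec.n_units):
        uid = f"u{i:03d}"
        baseline = rng.uniform(*spec.baseline_range)
        if i < n_tuned:
            pref = int(rng.choice(np.arange(1, 6), p=spec.preferred_number_distribution))
            prof = profiles[int(rng.choice(len(profiles), p=probs))]
            if prof == "transient":
                t_on = rng.uniform(0.0, task.planning_offset - 400.0)
                prof = ("transient", t_on, t_on + rng.uniform(300.0, 500.0))
            units[uid] = UnitParams(
                preferred_number=pref,
                baseline_rate=baseline,
                peak_gain=rng.uniform(*spec.peak_gain_range),
                tuning_sigma_log=rng.uniform(*spec.sigma_log_range),
                temporal_profile=prof,
                error_gain=spec.error_gain,
                protocol_effect=spec.protocol_effect,
            )
        else:
            units[uid] = UnitParams(preferred_number=None, baseline_rate=baseline)
    return units


def _wait_sequence(arrangement: str, target: int, n_waits: int, rng) -> list[float]:
    if arrangement == "standard":
        return [float(rng.choice(_STANDARD_WAITS)) for _ in range(n_waits)]
    if arrangement == "control1":
        return [300.0] * n_waits
    if arrangement == "control2":
        base = list(_CONTROL2_WAITS[min(max(target, 1), 5)])
        while len(base) < n_waits:  # overshoot trials need one extra wait
            base.append(base[-1] if base else 300.0)
        return base[:n_waits]
    raise ValueError(f"unknown arrangement {arrangement!r}")


def _simulate_pecks(
    trial: dict, produced: int, outcome: str, behavior: BehaviorParams, rng, task: TaskConfig
):
    """Peck/confirmation event times for one trial; returns (pecks, conf, rt)."""

    def rt():
        r = rng.normal(behavior.motor_delay_ms, behavior.motor_delay_sd_ms)
        return float(np.clip(r, 50.0, task.response_epoch_duration - 10.0))

    exec_on = task.execution_onset
    waits = _wait_sequence(trial["timing_arrangement"], trial["target_number"],
                           max(produced - 1, 0), rng)
    pecks = []
    onset = exec_on
    for i in range(produced):
        pecks.append(onset + rt())
        if i < produced - 1:
            onset = pecks[-1] + waits[i]
    if outcome == "error_plus" or outcome == "aborted":
        conf = None
    else:
        conf = (pecks[-1] if pecks else exec_on) + rt()
    first = pecks[0] - exec_on if pecks else (conf - exec_on if conf is not None else None)
    return pecks, conf, first


def generate_session(
    spec: PopulationSpec | None = None,
    behavior: BehaviorParams | None = None,
    task: TaskConfig | None = None,
    n_trials: int | None = None,
    seed: int = 0,
    session_id: str | None = None,
    crow_id: str = "synthcrow",
    control_arrangement: str | None = None,
    units: dict[str, UnitParams] | None = None,
) -> tuple[Session, GroundTruth]:
    """Generate one balanced synthetic session plus its ground truth.

    The trial list is a balanced 5 (number) x 2 (protocol) x 2
    (condition) factorial in pseudo-random order; ``n_trials`` must
    divide into the 20 cells (default ``20 * trials_per_cell``).  Each
    session mixes the standard timing arrangement with one control
    arrangement, as in the recorded experiment.
    """
    spec = spec or PopulationSpec()
    behavior = behavior or BehaviorParams()
    task = task or DEFAULT_TASK
    rng = np.random.default_rng(seed)
    if n_trials is None:
        n_trials = 20 * behavior.trials_per_cell
    n_cells = len(task.target_numbers) * len(task.protocols) * len(task.conditions)
    if n_trials % n_cells:
        raise ValueError(f"n_trials={n_trials} not divisible into {n_cells} design cells")
    reps = n_trials // n_cells

    if control_arrangement is None:
        control_arrangement = str(rng.choice(["control1", "control2"]))
    elif control_arrangement not in ARRANGEMENTS[1:]:
        raise ValueError(f"control_arrangement must be one of {ARRANGEMENTS[1:]}")

    cells = list(product(task.target_numbers, task.protocols, task.conditions))
    design = []
    for n, prot, cond in cells:
        arr = ["standard", control_arrangement] * (reps // 2 + 1)
        for r in range(reps):
            design.append(dict(target_number=n, protocol=prot, condition=cond,
                               timing_arrangement=arr[r]))
    order = rng.permutation(len(design))

    if units is None:
        units = sample_population(spec, rng)
    trials: list[TrialRecord] = []
    planned_counts: dict[int, int] = {}
    spike_store: dict[str, dict[int, np.ndarray]] = {uid: {} for uid in units}

    for tid, idx in enumerate(order):
        t = design[idx]
        n = t["target_number"]
        planned = simulate_behavior(n, behavior, rng)
        if behavior.abort_rate > 0 and rng.uniform() < behavior.abort_rate:
            outcome = "aborted"
            produced = int(rng.integers(0, planned + 1))
        else:
            produced = planned
            if produced == n:
                outcome = "correct"
            elif produced == n + 1:
                outcome = "error_plus"
            else:
                outcome = "error_minus"
        pecks, conf, first = _simulate_pecks(t, produced, outcome, behavior, rng, task)
        trials.append(
            TrialRecord(
                trial_id=tid,
                target_number=n,
                protocol=t["protocol"],
                condition=t["condition"],
                timing_arrangement=t["timing_arrangement"],
                outcome=outcome,
                produced_count=produced,
                peck_times=pecks,
                confirmation_time=conf,
                first_response_rt=first,
            )
        )
        planned_counts[tid] = planned
        is_error = outcome in ("error_minus", "error_plus")
        for uid, unit in units.items():
            spike_store[uid][tid] = _simulate_spike_train(
                unit, planned, t["protocol"], is_error, rng, task
            )

    session = Session(
        session_id=session_id or f"synth-{seed:04d}",
        crow_id=crow_id,
        trials=trials,
        units=spike_store,
        metadata={
            "generator": "numprod.synth",
            "seed": seed,
            "recorded_span": list(RECORDED_SPAN),
            "control_arrangement": control_arrangement,
        },
    )
    session.validate()
    truth = GroundTruth(units=units, planned_counts=planned_counts, behavior=behavior, spec=spec)
    return session, truth
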