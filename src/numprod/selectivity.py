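"""Single-unit selectivity: sliding ANOVA, selective intervals, tuning.

A unit is number-selective when a sliding two-factor ANOVA (number x
protocol) on its planning-period firing rates shows a main effect of
number (p < 0.01) over at least 11 consecutive 10-ms-stepped bins -- a
continuous interval of at least 300 ms -- with no protocol main effect
or interaction anywhere in the run.  The stimulus condition
(standard/control) is never an ANOVA factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._anova import TwoWayAnova
from .session import DEFAULT_TASK, Session, TaskConfig, bin_rates

__all__ = [
    "AnovaTimecourse",
    "SelectivityResult",
    "include_unit",
    "sliding_anova",
    "detect_selective_interval",
    "tuning_and_normalize",
    "analyze_unit",
    "analyze_session",
    "population_tuning",
    "error_trial_contrast",
]


@dataclass
class AnovaTimecourse:
    """Per-bin p-values of the two-factor sliding ANOVA for one unit."""

    unit_id: str
    bin_starts: np.ndarray
    width: float
    step: float
    p_number: np.ndarray
    p_protocol: np.ndarray
    p_interaction: np.ndarray


@dataclass
class SelectivityResult:
    """Selectivity verdict and tuning for one unit.

    ``interval`` is [start, end) in ms; ``tuning`` holds the mean rate
    (Hz) per target number within the interval; ``normalized_tuning`` is
    min-max normalized (1 at the preferred, 0 at the least-preferred
    number).
    """

    unit_id: str
    selective: bool
    interval: tuple[float, float] | None = None
    preferred_number: int | None = None
    tuning: dict[int, float] | None = None
    normalized_tuning: dict[int, float] | None = None
    flags: list[str] = field(default_factory=list)


# ----------------------------------------------------------------------


def include_unit(
    session: Session,
    unit_id: str,
    task: TaskConfig = DEFAULT_TASK,
    min_rate_hz: float = 0.5,
    min_trials_per_cell: int = 2,
) -> bool:
    """Unit inclusion filter.

    True iff the unit's average firing rate from baseline onset through
    planning offset is at least ``min_rate_hz`` and it has at least
    ``min_trials_per_cell`` correct trials in every number x protocol x
    condition design cell (5 x 2 x 2 = 20 cells).
    """
    t0, t1 = task.trial_start, task.planning_offset
    scored = session.scored_trials()
    if not scored:
        return False
    by_trial = session.units.get(unit_id, {})
    total = sum(
        int(np.searchsorted(by_trial.get(t.trial_id, ()), t1, side="left")
            - np.searchsorted(by_trial.get(t.trial_id, ()), t0, side="left"))
        for t in scored
    )
    mean_rate = total / (len(scored) * (t1 - t0) / 1000.0)
    if mean_rate < min_rate_hz:
        return False
    counts: dict[tuple, int] = {}
    for t in session.correct_trials():
        key = (t.target_number, t.protocol, t.condition)
        counts[key] = counts.get(key, 0) + 1
    for n in task.target_numbers:
        for prot in task.protocols:
            for cond in task.conditions:
                if counts.get((n, prot, cond), 0) < min_trials_per_cell:
                    return False
    return True


def sliding_anova(
    session: Session,
    unit_id: str,
    window: tuple[float, float] | None = None,
    span: tuple[float, float] | None = None,
    task: TaskConfig = DEFAULT_TASK,
) -> AnovaTimecourse:
    """Two-factor (number x protocol) sliding-window ANOVA on correct trials.

    Default window is 200 ms wide with a 10 ms step over the planning
    analysis span [800, 1700] ms (71 bins).  If a design cell is empty
    the p-values are set to 1 for every bin with a warning.
    """
    width, step = window or task.anova_window
    span = span or task.planning_analysis_window
    correct = session.correct_trials()
    trial_ids = [t.trial_id for t in correct]
    br = bin_rates(session, width, step, span, unit_ids=[unit_id], trial_ids=trial_ids)
    y = br.rates[0]  # trials x bins
    numbers = np.array([t.target_number for t in correct])
    protocols = np.array([t.protocol for t in correct])
    try:
        model = TwoWayAnova(numbers, protocols)
        res = model.anova(y)
        p_num, p_prot, p_int = res["a"]["p"], res["b"]["p"], res["ab"]["p"]
    except ValueError as exc:
        warnings.warn(f"unit {unit_id}: degenerate design ({exc}); p set to 1", stacklevel=2)
        ones = np.ones(br.n_bins)
        p_num = p_prot = p_int = ones
    return AnovaTimecourse(unit_id, br.bin_starts, width, step, p_num, p_prot, p_int)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs, stop exclusive."""
    out = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def detect_selective_interval(
    tc: AnovaTimecourse,
    rates: np.ndarray | None = None,
    numbers: np.ndarray | None = None,
    alpha: float = 0.01,
    min_bins: int = 11,
) -> SelectivityResult:
    """Find the selective interval from an ANOVA time course.

    A qualifying run has >= ``min_bins`` consecutive bins with a number
    main effect below ``alpha`` while the protocol main effect and the
    interaction stay above ``alpha`` throughout (protocol-invariant
    coding).  Among several qualifying runs, the one with the largest
    spread of per-number mean rates (max minus min, averaged over the
    run's bins) is kept; ``rates`` (trials x bins) and ``numbers`` are
    needed for that tie-break and for longer-run preference otherwise.
    """
    sig = (tc.p_number < alpha) & (tc.p_protocol >= alpha) & (tc.p_interaction >= alpha)
    candidates = [(i, j) for i, j in _runs(sig) if j - i >= min_bins]
    if not candidates:
        return SelectivityResult(tc.unit_id, selective=False)
    if len(candidates) == 1 or rates is None or numbers is None:
        if len(candidates) > 1:
            candidates.sort(key=lambda r: r[1] - r[0], reverse=True)
        i, j = candidates[0]
    else:
        spreads = []
        for i, j in candidates:
            means = [rates[numbers == n, i:j].mean() for n in np.unique(numbers)]
            spreads.append(max(means) - min(means))
        i, j = candidates[int(np.argmax(spreads))]
    interval = (float(tc.bin_starts[i]), float(tc.bin_starts[j - 1] + tc.width))
    return SelectivityResult(tc.unit_id, selective=True, interval=interval)


def tuning_and_normalize(
    session: Session,
    unit_id: str,
    interval: tuple[float, float],
    task: TaskConfig = DEFAULT_TASK,
) -> SelectivityResult:
    """Mean rate per target number within the selective interval, min-max
    normalized; protocols pooled by trial.

    The preferred number maximizes the mean rate; ties break toward the
    smaller numerosity with a ``"preferred_tie"`` flag.  Flat tuning
    (max == min) leaves the normalized curve undefined and flags the unit.
    """
    t0, t1 = interval
    dur_s = (t1 - t0) / 1000.0
    by_trial = session.units.get(unit_id, {})
    per_number: dict[int, list[float]] = {n: [] for n in task.target_numbers}
    for t in session.correct_trials():
        sp = by_trial.get(t.trial_id, ())
        count = int(np.searchsorted(sp, t1, side="left") - np.searchsorted(sp, t0, side="left"))
        per_number[t.target_number].append(count / dur_s)
    tuning = {n: float(np.mean(v)) if v else float("nan") for n, v in per_number.items()}
    flags = []
    rates = np.array([tuning[n] for n in task.target_numbers])
    lo, hi = np.nanmin(rates), np.nanmax(rates)
    preferred = int(task.target_numbers[int(np.nanargmax(rates))])  # argmax takes first -> smaller
    if np.sum(rates == hi) > 1:
        flags.append("preferred_tie")
    if hi == lo:
        flags.append("flat_tuning")
        normalized = None
    else:
        normalized = {n: float((tuning[n] - lo) / (hi - lo)) for n in task.target_numbers}
    return SelectivityResult(
        unit_id,
        selective=True,
        preferred_number=preferred,
        tuning=tuning,
        normalized_tuning=normalized,
        flags=flags,
    )


def analyze_unit(
    session: Session,
    unit_id: str,
    task: TaskConfig = DEFAULT_TASK,
    alpha: float = 0.01,
    min_bins: int = 11,
) -> SelectivityResult | None:
    """Full selectivity pipeline for one unit; None if the unit fails inclusion."""
    if not include_unit(session, unit_id, task):
        return None
    tc = sliding_anova(session, unit_id, task=task)
    correct = session.correct_trials()
    br = bin_rates(
        session,
        *task.anova_window,
        task.planning_analysis_window,
        unit_ids=[unit_id],
        trial_ids=[t.trial_id for t in correct],
    )
    numbers = np.array([t.target_number for t in correct])
    res = detect_selective_interval(tc, br.rates[0], numbers, alpha=alpha, min_bins=min_bins)
    if not res.selective:
        return res
    tuned = tuning_and_normalize(session, unit_id, res.interval, task)
    tuned.interval = res.interval
    return tuned


def analyze_session(
    session: Session, task: TaskConfig = DEFAULT_TASK, **kwargs
) -> list[SelectivityResult]:
    """Selectivity results for all included units of a session."""
    out = []
    for uid in session.unit_ids:
        res = analyze_unit(session, uid, task, **kwargs)
        if res is not None:
            out.append(res)
    return out


# ----------------------------------------------------------------------
# Population summaries


def population_tuning(results: list[SelectivityResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Averaged normalized tuning curves grouped by preferred number.

    Returns ``(by_preferred, by_distance)``: mean +/- SEM of normalized
    tuning per preferred-number group, and the same curves re-indexed by
    numerical distance from the preferred value (distance 0 at the peak,
    where the aligned mean is 1 by construction).
    """
    rows = []
    for r in results:
        if not r.selective or r.normalized_tuning is None:
            continue
        for n, v in r.normalized_tuning.items():
            rows.append((r.unit_id, r.preferred_number, n, v, n - r.preferred_number))
    df = pd.DataFrame(rows, columns=["unit_id", "preferred", "number", "norm_rate", "distance"])
    if df.empty:
        empty = pd.DataFrame(columns=["preferred", "number", "mean", "sem", "n_units"])
        return empty, pd.DataFrame(columns=["distance", "mean", "sem", "n_units"])

    def agg(g):
        return pd.Series(
            {
                "mean": g["norm_rate"].mean(),
                "sem": g["norm_rate"].std(ddof=1) / np.sqrt(len(g)) if len(g) > 1 else 0.0,
                "n_units": len(g),
            }
        )

    by_pref = (
        df.groupby(["preferred", "number"]).apply(agg, include_groups=False).reset_index()
    )
    by_dist = df.groupby("distance").apply(agg, include_groups=False).reset_index()
    return by_pref, by_dist


def error_trial_contrast(
    session: Session,
    results: list[SelectivityResult],
    min_error_trials: int = 3,
) -> dict:
    """Correct-versus-error firing contrasts for selective units.

    Eligible units are number-selective with at least ``min_error_trials``
    incorrect trials for every instructed value.  Per unit the mean
    preferred-number rate (within its own selective interval) on correct
    trials is paired with the mean on incorrect trials of the same
    instructed value; a two-sided Wilcoxon signed-rank test runs across
    units.

    A second contrast, restricted to units preferring 2-4, compares
    activity in trials where the preferred number ``n`` was *produced*
    erroneously (instructed n-1 or n+1) against correct trials of those
    instructed values.
    """
    per_n = {n: 0 for n in (1, 2, 3, 4, 5)}
    for t in session.scored_trials():
        if not t.is_correct:
            per_n[t.target_number] = per_n.get(t.target_number, 0) + 1
    enough_errors = all(v >= min_error_trials for v in per_n.values())
    eligible = [
        r
        for r in results
        if enough_errors and r.selective and r.interval is not None
        and r.preferred_number is not None
    ]

    def _mean_rate(r, trials):
        t0, t1 = r.interval
        dur_s = (t1 - t0) / 1000.0
        by_trial = session.units.get(r.unit_id, {})
        vals = []
        for t in trials:
            sp = by_trial.get(t.trial_id, ())
            c = np.searchsorted(sp, t1, side="left") - np.searchsorted(sp, t0, side="left")
            vals.append(c / dur_s)
        return float(np.mean(vals)) if vals else np.nan

    correct_rates, error_rates = [], []
    for r in eligible:
        p = r.preferred_number
        cor = [t for t in session.correct_trials() if t.target_number == p]
        err = [t for t in session.scored_trials() if t.target_number == p and not t.is_correct]
        if not cor or not err:
            continue
        correct_rates.append(_mean_rate(r, cor))
        error_rates.append(_mean_rate(r, err))

    out: dict = {
        "n_eligible_units": len(correct_rates),
        "correct_rates": correct_rates,
        "error_rates": error_rates,
    }
    if len(correct_rates) < 2:
        out["preferred_contrast"] = {"skipped": True, "reason": "fewer than 2 eligible units"}
    else:
        diffs = np.asarray(correct_rates) - np.asarray(error_rates)
        if np.all(diffs == 0):
            out["preferred_contrast"] = {"statistic": None, "pvalue": 1.0, "note": "all ties"}
        else:
            st = stats.wilcoxon(correct_rates, error_rates)
            out["preferred_contrast"] = {
                "statistic": float(st.statistic),
                "pvalue": float(st.pvalue),
                "mean_correct_hz": float(np.mean(correct_rates)),
                "mean_error_hz": float(np.mean(error_rates)),
            }

    # produced-preferred contrast: units tuned to 2, 3, 4 only
    adj: dict[str, dict] = {}
    for direction, offset in (("minus", -1), ("plus", +1)):
        pairs = []
        for r in results:
            p = r.preferred_number
            if not r.selective or p is None or p not in (2, 3, 4) or r.interval is None:
                continue
            instructed = p + offset
            produced_pref = [
                t
                for t in session.scored_trials()
                if t.target_number == instructed and t.produced_count == p and not t.is_correct
            ]
            cor = [t for t in session.correct_trials() if t.target_number == instructed]
            if len(produced_pref) < min_error_trials or not cor:
                continue
            pairs.append((_mean_rate(r, cor), _mean_rate(r, produced_pref)))
        if len(pairs) < 2:
            adj[direction] = {"skipped": True, "n_units": len(pairs)}
            continue
        cor_v, err_v = map(np.asarray, zip(*pairs))
        if np.all(cor_v - err_v == 0):
            adj[direction] = {"n_units": len(pairs), "pvalue": 1.0, "note": "all ties"}
        else:
            st = stats.wilcoxon(cor_v, err_v)
            adj[direction] = {
                "n_units": len(pairs),
                "statistic": float(st.statistic),
                "pvalue": float(st.pvalue),
                "mean_correct_hz": float(cor_v.mean()),
                "mean_produced_preferred_hz": float(err_v.mean()),
            }
    out["produced_preferred_contrast"] = adj
    return out
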