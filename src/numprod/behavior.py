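"""Behavioral performance: curves, percent correct, chance levels, tests.

Percent correct uses correct / (correct + counted errors); aborted
trials (light-barrier exits, missed epochs) are stored in the session
but never scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .session import Session

__all__ = [
    "PerformanceCurve",
    "chance_level",
    "performance_curves",
    "percent_correct",
    "above_chance_test",
    "median_rt",
]

_GROUP_FIELDS = ("target_number", "protocol", "condition", "timing_arrangement")


def chance_level(n: int) -> float:
    """Probability of producing the instructed count by guessing.

    A guesser may emit any count in ``{0, ..., n+1}`` (the trial aborts
    at n+1 pecks), one of which is correct, so chance is ``1/(n+2)``:
    33.3% for target 1 down to 14.3% for target 5.
    """
    if n < 1:
        raise ValueError("target number must be >= 1")
    return 1.0 / (n + 2)


@dataclass
class PerformanceCurve:
    """Relative frequency of each produced count for one (target, protocol)."""

    target_number: int
    protocol: str
    probabilities: dict[int, float] | None  # produced count -> relative frequency
    n_trials: int
    absent: bool = False


def performance_curves(sessions: list[Session] | Session) -> list[PerformanceCurve]:
    """Bell-shaped performance curves per instructed value and protocol.

    Relative frequencies are computed within each session and averaged
    over sessions (sessions weigh equally, as in session-wise behavioral
    summaries).  A (target, protocol) cell with no scored trials in any
    session is flagged ``absent``.
    """
    if isinstance(sessions, Session):
        sessions = [sessions]
    rows = []
    for s in sessions:
        for t in s.scored_trials():
            rows.append((s.session_id, t.target_number, t.protocol, t.produced_count))
    df = pd.DataFrame(rows, columns=["session", "target_number", "protocol", "produced_count"])
    curves = []
    targets = sorted({t.target_number for s in sessions for t in s.trials}) or [1, 2, 3, 4, 5]
    protocols = ("dot", "sign")
    for n in targets:
        for prot in protocols:
            sub = df[(df.target_number == n) & (df.protocol == prot)] if len(df) else df
            if len(sub) == 0:
                curves.append(PerformanceCurve(n, prot, None, 0, absent=True))
                continue
            per_session = (
                sub.groupby("session")["produced_count"]
                .value_counts(normalize=True)
                .unstack(fill_value=0.0)
            )
            mean = per_session.mean(axis=0)
            curves.append(
                PerformanceCurve(n, prot, {int(k): float(v) for k, v in mean.items()}, len(sub))
            )
    return curves


def curves_frame(curves: list[PerformanceCurve]) -> pd.DataFrame:
    """Long-format table of performance curves (absent cells omitted)."""
    rows = [
        (c.target_number, c.protocol, k, p, c.n_trials)
        for c in curves
        if not c.absent
        for k, p in sorted(c.probabilities.items())
    ]
    return pd.DataFrame(
        rows, columns=["target_number", "protocol", "produced_count", "probability", "n_trials"]
    )


def percent_correct(
    sessions: list[Session] | Session, grouping: tuple[str, ...] = ("target_number",)
) -> pd.DataFrame:
    """Mean +/- SEM percent correct over sessions, per design group.

    ``grouping`` is any subset of {target_number, protocol, condition,
    timing_arrangement}.  Within each session and group, percent correct
    is 100 * correct / (correct + errors); the SEM is SD/sqrt(n_sessions).
    """
    if isinstance(sessions, Session):
        sessions = [sessions]
    if not sessions:
        raise ValueError("no sessions given")
    bad = set(grouping) - set(_GROUP_FIELDS)
    if bad:
        raise ValueError(f"unknown grouping fields {sorted(bad)}")
    rows = []
    for s in sessions:
        for t in s.scored_trials():
            rows.append(
                (s.session_id, t.target_number, t.protocol, t.condition,
                 t.timing_arrangement, 1.0 if t.is_correct else 0.0)
            )
    df = pd.DataFrame(rows, columns=["session", *_GROUP_FIELDS, "correct"])
    keys = list(grouping) if grouping else []
    per_session = (
        df.groupby(["session", *keys], sort=True)["correct"].mean().mul(100.0).rename("pc")
    )
    if keys:
        g = per_session.groupby(keys)
    else:
        g = per_session.groupby(lambda _: "all")
    out = g.agg(mean="mean", sd="std", n_sessions="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n_sessions"])
    return out.drop(columns="sd")


def above_chance_test(per_session_percent_correct, n: int) -> float:
    """One-sided one-sample t-test of session percent-correct vs chance.

    Tests whether the mean across sessions exceeds ``100 * chance_level(n)``.
    With zero variance the t statistic is undefined; the p-value is then
    0 when the common value is above chance and 1 otherwise (warned).
    """
    vals = np.asarray(per_session_percent_correct, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two sessions for a t-test")
    expected = 100.0 * chance_level(n)
    if np.ptp(vals) == 0:
        warnings.warn("zero variance across sessions; degenerate t-test", stacklevel=2)
        return 0.0 if vals[0] > expected else 1.0
    return float(stats.ttest_1samp(vals, expected, alternative="greater").pvalue)


def median_rt(session: Session) -> float:
    """Median latency (ms) from first enumeration/confirmation stimulus
    onset to the first peck, over scored trials.  Even counts use the
    midpoint of the central pair."""
    rts = [
        t.first_response_rt
        for t in session.scored_trials()
        if t.first_response_rt is not None
    ]
    if not rts:
        raise ValueError("no trials with a first response")
    return float(np.median(rts))
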