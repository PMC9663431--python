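"""Resampled linear-SVM population decoding.

Pseudo-populations are assembled by drawing, per unit and per class, a
fixed number of trials and aligning the draws across units (units were
recorded in different sessions, so trials are matched by class only).
Decoding is a one-vs-one linear SVM with 10-fold cross-validation;
features are z-scored with training-fold statistics only, and the same
parameters are applied to the test fold.  Shuffled-label nulls run
through the identical pipeline with permuted labels.

Accuracy is the mean of the diagonal of the row-normalized confusion
matrix (rows = true class, columns = predicted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .session import DEFAULT_TASK, Session, TaskConfig

__all__ = [
    "DecodingSpec",
    "DecodingResult",
    "n_binary_problems",
    "collect_unit_rates",
    "build_pseudopopulation",
    "cv_accuracy",
    "svm_crossval",
    "decode_numbers",
    "cross_protocol_decode",
    "error_generalization",
    "outcome_classifier",
]

log = logging.getLogger(__name__)


def n_binary_problems(n_classes: int) -> int:
    """Binary sub-problems of a one-vs-one decomposition: C(K, 2)."""
    return n_classes * (n_classes - 1) // 2


@dataclass
class DecodingSpec:
    """Decoding hyper-parameters.

    ``trials_per_class`` must be divisible by ``folds`` so folds stay
    class-balanced.  ``C`` is the SVM regularization constant (linear
    kernel); results on separable and null data are insensitive to it.
    """

    trials_per_class: int = 20
    folds: int = 10
    resamples: int = 100
    shuffle_resamples: int = 100
    window: tuple[float, float] = (800.0, 1700.0)
    C: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.trials_per_class % self.folds:
            raise ValueError("trials_per_class must be divisible by folds")


@dataclass
class DecodingResult:
    """Accuracies and confusion over resamples, plus a shuffled null."""

    classes: list
    accuracies: np.ndarray  # (resamples,)
    null_accuracies: np.ndarray  # (shuffle_resamples,)
    confusion: np.ndarray  # (K, K), rows normalized, mean over resamples
    n_units: int
    excluded_units: list = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sem_accuracy(self) -> float:
        a = self.accuracies
        return float(np.std(a, ddof=1) / np.sqrt(a.size)) if a.size > 1 else 0.0

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_accuracies)) if self.null_accuracies.size else float("nan")

    def null_percentile(self, q: float = 95.0) -> float:
        return float(np.percentile(self.null_accuracies, q))

    def summary(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "mean_accuracy": self.mean_accuracy,
            "sem_accuracy": self.sem_accuracy,
            "null_mean": self.null_mean,
            "n_units": self.n_units,
            "n_resamples": int(self.accuracies.size),
        }


# ----------------------------------------------------------------------
# Rate extraction


def _window_rates(session: Session, unit_id: str, trials, window) -> np.ndarray:
    t0, t1 = window
    dur_s = (t1 - t0) / 1000.0
    by_trial = session.units.get(unit_id, {})
    out = np.empty(len(trials))
    for i, t in enumerate(trials):
        sp = by_trial.get(t.trial_id, ())
        out[i] = (
            np.searchsorted(sp, t1, side="left") - np.searchsorted(sp, t0, side="left")
        ) / dur_s
    return out


def collect_unit_rates(
    sessions: list[Session] | Session,
    class_of_trial,
    window: tuple[float, float],
    min_per_class: int,
    classes: list | None = None,
) -> tuple[dict, list, list]:
    """Per-unit, per-class firing-rate pools for pseudo-population draws.

    ``class_of_trial(trial)`` returns a class label or None (trial not
    used).  Units lacking ``min_per_class`` trials in any class are
    excluded (logged).  Returns ``(unit_rates, classes, excluded)`` with
    ``unit_rates[unit][class]`` an array of single-trial rates; unit keys
    are ``session_id/unit_id``.
    """
    if isinstance(sessions, Session):
        sessions = [sessions]
    pools: dict[str, dict] = {}
    seen_classes: set = set()
    for s in sessions:
        by_class: dict = {}
        for t in s.scored_trials():
            c = class_of_trial(t)
            if c is not None:
                by_class.setdefault(c, []).append(t)
                seen_classes.add(c)
        for uid in s.unit_ids:
            key = f"{s.session_id}/{uid}"
            pools[key] = {
                c: _window_rates(s, uid, trs, window) for c, trs in by_class.items()
            }
    classes = sorted(seen_classes) if classes is None else list(classes)
    unit_rates, excluded = {}, []
    for key, by_class in pools.items():
        if all(by_class.get(c, np.empty(0)).size >= min_per_class for c in classes):
            unit_rates[key] = by_class
        else:
            excluded.append(key)
            log.info("excluding %s: fewer than %d trials in some class", key, min_per_class)
    return unit_rates, classes, excluded


def build_pseudopopulation(
    unit_rates: dict, classes: list, trials_per_class: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One resample draw: (K*trials_per_class) x n_units rate matrix + labels.

    Rows are blocked by class; each unit contributes an independent
    without-replacement draw of its own trials, aligned by position.
    """
    units = list(unit_rates)
    k, tpc = len(classes), trials_per_class
    X = np.empty((k * tpc, len(units)))
    y = np.repeat(np.arange(k), tpc)
    for j, u in enumerate(units):
        for ci, c in enumerate(classes):
            pool = unit_rates[u][c]
            idx = rng.choice(pool.size, size=tpc, replace=False)
            X[ci * tpc : (ci + 1) * tpc, j] = pool[idx]
    return X, y


# ----------------------------------------------------------------------
# Cross-validated SVM


def _zscore_pair(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """z-score both sets with *training* mean/SD; zero-variance features -> 0."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    ok = sd > 0
    zt = np.where(ok, (train - mu) / np.where(ok, sd, 1.0), 0.0)
    zs = np.where(ok, (test - mu) / np.where(ok, sd, 1.0), 0.0)
    return zt, zs


def cv_accuracy(
    X: np.ndarray, y: np.ndarray, folds: int = 10, C: float = 1.0
) -> tuple[float, np.ndarray]:
    """Class-balanced k-fold CV accuracy of a one-vs-one linear SVM.

    Rows of ``X`` must be blocked by class with equal counts (as built
    by :func:`build_pseudopopulation`); fold f holds out positions
    ``f*(tpc/folds):(f+1)*(tpc/folds)`` within each class block.
    Returns (mean-diagonal accuracy, row-normalized confusion matrix).
    """
    classes = np.unique(y)
    k = classes.size
    tpc = np.sum(y == classes[0])
    if np.any([np.sum(y == c) != tpc for c in classes]) or tpc % folds:
        raise ValueError("need balanced class blocks divisible by folds")
    per_fold = tpc // folds
    block_starts = {c: np.flatnonzero(y == c)[0] for c in classes}
    confusion = np.zeros((k, k))
    for f in range(folds):
        test_idx = np.concatenate(
            [block_starts[c] + np.arange(f * per_fold, (f + 1) * per_fold) for c in classes]
        )
        train_mask = np.ones(y.size, dtype=bool)
        train_mask[test_idx] = False
        ztr, zte = _zscore_pair(X[train_mask], X[test_idx])
        clf = SVC(kernel="linear", C=C)
        clf.fit(ztr, y[train_mask])
        pred = clf.predict(zte)
        for true, p in zip(y[test_idx], pred):
            confusion[np.searchsorted(classes, true), np.searchsorted(classes, p)] += 1
    confusion /= confusion.sum(axis=1, keepdims=True)
    return float(np.mean(np.diag(confusion))), confusion


def svm_crossval(
    unit_rates: dict, classes: list, spec: DecodingSpec, rng: np.random.Generator | None = None
) -> DecodingResult:
    """Resampled cross-validated decoding with a shuffled-label null.

    Each resample draws a fresh pseudo-population, runs k-fold CV, and
    records accuracy and confusion; the null repeats the identical
    procedure (fresh draws included) with permuted labels.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    if not unit_rates:
        raise ValueError("no units pass the trial-count minimum")
    accs = np.empty(spec.resamples)
    confusion = np.zeros((len(classes), len(classes)))
    for r in range(spec.resamples):
        X, y = build_pseudopopulation(unit_rates, classes, spec.trials_per_class, rng)
        accs[r], cm = cv_accuracy(X, y, spec.folds, spec.C)
        confusion += cm
    confusion /= spec.resamples
    nulls = np.empty(spec.shuffle_resamples)
    for r in range(spec.shuffle_resamples):
        X, y = build_pseudopopulation(unit_rates, classes, spec.trials_per_class, rng)
        y = rng.permutation(y)
        # permuted labels break the class blocking, so use a generic
        # stratified-by-position split on the shuffled label vector
        nulls[r], _ = _shuffled_cv_accuracy(X, y, spec.folds, spec.C, rng)
    return DecodingResult(
        classes=list(classes),
        accuracies=accs,
        null_accuracies=nulls,
        confusion=confusion,
        n_units=len(unit_rates),
    )


def _shuffled_cv_accuracy(X, y, folds, C, rng):
    """CV for permuted labels: stratified folds on the permuted vector."""
    classes = np.unique(y)
    k = classes.size
    order = {c: np.flatnonzero(y == c) for c in classes}
    confusion = np.zeros((k, k))
    per_fold = {c: idx.size // folds for c, idx in order.items()}
    for f in range(folds):
        test_idx = np.concatenate(
            [order[c][f * per_fold[c] : (f + 1) * per_fold[c]] for c in classes]
        )
        train_mask = np.ones(y.size, dtype=bool)
        train_mask[test_idx] = False
        ztr, zte = _zscore_pair(X[train_mask], X[test_idx])
        clf = SVC(kernel="linear", C=C)
        clf.fit(ztr, y[train_mask])
        for true, p in zip(y[test_idx], clf.predict(zte)):
            confusion[np.searchsorted(classes, true), np.searchsorted(classes, p)] += 1
    row_sums = confusion.sum(axis=1, keepdims=True)
    confusion = np.divide(confusion, row_sums, out=np.zeros_like(confusion), where=row_sums > 0)
    return float(np.mean(np.diag(confusion))), confusion


# ----------------------------------------------------------------------
# Top-level decoding analyses


def decode_numbers(
    sessions, spec: DecodingSpec | None = None, task: TaskConfig = DEFAULT_TASK
) -> DecodingResult:
    """Decode the instructed target number from correct-trial planning rates."""
    spec = spec or DecodingSpec()
    unit_rates, classes, excluded = collect_unit_rates(
        sessions,
        lambda t: t.target_number if t.is_correct else None,
        spec.window,
        spec.trials_per_class,
        classes=list(task.target_numbers),
    )
    res = svm_crossval(unit_rates, classes, spec)
    res.excluded_units = excluded
    return res


def cross_protocol_decode(
    sessions, spec: DecodingSpec | None = None, task: TaskConfig = DEFAULT_TASK
) -> dict:
    """Train on one stimulus protocol, test on the other (both directions).

    Per split, 9 trials/class of the training protocol train the model
    and 1 trial/class of the other protocol tests it; 10 splits per
    resample.  Within-protocol accuracy from the same draws is reported
    for comparison.  Inclusion: >= ``trials_per_class`` (default 10)
    trials per numerical value and protocol.
    """
    spec = spec or DecodingSpec(trials_per_class=10)
    rng = np.random.default_rng(spec.seed)
    classes = list(task.target_numbers)
    pools = {}
    for prot in task.protocols:
        unit_rates, _, excluded = collect_unit_rates(
            sessions,
            lambda t, prot=prot: (
                t.target_number if t.is_correct and t.protocol == prot else None
            ),
            spec.window,
            spec.trials_per_class,
            classes=classes,
        )
        pools[prot] = unit_rates
    common = sorted(set(pools["dot"]) & set(pools["sign"]))
    if not common:
        raise ValueError("no units with enough trials in both protocols")
    tpc, folds = spec.trials_per_class, spec.folds
    k = len(classes)
    out: dict = {"n_units": len(common)}
    accs = {("dot", "sign"): [], ("sign", "dot"): [], ("dot", "dot"): [], ("sign", "sign"): []}
    nulls = {key: [] for key in accs}
    for _ in range(spec.resamples):
        draw = {
            prot: build_pseudopopulation(
                {u: pools[prot][u] for u in common}, classes, tpc, rng
            )
            for prot in task.protocols
        }
        for train_p, test_p in accs:
            Xa, ya = draw[train_p]
            Xb, yb = draw[test_p]
            accs[(train_p, test_p)].append(
                _split_transfer_accuracy(Xa, ya, Xb, yb, k, tpc, folds, spec.C,
                                         same=train_p == test_p)
            )
    for _ in range(spec.shuffle_resamples):
        draw = {
            prot: build_pseudopopulation(
                {u: pools[prot][u] for u in common}, classes, tpc, rng
            )
            for prot in task.protocols
        }
        for train_p, test_p in accs:
            Xa, ya = draw[train_p]
            Xb, yb = draw[test_p]
            ya = rng.permutation(ya)
            nulls[(train_p, test_p)].append(
                _split_transfer_accuracy(Xa, ya, Xb, yb, k, tpc, folds, spec.C,
                                         same=train_p == test_p)
            )
    out["accuracies"] = {k_: np.asarray(v) for k_, v in accs.items()}
    out["null_accuracies"] = {k_: np.asarray(v) for k_, v in nulls.items()}
    out["summary"] = {
        f"{a}->{b}": {
            "mean": float(np.mean(v)),
            "sem": float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0,
        }
        for (a, b), v in out["accuracies"].items()
    }
    return out


def _split_transfer_accuracy(Xa, ya, Xb, yb, k, tpc, folds, C, same=False):
    """Mean accuracy over splits, training on A-held-in, testing on B-held-out.

    With ``same=True`` the held-out rows come from the training matrix
    itself (ordinary cross-validation on protocol A).
    """
    per_fold = tpc // folds
    acc = 0.0
    for f in range(folds):
        test_rows = np.concatenate(
            [c * tpc + np.arange(f * per_fold, (f + 1) * per_fold) for c in range(k)]
        )
        train_mask = np.ones(Xa.shape[0], dtype=bool)
        train_mask[test_rows] = False
        Xtr, ytr = Xa[train_mask], ya[train_mask]
        Xte, yte = (Xa[test_rows], yb[test_rows]) if same else (Xb[test_rows], yb[test_rows])
        if same:
            yte = ya[test_rows]
        ztr, zte = _zscore_pair(Xtr, Xte)
        clf = SVC(kernel="linear", C=C)
        clf.fit(ztr, ytr)
        acc += float(np.mean(clf.predict(zte) == yte))
    return acc / folds


@dataclass
class ErrorGeneralizationResult:
    """Paired correct-test vs incorrect-test accuracies over resamples."""

    correct_accuracies: np.ndarray
    error_accuracies: np.ndarray
    n_units: int
    wilcoxon_pvalue: float

    def summary(self) -> dict:
        return {
            "correct_mean": float(self.correct_accuracies.mean()),
            "error_mean": float(self.error_accuracies.mean()),
            "wilcoxon_pvalue": self.wilcoxon_pvalue,
            "n_units": self.n_units,
        }


def error_generalization(
    sessions, spec: DecodingSpec | None = None, task: TaskConfig = DEFAULT_TASK
) -> ErrorGeneralizationResult:
    """Correct-trained decoder tested on correct vs incorrect trials.

    Models train on 9 correct trials/class; per split they are tested
    once on a held-out correct trial/class and once on an incorrect
    trial/class labeled by the *instructed* number.  Units need >= 10
    correct and >= 1 incorrect trial per class.  Returns paired accuracy
    streams and a two-sided Wilcoxon signed-rank over resamples.
    """
    spec = spec or DecodingSpec(trials_per_class=10)
    rng = np.random.default_rng(spec.seed)
    classes = list(task.target_numbers)
    correct_rates, _, _ = collect_unit_rates(
        sessions,
        lambda t: t.target_number if t.is_correct else None,
        spec.window,
        spec.trials_per_class,
        classes=classes,
    )
    error_rates, _, _ = collect_unit_rates(
        sessions,
        lambda t: t.target_number if (t.is_scored and not t.is_correct) else None,
        spec.window,
        1,
        classes=classes,
    )
    common = sorted(set(correct_rates) & set(error_rates))
    if not common:
        raise ValueError("no units with both enough correct and >=1 incorrect trial per class")
    k, tpc, folds = len(classes), spec.trials_per_class, spec.folds
    per_fold = tpc // folds
    acc_c = np.empty(spec.resamples)
    acc_e = np.empty(spec.resamples)
    for r in range(spec.resamples):
        Xc, yc = build_pseudopopulation(
            {u: correct_rates[u] for u in common}, classes, tpc, rng
        )
        ac = ae = 0.0
        for f in range(folds):
            test_rows = np.concatenate(
                [c * tpc + np.arange(f * per_fold, (f + 1) * per_fold) for c in range(k)]
            )
            train_mask = np.ones(Xc.shape[0], dtype=bool)
            train_mask[test_rows] = False
            # one incorrect pseudo-trial per class, drawn fresh each split
            Xe = np.empty((k * per_fold, len(common)))
            for j, u in enumerate(common):
                for ci, c in enumerate(classes):
                    pool = error_rates[u][c]
                    Xe[ci * per_fold : (ci + 1) * per_fold, j] = rng.choice(
                        pool, size=per_fold, replace=True
                    )
            ztr, zte_c = _zscore_pair(Xc[train_mask], Xc[test_rows])
            _, zte_e = _zscore_pair(Xc[train_mask], Xe)
            clf = SVC(kernel="linear", C=spec.C)
            clf.fit(ztr, yc[train_mask])
            ac += float(np.mean(clf.predict(zte_c) == yc[test_rows]))
            ae += float(np.mean(clf.predict(zte_e) == yc[test_rows]))
        acc_c[r] = ac / folds
        acc_e[r] = ae / folds
    diffs = acc_c - acc_e
    if np.all(diffs == 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(acc_c, acc_e).pvalue)
    return ErrorGeneralizationResult(acc_c, acc_e, len(common), p)


def outcome_classifier(
    sessions, spec: DecodingSpec | None = None, task: TaskConfig = DEFAULT_TASK
) -> DecodingResult:
    """3-class decoding of trial outcome: correct vs -1 error vs +1 error.

    Numerical values are pooled; only -1 errors are used (the task
    aborts at n+1 pecks, so only +1 overshoots exist).  Units need >= 30
    trials per outcome class.  Per-class prediction rates live in the
    confusion matrix so the -1/+1 asymmetry is testable.
    """
    spec = spec or DecodingSpec(trials_per_class=30, resamples=100, shuffle_resamples=100)

    def outcome_class(t):
        if t.outcome == "correct":
            return "correct"
        if t.outcome == "error_plus":
            return "error_plus"
        if t.outcome == "error_minus" and t.produced_count == t.target_number - 1:
            return "error_minus"
        return None

    unit_rates, classes, excluded = collect_unit_rates(
        sessions, outcome_class, spec.window, spec.trials_per_class,
        classes=["correct", "error_minus", "error_plus"],
    )
    if not unit_rates:
        raise ValueError("no units with enough trials per outcome class")
    res = svm_crossval(unit_rates, classes, spec)
    res.excluded_units = excluded
    return res
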