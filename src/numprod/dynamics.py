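"""Time-resolved population information and cross-temporal codes.

Three pieces:

* ``omega_squared`` -- small-sample-unbiased percent explained variance
  of each two-factor ANOVA term,
  ``omega2 = (SS_term - df * MS_error) / (SS_total + MS_error) * 100``;
* ``pev_timecourse`` -- sliding-window omega2 per unit, averaged over
  units, resampled over trial draws with a shuffled-label baseline;
* ``cross_temporal_decode`` + ``cluster_permutation_test`` -- SVM
  decoders trained in each time window and tested in every other one,
  with a two-stage cluster permutation test that separates static
  (off-diagonal generalization) from dynamic (diagonal-confined) codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.svm import SVC

from ._anova import TwoWayAnova
from .decoding import _zscore_pair
from .session import DEFAULT_TASK, Session, TaskConfig, bin_rates

__all__ = [
    "PEVTimecourse",
    "CrossTemporalMatrix",
    "ClusterTestResult",
    "omega_squared",
    "pev_timecourse",
    "cross_temporal_decode",
    "cluster_permutation_test",
]

_TERMS = {"a": "number", "b": "protocol", "ab": "interaction"}


def omega_squared(rates, numbers, protocols) -> dict[str, float | np.ndarray]:
    """omega-squared percent explained variance per ANOVA term.

    ``rates`` may be a vector (one value per trial) or a trials x bins
    matrix; labels are the per-trial target number and stimulus
    protocol.  Values can be slightly negative in small samples (the
    price of unbiasedness) and are reported as computed.  Degenerate
    tables (an empty design cell, no replicates) raise ``ValueError``.
    """
    model = TwoWayAnova(numbers, protocols)
    raw = model.omega_squared(np.asarray(rates, dtype=float))
    return {_TERMS[k]: v for k, v in raw.items()}


# ----------------------------------------------------------------------
# PEV time course


@dataclass
class PEVTimecourse:
    """Population omega2 over time with a shuffled-label baseline.

    ``omega2[term]`` is the mean over resamples of the unit-averaged
    curve; ``shuffled_baseline[term]`` averages the identically
    processed label-shuffled curves.  ``n_null_evaluations`` counts
    resamples x shuffles null evaluations.
    """

    bin_starts: np.ndarray
    width: float
    omega2: dict[str, np.ndarray]
    sem: dict[str, np.ndarray]
    shuffled_baseline: dict[str, np.ndarray]
    n_units: int
    n_resamples: int
    n_shuffles_per_resample: int
    n_null_evaluations: int = 0

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_starts + self.width / 2.0


def _eligible_unit_bins(sessions, window, span, trials_per_cell, task):
    """Binned correct-trial rates and labels per eligible unit.

    Eligibility: >= trials_per_cell correct trials in each number x
    protocol cell.  Yields (unit_key, rates trials x bins, cell_indices)
    where cell_indices[(n, prot)] lists row indices for that cell.
    """
    if isinstance(sessions, Session):
        sessions = [sessions]
    width, step = window
    out = []
    bin_starts = None
    for s in sessions:
        correct = s.correct_trials()
        trial_ids = [t.trial_id for t in correct]
        cells: dict[tuple, list[int]] = {}
        for i, t in enumerate(correct):
            cells.setdefault((t.target_number, t.protocol), []).append(i)
        ok = all(
            len(cells.get((n, p), ())) >= trials_per_cell
            for n in task.target_numbers
            for p in task.protocols
        )
        if not ok:
            continue
        br = bin_rates(s, width, step, span, trial_ids=trial_ids)
        bin_starts = br.bin_starts
        for i, uid in enumerate(br.unit_ids):
            out.append((f"{s.session_id}/{uid}", br.rates[i], cells))
    return out, bin_starts


def pev_timecourse(
    sessions,
    window: tuple[float, float] | None = None,
    span: tuple[float, float] = (-300.0, 1700.0),
    trials_per_cell: int = 10,
    resamples: int = 20,
    shuffles: int = 50,
    seed: int | None = None,
    task: TaskConfig = DEFAULT_TASK,
) -> PEVTimecourse:
    """Sliding-window population omega2 for number, protocol, interaction.

    Per resample, ``trials_per_cell`` correct trials are drawn per
    number x protocol cell for each eligible unit; omega2 per term and
    bin is averaged over units.  The shuffled baseline repeats the same
    computation ``shuffles`` times per resample with per-unit label
    permutations (resamples x shuffles null evaluations in total).
    """
    window = window or task.pev_window
    rng = np.random.default_rng(seed)
    units, bin_starts = _eligible_unit_bins(sessions, window, span, trials_per_cell, task)
    if not units:
        raise ValueError(f"no units with >= {trials_per_cell} correct trials per cell")
    n_bins = bin_starts.size
    numbers = np.repeat(
        [n for n in task.target_numbers for _ in task.protocols], trials_per_cell
    )
    protocols = np.tile(
        np.repeat(list(task.protocols), trials_per_cell), len(task.target_numbers)
    )
    model = TwoWayAnova(numbers, protocols)  # fixed sorted design, reused throughout
    n_rows = numbers.size

    curves = {t: np.zeros((resamples, n_bins)) for t in _TERMS.values()}
    null_sum = {t: np.zeros(n_bins) for t in _TERMS.values()}
    n_null = 0
    for r in range(resamples):
        drawn = []
        for _, rates, cells in units:
            rows = np.empty((n_rows, n_bins))
            pos = 0
            for n in task.target_numbers:
                for p in task.protocols:
                    idx = np.asarray(cells[(n, p)])
                    pick = rng.choice(idx, size=trials_per_cell, replace=False)
                    rows[pos : pos + trials_per_cell] = rates[pick]
                    pos += trials_per_cell
            drawn.append(rows)
        acc = {t: np.zeros(n_bins) for t in _TERMS.values()}
        for rows in drawn:
            w = model.omega_squared(rows)
            for k, t in _TERMS.items():
                acc[t] += w[k]
        for t in _TERMS.values():
            curves[t][r] = acc[t] / len(drawn)
        for _ in range(shuffles):
            acc_s = {t: np.zeros(n_bins) for t in _TERMS.values()}
            for rows in drawn:
                perm = rng.permutation(n_rows)
                w = model.omega_squared(rows[perm])
                for k, t in _TERMS.items():
                    acc_s[t] += w[k]
            for t in _TERMS.values():
                null_sum[t] += acc_s[t] / len(drawn)
            n_null += 1

    omega2 = {t: curves[t].mean(axis=0) for t in curves}
    sem = {
        t: (curves[t].std(axis=0, ddof=1) / np.sqrt(resamples)) if resamples > 1
        else np.zeros(n_bins)
        for t in curves
    }
    baseline = {t: null_sum[t] / max(n_null, 1) for t in null_sum}
    return PEVTimecourse(
        bin_starts=bin_starts,
        width=window[0],
        omega2=omega2,
        sem=sem,
        shuffled_baseline=baseline,
        n_units=len(units),
        n_resamples=resamples,
        n_shuffles_per_resample=shuffles,
        n_null_evaluations=n_null,
    )


# ----------------------------------------------------------------------
# Cross-temporal decoding


@dataclass
class CrossTemporalMatrix:
    """Train-bins x test-bins accuracy matrix (mean over resamples).

    The diagonal equals the time-resolved cross-validated accuracy
    trace.  ``null_matrices`` (when computed) stacks label-shuffled
    matrices built by the identical pipeline.
    """

    bin_starts: np.ndarray
    width: float
    accuracy: np.ndarray  # (B, B)
    n_units: int
    n_resamples: int
    null_matrices: np.ndarray | None = None  # (n_null, B, B)
    n_null_evaluations: int = 0

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.accuracy)


def _collect_class_bins(sessions, window, span, trials_per_class, task):
    """Per-unit binned correct-trial rates grouped by target number."""
    if isinstance(sessions, Session):
        sessions = [sessions]
    width, step = window
    out = []
    bin_starts = None
    for s in sessions:
        correct = s.correct_trials()
        trial_ids = [t.trial_id for t in correct]
        by_class: dict[int, list[int]] = {}
        for i, t in enumerate(correct):
            by_class.setdefault(t.target_number, []).append(i)
        if any(len(by_class.get(n, ())) < trials_per_class for n in task.target_numbers):
            continue
        br = bin_rates(s, width, step, span, trial_ids=trial_ids)
        bin_starts = br.bin_starts
        for i, uid in enumerate(br.unit_ids):
            out.append((f"{s.session_id}/{uid}", br.rates[i], by_class))
    return out, bin_starts


def cross_temporal_decode(
    sessions,
    window: tuple[float, float] | None = None,
    span: tuple[float, float] = (-300.0, 1700.0),
    trials_per_class: int = 20,
    folds: int = 10,
    resamples: int = 20,
    shuffles: int = 0,
    C: float = 1.0,
    seed: int | None = None,
    task: TaskConfig = DEFAULT_TASK,
) -> CrossTemporalMatrix:
    """Cross-temporal generalization matrix of a one-vs-one linear SVM.

    Per resample each eligible unit (>= ``trials_per_class`` correct
    trials per target number) contributes a fresh trial draw.  For every
    train bin, models fit on 18 trials/class (z-scored with that bin's
    training subset; the same parameters are applied wherever the model
    is tested) and are tested on the 2 held-out trials/class at every
    test bin; 10 splits per resample.  With ``shuffles > 0`` the same
    pipeline runs on label permutations, giving ``resamples * shuffles``
    null matrices for the cluster permutation test.
    """
    window = window or task.pev_window
    rng = np.random.default_rng(seed)
    units, bin_starts = _collect_class_bins(sessions, window, span, trials_per_class, task)
    if not units:
        raise ValueError(f"no units with >= {trials_per_class} correct trials per class")
    n_bins = bin_starts.size
    classes = list(task.target_numbers)
    k = len(classes)
    tpc = trials_per_class
    if tpc % folds:
        raise ValueError("trials_per_class must be divisible by folds")
    per_fold = tpc // folds
    y = np.repeat(np.arange(k), tpc)

    def one_matrix(tensor, labels):
        """Accuracy matrix for one draw: tensor (k*tpc, units, bins)."""
        acc = np.zeros((n_bins, n_bins))
        for f in range(folds):
            test_rows = np.concatenate(
                [c * tpc + np.arange(f * per_fold, (f + 1) * per_fold) for c in range(k)]
            )
            train_mask = np.ones(k * tpc, dtype=bool)
            train_mask[test_rows] = False
            ytr, yte = labels[train_mask], labels[test_rows]
            for b in range(n_bins):
                ztr, _ = _zscore_pair(tensor[train_mask, :, b], tensor[test_rows, :, b])
                mu = tensor[train_mask, :, b].mean(axis=0)
                sd = tensor[train_mask, :, b].std(axis=0)
                ok = sd > 0
                clf = SVC(kernel="linear", C=C)
                clf.fit(ztr, ytr)
                # test every bin with this train-bin's z-parameters
                test_all = tensor[test_rows]  # (n_test, units, bins)
                z = np.where(
                    ok[None, :, None],
                    (test_all - mu[None, :, None]) / np.where(ok, sd, 1.0)[None, :, None],
                    0.0,
                )
                flat = np.moveaxis(z, 2, 0).reshape(n_bins * test_rows.size, -1)
                pred = clf.predict(flat).reshape(n_bins, test_rows.size)
                acc[b] += (pred == yte[None, :]).mean(axis=1)
        return acc / folds

    mean_acc = np.zeros((n_bins, n_bins))
    null_list = []
    for _ in range(resamples):
        tensor = np.empty((k * tpc, len(units), n_bins))
        for j, (_, rates, by_class) in enumerate(units):
            for ci, c in enumerate(classes):
                idx = np.asarray(by_class[c])
                pick = rng.choice(idx, size=tpc, replace=False)
                tensor[ci * tpc : (ci + 1) * tpc, j] = rates[pick]
        mean_acc += one_matrix(tensor, y)
        for _ in range(shuffles):
            null_list.append(one_matrix(tensor, rng.permutation(y)))
    mean_acc /= resamples
    return CrossTemporalMatrix(
        bin_starts=bin_starts,
        width=window[0],
        accuracy=mean_acc,
        n_units=len(units),
        n_resamples=resamples,
        null_matrices=np.stack(null_list) if null_list else None,
        n_null_evaluations=len(null_list),
    )


# ----------------------------------------------------------------------
# Cluster permutation test


@dataclass
class ClusterTestResult:
    """Significant-cluster mask and per-cluster statistics."""

    mask: np.ndarray  # bool, True where a significant cluster lies
    clusters: list[dict] = field(default_factory=list)
    pixel_threshold: np.ndarray | None = None
    null_cluster_sizes: np.ndarray | None = None

    @property
    def n_significant(self) -> int:
        return sum(c["significant"] for c in self.clusters)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    raise ValueError("connectivity must be 4 or 8")


def cluster_permutation_test(
    matrix: np.ndarray,
    null_matrices: np.ndarray,
    alpha_cluster: float = 0.05,
    alpha_rank: float = 0.05,
    connectivity: int = 4,
    null_cluster_stat: str = "max",
) -> ClusterTestResult:
    """Two-stage cluster permutation test on an accuracy matrix.

    Stage 1 thresholds each pixel against its own null distribution:
    significant means strictly greater than the ``ceil((1-alpha)*n)``-th
    order statistic of the ``n`` null values (the 950th of 1000 at 5%).
    Stage 2 labels connected components (edge-adjacency by default) of
    supra-threshold pixels in the true and in every null matrix; the
    null cluster-size distribution takes the maximum cluster size per
    null matrix (``null_cluster_stat="max"``, familywise control) or
    pools all null cluster sizes (``"all"``).  A true cluster is
    significant when its size-rank p-value is at most ``alpha_rank``.
    """
    matrix = np.asarray(matrix, dtype=float)
    nulls = np.asarray(null_matrices, dtype=float)
    if nulls.ndim != 3 or nulls.shape[1:] != matrix.shape:
        raise ValueError("null_matrices must be a stack shaped like the true matrix")
    n_null = nulls.shape[0]
    order = int(np.ceil((1.0 - alpha_cluster) * n_null)) - 1
    thr = np.sort(nulls, axis=0)[order]

    structure = _structure(connectivity)

    def cluster_sizes(mask):
        labels, n = ndimage.label(mask, structure=structure)
        return labels, np.bincount(labels.ravel())[1:] if n else np.empty(0, dtype=int)

    true_labels, true_sizes = cluster_sizes(matrix > thr)
    null_sizes = []
    for m in nulls:
        _, sizes = cluster_sizes(m > thr)
        if null_cluster_stat == "max":
            null_sizes.append(int(sizes.max()) if sizes.size else 0)
        elif null_cluster_stat == "all":
            null_sizes.extend(int(s) for s in sizes)
        else:
            raise ValueError("null_cluster_stat must be 'max' or 'all'")
    null_sizes = np.asarray(null_sizes, dtype=int)

    clusters = []
    mask = np.zeros(matrix.shape, dtype=bool)
    denom = null_sizes.size + 1
    for label, size in enumerate(true_sizes, start=1):
        p = (1 + int(np.sum(null_sizes >= size))) / denom
        significant = p <= alpha_rank
        clusters.append({"label": label, "size": int(size), "pvalue": float(p),
                         "significant": bool(significant)})
        if significant:
            mask |= true_labels == label
    clusters.sort(key=lambda c: -c["size"])
    return ClusterTestResult(
        mask=mask,
        clusters=clusters,
        pixel_threshold=thr,
        null_cluster_sizes=null_sizes,
    )
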