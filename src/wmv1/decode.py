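"""Population decoding of memory content.

Trials are averaged into batches of adjacent same-condition trials, firing
is windowed on a sliding grid, and content is decoded with the Poisson
independent decoder (PID):

    log L(theta) = sum_i n_i log f_i(theta) - sum_i f_i(theta)

where n_i is electrode i's activity in the test window and f_i(theta) the
condition tuning (mean count) from the training window; the second term is
the bias correction. Training in one window and testing in every other
yields the cross-temporal generalization matrix, assessed against a
label-permutation null. A linear SVM harness provides the cross-task
generalization check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import GridSearchCV
from sklearn.svm import LinearSVC

from .session import SessionData

DEFAULT_FLOOR = 0.01


def make_windows(t_range: tuple[float, float], width: float = 200.0,
                 step: float = 50.0) -> list[tuple[float, float]]:
    """Sliding half-open windows [s, s+width) covering t_range."""
    if step <= 0:
        raise ValueError("step must be positive")
    start, end = t_range
    if width > end - start:
        raise ValueError("width exceeds range")
    out = []
    s = start
    while s + width <= end + 1e-9:
        out.append((s, s + width))
        s += step
    return out


@dataclass
class BatchSet:
    """Batched, windowed population activity.

    ``counts``: (n_batches, n_windows, n_electrodes) mean spike count per
    batch trial in each window; ``labels``: condition per batch.
    """

    counts: np.ndarray
    labels: np.ndarray
    windows: list[tuple[float, float]]
    batch_size: int = 20

    @property
    def conditions(self) -> np.ndarray:
        return np.unique(self.labels)

    def rates(self) -> np.ndarray:
        widths = np.array([(b - a) / 1000.0 for a, b in self.windows])
        return self.counts / widths[None, :, None]


def window_counts(session: SessionData, windows: list[tuple[float, float]],
                  electrodes: np.ndarray | None = None) -> np.ndarray:
    """Trial x window x electrode spike counts on the shared window grid."""
    t0 = min(w[0] for w in windows)
    t1 = max(w[1] for w in windows)
    binned = session.binned_counts((t0, t1), electrodes=electrodes)  # (T, E, B)
    cum = np.concatenate([np.zeros(binned.shape[:2] + (1,)),
                          np.cumsum(binned, axis=2)], axis=2)
    out = np.empty((binned.shape[0], len(windows), binned.shape[1]))
    for w, (a, b) in enumerate(windows):
        ia, ib = int(round(a - t0)), int(round(b - t0))
        out[:, w, :] = cum[:, :, ib] - cum[:, :, ia]
    return out


def make_batches(session: SessionData, windows: list[tuple[float, float]],
                 batch_size: int = 20, electrodes: np.ndarray | None = None,
                 correct_only: bool = True) -> BatchSet:
    """Average adjacent same-condition trials (acquisition order) into batches.

    Each condition's trials are taken in acquisition order and chunked into
    groups of ``batch_size``; the final partial group is dropped, so each
    condition yields floor(n_c / batch_size) batches.
    """
    if correct_only:
        session = session.subset_trials(session.correct_mask())
    labels = session.condition_labels()
    counts = window_counts(session, windows, electrodes=electrodes)
    batch_counts, batch_labels = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < batch_size:
            raise ValueError(f"condition {c} has {len(idx)} trials < batch_size")
        n_b = len(idx) // batch_size
        for b in range(n_b):
            members = idx[b * batch_size:(b + 1) * batch_size]
            batch_counts.append(counts[members].mean(axis=0))
            batch_labels.append(c)
    return BatchSet(np.stack(batch_counts), np.asarray(batch_labels),
                    list(windows), batch_size)


@dataclass
class TuningFunction:
    """Per-condition mean-count tuning f_i(theta) for one training window."""

    f: np.ndarray                      # (n_conditions, n_electrodes)
    conditions: np.ndarray
    floor: float = DEFAULT_FLOOR


def fit_pid(train: BatchSet, window_index: int,
            floor: float = DEFAULT_FLOOR) -> TuningFunction:
    """Condition tuning from training batches: per-condition mean, floored."""
    conditions = train.conditions
    rows = []
    for c in conditions:
        m = train.labels == c
        if not m.any():
            raise ValueError(f"no training batches for condition {c}")
        rows.append(train.counts[m, window_index, :].mean(axis=0))
    f = np.maximum(np.stack(rows), floor)
    return TuningFunction(f, conditions, floor)


def pid_loglik(tuning: TuningFunction, n: np.ndarray) -> np.ndarray:
    """log L(theta) = sum_i n_i log f_i(theta) - sum_i f_i(theta)."""
    n = np.asarray(n, dtype=float)
    if (n < 0).any():
        raise ValueError("negative activity")
    return n @ np.log(tuning.f).T - tuning.f.sum(axis=1)


def pid_decode(tuning: TuningFunction, n: np.ndarray,
               rng: np.random.Generator | None = None):
    """Decode one activity vector; ties broken uniformly at random."""
    ll = pid_loglik(tuning, n)
    top = np.flatnonzero(ll == ll.max())
    if len(top) > 1 and rng is not None:
        pick = int(rng.choice(top))
    else:
        pick = int(top[0])
    return tuning.conditions[pick], ll


@dataclass
class DecodingMatrix:
    """Train-window x test-window accuracy grid with its permutation null."""

    accuracy: np.ndarray                      # (n_windows, n_windows)
    windows: list[tuple[float, float]]
    n_repetitions: int
    chance: float
    null_distribution: np.ndarray | None = None   # (n_perm, W, W)
    meta: dict = field(default_factory=dict)

    def pvalues(self) -> np.ndarray:
        """One-tailed permutation p per cell: (1 + #{null >= obs}) / (1 + n_perm)."""
        if self.null_distribution is None:
            raise ValueError("no permutation null attached")
        n_perm = self.null_distribution.shape[0]
        ge = (self.null_distribution >= self.accuracy[None]).sum(axis=0)
        return (1.0 + ge) / (1.0 + n_perm)


def _accuracy_grid(counts: np.ndarray, cond_codes: np.ndarray,
                   train_idx: np.ndarray, test_idx: np.ndarray,
                   floor: float, rng: np.random.Generator) -> np.ndarray:
    """Vectorised PID accuracy over all (train-window, test-window) pairs."""
    n_cond = cond_codes.max() + 1
    W = counts.shape[1]
    f = np.empty((W, n_cond, counts.shape[2]))
    for c in range(n_cond):
        m = train_idx[cond_codes[train_idx] == c]
        f[:, c, :] = counts[m].mean(axis=0)
    np.maximum(f, floor, out=f)
    # loglik: (B_test, W_test, W_train, C)
    ll = np.einsum("bwe,vce->bwvc", counts[test_idx], np.log(f))
    ll -= f.sum(axis=2)[None, None, :, :]
    # random tie-break via argmax over (ll == max) masked random keys
    mx = ll.max(axis=3, keepdims=True)
    keys = rng.random(ll.shape)
    keys[ll < mx] = -1.0
    pred = keys.argmax(axis=3)                        # (B_test, W_test, W_train)
    correct = pred == cond_codes[test_idx][:, None, None]
    return correct.mean(axis=0).T                     # (W_train, W_test)


def cross_temporal_matrix(batches: BatchSet, train_per_condition: int = 15,
                          repetitions: int = 1000, floor: float = DEFAULT_FLOOR,
                          n_perm: int = 0, seed: int | None = None) -> DecodingMatrix:
    """Averaged cross-temporal generalization matrix of PID accuracies.

    Per repetition, ``train_per_condition`` batches per condition are drawn
    at random as the training set and the rest are the test set; tuning is
    fitted in every training window and applied to every test window. The
    optional permutation null shuffles condition labels across batches.
    """
    conditions, cond_codes = np.unique(batches.labels, return_inverse=True)
    for c, cond in enumerate(conditions):
        n_c = int((cond_codes == c).sum())
        if n_c < train_per_condition + 1:
            raise ValueError(f"condition {cond}: {n_c} batches, need "
                             f">= {train_per_condition + 1}")
    rng = np.random.default_rng(seed)
    W = batches.counts.shape[1]
    B = len(batches.labels)

    def one_rep(codes: np.ndarray) -> np.ndarray:
        train = np.concatenate([
            rng.choice(np.flatnonzero(codes == c), size=train_per_condition,
                       replace=False) for c in range(len(conditions))])
        mask = np.ones(B, dtype=bool)
        mask[train] = False
        return _accuracy_grid(batches.counts, codes,
                              train, np.flatnonzero(mask), floor, rng)

    acc = np.zeros((W, W))
    for _ in range(repetitions):
        acc += one_rep(cond_codes)
    acc /= repetitions

    null = None
    if n_perm:
        null = np.empty((n_perm, W, W))
        for p in range(n_perm):
            null[p] = one_rep(rng.permutation(cond_codes))
    return DecodingMatrix(acc, batches.windows, repetitions,
                          1.0 / len(conditions), null)


def permutation_null(batches: BatchSet, observed: float,
                     window_index: int, n_perm: int = 99,
                     train_per_condition: int = 15,
                     floor: float = DEFAULT_FLOOR,
                     seed: int | None = None) -> tuple[float, np.ndarray]:
    """One-tailed permutation p-value for a single on-diagonal cell."""
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    conditions, cond_codes = np.unique(batches.labels, return_inverse=True)
    rng = np.random.default_rng(seed)
    B = len(batches.labels)
    null = np.empty(n_perm)
    for p in range(n_perm):
        codes = rng.permutation(cond_codes)
        train = np.concatenate([
            rng.choice(np.flatnonzero(codes == c), size=train_per_condition,
                       replace=False) for c in range(len(conditions))])
        mask = np.ones(B, dtype=bool)
        mask[train] = False
        grid = _accuracy_grid(
            batches.counts[:, [window_index], :], codes,
            train, np.flatnonzero(mask), floor, rng)
        null[p] = grid[0, 0]
    p_val = (1.0 + (null >= observed).sum()) / (1.0 + n_perm)
    return p_val, null


def svm_cross_task(train_session: SessionData, test_session: SessionData,
                   window: tuple[float, float], condition_map: dict[str, str],
                   n_per_condition: int = 300, iters: int = 100,
                   c_grid=(0.01, 0.1, 1.0, 10.0),
                   seed: int | None = None) -> np.ndarray:
    """Cross-task linear-classifier harness; returns per-iteration accuracies.

    Per iteration, ``n_per_condition`` training trials per condition are
    drawn from the training task, a linear max-margin classifier (small
    logarithmic regularization grid, 3-fold CV) is fitted on the
    window-averaged rates, and accuracy is measured on ``n_per_condition``
    random test-task trials per condition, with test labels translated
    through ``condition_map``.
    """
    rng = np.random.default_rng(seed)
    win = [window]
    x_train = window_counts(train_session, win)[:, 0, :]
    y_train = train_session.condition_labels()
    x_test = window_counts(test_session, win)[:, 0, :]
    y_test_raw = test_session.condition_labels()
    unmapped = set(np.unique(y_test_raw)) - set(condition_map)
    if unmapped:
        raise ValueError(f"unmapped test conditions: {sorted(unmapped)}")
    y_test = np.array([condition_map[c] for c in y_test_raw])

    accs = np.empty(iters)
    for it in range(iters):
        tr_idx = np.concatenate([
            rng.choice(np.flatnonzero(y_train == c),
                       size=min(n_per_condition, (y_train == c).sum()),
                       replace=False) for c in np.unique(y_train)])
        te_idx = np.concatenate([
            rng.choice(np.flatnonzero(y_test == c),
                       size=min(n_per_condition, (y_test == c).sum()),
                       replace=False) for c in np.unique(y_test)])
        clf = GridSearchCV(LinearSVC(dual="auto"), {"C": list(c_grid)}, cv=3)
        clf.fit(x_train[tr_idx], y_train[tr_idx])
        accs[it] = (clf.predict(x_test[te_idx]) == y_test[te_idx]).mean()
    return accs
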