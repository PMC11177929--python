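"""Content-modulation index (CMI) and auxiliary epoch statistics.

The CMI of an electrode is (FR_h - FR_l)/(FR_h + FR_l), where FR_h and FR_l
are the mean firing rates of the highest- and lowest-firing memory-content
conditions (the h/l pair). The h/l designation may be fixed in one dataset
or epoch and applied as minuend/subtrahend in another, so that a negative
CMI signals a reversal of the condition ranking. A held-out cross-validated
variant removes the selection bias that self-designation introduces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .session import SessionData

log = logging.getLogger(__name__)

INVALID = np.nan


@dataclass(frozen=True)
class HlPair:
    """Highest/lowest-firing condition designation for one electrode."""

    electrode_id: int
    cond_high: str
    cond_low: str
    source_dataset: str = "self"
    source_epoch: str = ""
    tied: bool = False

    def __post_init__(self):
        if self.cond_high == self.cond_low:
            raise ValueError("cond_high and cond_low must differ")


def epoch_rates(session: SessionData, epoch: tuple[float, float],
                electrodes: np.ndarray | None = None) -> np.ndarray:
    """Trial x electrode firing rates (sp/s) in a half-open window."""
    start, end = epoch
    if not (session.t_start <= start < end <= session.t_stop):
        raise ValueError("epoch outside recording window")
    counts = session.spike_counts(epoch, electrodes=electrodes)
    return counts / ((end - start) / 1000.0)


def condition_means(rates: np.ndarray, labels: np.ndarray,
                    conditions: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-condition mean rates, (n_conditions, n_electrodes), sorted labels."""
    labels = np.asarray(labels)
    conditions = np.unique(labels) if conditions is None else np.asarray(conditions)
    means = np.stack([rates[labels == c].mean(axis=0) for c in conditions])
    return means, conditions


def designate_hl(rates: np.ndarray, labels: np.ndarray,
                 source_dataset: str = "self", source_epoch: str = "",
                 electrode_ids: np.ndarray | None = None) -> list[HlPair]:
    """Pick the highest- and lowest-firing condition per electrode.

    Ties are broken by condition-label sort order (argmax/argmin return the
    first extreme) and flagged.
    """
    labels = np.asarray(labels)
    conditions = np.unique(labels)
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    means, conditions = condition_means(rates, labels, conditions)
    if electrode_ids is None:
        electrode_ids = np.arange(rates.shape[1])
    pairs = []
    for e in range(rates.shape[1]):
        hi = int(np.argmax(means[:, e]))
        lo = int(np.argmin(means[:, e]))
        tied = (np.sum(means[:, e] == means[hi, e]) > 1
                or np.sum(means[:, e] == means[lo, e]) > 1)
        if hi == lo:  # all means equal: first/second by label order
            hi, lo, tied = 0, 1, True
        pairs.append(HlPair(int(electrode_ids[e]), str(conditions[hi]),
                            str(conditions[lo]), source_dataset, source_epoch, tied))
    return pairs


def compute_cmi(rates: np.ndarray, labels: np.ndarray,
                hl: list[HlPair]) -> np.ndarray:
    """CMI per electrode with a fixed h/l designation.

    The designation's minuend/subtrahend roles are preserved regardless of
    which condition actually fires more in this data, so a ranking reversal
    shows up as a negative value. Electrodes whose two mean rates sum to
    zero return NaN and are excluded from aggregates.
    """
    labels = np.asarray(labels)
    out = np.full(rates.shape[1], INVALID)
    for e, pair in enumerate(hl):
        mask_h = labels == pair.cond_high
        mask_l = labels == pair.cond_low
        if not mask_h.any() or not mask_l.any():
            raise ValueError(f"condition {pair.cond_high}/{pair.cond_low} absent")
        fr_h = rates[mask_h, e].mean()
        fr_l = rates[mask_l, e].mean()
        denom = fr_h + fr_l
        if denom > 0:
            out[e] = (fr_h - fr_l) / denom
    return out


def delta_cmi_abs(cmi_a, cmi_b):
    """|CMI_a - CMI_b|; NaN propagates as the invalid sentinel."""
    return np.abs(np.asarray(cmi_a, dtype=float) - np.asarray(cmi_b, dtype=float))


def _matched_subset(rng, idx: np.ndarray, size: int) -> np.ndarray:
    if len(idx) < size:
        log.warning("matched size reduced from %d to %d", size, len(idx))
        size = len(idx)
    return rng.choice(idx, size=size, replace=False)


def cmi_crossval(rates_sets: dict[str, np.ndarray],
                 labels_sets: dict[str, np.ndarray],
                 k: int = 20, iters: int = 200,
                 seed: int | None = None) -> dict[str, np.ndarray]:
    """Cross-validated CMI with held-out designation, averaged over iterations.

    Per iteration the h/l pair is designated on all but a held-back 1/k of
    the correct trials (per condition); the CMI is then evaluated on the
    held-back correct trials and on trial-number-matched random subsets of
    every other set (e.g. incorrect, fixation). When the incorrect set is
    smaller than 5% of the total, the fold count adapts to the
    incorrect:correct ratio so the held-back portion stays matchable.
    Returns per-set electrode-wise mean CMI over iterations.
    """
    if "correct" not in rates_sets:
        raise ValueError("rates_sets must contain a 'correct' set")
    rng = np.random.default_rng(seed)
    correct = rates_sets["correct"]
    lab_c = np.asarray(labels_sets["correct"])
    conditions = np.unique(lab_c)
    n_correct = len(lab_c)

    k_eff = k
    if "incorrect" in rates_sets:
        n_inc = len(labels_sets["incorrect"])
        total = n_correct + n_inc
        if n_inc > 0 and n_inc < 0.05 * total:
            k_eff = max(k, int(round(n_correct / n_inc)))

    other = {name: (rates_sets[name], np.asarray(labels_sets[name]))
             for name in rates_sets if name != "correct"}
    sums = {name: np.zeros(correct.shape[1]) for name in rates_sets}
    counts = {name: np.zeros(correct.shape[1]) for name in rates_sets}

    cond_idx = {c: np.flatnonzero(lab_c == c) for c in conditions}
    for _ in range(iters):
        held = {c: rng.choice(cond_idx[c], size=max(1, len(cond_idx[c]) // k_eff),
                              replace=False) for c in conditions}
        held_all = np.concatenate(list(held.values()))
        design_mask = np.ones(n_correct, dtype=bool)
        design_mask[held_all] = False
        hl = designate_hl(correct[design_mask], lab_c[design_mask])
        vals = compute_cmi(correct[held_all], lab_c[held_all], hl)
        ok = ~np.isnan(vals)
        sums["correct"][ok] += vals[ok]
        counts["correct"][ok] += 1
        for name, (r, lab) in other.items():
            pick = []
            for c in conditions:
                idx = np.flatnonzero(lab == c)
                if len(idx) == 0:
                    continue
                pick.append(_matched_subset(rng, idx, len(held[c])))
            pick = np.concatenate(pick)
            vals = compute_cmi(r[pick], lab[pick], hl)
            ok = ~np.isnan(vals)
            sums[name][ok] += vals[ok]
            counts[name][ok] += 1
    return {name: np.where(counts[name] > 0, sums[name] / np.maximum(counts[name], 1),
                           INVALID) for name in sums}


def normalize_response(psth: np.ndarray, times: np.ndarray,
                       spontaneous: tuple[float, float] = (-150.0, 0.0),
                       stimulus: tuple[float, float] = (0.0, 200.0)) -> np.ndarray:
    """Normalise a PSTH to 0 at the spontaneous level and 1 at the stimulus peak."""
    psth = np.asarray(psth, dtype=float)
    times = np.asarray(times, dtype=float)
    sp = psth[(times >= spontaneous[0]) & (times < spontaneous[1])].mean()
    peak = psth[(times >= stimulus[0]) & (times < stimulus[1])].max()
    denom = peak - sp
    if denom <= 0:
        raise ValueError("stimulus peak does not exceed spontaneous level")
    return (psth - sp) / denom


def epoch_rank_correlation(rates_a: np.ndarray, rates_b: np.ndarray,
                           labels: np.ndarray) -> np.ndarray:
    """Spearman rho per electrode between the two epochs' condition-mean rankings."""
    labels = np.asarray(labels)
    conditions = np.unique(labels)
    if len(conditions) < 3:
        raise ValueError("rank correlation needs >= 3 conditions")
    means_a, _ = condition_means(rates_a, labels, conditions)
    means_b, _ = condition_means(rates_b, labels, conditions)
    out = np.empty(rates_a.shape[1])
    for e in range(rates_a.shape[1]):
        out[e] = stats.spearmanr(means_a[:, e], means_b[:, e]).statistic
    return out


def epoch_response_correlation(rates_a: np.ndarray, rates_b: np.ndarray,
                               labels: np.ndarray) -> np.ndarray:
    """Trial-by-trial Pearson r between two epochs' rates, per electrode.

    Computed within each condition and averaged, so condition-driven rate
    differences cannot masquerade as trial-wise coupling. NaN when a
    condition has zero variance in either epoch.
    """
    labels = np.asarray(labels)
    if rates_a.shape[0] < 10:
        raise ValueError("need at least 10 trials")
    conditions = np.unique(labels)
    out = np.empty(rates_a.shape[1])
    for e in range(rates_a.shape[1]):
        rs = []
        for c in conditions:
            m = labels == c
            a, b = rates_a[m, e], rates_b[m, e]
            if a.std() == 0 or b.std() == 0:
                rs.append(np.nan)
            else:
                rs.append(stats.pearsonr(a, b).statistic)
        out[e] = np.mean(rs)
    return out
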