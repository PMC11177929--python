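"""Jitter-corrected cross-correlogram (CCG) functional connectivity.

For a unit pair (j, k) and content condition c, the raw correlogram is

    CCG(tau) = sum_i sum_t r_ji(t - tau) r_ki(t)
               / sqrt( (sum_i sum_t r_ji(t)) * (sum_i sum_t r_ki(t)) )

with binary 1-ms bins r, trials i summed, and the geometric-mean-of-counts
normalisation mitigating firing-rate effects. Stimulus-locked and slow
correlations are removed by subtracting the correlogram expected under
interval jitter: spikes resampled uniformly within consecutive 25-ms blocks
of each trial, preserving per-trial block counts (hence the across-trial
PSTH at block resolution). A pair is functionally connected when the
corrected CCG's maximum over 1-20 ms lags exceeds seven SDs of its values
on the +/-20-40-ms flanks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

MAX_LAG = 40
SIG_LAG_RANGE = (1, 20)
FLANK_RANGE = (20, 40)


def ccg_lags(max_lag: int = MAX_LAG) -> np.ndarray:
    return np.arange(-max_lag, max_lag + 1)


def _raw_numerator(trains_j: np.ndarray, trains_k: np.ndarray,
                   max_lag: int) -> np.ndarray:
    """sum_i sum_t r_j(t - tau) r_k(t) for tau in [-max_lag, max_lag]."""
    n = trains_j.shape[1]
    full = fftconvolve(trains_k.astype(float), trains_j[:, ::-1].astype(float),
                       mode="full", axes=1).sum(axis=0)
    center = n - 1
    out = full[center - max_lag:center + max_lag + 1]
    if (np.issubdtype(trains_j.dtype, np.integer)
            and np.issubdtype(trains_k.dtype, np.integer)):
        out = np.round(out)  # integer coincidence counts: remove FFT round-off
    return out


def compute_ccg(trains_j: np.ndarray, trains_k: np.ndarray,
                max_lag: int = MAX_LAG) -> np.ndarray:
    """Raw normalised CCG over lags -max_lag..max_lag (1-ms bins).

    ``trains_j`` and ``trains_k`` are (n_trials, n_bins) binary arrays on
    identical bin grids. Raises if either unit is silent over all trials
    (the pair is then invalid).
    """
    trains_j = np.asarray(trains_j)
    trains_k = np.asarray(trains_k)
    if trains_j.shape != trains_k.shape:
        raise ValueError("trains must share trial count and bin grid")
    nj, nk = trains_j.sum(), trains_k.sum()
    if nj == 0 or nk == 0:
        raise ValueError("silent unit: CCG undefined for this pair")
    return _raw_numerator(trains_j, trains_k, max_lag) / np.sqrt(float(nj) * float(nk))


def compute_ccg_bruteforce(trains_j: np.ndarray, trains_k: np.ndarray,
                           max_lag: int = MAX_LAG) -> np.ndarray:
    """Naive triple-loop evaluation of the correlogram (oracle for tests)."""
    trains_j = np.asarray(trains_j)
    trains_k = np.asarray(trains_k)
    m, n = trains_j.shape
    lags = ccg_lags(max_lag)
    num = np.zeros(len(lags))
    for li, tau in enumerate(lags):
        for i in range(m):
            for t in range(n):
                if 0 <= t - tau < n:
                    num[li] += trains_j[i, t - tau] * trains_k[i, t]
    return num / np.sqrt(float(trains_j.sum()) * float(trains_k.sum()))


def jitter_trains(trains: np.ndarray, jitter_window: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Resample spike positions uniformly within per-trial jitter blocks.

    Bins are partitioned into consecutive blocks of ``jitter_window`` bins
    from the epoch start (a shorter final block is permuted within itself);
    within each (trial, block) the bins are randomly permuted, which
    redistributes spikes uniformly while preserving the per-trial per-block
    spike count exactly.
    """
    if jitter_window < 2:
        raise ValueError("jitter window must span at least 2 bins")
    m, n = trains.shape
    out = np.empty_like(trains)
    for start in range(0, n, jitter_window):
        stop = min(start + jitter_window, n)
        w = stop - start
        perm = np.argsort(rng.random((m, w)), axis=1)
        out[:, start:stop] = np.take_along_axis(trains[:, start:stop], perm, axis=1)
    return out


def expected_jitter_trains(trains: np.ndarray, jitter_window: int) -> np.ndarray:
    """Exact expectation of the jittered train: block-uniform spike density."""
    m, n = trains.shape
    out = np.empty(trains.shape, dtype=float)
    for start in range(0, n, jitter_window):
        stop = min(start + jitter_window, n)
        w = stop - start
        out[:, start:stop] = trains[:, start:stop].sum(axis=1, keepdims=True) / w
    return out


def jitter_correct(trains_j: np.ndarray, trains_k: np.ndarray,
                   raw: np.ndarray | None = None, jitter_window: int = 25,
                   rounds: int = 3, max_lag: int = MAX_LAG,
                   mode: str = "mc", seed: int | None = None,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Corrected CCG: raw minus the (averaged) jittered-correlogram expectation.

    ``mode='mc'`` averages ``rounds`` Monte-Carlo jitters of both trains;
    ``mode='exact'`` uses the closed-form expectation (product of
    block-uniform densities), a deterministic oracle for validation. The
    normalising spike counts are invariant under jitter, so the raw
    denominator is reused.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if raw is None:
        raw = compute_ccg(trains_j, trains_k, max_lag)
    denom = np.sqrt(float(trains_j.sum()) * float(trains_k.sum()))
    if mode == "exact":
        ej = expected_jitter_trains(trains_j, jitter_window)
        ek = expected_jitter_trains(trains_k, jitter_window)
        expectation = _raw_numerator(ej, ek, max_lag) / denom
    elif mode == "mc":
        acc = np.zeros_like(raw)
        for _ in range(rounds):
            jj = jitter_trains(trains_j, jitter_window, rng)
            jk = jitter_trains(trains_k, jitter_window, rng)
            acc += _raw_numerator(jj, jk, max_lag) / denom
        expectation = acc / rounds
    else:
        raise ValueError(f"unknown jitter mode {mode!r}")
    return raw - expectation


def test_significance(corrected: np.ndarray, max_lag: int = MAX_LAG,
                      sd_multiplier: float = 7.0) -> tuple[bool, int, float]:
    """Apply the 7-SD rule; returns (significant, peak_lag, noise_sd).

    noise_sd is the SD of the corrected CCG on the flank lags
    |tau| in [20, 40]; the pair is significant iff the maximum over
    tau in [1, 20] strictly exceeds ``sd_multiplier`` times that SD
    (or exceeds 0 when the flank SD is exactly 0).
    """
    lags = ccg_lags(max_lag)
    flank = (np.abs(lags) >= FLANK_RANGE[0]) & (np.abs(lags) <= FLANK_RANGE[1])
    window = (lags >= SIG_LAG_RANGE[0]) & (lags <= SIG_LAG_RANGE[1])
    noise_sd = float(corrected[flank].std())
    peak_idx = np.flatnonzero(window)[int(np.argmax(corrected[window]))]
    peak = float(corrected[peak_idx])
    if noise_sd == 0:
        significant = peak > 0
    else:
        significant = peak > sd_multiplier * noise_sd
    return bool(significant), int(lags[peak_idx]), noise_sd


test_significance.__test__ = False  # plain function despite the name


@dataclass
class CcgResult:
    """Correlogram of one (pair, condition, epoch) with its significance call."""

    pair: tuple[int, int]
    condition: str
    epoch: str
    lags: np.ndarray
    raw: np.ndarray
    corrected: np.ndarray
    peak_lag: int
    noise_sd: float
    significant: bool
    valid: bool = True


def ccg_analysis(session, pair: tuple[int, int], condition: str,
                 epoch: tuple[float, float], epoch_name: str = "",
                 jitter_window: int = 25, rounds: int = 3,
                 sd_multiplier: float = 7.0, max_lag: int = MAX_LAG,
                 mode: str = "mc", correct_only: bool = True,
                 seed: int | None = None) -> CcgResult:
    """Full per-pair pipeline: bin, correlate, jitter-correct, test."""
    mask = session.condition_labels() == condition
    if correct_only:
        mask &= session.correct_mask()
    sub = session.subset_trials(mask)
    tj = sub.binned(epoch, pair[0])
    tk = sub.binned(epoch, pair[1])
    lags = ccg_lags(max_lag)
    if tj.sum() == 0 or tk.sum() == 0:
        z = np.zeros(len(lags))
        return CcgResult(pair, condition, epoch_name, lags, z, z, 0, 0.0,
                         False, valid=False)
    raw = compute_ccg(tj, tk, max_lag)
    corrected = jitter_correct(tj, tk, raw, jitter_window, rounds, max_lag,
                               mode=mode, seed=seed)
    sig, peak_lag, noise_sd = test_significance(corrected, max_lag, sd_multiplier)
    return CcgResult(pair, condition, epoch_name, lags, raw, corrected,
                     peak_lag, noise_sd, sig)


@dataclass
class FcCategory:
    pair: tuple[int, int]
    condition: str
    category: str     # stimulus_only | delay_only | both


@dataclass
class FcSummary:
    categories: list[FcCategory] = field(default_factory=list)
    #: proportions relative to the count of stimulus-significant pairs
    proportions: dict[str, float] | None = None
    denominator_undefined: bool = False


def categorize_fc(stim_results: list[CcgResult],
                  delay_results: list[CcgResult]) -> FcSummary:
    """Label significant pairs stimulus_only / delay_only / both.

    Proportions are reported relative to the number of pairs significant in
    the stimulus period; with no such pair the proportions are undefined
    and flagged.
    """
    stim = {(r.pair, r.condition): r.significant for r in stim_results}
    delay = {(r.pair, r.condition): r.significant for r in delay_results}
    if set(stim) != set(delay):
        raise ValueError("stimulus and delay results cover different pairs")
    cats = []
    for key in stim:
        s, d = stim[key], delay[key]
        if s or d:
            cat = "both" if (s and d) else ("stimulus_only" if s else "delay_only")
            cats.append(FcCategory(key[0], key[1], cat))
    n_stim = sum(1 for v in stim.values() if v)
    if n_stim == 0:
        return FcSummary(cats, None, denominator_undefined=True)
    props = {name: sum(1 for c in cats if c.category == name) / n_stim
             for name in ("stimulus_only", "delay_only", "both")}
    return FcSummary(cats, props, False)
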