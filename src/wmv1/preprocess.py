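"""Quality control and signal-to-event preprocessing.

Multiunit-activity (MUA) detection by robust voltage thresholding of the
high-pass-filtered trace, artifact-trial rejection by modified z-score,
channel retention by evoked-response SNR, and receptive-field mapping by a
two-dimensional Gaussian fit to sparse-noise response grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal


@dataclass(frozen=True)
class EpochSpec:
    """Named analysis windows, half-open [start, end) in ms from cue onset."""

    spontaneous: tuple[float, float] = (-150.0, 0.0)
    stimulus: tuple[float, float] = (0.0, 200.0)
    delay: tuple[float, float] = (700.0, 1700.0)
    later_delay: tuple[float, float] = (1200.0, 1700.0)

    def __post_init__(self) -> None:
        for name in ("spontaneous", "stimulus", "delay", "later_delay"):
            a, b = getattr(self, name)
            if not a < b:
                raise ValueError(f"epoch {name} must have start < end")


def highpass_filter(trace: np.ndarray, fs_hz: float, cutoff_hz: float = 1000.0,
                    order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth high-pass, the conventional front end for MUA."""
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=fs_hz, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(trace, dtype=float))


def estimate_noise_sd(trace: np.ndarray) -> float:
    """Robust noise SD, median(|trace|)/0.6745 (insensitive to spikes)."""
    return float(np.median(np.abs(trace)) / 0.6745)


def detect_mua_events(trace: np.ndarray, threshold_factor: float = 4.5,
                      threshold: float | None = None) -> np.ndarray:
    """Binary event train from positive threshold crossings of ``|trace|``.

    An event is marked at samples where the absolute trace first reaches or
    exceeds the threshold (transition from below), and nowhere else, so a
    sustained excursion yields a single event. The threshold defaults to
    ``threshold_factor`` times a robust noise-SD estimate; pass ``threshold``
    for an absolute level.
    """
    x = np.abs(np.asarray(trace, dtype=float))
    if threshold is None:
        if np.ptp(trace) == 0:
            raise ValueError("constant trace: noise SD is zero")
        sd = estimate_noise_sd(trace)
        if sd == 0:
            raise ValueError("zero noise SD estimate")
        threshold = threshold_factor * sd
    above = x >= threshold
    events = above & ~np.concatenate(([False], above[:-1]))
    return events.astype(np.int8)


def modified_zscore(x: np.ndarray) -> np.ndarray:
    """Iglewicz-Hoaglin modified z, 0.6745*(x - median)/MAD.

    Falls back to the ordinary z-score when the MAD is zero, and to all
    zeros when the SD is also zero (identical values).
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad > 0:
        return 0.6745 * (x - med) / mad
    sd = x.std()
    if sd > 0:
        return (x - x.mean()) / sd
    return np.zeros_like(x)


def reject_artifact_trials(per_trial_rates: np.ndarray, z_cut: float = 2.5) -> np.ndarray:
    """Keep mask over trials: |modified z| <= z_cut on the pooled rate distribution."""
    x = np.asarray(per_trial_rates, dtype=float)
    if x.size == 0:
        raise ValueError("empty rate vector")
    if x.size < 3:
        raise ValueError("need at least 3 trials")
    z = modified_zscore(x)
    return np.abs(z) <= z_cut


def boxcar_smooth(x: np.ndarray, width_bins: int) -> np.ndarray:
    """Centered moving average with edge-truncated normalisation."""
    if width_bins <= 1:
        return np.asarray(x, dtype=float)
    kernel = np.ones(width_bins)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / den


def channel_snr(psth: np.ndarray, times: np.ndarray,
                spontaneous_window: tuple[float, float] = (-150.0, 0.0),
                stimulus_window: tuple[float, float] = (0.0, 200.0),
                smooth_ms: float = 10.0, min_snr: float = 5.0) -> tuple[float, bool]:
    """Evoked-response SNR of a channel and its retention flag.

    SNR = peak height of the (boxcar-smoothed) stimulus-window PSTH above
    the prestimulus mean, divided by the SD of the prestimulus PSTH.
    Measuring the peak as a height above baseline keeps unresponsive
    channels excluded however much data is averaged. Channels below
    ``min_snr`` (or with zero prestimulus SD) are flagged for exclusion.
    """
    psth = np.asarray(psth, dtype=float)
    times = np.asarray(times, dtype=float)
    dt = float(np.median(np.diff(times)))
    smoothed = boxcar_smooth(psth, max(1, int(round(smooth_ms / dt))))
    spont = smoothed[(times >= spontaneous_window[0]) & (times < spontaneous_window[1])]
    stim = smoothed[(times >= stimulus_window[0]) & (times < stimulus_window[1])]
    if spont.size == 0 or stim.size == 0:
        raise ValueError("PSTH does not cover both windows")
    sd = spont.std()
    if sd == 0:
        return float("nan"), False
    snr = float((stim.max() - spont.mean()) / sd)
    return snr, snr >= min_snr


# ---------------------------------------------------------------------------
# receptive-field mapping


@dataclass
class RFEntry:
    electrode_id: int
    center: tuple[float, float]
    size_deg: float
    r_squared: float

    @property
    def well_fitted(self) -> bool:
        return self.r_squared > 0.6


@dataclass
class RFMap:
    entries: list[RFEntry] = field(default_factory=list)

    @property
    def array_center(self) -> tuple[float, float] | None:
        """Mean center over well-fitted electrodes (r^2 > 0.6)."""
        good = [e.center for e in self.entries if e.well_fitted]
        if not good:
            return None
        arr = np.asarray(good)
        return float(arr[:, 0].mean()), float(arr[:, 1].mean())


def _gauss2d(coords, amp, x0, y0, sx, sy, base):
    x, y = coords
    return amp * np.exp(-((x - x0) ** 2 / (2 * sx ** 2)
                          + (y - y0) ** 2 / (2 * sy ** 2))) + base


def fit_rf(responses: np.ndarray, x_deg: np.ndarray | None = None,
           y_deg: np.ndarray | None = None, electrode_id: int = 0) -> RFEntry:
    """Two-dimensional Gaussian fit to a grid of mean probe responses.

    Returns the fitted center, size as twice the geometric mean of the axis
    sigmas (the conventional 2-sigma receptive-field diameter), and the
    coefficient of determination. A non-convergent fit is marked unfitted
    (r_squared = -inf) and is excluded from the array center.
    """
    z = np.asarray(responses, dtype=float)
    if z.ndim != 2 or min(z.shape) < 5:
        raise ValueError("response grid must be at least 5x5")
    ny, nx = z.shape
    x = np.arange(nx, dtype=float) if x_deg is None else np.asarray(x_deg, float)
    y = np.arange(ny, dtype=float) if y_deg is None else np.asarray(y_deg, float)
    xx, yy = np.meshgrid(x, y)
    flat = z.ravel()
    i0 = int(np.argmax(flat))
    span_x = x.max() - x.min()
    span_y = y.max() - y.min()
    p0 = [flat.max() - flat.min() or 1.0, xx.ravel()[i0], yy.ravel()[i0],
          span_x / 6 or 1.0, span_y / 6 or 1.0, flat.min()]
    try:
        popt, _ = optimize.curve_fit(
            _gauss2d, (xx.ravel(), yy.ravel()), flat, p0=p0, maxfev=5000,
            bounds=([0, x.min() - span_x, y.min() - span_y, 1e-6, 1e-6, -np.inf],
                    [np.inf, x.max() + span_x, y.max() + span_y,
                     2 * span_x + 1, 2 * span_y + 1, np.inf]))
    except (RuntimeError, ValueError):
        return RFEntry(electrode_id, (np.nan, np.nan), np.nan, float("-inf"))
    pred = _gauss2d((xx.ravel(), yy.ravel()), *popt)
    ss_res = float(((flat - pred) ** 2).sum())
    ss_tot = float(((flat - flat.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    amp, x0, y0, sx, sy, base = popt
    return RFEntry(electrode_id, (float(x0), float(y0)),
                   float(2.0 * np.sqrt(sx * sy)), float(r2))
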