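"""Synthetic delayed match-to-sample (DMTS) session generator.

Emulates the statistical structure the downstream analyses assume: a 200-ms
cue-evoked tuned response, an exponentially decaying off-response after cue
offset, a delay period (700-1700 ms) with weak content-dependent rate
modulation at near-spontaneous firing levels, a condition ranking in the
delay drawn independently of the stimulus-period ranking, injectable
pairwise lagged synchrony, and a configurable fraction of incorrect trials
with attenuated delay modulation.

Spikes are drawn as an inhomogeneous Poisson process discretised to 1-ms
bins by Bernoulli thinning (at most one spike per bin), matching the binary
0/1-per-bin convention of threshold-crossing multiunit activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .session import SessionData, events_from_arrays

log = logging.getLogger(__name__)

#: stimulus-period gain multipliers, strongest to weakest condition
DEFAULT_STIM_LEVELS = (6.0, 4.0, 2.5, 1.5)
#: delay-period additive rate offsets in sp/s, strongest to weakest
DEFAULT_DELAY_LEVELS = (2.0, 0.7, -0.7, -2.0)


@dataclass
class SimConfig:
    """Generative parameters for one synthetic DMTS session.

    ``stim_gain`` and ``delay_delta`` are (n_electrodes, n_conditions)
    arrays: multiplicative cue-response gains and additive delay-rate
    offsets (sp/s). ``sync_pairs`` entries are
    ``(electrode_a, electrode_b, copy_probability, lag_ms, epoch)``.
    """

    n_electrodes: int = 8
    n_conditions: int = 4
    n_trials_per_condition: int = 400
    #: pre-cue recording span (ms); the window is [-pre_ms, trial_duration_ms)
    pre_ms: float = 300.0
    #: post-cue recording span (ms)
    trial_duration_ms: float = 1800.0
    cue_window: tuple[float, float] = (0.0, 200.0)
    delay_window: tuple[float, float] = (700.0, 1700.0)
    baseline_rate: float = 10.0
    stim_gain: np.ndarray | None = None
    delay_delta: np.ndarray | None = None
    off_response_amp: float = 15.0
    off_response_tau_ms: float = 100.0
    incorrect_fraction: float = 0.05
    incorrect_attenuation: float = 0.25
    sync_pairs: list = field(default_factory=list)
    clip_rates: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_condition <= 0:
            raise ValueError("zero trials per condition")
        if not 0.0 <= self.incorrect_fraction <= 1.0:
            raise ValueError("incorrect_fraction must be in [0, 1]")
        if not 0.0 <= self.incorrect_attenuation <= 1.0:
            raise ValueError("incorrect_attenuation must be in [0, 1]")
        for pair in self.sync_pairs:
            if abs(pair[3]) > 40:
                raise ValueError("sync lag_ms must be within +/-40 ms")
        if self.stim_gain is not None:
            self.stim_gain = np.asarray(self.stim_gain, dtype=float)
        if self.delay_delta is not None:
            self.delay_delta = np.asarray(self.delay_delta, dtype=float)

    @property
    def conditions(self) -> list[str]:
        return [f"c{i}" for i in range(self.n_conditions)]

    def resolved_tuning(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-electrode tuning arrays, drawing defaults when unset.

        Default stimulus gains and delay deltas are fixed level sets assigned
        to conditions by per-electrode random permutations; the delay
        permutation is drawn independently of the stimulus one, so the two
        epochs' condition rankings are unrelated.
        """
        rng = np.random.default_rng(self.seed + 777)
        e, c = self.n_electrodes, self.n_conditions
        stim = self.stim_gain
        if stim is None:
            levels = np.resize(DEFAULT_STIM_LEVELS, c)
            stim = np.stack([levels[rng.permutation(c)] for _ in range(e)])
        delay = self.delay_delta
        if delay is None:
            levels = np.resize(DEFAULT_DELAY_LEVELS, c)
            delay = np.stack([levels[rng.permutation(c)] for _ in range(e)])
        if stim.shape != (e, c) or delay.shape != (e, c):
            raise ValueError("tuning arrays must be (n_electrodes, n_conditions)")
        return stim, delay


def equal_ranking_config(config: SimConfig) -> SimConfig:
    """Variant whose delay ranking copies the stimulus ranking (contrast tests)."""
    stim, _ = config.resolved_tuning()
    order = np.argsort(np.argsort(-stim, axis=1), axis=1)
    levels = np.resize(DEFAULT_DELAY_LEVELS, config.n_conditions)
    return replace(config, stim_gain=stim, delay_delta=levels[order])


def fixation_config(config: SimConfig) -> SimConfig:
    """Variant with no delay-period content modulation (fixation control)."""
    stim, delay = config.resolved_tuning()
    return replace(config, stim_gain=stim, delay_delta=np.zeros_like(delay))


def rate_profile(config: SimConfig, electrode: int, condition: int,
                 attenuation: float = 1.0) -> np.ndarray:
    """Firing-rate profile (sp/s) over 1-ms bins spanning the recording window."""
    stim, delay = config.resolved_tuning()
    t = np.arange(-config.pre_ms, config.trial_duration_ms)
    rate = np.full(t.shape, config.baseline_rate, dtype=float)
    c0, c1 = config.cue_window
    in_cue = (t >= c0) & (t < c1)
    rate[in_cue] = config.baseline_rate * stim[electrode, condition]
    post = t >= c1
    rate[post] += config.off_response_amp * np.exp(-(t[post] - c1) / config.off_response_tau_ms)
    d0, d1 = config.delay_window
    in_delay = (t >= d0) & (t < d1)
    rate[in_delay] += attenuation * delay[electrode, condition]
    if (rate < 0).any():
        if not config.clip_rates:
            raise ValueError("negative firing rate; enable clip_rates or adjust deltas")
        rate = np.clip(rate, 0.0, None)
    return rate


def simulate_session(config: SimConfig, task_id: str = "dmts",
                     session_id: str = "sim") -> SessionData:
    """Generate one synthetic session as inhomogeneous-Poisson binary trains.

    Per condition, ``floor(incorrect_fraction * n)`` trials are marked
    incorrect and their delay-period rate offsets are scaled by
    ``incorrect_attenuation``. Identical configs (including seed) give
    byte-identical sessions.
    """
    rng = np.random.default_rng(config.seed)
    e, c, n = config.n_electrodes, config.n_conditions, config.n_trials_per_condition
    t_start, t_stop = -config.pre_ms, config.trial_duration_ms
    n_bins = int(round(t_stop - t_start))

    # acquisition order: conditions randomly interleaved
    cond_of_trial = np.repeat(np.arange(c), n)
    rng.shuffle(cond_of_trial)
    n_trials = c * n
    n_inc = int(np.floor(config.incorrect_fraction * n))
    correct = np.ones(n_trials, dtype=bool)
    for ci in range(c):
        idx = np.flatnonzero(cond_of_trial == ci)
        correct[rng.choice(idx, size=n_inc, replace=False)] = False

    # Bernoulli-thinned profiles: p(spike in 1-ms bin) = rate / 1000
    profiles = np.empty((e, c, 2, n_bins))
    for ei in range(e):
        for ci in range(c):
            profiles[ei, ci, 0] = rate_profile(config, ei, ci, 1.0)
            profiles[ei, ci, 1] = rate_profile(config, ei, ci, config.incorrect_attenuation)

    rows_t, rows_e, rows_time = [], [], []
    p = profiles * 1e-3
    np.clip(p, 0.0, 1.0, out=p)
    for trial in range(n_trials):
        ci = cond_of_trial[trial]
        prof = p[:, ci, 0 if correct[trial] else 1]  # (e, n_bins)
        spikes = rng.random((e, n_bins)) < prof
        eid, b = np.nonzero(spikes)
        rows_t.append(np.full(len(eid), trial))
        rows_e.append(eid)
        rows_time.append(t_start + b.astype(float))

    events = events_from_arrays(
        np.concatenate(rows_t), np.concatenate(rows_e),
        np.concatenate(rows_e) * 0, np.concatenate(rows_time))
    conditions = config.conditions
    trials = pd.DataFrame({
        "trial_id": np.arange(n_trials),
        "condition": [conditions[ci] for ci in cond_of_trial],
        "task_id": task_id,
        "correct": correct,
        "session_id": session_id,
    })
    session = SessionData(events, trials, t_start, t_stop,
                          meta={"seed": config.seed, "task_id": task_id})
    for (a, b_el, prob, lag, epoch) in config.sync_pairs:
        session = inject_pairwise_synchrony(
            session, (a, b_el), prob, lag, epoch,
            rng=np.random.default_rng(config.seed + 10_000 + 131 * a + b_el))
    return session


def inject_pairwise_synchrony(session: SessionData, pair: tuple[int, int],
                              copy_probability: float, lag_ms: float,
                              epoch: tuple[float, float],
                              rng: np.random.Generator | None = None,
                              seed: int | None = None) -> SessionData:
    """Copy source spikes to a target electrode at a fixed lag.

    Each spike of ``pair[0]`` inside ``epoch`` is duplicated onto ``pair[1]``
    at ``+lag_ms`` with probability ``copy_probability``; copies falling
    outside the recording window are dropped (count logged). Ground truth
    for the functional-connectivity stage.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    src, dst = pair
    ev = session.events
    for el in (src, dst):
        if el not in set(ev.electrode_id):
            raise ValueError(f"electrode {el} absent from session")
    if not (session.t_start <= epoch[0] < epoch[1] <= session.t_stop):
        raise ValueError("epoch outside recording window")
    if copy_probability <= 0:
        return session
    t = ev.time_ms.to_numpy()
    sel = (ev.electrode_id.to_numpy() == src) & (t >= epoch[0]) & (t < epoch[1])
    src_idx = np.flatnonzero(sel)
    copied = src_idx[rng.random(len(src_idx)) < copy_probability]
    new_t = t[copied] + lag_ms
    inside = (new_t >= session.t_start) & (new_t < session.t_stop)
    n_dropped = int((~inside).sum())
    if n_dropped:
        log.info("synchrony injection dropped %d out-of-window copies", n_dropped)
    add = events_from_arrays(
        ev.trial_id.to_numpy()[copied][inside],
        np.full(int(inside.sum()), dst),
        np.zeros(int(inside.sum()), dtype=int),
        new_t[inside])
    events = pd.concat([ev, add], ignore_index=True)
    out = SessionData(events, session.trials, session.t_start, session.t_stop,
                      session.bin_ms, dict(session.meta))
    out.meta["synchrony_dropped"] = out.meta.get("synchrony_dropped", 0) + n_dropped
    return out


#: biphasic unit waveform applied at each spike sample (peak |value| = 1)
SPIKE_KERNEL = np.array([1.0, -0.6, -0.25])


def synthesize_raw_trace(spike_times: np.ndarray, noise_sd: float,
                         spike_amp: float, duration: float, dt: float,
                         seed: int | None = None) -> np.ndarray:
    """Gaussian-noise voltage trace with a biphasic deflection per spike.

    ``spike_times``, ``duration`` and ``dt`` are in ms; the waveform's peak
    absolute amplitude equals ``spike_amp`` at each spike time. Fixture for
    threshold-crossing event detection.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if spike_amp <= 0:
        raise ValueError("spike_amp must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    trace = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    for t in np.asarray(spike_times, dtype=float):
        i = int(round(t / dt))
        for k, w in enumerate(SPIKE_KERNEL):
            if 0 <= i + k < n:
                trace[i + k] += spike_amp * w
    return trace
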