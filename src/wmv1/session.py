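"""Session container: spike events plus trial metadata, aligned to cue onset.

All spike times are in milliseconds relative to cue onset (signed). Trials
carry a content condition label, a task identifier, a correct/incorrect flag
and a session identifier. The container validates referential integrity and
offers the binned and windowed views the analysis stages consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EVENT_COLUMNS = ["trial_id", "electrode_id", "unit_id", "time_ms"]
TRIAL_COLUMNS = ["trial_id", "condition", "task_id", "correct", "session_id"]


@dataclass
class SessionData:
    """Spike events and trial metadata for one task/experiment.

    Parameters
    ----------
    events : DataFrame with columns (trial_id, electrode_id, unit_id, time_ms).
    trials : DataFrame with columns (trial_id, condition, task_id, correct,
        session_id), one row per trial, in acquisition order.
    t_start, t_stop : recording window in ms relative to cue onset; events
        must fall in ``[t_start, t_stop)``.
    bin_ms : resolution at which spikes were (or will be) binned.
    """

    events: pd.DataFrame
    trials: pd.DataFrame
    t_start: float
    t_stop: float
    bin_ms: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = self.events.reset_index(drop=True)
        self.trials = self.trials.reset_index(drop=True)
        errors = self.validate()
        if errors:
            raise ValueError("invalid session: " + "; ".join(errors))

    # -- validation ---------------------------------------------------------
    def validate(self) -> list[str]:
        errors: list[str] = []
        missing = set(EVENT_COLUMNS) - set(self.events.columns)
        if missing:
            errors.append(f"events missing columns {sorted(missing)}")
        missing = set(TRIAL_COLUMNS) - set(self.trials.columns)
        if missing:
            errors.append(f"trials missing columns {sorted(missing)}")
        if errors:
            return errors
        if self.trials.trial_id.duplicated().any():
            errors.append("duplicate trial ids")
        orphans = set(self.events.trial_id) - set(self.trials.trial_id)
        if orphans:
            errors.append(f"events reference missing trials {sorted(orphans)[:5]}")
        t = self.events.time_ms.to_numpy()
        if len(t) and (t.min() < self.t_start or t.max() >= self.t_stop):
            errors.append("event times outside recording window")
        if not self.t_start < self.t_stop:
            errors.append("empty recording window")
        return errors

    # -- basic views --------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def electrodes(self) -> np.ndarray:
        return np.unique(self.events.electrode_id)

    @property
    def conditions(self) -> np.ndarray:
        return np.unique(self.trials.condition)

    def condition_labels(self) -> np.ndarray:
        """Condition label per trial, in acquisition order."""
        return self.trials.condition.to_numpy()

    def correct_mask(self) -> np.ndarray:
        return self.trials.correct.to_numpy().astype(bool)

    def subset_trials(self, mask: np.ndarray) -> "SessionData":
        """Session restricted to the trials selected by a boolean mask."""
        keep = self.trials.trial_id.to_numpy()[np.asarray(mask, bool)]
        ev = self.events[self.events.trial_id.isin(keep)]
        tr = self.trials[self.trials.trial_id.isin(keep)]
        return SessionData(ev, tr, self.t_start, self.t_stop, self.bin_ms, dict(self.meta))

    # -- numeric views ------------------------------------------------------
    def spike_counts(self, window: tuple[float, float],
                     electrodes: np.ndarray | None = None) -> np.ndarray:
        """Trial x electrode spike counts in the half-open window [start, end)."""
        start, end = window
        if not start < end:
            raise ValueError("empty window")
        return self.binned_counts(window, electrodes=electrodes,
                                  bin_ms=end - start)[:, :, 0].astype(float)

    def binned(self, window: tuple[float, float], electrode, unit=None,
               bin_ms: float | None = None) -> np.ndarray:
        """Trial x bin binary (0/1 per bin) array for one electrode (or unit).

        Bins are half-open ``[t, t + bin_ms)`` starting at ``window[0]``.
        Multiple spikes in one bin count as 1, matching the binary-bin
        convention of threshold-crossing multiunit activity.
        """
        bin_ms = self.bin_ms if bin_ms is None else bin_ms
        start, end = window
        n_bins = int(round((end - start) / bin_ms))
        trial_ids = self.trials.trial_id.to_numpy()
        trow = {t: i for i, t in enumerate(trial_ids)}
        out = np.zeros((len(trial_ids), n_bins), dtype=np.int8)
        ev = self.events
        sel = (ev.electrode_id == electrode)
        if unit is not None:
            sel &= (ev.unit_id == unit)
        ev = ev[sel]
        t = ev.time_ms.to_numpy()
        inwin = (t >= start) & (t < end)
        bins = ((t[inwin] - start) / bin_ms).astype(int)
        rows = np.fromiter((trow[i] for i in ev.trial_id.to_numpy()[inwin]),
                           dtype=int, count=int(inwin.sum()))
        out[rows, bins] = 1
        return out

    def binned_counts(self, window: tuple[float, float],
                      electrodes: np.ndarray | None = None,
                      bin_ms: float | None = None) -> np.ndarray:
        """Trial x electrode x bin spike-count array (not clipped to 0/1)."""
        bin_ms = self.bin_ms if bin_ms is None else bin_ms
        start, end = window
        n_bins = int(round((end - start) / bin_ms))
        electrodes = self.electrodes if electrodes is None else np.asarray(electrodes)
        trial_ids = self.trials.trial_id.to_numpy()
        trow = {t: i for i, t in enumerate(trial_ids)}
        ecol = {e: i for i, e in enumerate(electrodes)}
        out = np.zeros((len(trial_ids), len(electrodes), n_bins), dtype=np.int32)
        t = self.events.time_ms.to_numpy()
        inwin = (t >= start) & (t < end)
        ev = self.events[inwin]
        rows = ev.trial_id.map(trow).to_numpy()
        cols = ev.electrode_id.map(ecol).to_numpy()
        keep = ~pd.isna(cols)
        bins = ((ev.time_ms.to_numpy()[keep] - start) / bin_ms).astype(int)
        np.add.at(out, (rows[keep].astype(int), cols[keep].astype(int), bins), 1)
        return out


def events_from_arrays(trial_id, electrode_id, unit_id, time_ms) -> pd.DataFrame:
    return pd.DataFrame({
        "trial_id": np.asarray(trial_id, dtype=np.int64),
        "electrode_id": np.asarray(electrode_id, dtype=np.int64),
        "unit_id": np.asarray(unit_id, dtype=np.int64),
        "time_ms": np.asarray(time_ms, dtype=np.float64),
    })
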