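"""Session file format, run configuration, and the end-to-end pipeline.

Sessions are stored as an HDF5 container (``/events`` table, ``/trials``
table, ``/meta`` attributes) with the trial table mirrored as a standalone
CSV next to it. Every numeric output is stamped with (schema version,
config hash, seed) so identical triples reproduce identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import cmi as cmi_mod
from . import connectivity as conn_mod
from . import decode as decode_mod
from . import preprocess as pre_mod
from .preprocess import EpochSpec
from .session import EVENT_COLUMNS, TRIAL_COLUMNS, SessionData

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """All tunable constants of the pipeline, serialised into every output."""

    epochs: EpochSpec = field(default_factory=EpochSpec)
    batch_size: int = 20
    window_width: float = 200.0
    window_step: float = 50.0
    repetitions: int = 1000
    train_per_condition: int = 15
    tuning_floor: float = 0.01
    jitter_window: int = 25
    jitter_rounds: int = 3
    sd_multiplier: float = 7.0
    max_lag: int = 40
    cv_folds: int = 20
    cv_iters: int = 200
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for name in ("window_width", "window_step", "jitter_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["epochs"] = dataclasses.asdict(self.epochs)
        return d

    def hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir")  # analysis parameters only, not output placement
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "epochs" in d:
            d["epochs"] = EpochSpec(**{k: tuple(v) for k, v in d["epochs"].items()})
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def write_session(session: SessionData, path: str | Path,
                  csv_path: str | Path | None = None) -> None:
    """Write a session to HDF5 (+ mirrored CSV trial table)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        ev = f.create_group("events")
        for col in EVENT_COLUMNS:
            ev.create_dataset(col, data=session.events[col].to_numpy())
        tr = f.create_group("trials")
        for col in TRIAL_COLUMNS:
            data = session.trials[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            tr.create_dataset(col, data=data)
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["t_start"] = session.t_start
        f.attrs["t_stop"] = session.t_stop
        f.attrs["bin_ms"] = session.bin_ms
        f.attrs["meta_json"] = json.dumps(session.meta, default=str)
    csv_path = path.with_suffix(".trials.csv") if csv_path is None else Path(csv_path)
    session.trials.to_csv(csv_path, index=False)


def read_session(path: str | Path) -> SessionData:
    """Read and validate a session container; raises on schema violations."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(f"unknown schema version {version}")
        events = pd.DataFrame({c: f["events"][c][...] for c in EVENT_COLUMNS})
        trials = {}
        for c in TRIAL_COLUMNS:
            data = f["trials"][c][...]
            if data.dtype.kind == "S":
                data = data.astype(str)
            trials[c] = data
        trials = pd.DataFrame(trials)
        session = SessionData(events, trials, float(f.attrs["t_start"]),
                              float(f.attrs["t_stop"]), float(f.attrs["bin_ms"]),
                              json.loads(f.attrs["meta_json"]))
    if len(trials) == 0:
        log.warning("session %s has no trials", path)
    return session


def _stamp(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    df = df.copy()
    df["schema_version"] = SCHEMA_VERSION
    df["config_hash"] = config.hash()
    df["seed"] = config.seed
    return df


def run_pipeline(config: RunConfig, session_paths: list[str | Path]) -> dict:
    """Chain preprocess -> CMI -> decoding -> connectivity over sessions.

    Writes stamped CSV artifacts under ``config.out_dir`` and returns a
    report dictionary with the per-stage counts and headline statistics.
    Any stage failure aborts with the stage name and offending input.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.hash(), "seed": config.seed,
                    "sessions": []}
    for path in session_paths:
        entry: dict = {"path": str(path)}
        try:
            session = read_session(path)
        except Exception as exc:
            raise RuntimeError(f"stage=read session={path}: {exc}") from exc
        name = Path(path).stem
        epochs = config.epochs
        try:
            delay_rates = cmi_mod.epoch_rates(session, epochs.delay)
            keep = pre_mod.reject_artifact_trials(delay_rates.mean(axis=1))
            session_qc = session.subset_trials(keep)
            entry["trials_total"] = int(session.n_trials)
            entry["trials_kept"] = int(keep.sum())
        except Exception as exc:
            raise RuntimeError(f"stage=preprocess session={path}: {exc}") from exc
        try:
            rates = cmi_mod.epoch_rates(session_qc, epochs.delay)
            labels = session_qc.condition_labels()
            hl = cmi_mod.designate_hl(rates, labels)
            values = cmi_mod.compute_cmi(rates, labels, hl)
            cmi_df = pd.DataFrame({
                "electrode_id": [p.electrode_id for p in hl],
                "epoch": "delay",
                "cmi": values,
                "cond_high": [p.cond_high for p in hl],
                "cond_low": [p.cond_low for p in hl],
                "n_trials": session_qc.n_trials,
                "valid": ~np.isnan(values),
            })
            _stamp(cmi_df, config).to_csv(out_dir / f"{name}_cmi.csv", index=False)
            entry["mean_cmi"] = float(np.nanmean(values))
        except Exception as exc:
            raise RuntimeError(f"stage=cmi session={path}: {exc}") from exc
        try:
            windows = decode_mod.make_windows(
                (session_qc.t_start, session_qc.t_stop),
                config.window_width, config.window_step)
            batches = decode_mod.make_batches(session_qc, windows,
                                              config.batch_size)
            matrix = decode_mod.cross_temporal_matrix(
                batches, config.train_per_condition, config.repetitions,
                config.tuning_floor, seed=config.seed)
            acc_df = pd.DataFrame(matrix.accuracy,
                                  columns=[f"test_{int(w[0])}" for w in windows])
            acc_df.insert(0, "train_start", [w[0] for w in windows])
            _stamp(acc_df, config).to_csv(out_dir / f"{name}_decoding.csv",
                                          index=False)
            entry["peak_accuracy"] = float(matrix.accuracy.max())
            entry["chance"] = matrix.chance
        except Exception as exc:
            raise RuntimeError(f"stage=decode session={path}: {exc}") from exc
        try:
            rows = []
            electrodes = session_qc.electrodes
            conditions = session_qc.conditions
            pairs = [(int(a), int(b)) for i, a in enumerate(electrodes)
                     for b in electrodes[i + 1:]]
            stim_results, delay_results = [], []
            for cond in conditions:
                for pair in pairs:
                    for epoch, ename, store in ((epochs.stimulus, "stimulus", stim_results),
                                                (epochs.delay, "delay", delay_results)):
                        r = conn_mod.ccg_analysis(
                            session_qc, pair, cond, epoch, ename,
                            config.jitter_window, config.jitter_rounds,
                            config.sd_multiplier, config.max_lag,
                            seed=config.seed)
                        store.append(r)
                        rows.append({
                            "pair_a": pair[0], "pair_b": pair[1],
                            "condition": cond, "epoch": ename,
                            "peak": float(r.corrected[r.lags == r.peak_lag][0])
                            if r.valid else np.nan,
                            "peak_lag": r.peak_lag, "noise_sd": r.noise_sd,
                            "significant": r.significant, "valid": r.valid,
                        })
            summary = conn_mod.categorize_fc(stim_results, delay_results)
            ccg_df = pd.DataFrame(rows)
            _stamp(ccg_df, config).to_csv(out_dir / f"{name}_ccg.csv", index=False)
            entry["fc_proportions"] = summary.proportions
            entry["fc_denominator_undefined"] = summary.denominator_undefined
        except Exception as exc:
            raise RuntimeError(f"stage=connectivity session={path}: {exc}") from exc
        report["sessions"].append(entry)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
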