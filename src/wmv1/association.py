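"""Association-task machinery.

Early/late training-stage definition from session accuracies, antagonistic
cue-probe pairing from two source tasks' delay-period population rates,
stagewise CMI contrasts with the h/l designation held fixed from the early
stage, and a principal-component projection of CMI time courses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .cmi import compute_cmi, delta_cmi_abs, designate_hl, epoch_rates
from .preprocess import boxcar_smooth


@dataclass
class StageAssignment:
    early_sessions: list[int]
    late_sessions: list[int]
    overlap_flag: bool = False
    late_empty_flag: bool = False


def define_stages(sessions: list[tuple[float, int]],
                  early_correct: int = 1000,
                  late_accuracy: float = 0.90,
                  include_breaking_session: bool = False) -> StageAssignment:
    """Assign sessions to the early and late training stages.

    ``sessions`` is an ordered list of (accuracy, n_correct) per session.
    Early = the shortest prefix accumulating >= ``early_correct`` correct
    trials. Late = the longest suffix whose unweighted mean accuracy stays
    >= ``late_accuracy``; the session whose inclusion drops the mean below
    the bar is excluded unless ``include_breaking_session``.
    """
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions")
    acc = np.array([s[0] for s in sessions], dtype=float)
    n_correct = np.array([s[1] for s in sessions], dtype=int)
    if n_correct.sum() < early_correct:
        raise ValueError(f"total correct trials < {early_correct}")
    cum = np.cumsum(n_correct)
    early_end = int(np.searchsorted(cum, early_correct)) + 1
    early = list(range(early_end))

    late: list[int] = []
    n = len(sessions)
    for start in range(n - 1, -1, -1):
        if acc[start:].mean() >= late_accuracy:
            late = list(range(start, n))
        else:
            if include_breaking_session and late:
                late = [start] + late
            break
    assignment = StageAssignment(early, late)
    if not late:
        assignment.late_empty_flag = True
    elif set(early) & set(late):
        assignment.overlap_flag = True
    return assignment


def select_antagonistic_pairs(task_a_means: dict[str, float],
                              task_b_means: dict[str, float]) -> list[tuple[str, str]]:
    """Pair each task's extreme delay-firing conditions antagonistically.

    Returns [(argmax of task A, argmin of task B), (argmin of task A,
    argmax of task B)]; with more than two conditions per task only the two
    extremes are used. Ties are broken by label sort order.
    """
    def extremes(means: dict[str, float]) -> tuple[str, str]:
        labels = sorted(means)
        vals = np.array([means[l] for l in labels])
        return labels[int(np.argmax(vals))], labels[int(np.argmin(vals))]

    a_hi, a_lo = extremes(task_a_means)
    b_hi, b_lo = extremes(task_b_means)
    return [(a_hi, b_lo), (a_lo, b_hi)]


@dataclass
class StageContrast:
    cmi_early: np.ndarray
    cmi_late: np.ndarray
    delta_late_cct: np.ndarray
    delta_early_cct: np.ndarray
    delta_late_oot: np.ndarray
    delta_early_oot: np.ndarray
    hl_pairs: list = field(default_factory=list)


def stage_cmi_contrast(session_early, session_late, session_cct, session_oot,
                       epoch: tuple[float, float] = (1200.0, 1700.0),
                       correct_only: bool = True) -> StageContrast:
    """Stagewise CMI comparison with the early-stage h/l pair held fixed.

    CMIs are computed in the later-delay window for the early and late
    association stages and the two reference tasks (color-color, CCT, and
    orientation-orientation, OOT), all with the minuend/subtrahend roles
    designated in the early stage, then contrasted as |dCMI| per electrode.
    Electrodes invalid (NaN) in any dataset are dropped from the deltas by
    NaN propagation.
    """
    def rates_labels(s):
        if correct_only:
            s = s.subset_trials(s.correct_mask())
        return epoch_rates(s, epoch), s.condition_labels()

    r_early, l_early = rates_labels(session_early)
    hl = designate_hl(r_early, l_early, source_dataset="early",
                      source_epoch=f"[{epoch[0]},{epoch[1]})")
    cmi_early = compute_cmi(r_early, l_early, hl)
    out = {}
    for name, s in (("late", session_late), ("cct", session_cct),
                    ("oot", session_oot)):
        r, l = rates_labels(s)
        out[name] = compute_cmi(r, l, hl)
    return StageContrast(
        cmi_early, out["late"],
        delta_cmi_abs(out["late"], out["cct"]),
        delta_cmi_abs(cmi_early, out["cct"]),
        delta_cmi_abs(out["late"], out["oot"]),
        delta_cmi_abs(cmi_early, out["oot"]),
        hl)


@dataclass
class CmiTrajectory:
    projections: dict[str, np.ndarray]   # name -> (3, n_time) smoothed
    variance_fractions: np.ndarray
    times: np.ndarray


def cmi_trajectory_pca(fit_matrices: list[np.ndarray],
                       project: dict[str, np.ndarray],
                       times: np.ndarray,
                       n_components: int = 3,
                       smooth_ms: float = 100.0,
                       interp_ms: float = 10.0) -> CmiTrajectory:
    """Project electrode x time CMI matrices onto shared principal components.

    Components are fitted on the pooled ``fit_matrices`` (time points as
    samples, electrodes as features, per-electrode mean over pooled time
    removed), then every requested dataset is projected; trajectories are
    linearly interpolated onto a ``interp_ms`` grid and smoothed with a
    ``smooth_ms`` boxcar after projection. Variance fractions are per
    fitted component.
    """
    times = np.asarray(times, dtype=float)
    n_electrodes = fit_matrices[0].shape[0]
    if n_electrodes < n_components:
        raise ValueError("fewer electrodes than components")
    if np.median(np.diff(times)) > smooth_ms:
        raise ValueError("time step must not exceed the smoothing width")
    pooled = np.concatenate([m.T for m in fit_matrices], axis=0)  # (T*, E)
    pca = PCA(n_components=n_components)
    pca.fit(pooled)
    t_grid = np.arange(times[0], times[-1] + 1e-9, interp_ms)
    width = max(1, int(round(smooth_ms / interp_ms)))
    projections = {}
    for name, mat in project.items():
        pcs = pca.transform(mat.T).T                      # (k, T)
        interp = np.stack([np.interp(t_grid, times, pc) for pc in pcs])
        projections[name] = np.stack([boxcar_smooth(pc, width) for pc in interp])
    return CmiTrajectory(projections, pca.explained_variance_ratio_, t_grid)
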