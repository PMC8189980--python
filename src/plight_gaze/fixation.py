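"""Binocular fixation detection with individual adaptive velocity thresholds.

Fixations are the units over which looking time accrues.  The detector is a
binocular individual-threshold scheme: each eye gets its own velocity cutoff
estimated iteratively from that participant's own speed distribution
(mean + k*SD of the sub-cutoff speeds, iterated to a fixed point), a sample
is fixational only when *both* eyes are below their cutoffs, and runs of
fixational samples become fixations subject to two count rules — at least
``min_tracked_samples`` tracked samples, and no internal run of untracked
samples longer than ``max_consecutive_untracked`` (both default 3).

Velocities are never interpolated across tracking loss: a sample pair
spanning an untracked sample has undefined speed, and untracked samples
inside a fixation contribute neither position nor looking time; they only
bridge the run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gaze_synth import GazeRecording
from .geometry import ScreenGeometry
from .stimulus import InsufficientDataError, SceneClip

__all__ = [
    "FixationParams",
    "Fixation",
    "sample_velocities",
    "estimate_threshold",
    "detect_fixations",
    "assign_trials",
]


@dataclass
class FixationParams:
    min_tracked_samples: int = 3
    max_consecutive_untracked: int = 3
    threshold_k: float = 3.0
    convergence_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.min_tracked_samples < 1:
            raise ValueError("min_tracked_samples must be >= 1")
        if self.max_consecutive_untracked < 0:
            raise ValueError("max_consecutive_untracked must be >= 0")


@dataclass
class Fixation:
    start_ms: float
    end_ms: float
    centroid_px: tuple[float, float]
    n_tracked: int
    trial_id: str | None = None
    sample_idx: np.ndarray | None = None  # indices of the tracked samples

    def __post_init__(self) -> None:
        if self.end_ms <= self.start_ms:
            raise ValueError("end_ms must exceed start_ms")


def sample_velocities(
    recording: GazeRecording, geometry: ScreenGeometry
) -> dict[str, np.ndarray]:
    """Per-eye angular speed (deg/s) between consecutive samples.

    Entry ``i`` is the speed over the interval from sample ``i`` to ``i+1``;
    it is NaN whenever either endpoint is untracked for that eye.
    """
    if recording.n_samples < 2:
        raise InsufficientDataError("need at least 2 samples")
    ppd = geometry.pixels_per_degree
    dt_s = np.diff(recording.t_ms) / 1000.0
    out = {}
    for eye, x, y, valid in (
        ("left", recording.lx_px, recording.ly_px, recording.l_valid),
        ("right", recording.rx_px, recording.ry_px, recording.r_valid),
    ):
        disp = np.hypot(np.diff(x), np.diff(y)) / ppd
        speed = disp / dt_s
        speed[~(valid[:-1] & valid[1:])] = np.nan
        out[eye] = speed
    return out


def estimate_threshold(
    speeds: np.ndarray,
    threshold_k: float = 3.0,
    convergence_tol: float = 1e-3,
    max_iter: int = 200,
) -> float:
    """Iterative adaptive velocity cutoff: mean + k*SD of sub-cutoff speeds.

    Starts from all defined speeds and re-estimates until the relative
    change falls below ``convergence_tol``.  A degenerate (constant) speed
    distribution converges immediately to that constant.
    """
    s = np.asarray(speeds, float)
    s = s[np.isfinite(s)]
    if len(s) < 3:
        raise InsufficientDataError("need at least 3 defined speeds")
    cutoff = s.mean() + threshold_k * s.std()
    for _ in range(max_iter):
        sel = s[s <= cutoff]
        if len(sel) == 0:
            break
        new = sel.mean() + threshold_k * sel.std()
        denom = cutoff if cutoff > 0 else 1.0
        done = abs(new - cutoff) / denom < convergence_tol
        cutoff = new
        if done:
            break
    return float(cutoff)


def detect_fixations(
    recording: GazeRecording,
    geometry: ScreenGeometry,
    params: FixationParams | None = None,
    scenes: list[SceneClip] | None = None,
) -> list[Fixation]:
    """Detect fixations from a binocular recording.

    A sample is fixational iff it is tracked in both eyes and at least one
    adjacent inter-sample interval has both eyes' speeds defined and below
    their per-eye cutoffs (binocular AND).  Maximal fixational runs are
    kept, tolerating internal untracked runs up to the configured limit;
    runs with fewer tracked samples than required are discarded.  The
    centroid is the mean cyclopean position of the tracked samples.
    """
    params = params or FixationParams()
    n = recording.n_samples
    if n == 0:
        return []
    if n < 2:
        return []
    speeds = sample_velocities(recording, geometry)
    cut = {}
    try:
        for eye in ("left", "right"):
            cut[eye] = estimate_threshold(
                speeds[eye], params.threshold_k, params.convergence_tol
            )
    except InsufficientDataError:
        return []  # nothing tracked well enough to calibrate a threshold
    defined = np.isfinite(speeds["left"]) & np.isfinite(speeds["right"])
    interval_fix = np.zeros(n - 1, dtype=bool)
    interval_fix[defined] = (speeds["left"][defined] <= cut["left"]) & (
        speeds["right"][defined] <= cut["right"]
    )
    interval_sacc = defined & ~interval_fix
    sample_fix = np.zeros(n, dtype=bool)
    sample_fix[:-1] |= interval_fix
    sample_fix[1:] |= interval_fix

    tracked = recording.l_valid & recording.r_valid
    is_fix = tracked & sample_fix
    is_sacc = tracked & ~sample_fix

    fix_idx = np.flatnonzero(is_fix)
    if len(fix_idx) == 0:
        return []
    # break between consecutive fixational samples if a saccadic sample or a
    # defined above-threshold interval intervenes, or the untracked gap is
    # too long (a one-interval saccade must split the two fixations even
    # though both flanking samples are locally fixational)
    sacc_cum = np.concatenate([[0], np.cumsum(is_sacc)])
    isacc_cum = np.concatenate([[0], np.cumsum(interval_sacc)])
    gaps = np.diff(fix_idx) - 1
    sacc_between = sacc_cum[fix_idx[1:]] - sacc_cum[fix_idx[:-1] + 1]
    isacc_between = isacc_cum[fix_idx[1:]] - isacc_cum[fix_idx[:-1]]
    brk = (
        (gaps > params.max_consecutive_untracked)
        | (sacc_between > 0)
        | (isacc_between > 0)
    )
    group = np.concatenate([[0], np.cumsum(brk)])

    dt = 1000.0 / recording.sample_rate_hz
    cyc_x, cyc_y = recording.cyclopean()
    fixations: list[Fixation] = []
    for g in range(group[-1] + 1):
        idx = fix_idx[group == g]
        if len(idx) < params.min_tracked_samples:
            continue
        fixations.append(
            Fixation(
                start_ms=float(recording.t_ms[idx[0]]),
                end_ms=float(recording.t_ms[idx[-1]] + dt),
                centroid_px=(float(np.mean(cyc_x[idx])), float(np.mean(cyc_y[idx]))),
                n_tracked=int(len(idx)),
                sample_idx=idx,
            )
        )
    if scenes is not None:
        assign_trials(fixations, scenes)
    return fixations


def assign_trials(fixations: list[Fixation], scenes: list[SceneClip]) -> None:
    """Assign each fixation to the trial whose window contains its start."""
    scenes = sorted(scenes, key=lambda s: s.onset_ms)
    onsets = np.array([s.onset_ms for s in scenes])
    for fx in fixations:
        i = int(np.searchsorted(onsets, fx.start_ms, side="right")) - 1
        if i >= 0 and fx.start_ms < scenes[i].onset_ms + scenes[i].duration_ms:
            fx.trial_id = scenes[i].trial_id
        else:
            fx.trial_id = None
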