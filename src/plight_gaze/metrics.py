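"""Dynamic-ROI eye-movement metrics for preferential looking.

For every stimulus frame, each side's region of interest (ROI) is the union
of circles of fixed visual-angle radius centered on that side's dots, so the
ROIs move with the dots.  Looking time accrues per tracked fixation sample,
classified by which ROI contains the sample's cyclopean position at that
moment (ties go to the side of the nearest dot).

The per-participant metrics:

* ``total_valid_pct`` — % of stimulus-window samples with at least one eye
  tracked and the gaze position on the screen (the complement of data loss),
* ``preference_bio_pct`` — pooled ratio of biological-side looking time to
  all on-ROI looking time,
* ``first_fix_bio_pct`` — % of trials whose earliest ROI-assigned fixation
  was on the biological side (among trials with any ROI fixation),
* ``latency_bio_ms`` / ``latency_nonbio_ms`` — mean time from trial onset to
  the first fixation assigned to that side, over trials where it was fixated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fixation import Fixation, FixationParams, assign_trials, detect_fixations
from .gaze_synth import GazeRecording
from .geometry import ScreenGeometry, deg_to_px_xy
from .stimulus import SceneClip

__all__ = [
    "RoiConfig",
    "ParticipantMetrics",
    "roi_membership",
    "classify_samples",
    "total_valid_time",
    "preference_biological",
    "first_fixation_metrics",
    "compute_participant_metrics",
    "cohort_metrics_table",
]


@dataclass
class RoiConfig:
    radius_deg: float = 3.7
    assignment_rule: float = 0.5  # fraction of tracked samples inside an ROI

    def __post_init__(self) -> None:
        if self.radius_deg <= 0:
            raise ValueError("radius_deg must be positive")
        if not 0.0 < self.assignment_rule <= 1.0:
            raise ValueError("assignment_rule must lie in (0, 1]")


@dataclass
class ParticipantMetrics:
    participant_id: str
    total_valid_pct: float
    preference_bio_pct: float  # NaN when no on-ROI time
    first_fix_bio_pct: float
    latency_bio_ms: float
    latency_nonbio_ms: float
    n_trials_latency_bio: int = 0
    n_trials_latency_nonbio: int = 0

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "total_valid_pct": self.total_valid_pct,
            "preference_bio_pct": self.preference_bio_pct,
            "first_fix_bio_pct": self.first_fix_bio_pct,
            "latency_bio_ms": self.latency_bio_ms,
            "latency_nonbio_ms": self.latency_nonbio_ms,
        }


# ---------------------------------------------------------------------------
# ROI classification

def _side_dots_px(clip, frame_idx: np.ndarray, geometry: ScreenGeometry) -> np.ndarray:
    """Dot pixel positions for given frames: (n, points, 2)."""
    coords = clip.coords[frame_idx]  # (n, P, 2) degrees
    x, y = deg_to_px_xy(coords[..., 0], coords[..., 1], geometry)
    return np.stack([x, y], axis=-1)


def classify_samples(
    scene: SceneClip,
    t_ms: np.ndarray,
    x_px: np.ndarray,
    y_px: np.ndarray,
    roi: RoiConfig | None = None,
) -> np.ndarray:
    """Classify gaze samples into ROIs: 1 = bio, 2 = nonbio, 0 = neither.

    Samples outside the scene's presentation window are 0.  A sample inside
    both unions is assigned to the side of the nearest dot (tie -> bio).
    """
    roi = roi or RoiConfig()
    geometry = scene.geometry
    t_ms = np.asarray(t_ms, float)
    rel = t_ms - scene.onset_ms
    in_window = (rel >= 0) & (rel < scene.duration_ms)
    codes = np.zeros(len(t_ms), dtype=np.int8)
    if not in_window.any():
        return codes
    fidx = scene.bio_clip.frame_index(rel[in_window])
    pt = np.stack([np.asarray(x_px, float)[in_window], np.asarray(y_px, float)[in_window]], axis=-1)
    r_px = roi.radius_deg * geometry.pixels_per_degree

    d_bio = np.min(
        np.linalg.norm(_side_dots_px(scene.bio_clip, fidx, geometry) - pt[:, None, :], axis=-1),
        axis=1,
    )
    d_non = np.min(
        np.linalg.norm(_side_dots_px(scene.nonbio_clip, fidx, geometry) - pt[:, None, :], axis=-1),
        axis=1,
    )
    sub = np.zeros(int(in_window.sum()), dtype=np.int8)
    in_bio = d_bio <= r_px
    in_non = d_non <= r_px
    sub[in_non] = 2
    sub[in_bio & (~in_non | (d_bio <= d_non))] = 1
    codes[in_window] = sub
    return codes


def roi_membership(
    scene: SceneClip,
    t_ms: float,
    point_px: tuple[float, float],
    roi: RoiConfig | None = None,
) -> str:
    """Which ROI (if any) contains a single point at time ``t_ms``."""
    code = classify_samples(
        scene, np.array([t_ms]), np.array([point_px[0]]), np.array([point_px[1]]), roi
    )[0]
    return {0: "neither", 1: "bio", 2: "nonbio"}[int(code)]


# ---------------------------------------------------------------------------
# metrics

def _trial_windows_mask(recording: GazeRecording, scenes: list[SceneClip]) -> np.ndarray:
    scenes = sorted(scenes, key=lambda s: s.onset_ms)
    onsets = np.array([s.onset_ms for s in scenes])
    durs = np.array([s.duration_ms for s in scenes])
    idx = np.searchsorted(onsets, recording.t_ms, side="right") - 1
    ok = idx >= 0
    mask = np.zeros(recording.n_samples, dtype=bool)
    mask[ok] = recording.t_ms[ok] < onsets[idx[ok]] + durs[idx[ok]]
    return mask


def total_valid_time(
    recording: GazeRecording,
    scenes: list[SceneClip],
    geometry: ScreenGeometry | None = None,
) -> float:
    """Percentage of stimulus-window samples tracked and on the screen."""
    geometry = geometry or scenes[0].geometry
    mask = _trial_windows_mask(recording, scenes)
    n_total = int(mask.sum())
    if n_total == 0:
        return float("nan")
    x, y = recording.cyclopean()
    any_valid = recording.l_valid | recording.r_valid
    on_screen = (
        np.nan_to_num(x, nan=-1.0) >= 0
    ) & (x <= geometry.width_px) & (np.nan_to_num(y, nan=-1.0) >= 0) & (y <= geometry.height_px)
    good = mask & any_valid & on_screen
    return 100.0 * int(good.sum()) / n_total


def _fixation_sample_idx(fx: Fixation, recording: GazeRecording) -> np.ndarray:
    if fx.sample_idx is not None:
        return fx.sample_idx
    tracked = recording.l_valid & recording.r_valid
    within = (recording.t_ms >= fx.start_ms) & (recording.t_ms < fx.end_ms)
    return np.flatnonzero(within & tracked)


def _trial_fixation_stats(
    fixations: list[Fixation],
    scenes: list[SceneClip],
    recording: GazeRecording,
    roi: RoiConfig | None = None,
) -> list[dict]:
    """Per trial, per assigned fixation: on-ROI sample counts.

    Classification runs once per trial over the concatenated tracked samples
    of that trial's fixations.
    """
    roi = roi or RoiConfig()
    by_trial: dict[str, list[Fixation]] = {}
    for fx in fixations:
        if fx.trial_id is not None:
            by_trial.setdefault(fx.trial_id, []).append(fx)
    cyc_x, cyc_y = recording.cyclopean()
    out = []
    for scene in scenes:
        fxs = sorted(by_trial.get(scene.trial_id, []), key=lambda f: f.start_ms)
        if not fxs:
            continue
        idx_list = [_fixation_sample_idx(fx, recording) for fx in fxs]
        all_idx = np.concatenate(idx_list) if idx_list else np.array([], dtype=int)
        if len(all_idx) == 0:
            continue
        codes = classify_samples(
            scene, recording.t_ms[all_idx], cyc_x[all_idx], cyc_y[all_idx], roi
        )
        trial = {"scene": scene, "fixations": []}
        pos = 0
        for fx, idx in zip(fxs, idx_list):
            c = codes[pos : pos + len(idx)]
            pos += len(idx)
            trial["fixations"].append(
                {
                    "fixation": fx,
                    "n_samples": int(len(c)),
                    "n_bio": int(np.sum(c == 1)),
                    "n_nonbio": int(np.sum(c == 2)),
                }
            )
        out.append(trial)
    return out


def preference_biological(
    fixations: list[Fixation],
    scenes: list[SceneClip],
    recording: GazeRecording,
    roi: RoiConfig | None = None,
) -> float:
    """Pooled % of on-ROI fixation time spent on the biological side."""
    stats = _trial_fixation_stats(fixations, scenes, recording, roi)
    n_bio = sum(f["n_bio"] for tr in stats for f in tr["fixations"])
    n_non = sum(f["n_nonbio"] for tr in stats for f in tr["fixations"])
    if n_bio + n_non == 0:
        return float("nan")
    return 100.0 * n_bio / (n_bio + n_non)


def _assign_side(fx_stats: dict, rule: float) -> str | None:
    n = fx_stats["n_samples"]
    if n == 0:
        return None
    frac_bio = fx_stats["n_bio"] / n
    frac_non = fx_stats["n_nonbio"] / n
    if frac_bio >= rule and frac_bio >= frac_non:
        return "bio"
    if frac_non >= rule:
        return "nonbio"
    return None


def first_fixation_metrics(
    fixations: list[Fixation],
    scenes: list[SceneClip],
    recording: GazeRecording,
    roi: RoiConfig | None = None,
) -> tuple[float, float, float, int, int]:
    """First-fixation orientation and latency metrics.

    Returns ``(first_fix_bio_pct, latency_bio_ms, latency_nonbio_ms,
    n_trials_bio, n_trials_nonbio)``.  A fixation is assigned to an ROI when
    at least ``assignment_rule`` of its tracked samples fall inside it.
    """
    roi = roi or RoiConfig()
    stats = _trial_fixation_stats(fixations, scenes, recording, roi)
    return _first_fix_from_stats(stats, roi)


def _first_fix_from_stats(
    stats: list[dict], roi: RoiConfig
) -> tuple[float, float, float, int, int]:
    n_any = 0
    n_first_bio = 0
    lat_bio: list[float] = []
    lat_non: list[float] = []
    for tr in stats:
        onset = tr["scene"].onset_ms
        first_side = None
        earliest: dict[str, float] = {}
        for f in tr["fixations"]:  # already time-ordered
            side = _assign_side(f, roi.assignment_rule)
            if side is None:
                continue
            if first_side is None:
                first_side = side
            if side not in earliest:
                earliest[side] = f["fixation"].start_ms - onset
        if first_side is None:
            continue
        n_any += 1
        if first_side == "bio":
            n_first_bio += 1
        if "bio" in earliest:
            lat_bio.append(earliest["bio"])
        if "nonbio" in earliest:
            lat_non.append(earliest["nonbio"])
    pct = 100.0 * n_first_bio / n_any if n_any else float("nan")
    return (
        pct,
        float(np.mean(lat_bio)) if lat_bio else float("nan"),
        float(np.mean(lat_non)) if lat_non else float("nan"),
        len(lat_bio),
        len(lat_non),
    )


# ---------------------------------------------------------------------------
# per-participant assembly

def compute_participant_metrics(
    recording: GazeRecording,
    scenes: list[SceneClip],
    geometry: ScreenGeometry | None = None,
    fix_params: FixationParams | None = None,
    roi: RoiConfig | None = None,
    fixations: list[Fixation] | None = None,
) -> ParticipantMetrics:
    """Run detection (unless fixations are supplied) and all five metrics."""
    geometry = geometry or scenes[0].geometry
    roi = roi or RoiConfig()
    if fixations is None:
        fixations = detect_fixations(recording, geometry, fix_params, scenes)
    elif fixations and fixations[0].trial_id is None:
        assign_trials(fixations, scenes)

    valid = total_valid_time(recording, scenes, geometry)
    stats = _trial_fixation_stats(fixations, scenes, recording, roi)
    n_bio = sum(f["n_bio"] for tr in stats for f in tr["fixations"])
    n_non = sum(f["n_nonbio"] for tr in stats for f in tr["fixations"])
    pref = 100.0 * n_bio / (n_bio + n_non) if (n_bio + n_non) else float("nan")
    ff_pct, lat_b, lat_n, n_b, n_n = _first_fix_from_stats(stats, roi)
    return ParticipantMetrics(
        participant_id=recording.participant_id,
        total_valid_pct=valid,
        preference_bio_pct=pref,
        first_fix_bio_pct=ff_pct,
        latency_bio_ms=lat_b,
        latency_nonbio_ms=lat_n,
        n_trials_latency_bio=n_b,
        n_trials_latency_nonbio=n_n,
    )


def cohort_metrics_table(
    recordings: list[GazeRecording],
    scenes: list[SceneClip],
    geometry: ScreenGeometry | None = None,
    fix_params: FixationParams | None = None,
    roi: RoiConfig | None = None,
) -> pd.DataFrame:
    """One metrics row per recording."""
    rows = [
        compute_participant_metrics(rec, scenes, geometry, fix_params, roi).to_dict()
        for rec in recordings
    ]
    return pd.DataFrame(rows)
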