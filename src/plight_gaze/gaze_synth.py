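"""Seeded synthetic binocular gaze for preferential-looking cohorts.

The generator emulates a 30 Hz remote eye tracker watching a participant
view side-by-side point-light trials.  Gaze is built as an alternating
fixation/saccade process: during each trial the first on-stimulus fixation
starts at onset plus a drawn latency, later fixations land on the biological
side with per-participant probability ``p_bio``, and between trials gaze
rests on the central attention-getter.  Tracking loss forms bursty runs with
geometric lengths so the long-run tracked fraction matches ``p_valid``.

Alongside the sample stream every recording carries a ground-truth event log
(true fixations with sides, true first-fixation latencies, realized
participant-level parameters) which downstream tests use as the detector's
and metrics' truth set.

Participant-level parameters are drawn from symmetric truncated normals
around the group preset means, so cohort means recover the presets without
truncation bias; the spreads model between-participant heterogeneity the
summary statistics of real cohorts imply.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    ScreenGeometry,
    deg_to_px_xy,
    degrees_to_pixels,
    pixels_to_degrees,
)
from .stats import SUBSCALE_COLUMNS
from .stimulus import PointLightClip, SceneClip, TrialSetConfig, generate_walker, make_trial_set

__all__ = [
    "ScreenGeometry",
    "degrees_to_pixels",
    "pixels_to_degrees",
    "ParticipantProfile",
    "GazeModelParams",
    "GazeRecording",
    "TruthFixation",
    "TruthLog",
    "CohortConfig",
    "ASD_PRESET",
    "TD_PRESET",
    "UNBIASED_PRESET",
    "draw_participant_params",
    "simulate_participant",
    "simulate_cohort",
    "make_cohort_trial_set",
]

SAMPLE_INTERVAL_MS = 1000.0 / 30.0


@dataclass
class ParticipantProfile:
    participant_id: str
    group: str  # "asd" | "td"
    age: float
    gender: str  # "male" | "female"
    iq: float | None = None
    symptom_scores: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.group not in ("asd", "td"):
            raise ValueError("group must be 'asd' or 'td'")
        if self.iq is not None and not (60.0 <= self.iq <= 136.0):
            raise ValueError("iq must lie within [60, 136]")
        if self.symptom_scores is not None:
            missing = set(SUBSCALE_COLUMNS) - set(self.symptom_scores)
            if missing:
                raise ValueError(f"missing symptom subscales: {sorted(missing)[:3]}...")


@dataclass
class GazeModelParams:
    """Generator parameters for one participant group.

    ``p_bio`` is the probability each on-stimulus fixation lands on the
    biological side; ``p_valid`` the long-run tracked fraction; latencies are
    in ms.  ``*_between_sd`` terms set between-participant heterogeneity.
    """

    p_bio: float = 0.5
    p_valid: float = 0.9
    first_fix_latency_mean_ms: float = 550.0
    first_fix_latency_sd_ms: float = 150.0  # trial-to-trial, within participant
    fixation_dur_mean_ms: float = 350.0
    saccade_dur_ms: float = 40.0
    dropout_run_geometric_p: float = 0.4
    binocular_noise_deg: float = 0.15
    # between-participant spreads calibrated so the group presets reproduce
    # the reported standardized effect sizes (d ~ 0.87 / 0.68 / 0.56 for
    # preference, valid time and latency at the study group means)
    p_bio_between_sd: float = 0.08
    p_valid_between_sd: float = 0.13
    latency_between_sd_ms: float = 230.0

    def __post_init__(self) -> None:
        for name in ("p_bio", "p_valid", "dropout_run_geometric_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in (
            "first_fix_latency_mean_ms",
            "fixation_dur_mean_ms",
            "saccade_dur_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dropout_run_geometric_p == 0.0 and self.p_valid < 1.0:
            raise ValueError("dropout_run_geometric_p must be > 0 when p_valid < 1")


# Calibration presets carrying the reported group means for the simulated
# study conditions (preference, valid time, first-fixation latency).
ASD_PRESET = GazeModelParams(
    p_bio=0.545, p_valid=0.800, first_fix_latency_mean_ms=649.1
)
TD_PRESET = GazeModelParams(
    p_bio=0.619, p_valid=0.892, first_fix_latency_mean_ms=521.3
)
UNBIASED_PRESET = GazeModelParams(
    p_bio=0.5, p_valid=0.85, first_fix_latency_mean_ms=550.0
)


@dataclass
class TruthFixation:
    start_ms: float
    end_ms: float
    side: str  # "bio" | "nonbio" | "center"
    trial_id: str | None


@dataclass
class TruthLog:
    """Generator-side ground truth used as the detector's truth set."""

    fixations: list[TruthFixation]
    first_fix: dict[str, dict]  # trial_id -> {"side", "latency_ms"}
    p_bio_realized: float
    p_valid_target: float
    latency_mean_ms: float


@dataclass
class GazeRecording:
    """Time-ordered 30 Hz binocular sample stream with validity flags."""

    participant_id: str
    t_ms: np.ndarray
    lx_px: np.ndarray
    ly_px: np.ndarray
    rx_px: np.ndarray
    ry_px: np.ndarray
    l_valid: np.ndarray
    r_valid: np.ndarray
    sample_rate_hz: float = 30.0
    truth: TruthLog | None = None

    def __post_init__(self) -> None:
        if len(self.t_ms) and np.any(np.diff(self.t_ms) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.t_ms)

    def cyclopean(self) -> tuple[np.ndarray, np.ndarray]:
        """Two-eye mean position; falls back to the single valid eye."""
        x = np.where(
            self.l_valid & self.r_valid,
            (self.lx_px + self.rx_px) / 2.0,
            np.where(self.l_valid, self.lx_px, self.rx_px),
        )
        y = np.where(
            self.l_valid & self.r_valid,
            (self.ly_px + self.ry_px) / 2.0,
            np.where(self.l_valid, self.ly_px, self.ry_px),
        )
        return x, y


@dataclass
class CohortConfig:
    """Sizes, presets and covariate distributions for a two-group cohort."""

    n_asd: int = 121
    n_td: int = 40
    asd_params: GazeModelParams = field(default_factory=lambda: ASD_PRESET)
    td_params: GazeModelParams = field(default_factory=lambda: TD_PRESET)
    trial_config: TrialSetConfig = field(default_factory=TrialSetConfig)
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_asd < 0 or self.n_td < 0:
            raise ValueError("group sizes must be non-negative")


# ---------------------------------------------------------------------------
# helpers

def _sym_trunc_normal(rng, mean: float, sd: float, lo: float, hi: float) -> float:
    """Normal draw truncated symmetrically around the mean (unbiased)."""
    delta = min(3 * sd, mean - lo, hi - mean)
    if delta <= 0 or sd <= 0:
        return float(np.clip(mean, lo, hi))
    while True:
        x = rng.normal(mean, sd)
        if abs(x - mean) <= delta:
            return float(x)


def _trunc_normal(rng, mean: float, sd: float, lo: float, hi: float) -> float:
    """One-sided/asymmetric truncation by rejection (covariates only)."""
    if sd <= 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def draw_participant_params(params: GazeModelParams, rng) -> dict[str, float]:
    """Realize one participant's latent parameters around the group preset."""
    return {
        "p_bio": _sym_trunc_normal(rng, params.p_bio, params.p_bio_between_sd, 0.0, 1.0),
        "p_valid": _sym_trunc_normal(
            rng, params.p_valid, params.p_valid_between_sd, 0.0, 1.0
        ),
        "latency_mean_ms": _sym_trunc_normal(
            rng,
            params.first_fix_latency_mean_ms,
            params.latency_between_sd_ms,
            2 * SAMPLE_INTERVAL_MS,
            3000.0,
        ),
    }


def _validity_runs(rng, n: int, p_valid: float, p_drop: float) -> np.ndarray:
    """Alternating tracked/untracked runs with geometric lengths."""
    if p_valid >= 0.999:
        return np.ones(n, dtype=bool)
    if p_valid <= 0.001:
        return np.zeros(n, dtype=bool)
    mean_u = 1.0 / p_drop
    mean_t = mean_u * p_valid / (1.0 - p_valid)
    p_t = min(1.0, 1.0 / mean_t)
    out = np.empty(n, dtype=bool)
    pos = 0
    tracked = bool(rng.random() < p_valid)
    while pos < n:
        run = int(rng.geometric(p_t if tracked else p_drop))
        out[pos : pos + run] = tracked
        pos += run
        tracked = not tracked
    return out


# ---------------------------------------------------------------------------
# participant simulation

def simulate_participant(
    profile: ParticipantProfile,
    trial_set: list[SceneClip],
    params: GazeModelParams,
    geometry: ScreenGeometry | None = None,
    seed=0,
) -> GazeRecording:
    """Simulate one participant's binocular 30 Hz recording over a trial set.

    Deterministic under ``seed`` (an int or :class:`numpy.random.SeedSequence`).
    """
    if not trial_set:
        raise ValueError("trial set must be non-empty")
    geometry = geometry or trial_set[0].geometry
    rng = np.random.default_rng(seed)
    level = draw_participant_params(params, rng)
    p_bio = level["p_bio"]
    lat_mean = level["latency_mean_ms"]
    sacc = params.saccade_dur_ms
    min_fix = 2 * SAMPLE_INTERVAL_MS

    cx, cy = geometry.center_px
    # fixation event list: (start, end, x_px, y_px, side, trial_id)
    fixs: list[tuple[float, float, float, float, str, str | None]] = []
    first_fix: dict[str, dict] = {}
    prev_end = 0.0

    def add_center(start: float, end: float) -> None:
        if end - start >= min_fix:
            fixs.append((start, end, cx, cy, "center", None))

    for scene in sorted(trial_set, key=lambda s: s.onset_ms):
        onset, dur = scene.onset_ms, scene.duration_ms
        te = onset + dur
        lat = _sym_trunc_normal(
            rng,
            lat_mean,
            params.first_fix_latency_sd_ms,
            SAMPLE_INTERVAL_MS,
            min(3000.0, dur - 500.0),
        )
        fs = onset + lat
        add_center(prev_end, fs - sacc)
        first = True
        while fs < te - min_fix:
            side = "bio" if rng.random() < p_bio else "nonbio"
            clip = scene.bio_clip if side == "bio" else scene.nonbio_clip
            dot = int(rng.integers(clip.points))
            f = int(clip.frame_index(fs - onset))
            x_px, y_px = deg_to_px_xy(*clip.coords[f, dot], geometry)
            dur_f = max(rng.gamma(4.0, params.fixation_dur_mean_ms / 4.0), min_fix)
            fe = min(fs + dur_f, te)
            if fe - fs < min_fix:
                break
            fixs.append((fs, fe, float(x_px), float(y_px), side, scene.trial_id))
            if first:
                first_fix[scene.trial_id] = {"side": side, "latency_ms": float(lat)}
                first = False
            fs = fe + sacc
        prev_end = (fixs[-1][1] if fixs else te) + sacc
        prev_end = max(prev_end, te)
    t_end = prev_end + 1500.0
    add_center(prev_end, t_end)

    # --- rasterize to the 30 Hz grid
    n = int(np.floor(t_end / SAMPLE_INTERVAL_MS))
    t = np.arange(n) * SAMPLE_INTERVAL_MS
    starts = np.array([f[0] for f in fixs])
    ends = np.array([f[1] for f in fixs])
    fx = np.array([f[2] for f in fixs])
    fy = np.array([f[3] for f in fixs])

    idx = np.searchsorted(starts, t, side="right") - 1
    idx = np.clip(idx, 0, len(fixs) - 1)
    in_fix = (t >= starts[idx]) & (t < ends[idx])
    # saccade interpolation between fixation idx and idx+1
    nxt = np.clip(idx + 1, 0, len(fixs) - 1)
    gap = np.maximum(starts[nxt] - ends[idx], 1e-9)
    frac = np.clip((t - ends[idx]) / gap, 0.0, 1.0)
    x = np.where(in_fix, fx[idx], fx[idx] + frac * (fx[nxt] - fx[idx]))
    y = np.where(in_fix, fy[idx], fy[idx] + frac * (fy[nxt] - fy[idx]))

    noise_px = params.binocular_noise_deg * geometry.pixels_per_degree
    lx = x + rng.normal(0.0, noise_px, n)
    ly = y + rng.normal(0.0, noise_px, n)
    rx = x + rng.normal(0.0, noise_px, n)
    ry = y + rng.normal(0.0, noise_px, n)

    tracked = _validity_runs(rng, n, level["p_valid"], params.dropout_run_geometric_p)
    for arr in (lx, ly, rx, ry):
        arr[~tracked] = np.nan

    # realized per-fixation allocation for the truth channel
    bio_t = sum(f[1] - f[0] for f in fixs if f[4] == "bio")
    nonbio_t = sum(f[1] - f[0] for f in fixs if f[4] == "nonbio")
    truth = TruthLog(
        fixations=[TruthFixation(*f[:2], f[4], f[5]) for f in fixs],
        first_fix=first_fix,
        p_bio_realized=bio_t / (bio_t + nonbio_t) if bio_t + nonbio_t else float("nan"),
        p_valid_target=level["p_valid"],
        latency_mean_ms=lat_mean,
    )
    return GazeRecording(
        participant_id=profile.participant_id,
        t_ms=t,
        lx_px=lx,
        ly_px=ly,
        rx_px=rx,
        ry_px=ry,
        l_valid=tracked.copy(),
        r_valid=tracked.copy(),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# cohort simulation

def make_cohort_trial_set(config: CohortConfig) -> list[SceneClip]:
    """The shared 60-trial counterbalanced stimulus set for a cohort."""
    walker = generate_walker(4.0, 120.0, 100, 15, seed=config.seed)
    tc = config.trial_config
    if tc.seed != config.seed:
        tc = TrialSetConfig(
            n_trials=tc.n_trials,
            n_blocks=tc.n_blocks,
            trials_per_block=tc.trials_per_block,
            inter_stimulus_ms=tc.inter_stimulus_ms,
            control_mix=tc.control_mix,
            seed=config.seed,
        )
    return make_trial_set(tc, [walker], config.geometry)


def _sample_profile(rng, group: str, index: int) -> ParticipantProfile:
    if group == "asd":
        age = _trunc_normal(rng, 14.6, 8.0, 6.0, 55.0)
        gender = "male" if rng.random() < 0.76 else "female"
        iq = _trunc_normal(rng, 98.5, 20.0, 60.0, 136.0)
        scores = {}
        for col in SUBSCALE_COLUMNS:
            if col == "ados2_total":
                scores[col] = _trunc_normal(rng, 7.6, 1.7, 4.0, 10.0)
            else:
                scores[col] = float(rng.normal(50.0, 10.0))
        return ParticipantProfile(f"asd-{index:03d}", "asd", age, gender, iq, scores)
    age = _trunc_normal(rng, 16.4, 13.3, 6.0, 63.0)
    gender = "male" if rng.random() < 0.65 else "female"
    return ParticipantProfile(f"td-{index:03d}", "td", age, gender, None, None)


def simulate_cohort(
    config: CohortConfig,
    trial_set: list[SceneClip] | None = None,
) -> tuple[pd.DataFrame, list[GazeRecording]]:
    """Simulate a full two-group cohort on a shared trial set.

    Returns the participant covariate table (one row per participant, with
    the 29 symptom columns NaN for the TD group) and one recording per row.
    Per-participant seeds are spawned from the master seed by participant
    index, so cohorts are reproducible and participants independent.
    """
    trial_set = trial_set if trial_set is not None else make_cohort_trial_set(config)
    master = np.random.SeedSequence(config.seed)
    n_total = config.n_asd + config.n_td
    children = master.spawn(n_total + 1)
    rng_prof = np.random.default_rng(children[0])

    rows = []
    recordings = []
    for i in range(n_total):
        group = "asd" if i < config.n_asd else "td"
        idx = i if group == "asd" else i - config.n_asd
        profile = _sample_profile(rng_prof, group, idx)
        params = config.asd_params if group == "asd" else config.td_params
        rec = simulate_participant(
            profile, trial_set, params, config.geometry, seed=children[i + 1]
        )
        row = {
            "participant_id": profile.participant_id,
            "group": group,
            "age": profile.age,
            "gender": profile.gender,
            "iq": profile.iq if profile.iq is not None else np.nan,
        }
        for col in SUBSCALE_COLUMNS:
            row[col] = profile.symptom_scores[col] if profile.symptom_scores else np.nan
        rows.append(row)
        recordings.append(rec)
    participants = pd.DataFrame(
        rows, columns=["participant_id", "group", "age", "gender", "iq", *SUBSCALE_COLUMNS]
    )
    return participants, recordings
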