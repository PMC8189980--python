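"""Point-light stimulus synthesis and trial-set composition.

A *point-light display* (PLD) shows a handful of dots at a figure's major
joints; the kinematics alone convey a walking human.  This module provides

* a procedural periodic walker (sum-of-sinusoids limb model),
* estimation of the dominant gait period by averaged autocorrelation,
* the two non-biological controls used in preferential-looking designs —
  per-dot phase scrambling (cyclic time shifts that preserve local motion)
  and rigid rotation of the first frame about the vertical axis,
* composition of side-by-side scenes and counterbalanced trial sets.

All coordinates are screen-centered degrees of visual angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import ScreenGeometry

__all__ = [
    "PointLightClip",
    "ScrambleParams",
    "SceneClip",
    "TrialSetConfig",
    "ConditionError",
    "CompositionError",
    "InsufficientDataError",
    "generate_walker",
    "dominant_period",
    "phase_scramble",
    "rotational_control",
    "compose_scene",
    "make_trial_set",
]

CONDITIONS = ("biological", "scrambled", "rotational")


class ConditionError(ValueError):
    """An operation received a clip in the wrong stimulus condition."""


class CompositionError(ValueError):
    """Scene composition failed (mismatched clips or overlapping layouts)."""


class InsufficientDataError(ValueError):
    """Input too short for the requested estimate."""


@dataclass
class PointLightClip:
    """A dot-coordinate movie: ``coords[frame, point] = (x_deg, y_deg)``."""

    clip_id: str
    fps: float
    coords: np.ndarray  # (frames, points, 2), degrees, screen-centered
    condition: str
    period_ms: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("coords must have shape (frames, points, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain missing values")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def frames(self) -> int:
        return self.coords.shape[0]

    @property
    def points(self) -> int:
        return self.coords.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.frames / self.fps * 1000.0

    def frame_index(self, t_ms) -> np.ndarray:
        """Frame shown ``t_ms`` after clip onset (clipped to the last frame)."""
        idx = np.floor(np.asarray(t_ms, dtype=float) * self.fps / 1000.0).astype(int)
        return np.clip(idx, 0, self.frames - 1)


@dataclass
class ScrambleParams:
    """Parameters of per-dot cyclic time scrambling.

    ``max_offset_ms`` defaults to half the dominant period (833 ms gait ->
    417 ms bound); offsets are drawn uniformly in ``[-max, +max]`` per dot.
    """

    period_ms: float = 833.0
    max_offset_ms: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_ms <= 0:
            raise ValueError("period_ms must be positive")
        if self.max_offset_ms is None:
            # round half-period up: an 833 ms gait gives the 417 ms bound
            self.max_offset_ms = float(int(np.floor(self.period_ms / 2 + 0.5)))
        if self.max_offset_ms < 0:
            raise ValueError("max_offset_ms must be non-negative")


@dataclass
class SceneClip:
    """Two clips placed side-by-side; exactly one side is biological."""

    trial_id: str
    left_clip: PointLightClip
    right_clip: PointLightClip
    bio_side: str  # "left" | "right"
    onset_ms: float
    geometry: ScreenGeometry
    block: int = 0

    def __post_init__(self) -> None:
        if self.bio_side not in ("left", "right"):
            raise ValueError("bio_side must be 'left' or 'right'")
        n_bio = sum(
            c.condition == "biological" for c in (self.left_clip, self.right_clip)
        )
        if n_bio != 1:
            raise CompositionError("exactly one side must be biological")
        bio = self.left_clip if self.bio_side == "left" else self.right_clip
        if bio.condition != "biological":
            raise CompositionError("bio_side does not match clip conditions")

    @property
    def duration_ms(self) -> float:
        return self.left_clip.duration_ms

    @property
    def bio_clip(self) -> PointLightClip:
        return self.left_clip if self.bio_side == "left" else self.right_clip

    @property
    def nonbio_clip(self) -> PointLightClip:
        return self.right_clip if self.bio_side == "left" else self.left_clip


@dataclass
class TrialSetConfig:
    """Layout of a counterbalanced trial set: 6 blocks of 10 four-second trials."""

    n_trials: int = 60
    n_blocks: int = 6
    trials_per_block: int = 10
    inter_stimulus_ms: tuple[float, float] = (1500.0, 2000.0)
    control_mix: float = 0.5  # fraction of scrambled (vs rotational) controls
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials != self.n_blocks * self.trials_per_block:
            raise ValueError("n_trials must equal n_blocks * trials_per_block")
        lo, hi = self.inter_stimulus_ms
        if not (0 <= lo <= hi):
            raise ValueError("inter_stimulus_ms range invalid")
        if not 0.0 <= self.control_mix <= 1.0:
            raise ValueError("control_mix must lie in [0, 1]")


# ---------------------------------------------------------------------------
# procedural walker

# Canonical upright-walker joint layout (x, y) in degrees: head, shoulders,
# elbows, wrists, hips, knees, ankles -- 15 markers.
_SKELETON = np.array(
    [
        (0.00, 1.80),   # head
        (0.00, 1.25),   # neck
        (-0.45, 1.20),  # l shoulder
        (0.45, 1.20),   # r shoulder
        (-0.55, 0.70),  # l elbow
        (0.55, 0.70),   # r elbow
        (-0.60, 0.20),  # l wrist
        (0.60, 0.20),   # r wrist
        (-0.25, 0.00),  # l hip
        (0.25, 0.00),   # r hip
        (-0.30, -0.90), # l knee
        (0.30, -0.90),  # r knee
        (-0.30, -1.80), # l ankle
        (0.30, -1.80),  # r ankle
        (0.00, 0.55),   # torso midpoint
    ]
)


def generate_walker(
    duration_s: float,
    fps: float = 120.0,
    gait_period_frames: int = 100,
    n_points: int = 15,
    seed: int = 0,
) -> PointLightClip:
    """Synthesize an exactly periodic point-light walker.

    Each marker oscillates as a sum of sinusoids at the gait fundamental and
    its second harmonic, so every coordinate signal repeats bit-identically
    every ``gait_period_frames`` frames (signals are evaluated at the frame
    index modulo the period).  Limb markers swing more than trunk markers,
    and left/right limbs move in anti-phase, which is all the downstream
    pipeline needs: exact periodicity and a plausible dot geometry.
    """
    if duration_s <= 0 or fps <= 0:
        raise ValueError("duration_s and fps must be positive")
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    if gait_period_frames < 4:
        raise ValueError("gait_period_frames must be at least 4")

    rng = np.random.default_rng(seed)
    frames = int(round(duration_s * fps))
    period = int(gait_period_frames)

    # base marker positions: canonical skeleton, cycled/jittered if n differs
    base = _SKELETON[np.arange(n_points) % len(_SKELETON)].copy()
    if n_points > len(_SKELETON):
        base[len(_SKELETON):] += rng.uniform(-0.2, 0.2, (n_points - len(_SKELETON), 2))

    # swing amplitude grows with distance from the torso midline
    limb = np.hypot(base[:, 0], base[:, 1] - 0.3)
    a1x = 0.30 + 0.50 * limb / max(limb.max(), 1e-9)       # fundamental, x
    a2x = rng.uniform(0.05, 0.15, n_points)                 # 2nd harmonic, x
    a1y = 0.05 + 0.10 * rng.uniform(size=n_points)          # small vertical sway
    a2y = 0.05 + 0.10 * limb / max(limb.max(), 1e-9)        # vertical bounce

    # anti-phase left/right: phase offset pi for markers on the right (x>0)
    phase0 = np.where(base[:, 0] > 0, np.pi, 0.0)
    phase0 = phase0 + rng.uniform(-0.3, 0.3, n_points)
    phase2 = rng.uniform(0, 2 * np.pi, n_points)

    t = np.arange(frames) % period  # exact integer periodicity
    ph = 2 * np.pi * t[:, None] / period  # (frames, 1)

    x = base[None, :, 0] + a1x * np.sin(ph + phase0) + a2x * np.sin(2 * ph + phase2)
    y = base[None, :, 1] + a1y * np.sin(ph + phase0) + a2y * np.sin(2 * ph + phase2 / 2)

    coords = np.stack([x, y], axis=2)
    return PointLightClip(
        clip_id=f"walker-p{period}-s{seed}",
        fps=float(fps),
        coords=coords,
        condition="biological",
        period_ms=period / fps * 1000.0,
    )


# ---------------------------------------------------------------------------
# periodicity

def dominant_period(
    clip: PointLightClip,
    window_ms: tuple[float, float] = (250.0, 2000.0),
) -> int:
    """Dominant movement period (ms) via averaged normalized autocorrelation.

    Each dot's x and y signal is mean-centered; the biased sample
    autocorrelation (normalized to 1 at lag 0) is averaged over all dots and
    both axes, and the integer lag of the highest value inside the search
    window is returned, converted to milliseconds and rounded to the nearest
    millisecond.
    """
    lo = int(np.ceil(window_ms[0] * clip.fps / 1000.0))
    hi = int(np.floor(window_ms[1] * clip.fps / 1000.0))
    lo = max(lo, 1)
    if clip.frames <= hi:
        raise InsufficientDataError(
            f"clip has {clip.frames} frames; search window needs more than {hi}"
        )
    n = clip.frames
    acf_sum = np.zeros(n)
    n_signals = 0
    for p in range(clip.points):
        for axis in (0, 1):
            s = clip.coords[:, p, axis]
            s = s - s.mean()
            var = np.dot(s, s)
            if var <= 0:
                continue
            acf = np.correlate(s, s, mode="full")[n - 1:] / var
            acf_sum += acf
            n_signals += 1
    if n_signals == 0:
        raise InsufficientDataError("all dot signals are constant")
    acf_mean = acf_sum / n_signals
    lag = lo + int(np.argmax(acf_mean[lo : hi + 1]))
    return int(round(lag / clip.fps * 1000.0))


# ---------------------------------------------------------------------------
# controls

def phase_scramble(clip: PointLightClip, params: ScrambleParams) -> PointLightClip:
    """Phase-scrambled control: cyclic per-dot time shifts.

    Every dot's trajectory is shifted by an independent uniform offset in
    ``[-max_offset_ms, +max_offset_ms]`` (rounded to whole frames) and wrapped
    cyclically with wrap period equal to the dominant gait period, so the set
    of positions each dot visits over one period — and hence its local motion
    — is preserved exactly, while the global body form is destroyed.
    """
    if clip.condition != "biological":
        raise ConditionError("phase_scramble requires a biological clip")
    wrap = int(round(params.period_ms * clip.fps / 1000.0))
    if wrap < 1 or wrap > clip.frames:
        raise InsufficientDataError("wrap period exceeds clip length")

    rng = np.random.default_rng(params.seed)
    offsets_ms = rng.uniform(-params.max_offset_ms, params.max_offset_ms, clip.points)
    offsets = np.round(offsets_ms * clip.fps / 1000.0).astype(int)

    t = np.arange(clip.frames)
    template = clip.coords[:wrap]  # one full period
    new = np.empty_like(clip.coords)
    for p in range(clip.points):
        new[:, p] = template[(t + offsets[p]) % wrap, p]
    return PointLightClip(
        clip_id=f"{clip.clip_id}-scr{params.seed}",
        fps=clip.fps,
        coords=new,
        condition="scrambled",
        period_ms=clip.period_ms,
    )


def rotational_control(clip: PointLightClip, hip_period_ms: float) -> PointLightClip:
    """Rotational control: first frame spun rigidly about the vertical axis.

    Frame 0 is treated as a rigid planar point set at depth 0; it rotates
    about the vertical axis through its centroid at constant angular speed
    ``2*pi / hip_period_ms`` and is rendered by orthographic x-projection
    (y unchanged).  The first rendered frame equals the biological first
    frame, matching the design requirement that all conditions open alike.
    """
    if clip.condition != "biological":
        raise ConditionError("rotational_control requires a biological clip")
    if hip_period_ms <= 0:
        raise ValueError("hip_period_ms must be positive")

    frame0 = clip.coords[0]
    cx = frame0[:, 0].mean()
    dx = frame0[:, 0] - cx
    t_ms = np.arange(clip.frames) / clip.fps * 1000.0
    theta = 2 * np.pi * t_ms / hip_period_ms
    x = cx + dx[None, :] * np.cos(theta)[:, None]
    y = np.broadcast_to(frame0[:, 1], (clip.frames, clip.points)).copy()
    return PointLightClip(
        clip_id=f"{clip.clip_id}-rot",
        fps=clip.fps,
        coords=np.stack([x, y], axis=2),
        condition="rotational",
        period_ms=hip_period_ms,
    )


# ---------------------------------------------------------------------------
# scenes and trial sets

def compose_scene(
    bio: PointLightClip,
    control: PointLightClip,
    bio_side: str,
    geometry: ScreenGeometry,
    trial_id: str = "t000",
    onset_ms: float = 0.0,
    block: int = 0,
) -> SceneClip:
    """Place a biological clip and a control side-by-side on the screen.

    Each clip is recentred on the horizontal midpoint of its screen half
    (x = -/+ width/4 in degrees).  Raises if the two dot clouds would overlap.
    """
    if bio.condition != "biological":
        raise ConditionError("bio clip must be biological")
    if control.condition == "biological":
        raise ConditionError("control clip must be non-biological")
    if (bio.frames, bio.points) != (control.frames, control.points) or bio.fps != control.fps:
        raise CompositionError("clips must share fps, frame count and dot count")

    offset = geometry.width_deg / 4.0

    def place(clip: PointLightClip, x_center: float) -> PointLightClip:
        shifted = clip.coords.copy()
        shifted[..., 0] += x_center - clip.coords[..., 0].mean()
        half_width = np.abs(shifted[..., 0] - x_center).max()
        if half_width >= offset:
            raise CompositionError("clip too wide for its screen half")
        return replace(clip, coords=shifted)

    left, right = (bio, control) if bio_side == "left" else (control, bio)
    return SceneClip(
        trial_id=trial_id,
        left_clip=place(left, -offset),
        right_clip=place(right, +offset),
        bio_side=bio_side,
        onset_ms=onset_ms,
        geometry=geometry,
        block=block,
    )


def make_trial_set(
    config: TrialSetConfig,
    source_clips: list[PointLightClip],
    geometry: ScreenGeometry | None = None,
) -> list[SceneClip]:
    """Build a counterbalanced trial set from one or more biological clips.

    The biological side is left on exactly half the trials (right on the
    other half), in seeded random order.  Each trial pairs a source clip with
    a freshly generated control (scrambled with probability ``control_mix``,
    rotational otherwise).  Onsets are spaced by the clip duration plus an
    inter-stimulus gap drawn uniformly from the configured range.
    """
    if not source_clips:
        raise ValueError("need at least one source clip")
    geometry = geometry or ScreenGeometry()
    rng = np.random.default_rng(config.seed)

    n = config.n_trials
    sides = np.array(["left"] * (n // 2) + ["right"] * (n - n // 2))
    rng.shuffle(sides)

    scenes: list[SceneClip] = []
    t = 0.0
    lo, hi = config.inter_stimulus_ms
    for i in range(n):
        src = source_clips[i % len(source_clips)]
        period = src.period_ms if src.period_ms is not None else float(dominant_period(src))
        if rng.uniform() < config.control_mix:
            ctrl = phase_scramble(
                src, ScrambleParams(period_ms=period, seed=int(rng.integers(2**31)))
            )
        else:
            ctrl = rotational_control(src, period)
        t += rng.uniform(lo, hi)  # gap before each trial
        scenes.append(
            compose_scene(
                src,
                ctrl,
                str(sides[i]),
                geometry,
                trial_id=f"t{i:03d}",
                onset_ms=t,
                block=i // config.trials_per_block,
            )
        )
        t += src.duration_ms
    return scenes
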