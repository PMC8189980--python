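"""Readers and writers for the pipeline's file formats.

All artifacts are plain delimited text or JSON so fixtures diff cleanly.
Schemas are strict: an unexpected or missing column is an error, and gaze
timestamps must be strictly increasing per participant.  Every file starts
with (or embeds) a metadata record ``{tool version, seed, config hash}``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fixation import Fixation
from .gaze_synth import GazeRecording
from .geometry import ScreenGeometry
from .metrics import ParticipantMetrics
from .stimulus import PointLightClip, SceneClip

__all__ = [
    "ParseError",
    "config_hash",
    "write_clip",
    "read_clip",
    "write_scene_set",
    "read_scene_set",
    "write_gaze",
    "read_gaze",
    "write_fixations",
    "read_fixations",
    "write_metrics",
    "read_metrics",
    "write_report",
]

GAZE_COLUMNS = [
    "participant_id",
    "trial_id",
    "t_ms",
    "lx_px",
    "ly_px",
    "rx_px",
    "ry_px",
    "l_valid",
    "r_valid",
]
FIXATION_COLUMNS = [
    "participant_id",
    "trial_id",
    "start_ms",
    "end_ms",
    "x_px",
    "y_px",
    "n_tracked",
]
METRIC_FILE_COLUMNS = [
    "participant_id",
    "total_valid_pct",
    "preference_bio_pct",
    "first_fix_bio_pct",
    "latency_bio_ms",
    "latency_nonbio_ms",
]


class ParseError(ValueError):
    """Malformed artifact file (bad header or offending row is named)."""


def config_hash(config) -> str:
    """Stable short hash of a (nested) config dataclass."""
    if dataclasses.is_dataclass(config):
        payload = dataclasses.asdict(config)
    else:
        payload = config
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _meta_line(seed, cfg_hash) -> str:
    return f"# plight-gaze {__version__} seed={seed} config_hash={cfg_hash}\n"


def _write_table(df: pd.DataFrame, path, seed, cfg_hash) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_meta_line(seed, cfg_hash))
        # %.17g round-trips IEEE doubles exactly
        df.to_csv(fh, index=False, float_format="%.17g")


def _read_table(path, expected_columns: list[str]) -> pd.DataFrame:
    text = Path(path).read_text()
    body = "\n".join(l for l in text.splitlines() if not l.startswith("#"))
    df = pd.read_csv(_io.StringIO(body), float_precision="round_trip")
    if list(df.columns) != expected_columns:
        raise ParseError(
            f"{path}: header {list(df.columns)} does not match required "
            f"columns {expected_columns}"
        )
    return df


# ---------------------------------------------------------------------------
# clips and scene sets

def write_clip(clip: PointLightClip, path, seed="na", cfg_hash="na") -> None:
    """Long-format dot table plus a JSON metadata sidecar."""
    path = Path(path)
    frames, points = clip.frames, clip.points
    df = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(frames), points),
            "point": np.tile(np.arange(points), frames),
            "x_deg": clip.coords[..., 0].ravel(),
            "y_deg": clip.coords[..., 1].ravel(),
        }
    )
    _write_table(df, path, seed, cfg_hash)
    meta = {
        "clip_id": clip.clip_id,
        "fps": clip.fps,
        "condition": clip.condition,
        "period_ms": clip.period_ms,
        "frames": frames,
        "points": points,
        "tool_version": __version__,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_clip(path) -> PointLightClip:
    df = _read_table(path, ["frame", "point", "x_deg", "y_deg"])
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    frames, points = meta["frames"], meta["points"]
    if len(df) != frames * points:
        raise ParseError(f"{path}: expected {frames * points} rows, found {len(df)}")
    coords = np.empty((frames, points, 2))
    coords[df["frame"], df["point"], 0] = df["x_deg"]
    coords[df["frame"], df["point"], 1] = df["y_deg"]
    return PointLightClip(
        clip_id=meta["clip_id"],
        fps=meta["fps"],
        coords=coords,
        condition=meta["condition"],
        period_ms=meta["period_ms"],
    )


def write_scene_set(scenes: list[SceneClip], out_dir, seed="na", cfg_hash="na") -> Path:
    """Write a trial manifest plus one clip file per scene side."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for scene in scenes:
        entry = {
            "trial_id": scene.trial_id,
            "block": scene.block,
            "bio_side": scene.bio_side,
            "onset_ms": scene.onset_ms,
            "control_condition": scene.nonbio_clip.condition,
            "left_clip": f"{scene.trial_id}_left.csv",
            "right_clip": f"{scene.trial_id}_right.csv",
        }
        write_clip(scene.left_clip, out_dir / entry["left_clip"], seed, cfg_hash)
        write_clip(scene.right_clip, out_dir / entry["right_clip"], seed, cfg_hash)
        manifest.append(entry)
    geo = scenes[0].geometry
    payload = {
        "_meta": {"tool_version": __version__, "seed": seed, "config_hash": cfg_hash},
        "geometry": dataclasses.asdict(geo),
        "trials": manifest,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_scene_set(manifest_path) -> list[SceneClip]:
    manifest_path = Path(manifest_path)
    payload = json.loads(manifest_path.read_text())
    geo = ScreenGeometry(**payload["geometry"])
    scenes = []
    for entry in payload["trials"]:
        scenes.append(
            SceneClip(
                trial_id=entry["trial_id"],
                left_clip=read_clip(manifest_path.parent / entry["left_clip"]),
                right_clip=read_clip(manifest_path.parent / entry["right_clip"]),
                bio_side=entry["bio_side"],
                onset_ms=entry["onset_ms"],
                geometry=geo,
                block=entry["block"],
            )
        )
    return scenes


# ---------------------------------------------------------------------------
# gaze

def _sample_trial_ids(recording: GazeRecording, scenes: list[SceneClip] | None) -> np.ndarray:
    ids = np.full(recording.n_samples, "", dtype=object)
    if scenes:
        ordered = sorted(scenes, key=lambda s: s.onset_ms)
        onsets = np.array([s.onset_ms for s in ordered])
        idx = np.searchsorted(onsets, recording.t_ms, side="right") - 1
        for i, s in enumerate(ordered):
            sel = (idx == i) & (recording.t_ms < s.onset_ms + s.duration_ms)
            ids[sel] = s.trial_id
    return ids


def write_gaze(
    recordings: list[GazeRecording],
    path,
    scenes: list[SceneClip] | None = None,
    seed="na",
    cfg_hash="na",
) -> None:
    frames = []
    for rec in recordings:
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": rec.participant_id,
                    "trial_id": _sample_trial_ids(rec, scenes),
                    "t_ms": rec.t_ms,
                    "lx_px": rec.lx_px,
                    "ly_px": rec.ly_px,
                    "rx_px": rec.rx_px,
                    "ry_px": rec.ry_px,
                    "l_valid": rec.l_valid.astype(int),
                    "r_valid": rec.r_valid.astype(int),
                }
            )
        )
    _write_table(pd.concat(frames, ignore_index=True), path, seed, cfg_hash)


def read_gaze(path) -> list[GazeRecording]:
    df = _read_table(path, GAZE_COLUMNS)
    recordings = []
    for pid, sub in df.groupby("participant_id", sort=False):
        t = sub["t_ms"].to_numpy(float)
        bad = np.flatnonzero(np.diff(t) <= 0)
        if len(bad):
            row = sub.index[bad[0] + 1] + 2  # 1-based, after header
            raise ParseError(f"{path}: non-monotone t_ms at data row {row}")
        recordings.append(
            GazeRecording(
                participant_id=str(pid),
                t_ms=t,
                lx_px=sub["lx_px"].to_numpy(float),
                ly_px=sub["ly_px"].to_numpy(float),
                rx_px=sub["rx_px"].to_numpy(float),
                ry_px=sub["ry_px"].to_numpy(float),
                l_valid=sub["l_valid"].to_numpy(bool),
                r_valid=sub["r_valid"].to_numpy(bool),
            )
        )
    return recordings


# ---------------------------------------------------------------------------
# fixations, metrics, report

def write_fixations(
    fixations_by_participant: dict[str, list[Fixation]], path, seed="na", cfg_hash="na"
) -> None:
    rows = []
    for pid, fixs in fixations_by_participant.items():
        for fx in fixs:
            rows.append(
                {
                    "participant_id": pid,
                    "trial_id": fx.trial_id or "",
                    "start_ms": fx.start_ms,
                    "end_ms": fx.end_ms,
                    "x_px": fx.centroid_px[0],
                    "y_px": fx.centroid_px[1],
                    "n_tracked": fx.n_tracked,
                }
            )
    _write_table(pd.DataFrame(rows, columns=FIXATION_COLUMNS), path, seed, cfg_hash)


def read_fixations(path) -> dict[str, list[Fixation]]:
    df = _read_table(path, FIXATION_COLUMNS)
    out: dict[str, list[Fixation]] = {}
    for _, row in df.iterrows():
        fx = Fixation(
            start_ms=float(row["start_ms"]),
            end_ms=float(row["end_ms"]),
            centroid_px=(float(row["x_px"]), float(row["y_px"])),
            n_tracked=int(row["n_tracked"]),
            trial_id=str(row["trial_id"]) if str(row["trial_id"]) not in ("", "nan") else None,
        )
        out.setdefault(str(row["participant_id"]), []).append(fx)
    return out


def write_metrics(metrics: pd.DataFrame, path, seed="na", cfg_hash="na") -> None:
    _write_table(metrics[METRIC_FILE_COLUMNS], path, seed, cfg_hash)


def read_metrics(path) -> pd.DataFrame:
    return _read_table(path, METRIC_FILE_COLUMNS)


def write_participants(participants: pd.DataFrame, path, seed="na", cfg_hash="na") -> None:
    _write_table(participants, path, seed, cfg_hash)


def read_participants(path) -> pd.DataFrame:
    text = Path(path).read_text()
    body = "\n".join(l for l in text.splitlines() if not l.startswith("#"))
    return pd.read_csv(_io.StringIO(body), float_precision="round_trip")


def write_report(report: dict, path, seed="na", cfg_hash="na") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "_meta": {"tool_version": __version__, "seed": seed, "config_hash": cfg_hash},
        **report,
    }
    path.write_text(json.dumps(payload, indent=1, default=float, sort_keys=True))
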