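"""Reading, validating and reducing single-cell migration tracks.

A track is the time-ordered 2-D trajectory of one cell, as exported by
a time-lapse tracker.  This module turns track tables into per-track
motility quantities: instantaneous velocities, mean speed, net
displacement and net migration angle.  The coordinate convention is
Cartesian with 0° along +x, the direction of the neural spheroid in
the imaging layout; trackers that export row-major image coordinates
can be loaded with ``image_rows=True``, which negates y so angle signs
are preserved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from os import PathLike

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "MotilitySummary",
    "TrackFormatError",
    "TrackValidationError",
    "REQUIRED_COLUMNS",
    "read_tracks",
    "tracks_from_table",
    "motility_metrics",
    "net_displacement_angle",
    "metrics_table",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("track_id", "frame", "time_min", "x_um", "y_um", "condition")


class TrackFormatError(ValueError):
    """Input table lacks required columns or has unparseable values."""


class TrackValidationError(ValueError):
    """A track violates ordering/monotonicity invariants."""


@dataclass(frozen=True)
class Track:
    """One cell's trajectory: ordered frames, times (min), x/y (µm)."""

    track_id: str
    condition: str
    frames: np.ndarray
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class MotilitySummary:
    """Per-track motility reduction.

    ``velocities`` are per-step instantaneous velocities in µm/min;
    ``mean_speed`` is path length over elapsed time; ``net_angle`` is
    the direction of the start-to-end displacement in degrees in
    (−180, 180], ``None`` for a stationary track.
    """

    track_id: str
    condition: str
    velocities: np.ndarray
    mean_speed: float
    net_dx: float
    net_dy: float
    net_angle: float | None
    n_steps: int

    @property
    def net_displacement(self) -> float:
        return math.hypot(self.net_dx, self.net_dy)


def _validate_track_group(tid: object, g: pd.DataFrame) -> None:
    frames = g["frame"].to_numpy()
    times = g["time_min"].to_numpy()
    if np.any(np.diff(frames) <= 0):
        raise TrackValidationError(
            f"track {tid!r}: frames not strictly increasing"
        )
    if np.any(np.diff(times) <= 0):
        raise TrackValidationError(
            f"track {tid!r}: time not strictly increasing"
        )


def tracks_from_table(
    table: pd.DataFrame, *, image_rows: bool = False, min_points: int = 2
) -> list[Track]:
    """Build validated :class:`Track` objects from a tidy table.

    Rows with missing coordinates are dropped (count logged).  Tracks
    with fewer than ``min_points`` remaining points are dropped (count
    logged).  Non-monotonic frames or times raise
    :class:`TrackValidationError` naming the track.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise TrackFormatError(f"missing required column(s): {', '.join(missing)}")

    n_before = len(table)
    table = table.dropna(subset=["x_um", "y_um", "time_min", "frame"])
    dropped_rows = n_before - len(table)
    if dropped_rows:
        logger.warning("dropped %d rows with missing coordinates", dropped_rows)

    tracks: list[Track] = []
    short = 0
    for tid, g in table.groupby("track_id", sort=True):
        g = g.sort_values("frame", kind="stable")
        if len(g) < min_points:
            short += 1
            continue
        _validate_track_group(tid, g)
        y = g["y_um"].to_numpy(dtype=float)
        if image_rows:
            y = -y
        conditions = g["condition"].unique()
        if len(conditions) > 1:
            raise TrackValidationError(
                f"track {tid!r}: multiple condition labels {list(conditions)}"
            )
        tracks.append(
            Track(
                track_id=str(tid),
                condition=str(conditions[0]),
                frames=g["frame"].to_numpy(dtype=int),
                times=g["time_min"].to_numpy(dtype=float),
                x=g["x_um"].to_numpy(dtype=float),
                y=y,
            )
        )
    if short:
        logger.warning("dropped %d tracks shorter than %d points", short, min_points)
    return tracks


def read_tracks(
    path: str | PathLike, *, image_rows: bool = False, min_points: int = 2
) -> list[Track]:
    """Read a track CSV (columns ``track_id, frame, time_min, x_um,
    y_um, condition``) into validated tracks."""
    try:
        table = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pragma: no cover - passthrough
        raise TrackFormatError(str(exc)) from exc
    return tracks_from_table(table, image_rows=image_rows, min_points=min_points)


def motility_metrics(track: Track) -> MotilitySummary:
    """Reduce one track to velocities, mean speed and net displacement.

    instantaneous velocity_i = |p_{i+1} − p_i| / (t_{i+1} − t_i);
    mean speed = path length / elapsed time; both in µm/min.  A zero
    time interval between consecutive points is a validation error.
    """
    if len(track) < 2:
        raise TrackValidationError(
            f"track {track.track_id!r}: needs >= 2 points for motility metrics"
        )
    dt = np.diff(track.times)
    if np.any(dt <= 0):
        raise TrackValidationError(
            f"track {track.track_id!r}: zero or negative time interval"
        )
    steps = np.hypot(np.diff(track.x), np.diff(track.y))
    velocities = steps / dt
    elapsed = track.times[-1] - track.times[0]
    mean_speed = float(steps.sum() / elapsed)
    dx = float(track.x[-1] - track.x[0])
    dy = float(track.y[-1] - track.y[0])
    return MotilitySummary(
        track_id=track.track_id,
        condition=track.condition,
        velocities=velocities,
        mean_speed=mean_speed,
        net_dx=dx,
        net_dy=dy,
        net_angle=_angle_deg(dx, dy),
        n_steps=len(steps),
    )


def _angle_deg(dx: float, dy: float) -> float | None:
    if dx == 0.0 and dy == 0.0:
        return None
    ang = math.degrees(math.atan2(dy, dx))
    # atan2 returns [−180, 180]; fold −180 onto +180 so the interval is
    # (−180, 180] and the anti-spheroid direction is unambiguous.
    if ang <= -180.0:
        ang = 180.0
    return ang


def net_displacement_angle(track: Track) -> float | None:
    """Net migration angle in degrees in (−180, 180].

    0° points along +x, toward the spheroid.  Returns ``None`` for a
    stationary track (zero net displacement); callers exclude these
    from histograms and report the excluded count.
    """
    dx = float(track.x[-1] - track.x[0])
    dy = float(track.y[-1] - track.y[0])
    return _angle_deg(dx, dy)


def metrics_table(tracks: list[Track]) -> pd.DataFrame:
    """Per-track metrics for a set of tracks.

    Columns: ``track_id, condition, mean_speed, median_velocity,
    net_dx, net_dy, net_angle, n_steps``; ``net_angle`` is NaN for
    stationary tracks, with the count logged.
    """
    rows = []
    stationary = 0
    for t in tracks:
        m = motility_metrics(t)
        if m.net_angle is None:
            stationary += 1
        rows.append(
            {
                "track_id": m.track_id,
                "condition": m.condition,
                "mean_speed": m.mean_speed,
                "median_velocity": float(np.median(m.velocities)),
                "net_dx": m.net_dx,
                "net_dy": m.net_dy,
                "net_angle": m.net_angle if m.net_angle is not None else np.nan,
                "n_steps": m.n_steps,
            }
        )
    if stationary:
        logger.warning("%d stationary tracks have undefined net angle", stationary)
    return pd.DataFrame(rows)
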