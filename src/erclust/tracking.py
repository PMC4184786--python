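"""Spot detection and frame-to-frame linking for time-lapse movies of bright clusters.

Detection is Laplacian-of-Gaussian blob finding at a scale matched to the
expected cluster diameter, with sub-pixel refinement by a quadratic fit around
the response peak.  Linking is optimal per-frame bipartite assignment
(Hungarian algorithm) under a hard displacement gate, with no gap closing: a
spot that disappears for one frame terminates its track.

Coordinate convention: pixel centers sit at integer (row, col); ``x`` is the
column axis and ``y`` the row axis; physical coordinates are pixel index times
``pixel_size`` and all downstream analysis is in µm and seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Spot",
    "Trajectory",
    "detect_spots",
    "link_tracks",
    "read_track_table",
    "write_track_table",
]

#: cost assigned to gated (disallowed) pairings in the assignment matrix
_GATED = 1e12


@dataclass(frozen=True)
class Spot:
    """A single detection: position in µm plus detector response."""

    frame: int
    x: float
    y: float
    intensity: float = 0.0
    quality: float = 0.0

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError("frame index must be >= 0")


@dataclass
class Trajectory:
    """One cluster's time-ordered 2D positions in physical units.

    Parameters
    ----------
    track_id:
        Identifier, unique within a collection of tracks.
    frames:
        Strictly increasing integer frame indices.
    x, y:
        Positions in µm, same length as ``frames``.
    frame_interval:
        Acquisition interval in seconds.
    condition:
        Experimental-arm label (e.g. ``"untreated"``, ``"nocodazole"``).
    diameter:
        Optional cluster diameter in µm (e.g. from morphometry), used by the
        size–mobility analysis.
    """

    track_id: int | str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_interval: float
    condition: str = "untreated"
    diameter: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.frames.ndim != 1 or len(self.frames) < 2:
            raise ValueError(f"track {self.track_id!r}: needs >= 2 points")
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise ValueError(f"track {self.track_id!r}: frame/x/y length mismatch")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"track {self.track_id!r}: frames not strictly increasing")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError(f"track {self.track_id!r}: non-finite coordinates")

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        """Acquisition times in seconds."""
        return self.frames * self.frame_interval

    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) in µm."""
        return np.column_stack([self.x, self.y])


def _parabolic_offset(f_minus: float, f_0: float, f_plus: float) -> float:
    """Sub-sample offset of a peak from a 3-point quadratic fit, clipped to ±0.5."""
    denom = f_minus - 2.0 * f_0 + f_plus
    if denom == 0 or not math.isfinite(denom):
        return 0.0
    return float(np.clip(0.5 * (f_minus - f_plus) / denom, -0.5, 0.5))


def detect_spots(
    frame: np.ndarray,
    pixel_size: float,
    expected_diameter: float,
    quality_threshold: float | None = None,
    frame_index: int = 0,
) -> list[Spot]:
    """Detect bright roundish spots in a single frame.

    The frame is filtered with a scale-normalised negated Laplacian of
    Gaussian at ``sigma = radius / sqrt(2)`` (the LoG scale that maximises the
    response of a disk of that radius).  Local maxima above
    ``quality_threshold`` become spots; each is refined to sub-pixel precision
    by per-axis quadratic interpolation of the response, and detections closer
    than ``expected_diameter / 2`` to a stronger one are suppressed.

    Parameters
    ----------
    frame:
        2D intensity raster.
    pixel_size:
        µm per pixel.
    expected_diameter:
        Approximate cluster diameter in µm; must be at least 2 px.
    quality_threshold:
        Absolute threshold on the LoG response.  ``None`` uses
        ``mean + 5*std`` of the response, which rejects a blank frame.

    Returns
    -------
    list of :class:`Spot`, sorted by quality descending.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("frame must be a 2D array")
    if not pixel_size > 0:
        raise ValueError("pixel_size must be > 0")
    radius_px = 0.5 * expected_diameter / pixel_size
    if radius_px < 1.0:
        raise ValueError("expected_diameter must be at least 2 px in physical units")

    sigma = radius_px / math.sqrt(2.0)
    resp = -ndimage.gaussian_laplace(img, sigma) * sigma**2
    if quality_threshold is None:
        quality_threshold = float(resp.mean() + 5.0 * resp.std())

    footprint = max(3, int(round(radius_px)) | 1)
    local_max = ndimage.maximum_filter(resp, size=footprint, mode="nearest")
    rows, cols = np.nonzero((resp == local_max) & (resp > quality_threshold))
    if rows.size == 0:
        return []

    order = np.argsort(resp[rows, cols])[::-1]
    min_sep_px = 0.5 * expected_diameter / pixel_size
    kept_rc: list[tuple[float, float]] = []
    spots: list[Spot] = []
    for idx in order:
        i, j = int(rows[idx]), int(cols[idx])
        if any((i - ki) ** 2 + (j - kj) ** 2 < min_sep_px**2 for ki, kj in kept_rc):
            continue
        di = dj = 0.0
        if 0 < i < resp.shape[0] - 1:
            di = _parabolic_offset(resp[i - 1, j], resp[i, j], resp[i + 1, j])
        if 0 < j < resp.shape[1] - 1:
            dj = _parabolic_offset(resp[i, j - 1], resp[i, j], resp[i, j + 1])
        kept_rc.append((i, j))
        spots.append(
            Spot(
                frame=frame_index,
                x=(j + dj) * pixel_size,
                y=(i + di) * pixel_size,
                intensity=float(img[i, j]),
                quality=float(resp[i, j]),
            )
        )
    return spots


def _as_frame_dict(
    spots_by_frame: Mapping[int, Sequence[Spot]] | Sequence[Sequence[Spot]],
) -> dict[int, list[Spot]]:
    if isinstance(spots_by_frame, Mapping):
        return {int(f): list(s) for f, s in spots_by_frame.items()}
    return {f: list(s) for f, s in enumerate(spots_by_frame)}


def link_tracks(
    spots_by_frame: Mapping[int, Sequence[Spot]] | Sequence[Sequence[Spot]],
    max_displacement: float,
    min_track_length: int = 150,
    frame_interval: float = 0.5,
    condition: str = "untreated",
) -> list[Trajectory]:
    """Link per-frame detections into trajectories.

    Frame-to-frame correspondence is the assignment minimising total squared
    displacement (Hungarian algorithm) subject to a hard gate: pairs farther
    apart than ``max_displacement`` µm are never linked.  There is no gap
    closing — a track not extended in the next frame is terminated.  Tracks
    must be *longer than* ``min_track_length`` frames to be returned, i.e.
    at least ``min_track_length + 1`` points.

    Parameters
    ----------
    spots_by_frame:
        Mapping frame index -> spots, or a list indexed by frame.
    max_displacement:
        Gate in µm on the frame-to-frame displacement.
    min_track_length:
        Strict lower bound on track length in frames (default 150, i.e. only
        tracks with >= 151 points survive).
    """
    if not max_displacement > 0:
        raise ValueError("max_displacement must be > 0")
    frames = _as_frame_dict(spots_by_frame)
    if not frames:
        return []

    finished: list[list[Spot]] = []
    active: list[list[Spot]] = []
    last_frame = None
    for f in sorted(frames):
        spots = frames[f]
        if last_frame is not None and f != last_frame + 1:
            finished.extend(active)  # temporal gap: no gap closing
            active = []
        if not active:
            active = [[s] for s in spots]
            last_frame = f
            continue

        ends = np.array([[t[-1].x, t[-1].y] for t in active])
        if spots:
            pos = np.array([[s.x, s.y] for s in spots])
            d2 = ((ends[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
            cost = np.where(d2 <= max_displacement**2, d2, _GATED)
            rows, cols = linear_sum_assignment(cost)
        else:
            rows, cols = np.array([], dtype=int), np.array([], dtype=int)

        extended = set()
        used_spots = set()
        for r, c in zip(rows, cols):
            if cost[r, c] < _GATED:
                active[r].append(spots[c])
                extended.add(r)
                used_spots.add(c)
        next_active = [t for r, t in enumerate(active) if r in extended]
        finished.extend(t for r, t in enumerate(active) if r not in extended)
        next_active.extend([s] for c, s in enumerate(spots) if c not in used_spots)
        active = next_active
        last_frame = f
    finished.extend(active)

    tracks = []
    tid = 0
    for pts in finished:
        if len(pts) < max(2, min_track_length + 1):
            continue
        tracks.append(
            Trajectory(
                track_id=tid,
                frames=[s.frame for s in pts],
                x=[s.x for s in pts],
                y=[s.y for s in pts],
                frame_interval=frame_interval,
                condition=condition,
            )
        )
        tid += 1
    return tracks


def write_track_table(tracks: Sequence[Trajectory], path) -> None:
    """Write tracks as CSV with columns track_id, frame, t_s, x_um, y_um.

    Coordinates are written with 6 decimals, so a write→read round trip is
    lossless at that precision.  The column subset (track id, frame, position)
    is compatible with TrackMate "spots" CSV exports.
    """
    rows = []
    for t in tracks:
        for f, xx, yy in zip(t.frames, t.x, t.y):
            rows.append(
                {
                    "track_id": t.track_id,
                    "frame": int(f),
                    "t_s": f * t.frame_interval,
                    "x_um": xx,
                    "y_um": yy,
                    "condition": t.condition,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def read_track_table(
    path,
    pixel_size: float | None = None,
    frame_interval: float = 0.5,
    condition: str | None = None,
) -> list[Trajectory]:
    """Read a track table CSV into trajectories.

    Requires columns ``track_id`` and ``frame`` plus either ``x_um``/``y_um``
    (µm) or ``x``/``y``; plain ``x``/``y`` are interpreted as pixels and
    require ``pixel_size`` to convert (µm = pixel × pixel_size).  Duplicated
    (track, frame) rows and non-monotone frames raise errors naming the track.
    """
    df = pd.read_csv(path)
    if "x_um" in df.columns and "y_um" in df.columns:
        xcol, ycol, scale = "x_um", "y_um", 1.0
    elif "x" in df.columns and "y" in df.columns:
        if pixel_size is None:
            raise ValueError("columns x/y are in pixels: pixel_size is required")
        xcol, ycol, scale = "x", "y", float(pixel_size)
    else:
        raise ValueError("track table must have columns x_um/y_um or x/y")
    for col in ("track_id", "frame"):
        if col not in df.columns:
            raise ValueError(f"track table missing required column {col!r}")

    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        frames = grp["frame"].to_numpy(dtype=int)
        if pd.Series(frames).duplicated().any():
            raise ValueError(f"track {tid!r}: duplicated (track, frame) rows")
        if np.any(np.diff(frames) <= 0):
            raise ValueError(f"track {tid!r}: frames not strictly increasing")
        cond = condition
        if cond is None:
            cond = str(grp["condition"].iloc[0]) if "condition" in grp.columns else "untreated"
        tracks.append(
            Trajectory(
                track_id=tid,
                frames=frames,
                x=grp[xcol].to_numpy(dtype=float) * scale,
                y=grp[ycol].to_numpy(dtype=float) * scale,
                frame_interval=frame_interval,
                condition=cond,
            )
        )
    return tracks
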