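"""Synthetic trajectories and images with known ground truth.

Two generators make every downstream stage testable without real microscopy
data:

* **Trajectories** — 2D fractional Brownian motion realising the anomalous
  diffusion law ``MSD(t) = 4 D t^alpha`` (per axis: fGn increments with Hurst
  exponent ``H = alpha/2`` and variance ``2 D dt^alpha``), plus optional
  constant drift and static localization error.
* **Images** — roundish bright clusters on a dark background: a red core disk
  and a concentric green disk (or annulus) grown by a configurable fraction,
  blurred by a Gaussian confocal PSF, with optional Poisson shot noise and
  Gaussian read noise.  Ground truth (centers, diameters, D, alpha) is
  returned alongside every render.

All generators are pure functions of their configuration including the seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from scipy.linalg import toeplitz

from .tracking import Trajectory

__all__ = [
    "TrackSimConfig",
    "ImageSimConfig",
    "TwoChannelImage",
    "ImageStack",
    "fractional_gaussian_noise",
    "fgn_autocovariance",
    "simulate_track",
    "simulate_population",
    "render_cluster_pair",
    "render_movie",
    "write_two_channel_tiff",
    "write_movie_tiff",
    "write_ground_truth",
    "write_config_sidecar",
]

GROUND_TRUTH_COLUMNS = ["id", "frame", "x_um", "y_um", "d_r_um", "d_g_um", "D", "alpha"]


@dataclass(frozen=True)
class TrackSimConfig:
    """Parameters of one simulated trajectory.

    Defaults reproduce the reported live-cell imaging conditions: subdiffusive
    clusters (alpha ≈ 0.74, D ≈ 0.0045 µm²/s) imaged every 0.5 s for
    300 frames.

    Attributes
    ----------
    D:
        Short-term diffusion coefficient, µm²/s (prefactor of the 2D MSD
        power law at t = 1 s).
    alpha:
        Anomalous exponent; alpha < 1 subdiffusive, 1 Brownian, 2 ballistic.
        Must lie in (0, 2] — outside that range the fGn covariance is not
        positive semi-definite.
    n_frames:
        Number of positions (>= 2).
    frame_interval:
        Seconds between frames.
    drift_velocity:
        Constant (vx, vy) drift in µm/s, modelling directionally moving
        clusters.
    loc_noise_sd:
        Static localization error, µm per axis, added independently to every
        position.
    seed:
        RNG seed; same config (including seed) gives identical output.
    """

    D: float = 0.0045
    alpha: float = 0.74
    n_frames: int = 300
    frame_interval: float = 0.5
    drift_velocity: tuple[float, float] = (0.0, 0.0)
    loc_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if not 0 < self.alpha <= 2:
            raise ValueError("alpha must be in (0, 2]")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        if self.loc_noise_sd < 0:
            raise ValueError("loc_noise_sd must be >= 0")


@dataclass(frozen=True)
class ImageSimConfig:
    """Parameters of rendered cluster images.

    The defaults assume 0.1 µm pixels and a Gaussian PSF with sigma 0.085 µm
    (≈ 200 nm FWHM lateral confocal resolution).  Neither is a measured value
    from the source study — both are stated assumptions and always flow from
    this config, never from constants inside algorithms.
    """

    pixel_size: float = 0.1  # µm / px
    psf_sigma: float = 0.085  # µm
    core_diameter: float = 1.0  # µm, red-channel disk
    shell_growth_fraction: float = 0.16  # d_g = d_r * (1 + fraction)
    peak_intensity: float = 1000.0  # photons at the blurred plateau
    background: float = 10.0  # photons
    noise_model: str = "poisson"  # none | poisson | poisson+gaussian
    read_noise_sd: float = 1.0  # photons, for poisson+gaussian
    image_shape: tuple[int, int] = (64, 64)  # (rows, cols)
    supersample: int = 8  # anti-aliasing factor for disk rasterisation
    green_as_annulus: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if not self.psf_sigma > 0:
            raise ValueError("psf_sigma must be > 0")
        if not self.core_diameter > 0:
            raise ValueError("core_diameter must be > 0")
        if self.shell_growth_fraction < 0:
            raise ValueError("shell_growth_fraction must be >= 0")
        if self.peak_intensity < 0 or self.background < 0:
            raise ValueError("intensities must be >= 0")
        if self.noise_model not in ("none", "poisson", "poisson+gaussian"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")


@dataclass
class TwoChannelImage:
    """Co-registered red/green rasters with a common pixel size (µm/px)."""

    red: np.ndarray
    green: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        if self.red.shape != self.green.shape:
            raise ValueError("red and green rasters must share a shape")


@dataclass
class ImageStack:
    """A time series of frames (T, rows, cols) with calibration."""

    data: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack must be (T, rows, cols)")


# ---------------------------------------------------------------------------
# fractional Gaussian noise
# ---------------------------------------------------------------------------

def fgn_autocovariance(lags: np.ndarray, alpha: float, variance: float) -> np.ndarray:
    """Autocovariance of fGn increments with Var = ``variance`` per step.

    gamma(k) = (variance / 2) * (|k+1|^alpha - 2|k|^alpha + |k-1|^alpha)
    """
    k = np.abs(np.asarray(lags, dtype=float))
    return 0.5 * variance * (
        (k + 1.0) ** alpha - 2.0 * k**alpha + np.abs(k - 1.0) ** alpha
    )


def _fgn_davies_harte(n: int, alpha: float, variance: float, rng) -> np.ndarray | None:
    """Exact fGn by circulant embedding; None if the embedding is not PSD."""
    g = fgn_autocovariance(np.arange(n + 1), alpha, variance)
    c = np.concatenate([g[:n], g[n:n + 1], g[n - 1:0:-1]])
    lam = np.fft.fft(c).real
    if lam.min() < -1e-8 * max(abs(lam).max(), 1e-300):
        return None
    lam = np.clip(lam, 0.0, None)
    m = 2 * n
    z = rng.standard_normal(m)
    xi = np.empty(m, dtype=complex)
    xi[0] = z[0]
    xi[n] = z[n]
    if n > 1:
        k = np.arange(1, n)
        xi[k] = (z[k] + 1j * z[n + k]) / math.sqrt(2.0)
        xi[m - k] = xi[k].conj()
    return np.fft.fft(np.sqrt(lam / m) * xi).real[:n]


def _fgn_cholesky(n: int, alpha: float, variance: float, rng) -> np.ndarray:
    """Exact-covariance fallback: Cholesky factor of the Toeplitz covariance."""
    cov = toeplitz(fgn_autocovariance(np.arange(n), alpha, variance))
    jitter = 1e-12 * max(variance, 1e-300)
    chol = np.linalg.cholesky(cov + jitter * np.eye(n))
    return chol @ rng.standard_normal(n)


def fractional_gaussian_noise(
    n: int, alpha: float, variance: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` stationary fGn increments (Hurst H = alpha/2).

    Uses Davies–Harte circulant embedding (O(n log n)); if the embedding
    fails to be positive semi-definite for a given length, falls back to a
    Cholesky factorisation of the exact covariance matrix.
    """
    if not 0 < alpha <= 2:
        raise ValueError("alpha must be in (0, 2]")
    if n == 0:
        return np.zeros(0)
    out = _fgn_davies_harte(n, alpha, variance, rng)
    if out is None:
        out = _fgn_cholesky(n, alpha, variance, rng)
    return out


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------

def simulate_track(
    cfg: TrackSimConfig,
    track_id: int | str = 0,
    condition: str = "untreated",
    origin: tuple[float, float] = (0.0, 0.0),
) -> Trajectory:
    """Simulate one 2D trajectory with ensemble MSD ``4 D t^alpha``.

    Per axis the increments are fractional Gaussian noise with variance
    ``2 D dt^alpha`` per step, so the drift- and noise-free 2D ensemble MSD
    equals ``4 D t^alpha`` exactly.  Drift adds ``v * t``; localization error
    adds iid Gaussian offsets per position (contributing a constant
    ``4 * loc_noise_sd**2`` to the expected 2D MSD at every positive lag).
    """
    rng = np.random.default_rng(cfg.seed)
    n, dt = cfg.n_frames, cfg.frame_interval
    t = np.arange(n) * dt
    if cfg.D > 0:
        variance = 2.0 * cfg.D * dt**cfg.alpha
        x = np.concatenate([[0.0], np.cumsum(fractional_gaussian_noise(n - 1, cfg.alpha, variance, rng))])
        y = np.concatenate([[0.0], np.cumsum(fractional_gaussian_noise(n - 1, cfg.alpha, variance, rng))])
    else:
        x = np.zeros(n)
        y = np.zeros(n)
    x = x + origin[0] + cfg.drift_velocity[0] * t
    y = y + origin[1] + cfg.drift_velocity[1] * t
    if cfg.loc_noise_sd > 0:
        x = x + rng.normal(0.0, cfg.loc_noise_sd, n)
        y = y + rng.normal(0.0, cfg.loc_noise_sd, n)
    return Trajectory(
        track_id=track_id,
        frames=np.arange(n),
        x=x,
        y=y,
        frame_interval=dt,
        condition=condition,
    )


def derive_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2**31) for a population of generators."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def simulate_population(
    cfg: TrackSimConfig,
    n_tracks: int,
    seed: int,
    condition: str = "untreated",
    origins: Sequence[tuple[float, float]] | None = None,
) -> list[Trajectory]:
    """Simulate ``n_tracks`` independent trajectories sharing one config.

    Per-track seeds are derived deterministically from ``seed``; ``cfg.seed``
    is ignored.  ``origins`` optionally places each track's first position.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    if origins is not None and len(origins) != n_tracks:
        raise ValueError("origins must match n_tracks")
    seeds = derive_seeds(seed, n_tracks)
    tracks = []
    for i, s in enumerate(seeds):
        sub = dataclasses.replace(cfg, seed=s)
        origin = origins[i] if origins is not None else (0.0, 0.0)
        tracks.append(simulate_track(sub, track_id=i, condition=condition, origin=origin))
    return tracks


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

def _render_disks(
    centers_um: np.ndarray,
    radii_um: np.ndarray,
    cfg: ImageSimConfig,
) -> np.ndarray:
    """Rasterise filled disks (indicator height 1), PSF-blur and scale.

    Disks are drawn on a ``supersample``-times finer grid, block-averaged to
    pixel resolution, then convolved with the Gaussian PSF; the result is
    ``background + peak_intensity * blurred indicator`` so a disk much larger
    than the PSF reaches a plateau of ``peak_intensity`` above background.
    """
    rows, cols = cfg.image_shape
    ss = cfg.supersample
    canvas = np.zeros((rows * ss, cols * ss))
    for (cx, cy), r in zip(np.atleast_2d(centers_um), np.atleast_1d(radii_um)):
        # pixel coords -> supersampled coords: px p covers [p*ss, (p+1)*ss)
        cy_ss = (cy / cfg.pixel_size + 0.5) * ss - 0.5
        cx_ss = (cx / cfg.pixel_size + 0.5) * ss - 0.5
        r_ss = r / cfg.pixel_size * ss
        i0 = max(0, int(math.floor(cy_ss - r_ss)) - 1)
        i1 = min(rows * ss, int(math.ceil(cy_ss + r_ss)) + 2)
        j0 = max(0, int(math.floor(cx_ss - r_ss)) - 1)
        j1 = min(cols * ss, int(math.ceil(cx_ss + r_ss)) + 2)
        if i0 >= i1 or j0 >= j1:
            continue
        ii = np.arange(i0, i1)[:, None] - cy_ss
        jj = np.arange(j0, j1)[None, :] - cx_ss
        window = canvas[i0:i1, j0:j1]
        np.maximum(window, (ii**2 + jj**2 <= r_ss**2).astype(float), out=window)
    img = canvas.reshape(rows, ss, cols, ss).mean(axis=(1, 3))
    img = ndimage.gaussian_filter(img, cfg.psf_sigma / cfg.pixel_size, mode="constant")
    return cfg.background + cfg.peak_intensity * img


def _apply_noise(img: np.ndarray, cfg: ImageSimConfig, rng) -> np.ndarray:
    if cfg.noise_model == "none":
        return img
    noisy = rng.poisson(np.clip(img, 0.0, None)).astype(float)
    if cfg.noise_model == "poisson+gaussian":
        noisy = noisy + rng.normal(0.0, cfg.read_noise_sd, img.shape)
    return noisy


def _check_margin(center_um, radius_um, cfg: ImageSimConfig, label: str) -> None:
    rows, cols = cfg.image_shape
    margin = radius_um + 3.0 * cfg.psf_sigma
    cx, cy = center_um
    x_max = (cols - 1) * cfg.pixel_size
    y_max = (rows - 1) * cfg.pixel_size
    if cx - margin < 0 or cx + margin > x_max or cy - margin < 0 or cy + margin > y_max:
        raise ValueError(
            f"{label} at ({cx:.3f}, {cy:.3f}) µm violates the required margin of "
            f"radius + 3*psf_sigma = {margin:.3f} µm inside the "
            f"{y_max:.3f} x {x_max:.3f} µm field"
        )


def render_cluster_pair(
    cfg: ImageSimConfig,
    center_um: tuple[float, float] | None = None,
    cluster_id: int = 0,
) -> tuple[TwoChannelImage, pd.DataFrame]:
    """Render one pulse-chase cluster pair plus its ground truth.

    The red channel holds a disk of ``core_diameter`` (pre-existing core);
    the green channel a concentric disk of
    ``core_diameter * (1 + shell_growth_fraction)`` (core plus newly added
    shell), or an annulus between the two diameters if
    ``green_as_annulus=True``.  Both are blurred with the Gaussian PSF, then
    noise is applied.

    Returns
    -------
    (image, ground_truth):
        :class:`TwoChannelImage` and a one-row DataFrame with columns
        ``id, x_um, y_um, d_r_um, d_g_um``.
    """
    rows, cols = cfg.image_shape
    if center_um is None:
        center_um = ((cols - 1) / 2 * cfg.pixel_size, (rows - 1) / 2 * cfg.pixel_size)
    d_r = cfg.core_diameter
    d_g = d_r * (1.0 + cfg.shell_growth_fraction)
    _check_margin(center_um, d_g / 2, cfg, "cluster")

    centers = np.array([center_um])
    red = _render_disks(centers, np.array([d_r / 2]), cfg)
    if cfg.green_as_annulus and cfg.shell_growth_fraction > 0:
        outer = _render_disks(centers, np.array([d_g / 2]), cfg)
        inner = _render_disks(centers, np.array([d_r / 2]), cfg)
        green = outer - inner + cfg.background
    else:
        green = _render_disks(centers, np.array([d_g / 2]), cfg)

    rng = np.random.default_rng(cfg.seed)
    red = _apply_noise(red, cfg, rng)
    green = _apply_noise(green, cfg, rng)
    gt = pd.DataFrame(
        [
            {
                "id": cluster_id,
                "x_um": center_um[0],
                "y_um": center_um[1],
                "d_r_um": d_r,
                "d_g_um": d_g,
            }
        ]
    )
    return TwoChannelImage(red, green, cfg.pixel_size), gt


def render_movie(
    tracks: Sequence[Trajectory],
    cfg: ImageSimConfig,
    truth: pd.DataFrame | None = None,
) -> tuple[ImageStack, pd.DataFrame]:
    """Render a time-lapse movie of clusters following the given tracks.

    Every frame shows each active track as a PSF-blurred disk of
    ``core_diameter`` at its true position.  The returned ground truth has one
    row per (track, frame) with the true position and diameter; pairs of
    clusters closer than the sum of their radii in any frame are recorded in
    ``ground_truth.attrs['overlap_warnings']`` so tests may exclude them.

    Parameters
    ----------
    truth:
        Optional per-track table with columns ``id, D, alpha`` to carry the
        simulation parameters into the ground-truth output.
    """
    radius = cfg.core_diameter / 2
    frame_interval = tracks[0].frame_interval if tracks else 0.5
    n_frames = max((int(t.frames.max()) for t in tracks), default=-1) + 1
    n_frames = max(n_frames, 1)

    by_frame: dict[int, list[tuple]] = {f: [] for f in range(n_frames)}
    gt_rows = []
    for t in tracks:
        for f, xx, yy in zip(t.frames, t.x, t.y):
            _check_margin((xx, yy), radius, cfg, f"track {t.track_id} frame {f}")
            by_frame[int(f)].append((t.track_id, xx, yy))
            gt_rows.append(
                {"id": t.track_id, "frame": int(f), "x_um": xx, "y_um": yy,
                 "d_r_um": cfg.core_diameter}
            )

    warnings = []
    rng = np.random.default_rng(cfg.seed)
    frames = np.empty((n_frames, *cfg.image_shape))
    for f in range(n_frames):
        entries = by_frame[f]
        if entries:
            centers = np.array([(e[1], e[2]) for e in entries])
            for a in range(len(entries)):
                for b in range(a + 1, len(entries)):
                    if np.hypot(*(centers[a] - centers[b])) < 2 * radius:
                        warnings.append(
                            {"frame": f, "id_a": entries[a][0], "id_b": entries[b][0]}
                        )
            img = _render_disks(centers, np.full(len(entries), radius), cfg)
        else:
            img = np.full(cfg.image_shape, float(cfg.background))
        frames[f] = _apply_noise(img, cfg, rng)

    gt = pd.DataFrame(gt_rows, columns=["id", "frame", "x_um", "y_um", "d_r_um"])
    if truth is not None and len(gt):
        gt = gt.merge(truth, on="id", how="left")
    gt.attrs["overlap_warnings"] = warnings
    return ImageStack(frames, cfg.pixel_size, frame_interval), gt


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_two_channel_tiff(image: TwoChannelImage, path) -> None:
    """Write a two-channel (CYX) TIFF, red first."""
    stack = np.stack([image.red, image.green]).astype(np.float32)
    tifffile.imwrite(path, stack, metadata={"axes": "CYX"})


def write_movie_tiff(stack: ImageStack, path) -> None:
    """Write a multi-page (TYX) TIFF time series."""
    tifffile.imwrite(path, stack.data.astype(np.float32), metadata={"axes": "TYX"})


def write_ground_truth(gt: pd.DataFrame, path) -> None:
    """Write a ground-truth table as CSV with the canonical column order."""
    cols = [c for c in GROUND_TRUTH_COLUMNS if c in gt.columns]
    cols += [c for c in gt.columns if c not in cols]
    gt.loc[:, cols].to_csv(path, index=False)


def write_config_sidecar(cfg, path) -> None:
    """Write any sim config (including seed) as a JSON sidecar."""
    payload = {"type": type(cfg).__name__, **dataclasses.asdict(cfg)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=list)
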