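"""Mean-square displacement analysis and anomalous-diffusion fitting.

Per track, the time-averaged MSD with overlapping displacement pairs is

    MSD(k dt) = mean over i of |r(i+k) - r(i)|^2 ,

and the anomalous-diffusion model ``MSD = 4 D t^alpha`` is fit to the first
``n_points`` lags (default 20) by ordinary least squares of log MSD on
log t — exact on noiseless power laws and free of scale choices.  alpha is the
slope and ``D = exp(intercept) / 4``.

Population-level helpers summarise fits (mean ± SEM over tracks), correlate
mobility with cluster size (Spearman), and compare experimental arms
(two-sided Mann–Whitney U per parameter), mirroring the untreated-vs-
nocodazole comparison where only D, not alpha or size, responds to
microtubule depolymerisation.

Static localization error adds a constant to the MSD at all lags; because the
model has no offset term, it biases fitted alpha downward at small lags.  That
bias is documented and tested, not corrected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tracking import Trajectory

__all__ = [
    "MSDCurve",
    "DiffusionFit",
    "PopulationSummary",
    "ConditionComparison",
    "compute_msd",
    "fit_anomalous",
    "summarize_population",
    "size_mobility_relation",
    "compare_conditions",
    "fits_to_dataframe",
    "plot_msd_curves",
]

ALPHA_SOFT_CAP = 2.5
# directed/ballistic motion flag; the tolerance keeps the exact ballistic
# limit (alpha = 2 up to roundoff) flagged
SUPERDIFFUSIVE_THRESHOLD = 2.0 - 1e-6


@dataclass
class MSDCurve:
    """Time-averaged MSD of one track: lags (s), values (µm²), pair counts."""

    lags: np.ndarray
    values: np.ndarray
    n_pairs: np.ndarray
    track_id: int | str = 0
    condition: str = "untreated"

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if not (len(self.lags) == len(self.values) == len(self.n_pairs)):
            raise ValueError("lags/values/n_pairs length mismatch")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("MSD values must be >= 0")


@dataclass(frozen=True)
class DiffusionFit:
    """Per-track anomalous-diffusion estimates.

    ``superdiffusive`` flags alpha at or above 2 (directed motion, up to
    roundoff at the exact ballistic limit); alpha is soft-capped at 2.5 so
    drifting clusters stay visible rather than silently clipped.
    """

    D: float  # µm²/s
    alpha: float
    n_points_fit: int
    r_squared: float
    track_id: int | str = 0
    condition: str = "untreated"
    superdiffusive: bool = False

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if not 0 < self.alpha <= ALPHA_SOFT_CAP:
            raise ValueError(f"alpha must be in (0, {ALPHA_SOFT_CAP}]")
        if self.n_points_fit < 2:
            raise ValueError("n_points_fit must be >= 2")


@dataclass(frozen=True)
class PopulationSummary:
    """Mean ± SEM of D and alpha over tracks of one condition."""

    mean_D: float
    sem_D: float
    mean_alpha: float
    sem_alpha: float
    n_tracks: int
    condition: str = "untreated"


@dataclass(frozen=True)
class ConditionComparison:
    """Two-group comparison of D, alpha (and optionally diameter).

    ``tests`` maps parameter name to a dict with the test statistic, p-value,
    group means, the effect ratio of group means (b / a) and of group medians
    (the source data are unpaired, so a mean of per-track ratios is not
    defined).
    """

    tests: dict
    n_a: int
    n_b: int
    label_a: str = "a"
    label_b: str = "b"
    method: str = "mannwhitney"


def compute_msd(track: Trajectory, max_lag_fraction: float = 0.25) -> MSDCurve:
    """Time-averaged MSD with overlapping pairs, up to a fraction of the track.

    The curve covers lags ``k = 1 .. floor(max_lag_fraction * n_points)`` (at
    least 1); ``n_pairs[k-1] = n_points - k`` for a gap-free track.

    Raises
    ------
    ValueError
        If the track has fewer than 3 points, frames are not consecutive, or
        ``max_lag_fraction`` is outside (0, 1].
    """
    if not 0 < max_lag_fraction <= 1:
        raise ValueError("max_lag_fraction must be in (0, 1]")
    n = track.n_points
    if n < 3:
        raise ValueError("track too short for an MSD curve (need >= 3 points)")
    if np.any(np.diff(track.frames) != 1):
        raise ValueError(f"track {track.track_id!r}: frames must be consecutive")
    k_max = max(1, int(math.floor(max_lag_fraction * n)))
    k_max = min(k_max, n - 1)
    lags = np.arange(1, k_max + 1) * track.frame_interval
    values = np.empty(k_max)
    n_pairs = np.empty(k_max, dtype=int)
    for k in range(1, k_max + 1):
        dx = track.x[k:] - track.x[:-k]
        dy = track.y[k:] - track.y[:-k]
        values[k - 1] = np.mean(dx**2 + dy**2)
        n_pairs[k - 1] = n - k
    return MSDCurve(lags, values, n_pairs, track_id=track.track_id, condition=track.condition)


def fit_anomalous(curve: MSDCurve, n_points: int = 20) -> DiffusionFit:
    """Fit ``MSD = 4 D t^alpha`` to the first ``n_points`` lags of a curve.

    Ordinary least squares of log MSD on log lag; alpha is the slope and
    ``D = exp(intercept)/4``.  Exact on noiseless power laws.

    Raises
    ------
    ValueError
        If the curve has fewer than ``n_points`` lags, or any MSD value in
        the window is non-positive ("log-fit undefined"; the caller may drop
        the track).
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if len(curve.lags) < n_points:
        raise ValueError(
            f"curve has {len(curve.lags)} lags, fewer than n_points={n_points}"
        )
    t = curve.lags[:n_points]
    m = curve.values[:n_points]
    if np.any(m <= 0):
        raise ValueError("log-fit undefined: non-positive MSD value in the fit window")
    log_t = np.log(t)
    log_m = np.log(m)
    slope, intercept = np.polyfit(log_t, log_m, 1)
    resid = log_m - (slope * log_t + intercept)
    ss_tot = np.sum((log_m - log_m.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0
    alpha = float(min(slope, ALPHA_SOFT_CAP))
    return DiffusionFit(
        D=float(np.exp(intercept) / 4.0),
        alpha=alpha,
        n_points_fit=n_points,
        r_squared=r2,
        track_id=curve.track_id,
        condition=curve.condition,
        superdiffusive=alpha >= SUPERDIFFUSIVE_THRESHOLD,
    )


def summarize_population(
    fits: Sequence[DiffusionFit], condition: str | None = None
) -> PopulationSummary:
    """Mean and SEM (SD/sqrt(n) over tracks) of D and alpha."""
    if not fits:
        raise ValueError("summarize_population requires at least one fit")
    D = np.array([f.D for f in fits])
    alpha = np.array([f.alpha for f in fits])
    n = len(fits)
    sem = lambda v: float(v.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return PopulationSummary(
        mean_D=float(D.mean()),
        sem_D=sem(D),
        mean_alpha=float(alpha.mean()),
        sem_alpha=sem(alpha),
        n_tracks=n,
        condition=condition if condition is not None else fits[0].condition,
    )


def size_mobility_relation(
    fits: Sequence[DiffusionFit], diameters: Sequence[float]
) -> dict:
    """Spearman correlation of D and of alpha against cluster diameter.

    Returns ``{"D": (rho, p), "alpha": (rho, p), "n": n}``.  Subdiffusing
    aggregates are expected to show a negative D–diameter correlation and no
    alpha–diameter dependence.

    Raises
    ------
    ValueError
        On length mismatch, fewer than 3 pairs, or constant input
        ("degenerate ranks").
    """
    if len(fits) != len(diameters):
        raise ValueError("fits and diameters must be paired (equal length)")
    if len(fits) < 3:
        raise ValueError("need at least 3 paired observations")
    d = np.asarray(diameters, dtype=float)
    out = {"n": len(fits)}
    for name, vals in (("D", np.array([f.D for f in fits])),
                       ("alpha", np.array([f.alpha for f in fits]))):
        if np.ptp(vals) == 0 or np.ptp(d) == 0:
            raise ValueError(f"degenerate ranks: constant {name} or diameter input")
        rho, p = stats.spearmanr(vals, d)
        out[name] = (float(rho), float(p))
    return out


def compare_conditions(
    fits_a: Sequence[DiffusionFit],
    fits_b: Sequence[DiffusionFit],
    diameters_a: Sequence[float] | None = None,
    diameters_b: Sequence[float] | None = None,
    method: str = "mannwhitney",
) -> ConditionComparison:
    """Compare two experimental arms parameter by parameter.

    Per parameter (D, alpha, and diameter if provided) runs a two-sided
    Mann–Whitney U test (or Welch t-test with ``method="welch"``) and reports
    group means, the ratio of means (b / a) and the ratio of medians.

    Raises
    ------
    ValueError
        If either group has fewer than 3 tracks.
    """
    if len(fits_a) < 3 or len(fits_b) < 3:
        raise ValueError("each group needs at least 3 tracks")
    if method not in ("mannwhitney", "welch"):
        raise ValueError("method must be 'mannwhitney' or 'welch'")

    params: dict[str, tuple[np.ndarray, np.ndarray]] = {
        "D": (np.array([f.D for f in fits_a]), np.array([f.D for f in fits_b])),
        "alpha": (np.array([f.alpha for f in fits_a]), np.array([f.alpha for f in fits_b])),
    }
    if diameters_a is not None and diameters_b is not None:
        params["diameter"] = (np.asarray(diameters_a, float), np.asarray(diameters_b, float))

    tests = {}
    for name, (a, b) in params.items():
        if method == "mannwhitney":
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
        mean_a, mean_b = float(a.mean()), float(b.mean())
        tests[name] = {
            "statistic": float(res.statistic),
            "p_value": float(res.pvalue),
            "mean_a": mean_a,
            "mean_b": mean_b,
            "ratio_of_means": mean_b / mean_a if mean_a != 0 else math.inf,
            "ratio_of_medians": (
                float(np.median(b)) / float(np.median(a))
                if np.median(a) != 0
                else math.inf
            ),
        }
    return ConditionComparison(
        tests=tests,
        n_a=len(fits_a),
        n_b=len(fits_b),
        label_a=fits_a[0].condition,
        label_b=fits_b[0].condition,
        method=method,
    )


def fits_to_dataframe(fits: Sequence[DiffusionFit]) -> pd.DataFrame:
    """Per-track fits as a table (track_id, D_um2_s, alpha, r2, n_points_fit)."""
    return pd.DataFrame(
        {
            "track_id": [f.track_id for f in fits],
            "condition": [f.condition for f in fits],
            "D_um2_s": [f.D for f in fits],
            "alpha": [f.alpha for f in fits],
            "r2": [f.r_squared for f in fits],
            "n_points_fit": [f.n_points_fit for f in fits],
            "superdiffusive": [f.superdiffusive for f in fits],
        }
    )


def plot_msd_curves(curves: Sequence[MSDCurve], path=None, color: str = "tab:orange"):
    """Plot individual MSD curves (thin) with their average (thick).

    Matplotlib is imported lazily; with ``path`` given the figure is saved and
    closed (headless safe), otherwise the figure is returned.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    min_len = min(len(c.values) for c in curves)
    for c in curves:
        ax.plot(c.lags, c.values, color=color, alpha=0.3, lw=0.7)
    avg = np.mean([c.values[:min_len] for c in curves], axis=0)
    ax.plot(curves[0].lags[:min_len], avg, color=color, lw=2.5, label="average")
    ax.set_xlabel("lag time (s)")
    ax.set_ylabel("MSD (µm²)")
    ax.legend()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def write_comparison_json(comparison: ConditionComparison, path) -> None:
    payload = {
        "label_a": comparison.label_a,
        "label_b": comparison.label_b,
        "n_a": comparison.n_a,
        "n_b": comparison.n_b,
        "method": comparison.method,
        "tests": comparison.tests,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
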