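"""End-to-end orchestration: simulate or ingest, track, fit, summarise, compare.

A :class:`RunConfig` captures every constant of a run — pixel size, frame
interval, detection/linking/fit/morphometry parameters, seeds and condition
labels — and is echoed verbatim into the output directory so any run can be
reproduced from its artifacts alone.  :func:`end_to_end` executes the chain

    simulate/ingest -> (detect -> link) -> filter -> MSD fit -> summarise -> compare

and returns a :class:`RunReport` with an input manifest (paths + SHA-256),
per-stage counts that reconcile (kept + dropped = detected), population
summaries and, with exactly two conditions, a condition comparison.  Every
dropped track is logged with its reason.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .msd import (
    compare_conditions,
    compute_msd,
    fit_anomalous,
    fits_to_dataframe,
    summarize_population,
    write_comparison_json,
)
from .synth import ImageSimConfig, TrackSimConfig, render_movie, simulate_population
from .tracking import detect_spots, link_tracks, read_track_table, write_track_table

logger = logging.getLogger("erclust")

__all__ = [
    "DetectionParams",
    "LinkingParams",
    "FitParams",
    "MorphometryParams",
    "ConditionSpec",
    "RunConfig",
    "RunReport",
    "load_config",
    "end_to_end",
]


@dataclass(frozen=True)
class DetectionParams:
    expected_diameter: float = 0.6  # µm
    quality_threshold: float | None = None


@dataclass(frozen=True)
class LinkingParams:
    max_displacement: float = 0.5  # µm per frame
    min_track_length: int = 150  # strict: tracks longer than this survive


@dataclass(frozen=True)
class FitParams:
    n_points: int = 20
    max_lag_fraction: float = 0.25


@dataclass(frozen=True)
class MorphometryParams:
    n_angles: int = 8
    half_length_um: float | None = None


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental arm: either simulated tracks or an input track table."""

    label: str
    n_tracks: int = 115
    n_frames: int = 300
    D: float = 0.0045  # µm²/s
    alpha: float = 0.74
    drift_velocity: tuple[float, float] = (0.0, 0.0)
    loc_noise_sd: float = 0.0
    track_table: str | None = None  # ingest this CSV instead of simulating


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of a full run; written verbatim to the output."""

    pixel_size: float = 0.1  # µm/px
    frame_interval: float = 0.5  # s
    detection: DetectionParams = field(default_factory=DetectionParams)
    linking: LinkingParams = field(default_factory=LinkingParams)
    fit: FitParams = field(default_factory=FitParams)
    morphometry: MorphometryParams = field(default_factory=MorphometryParams)
    conditions: tuple[ConditionSpec, ...] = (
        ConditionSpec(label="untreated"),
        ConditionSpec(label="nocodazole", D=0.00225),
    )
    seed: int = 0
    render_movies: bool = False  # run the detect+link stages on rendered frames
    image: ImageSimConfig = field(default_factory=lambda: ImageSimConfig(
        core_diameter=0.6, image_shape=(128, 128), noise_model="none"))

    def __post_init__(self) -> None:
        for name, value in (
            ("pixel_size", self.pixel_size),
            ("frame_interval", self.frame_interval),
        ):
            if not value > 0:
                raise ValueError(f"{name} must be > 0")
        if not self.conditions:
            raise ValueError("at least one condition is required")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    """What a run did: manifest, reconciled counts, summaries, comparison."""

    config_hash: str
    manifest: dict
    counts: dict
    summaries: dict
    comparison: dict | None
    warnings: list
    version: str = __version__

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _nested(dc_cls, value):
    return dc_cls(**value) if isinstance(value, dict) else value


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML or JSON."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["detection"] = _nested(DetectionParams, raw.get("detection", {}))
    raw["linking"] = _nested(LinkingParams, raw.get("linking", {}))
    raw["fit"] = _nested(FitParams, raw.get("fit", {}))
    raw["morphometry"] = _nested(MorphometryParams, raw.get("morphometry", {}))
    raw["image"] = _nested(ImageSimConfig, raw.get("image", {}))
    conds = []
    for c in raw.get("conditions", []):
        if isinstance(c, dict):
            if "drift_velocity" in c:
                c["drift_velocity"] = tuple(c["drift_velocity"])
            c = ConditionSpec(**c)
        conds.append(c)
    if conds:
        raw["conditions"] = tuple(conds)
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _tracks_for_condition(cfg: RunConfig, spec: ConditionSpec, seed: int, counts: dict):
    """Produce filtered trajectories for one arm, updating stage counts."""
    label = spec.label
    if spec.track_table is not None:
        tracks = read_track_table(
            spec.track_table,
            pixel_size=cfg.pixel_size,
            frame_interval=cfg.frame_interval,
            condition=label,
        )
        counts[label] = {"source": "ingested", "tracks_in": len(tracks)}
    else:
        sim_cfg = TrackSimConfig(
            D=spec.D,
            alpha=spec.alpha,
            n_frames=spec.n_frames,
            frame_interval=cfg.frame_interval,
            drift_velocity=spec.drift_velocity,
            loc_noise_sd=spec.loc_noise_sd,
        )
        if cfg.render_movies:
            tracks = _simulate_via_movie(cfg, sim_cfg, spec, seed, counts)
            return tracks
        tracks = simulate_population(sim_cfg, spec.n_tracks, seed, condition=label)
        counts[label] = {"source": "simulated", "tracks_in": len(tracks)}

    kept = [t for t in tracks if t.n_points > cfg.linking.min_track_length]
    for t in tracks:
        if t.n_points <= cfg.linking.min_track_length:
            logger.info(
                "condition %s: dropped track %s (length %d <= %d)",
                label, t.track_id, t.n_points, cfg.linking.min_track_length,
            )
    counts[label].update(
        tracks_kept=len(kept), tracks_dropped=len(tracks) - len(kept)
    )
    return kept


def _simulate_via_movie(cfg, sim_cfg, spec, seed, counts):
    """Simulate tracks, render them into frames, then re-detect and re-link."""
    img = cfg.image
    rows, cols = img.image_shape
    margin = img.core_diameter / 2 + 3 * img.psf_sigma + cfg.linking.max_displacement
    # lay true tracks on a grid leaving room for diffusion
    side = int(np.ceil(np.sqrt(spec.n_tracks)))
    xs = np.linspace(margin, (cols - 1) * img.pixel_size - margin, side)
    ys = np.linspace(margin, (rows - 1) * img.pixel_size - margin, side)
    origins = [(xs[i % side], ys[i // side]) for i in range(spec.n_tracks)]
    tracks_true = simulate_population(
        sim_cfg, spec.n_tracks, seed, condition=spec.label, origins=origins
    )
    stack, _gt = render_movie(tracks_true, img)
    spots = [
        detect_spots(
            frame,
            img.pixel_size,
            cfg.detection.expected_diameter,
            cfg.detection.quality_threshold,
            frame_index=i,
        )
        for i, frame in enumerate(stack.data)
    ]
    n_spots = sum(len(s) for s in spots)
    linked = link_tracks(
        spots,
        cfg.linking.max_displacement,
        cfg.linking.min_track_length,
        cfg.frame_interval,
        condition=spec.label,
    )
    n_linked_spots = sum(t.n_points for t in linked)
    counts[spec.label] = {
        "source": "movie",
        "tracks_in": spec.n_tracks,
        "spots_detected": n_spots,
        "spots_linked": n_linked_spots,
        "spots_dropped": n_spots - n_linked_spots,
        "tracks_kept": len(linked),
        "tracks_dropped": 0,
    }
    return linked


def end_to_end(cfg: RunConfig, out_dir) -> RunReport:
    """Run the full analysis chain and write all artifacts to ``out_dir``.

    Writes: the resolved config (``config.yaml``), per-condition track tables
    and fit tables (CSV), population summaries, the comparison (two
    conditions) and ``report.json`` / ``report.txt``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_path = out / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)

    counts: dict = {}
    summaries: dict = {}
    warnings: list[str] = []
    manifest: dict = {}
    all_fits: dict = {}
    seeds = np.random.SeedSequence(cfg.seed).spawn(len(cfg.conditions))

    for spec, child in zip(cfg.conditions, seeds):
        seed = int(child.generate_state(1)[0] % (2**31))
        tracks = _tracks_for_condition(cfg, spec, seed, counts)
        if not tracks:
            warnings.append(f"condition {spec.label}: zero tracks kept after filtering")
            logger.warning("condition %s: zero tracks kept", spec.label)
            counts[spec.label].setdefault("fits_kept", 0)
            counts[spec.label].setdefault("fits_dropped", 0)
            continue

        track_path = out / f"tracks_{spec.label}.csv"
        write_track_table(tracks, track_path)

        fits, dropped = [], 0
        for t in tracks:
            try:
                curve = compute_msd(t, cfg.fit.max_lag_fraction)
                fits.append(fit_anomalous(curve, cfg.fit.n_points))
            except ValueError as err:
                dropped += 1
                logger.info("condition %s: dropped track %s from fit (%s)",
                            spec.label, t.track_id, err)
        counts[spec.label].update(fits_kept=len(fits), fits_dropped=dropped)
        all_fits[spec.label] = fits

        fits_path = out / f"fits_{spec.label}.csv"
        fits_to_dataframe(fits).to_csv(fits_path, index=False, float_format="%.10g")
        if fits:
            summaries[spec.label] = summarize_population(fits, spec.label).__dict__
        manifest[str(track_path.name)] = _sha256(track_path)
        manifest[str(fits_path.name)] = _sha256(fits_path)

    comparison = None
    labels = [s.label for s in cfg.conditions]
    if len(labels) == 2 and all(len(all_fits.get(l, [])) >= 3 for l in labels):
        cmp = compare_conditions(all_fits[labels[0]], all_fits[labels[1]])
        comparison = {
            "label_a": cmp.label_a, "label_b": cmp.label_b,
            "n_a": cmp.n_a, "n_b": cmp.n_b,
            "method": cmp.method, "tests": cmp.tests,
        }
        write_comparison_json(cmp, out / "comparison.json")
        manifest["comparison.json"] = _sha256(out / "comparison.json")

    # count conservation at every stage boundary
    for label, c in counts.items():
        if c.get("tracks_kept", 0) + c.get("tracks_dropped", 0) not in (
            c.get("tracks_in", c.get("tracks_kept", 0)),
        ):
            warnings.append(f"condition {label}: stage counts do not reconcile")

    manifest["config.yaml"] = _sha256(cfg_path)
    report = RunReport(
        config_hash=_config_hash(cfg),
        manifest=manifest,
        counts=counts,
        summaries=summaries,
        comparison=comparison,
        warnings=warnings,
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, default=str)
    _write_text_report(report, out / "report.txt")
    return report


def _write_text_report(report: RunReport, path: Path) -> None:
    lines = [
        f"erclust {report.version}  (config {report.config_hash})",
        "",
        "Per-condition counts:",
    ]
    for label, c in report.counts.items():
        lines.append(f"  {label}: " + ", ".join(f"{k}={v}" for k, v in c.items()))
    lines.append("")
    for label, s in report.summaries.items():
        lines.append(
            f"  {label}: D = {s['mean_D']:.4g} ± {s['sem_D']:.2g} µm²/s, "
            f"alpha = {s['mean_alpha']:.3g} ± {s['sem_alpha']:.2g} "
            f"(n = {s['n_tracks']} tracks)"
        )
    if report.comparison:
        lines.append("")
        lines.append(
            f"Comparison {report.comparison['label_b']} vs {report.comparison['label_a']}:"
        )
        for name, t in report.comparison["tests"].items():
            lines.append(
                f"  {name}: ratio of means = {t['ratio_of_means']:.3g}, "
                f"p = {t['p_value']:.3g}"
            )
    for w in report.warnings:
        lines.append(f"WARNING: {w}")
    path.write_text("\n".join(lines) + "\n")
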