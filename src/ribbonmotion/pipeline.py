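"""Configuration, the end-to-end pipeline runner, and group comparison.

The pipeline binds the stages in the order the analysis uses them:
(detect ->) link -> filter -> MSD / polarity / fusion -> summarize.
Configs are plain YAML with defaults equal to the workflow's printed
parameters; unknown keys are rejected.  Runs are fail-fast (a stage
error halts with the stage named, partial outputs retained) and
deterministic under a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fusion import FusionParams, detect_fusions, fusion_rate
from .geometry import CellGeometry
from .imaging import DEFAULT_Z_INTERVAL_UM, detect_spots_movie
from .io import read_spot_table, read_stack, read_track_table, write_track_table
from .linking import (
    EB3_LINKER,
    MIN_SPOTS_EB3,
    MIN_SPOTS_MSD,
    MIN_SPOTS_RIBBON,
    RIBBON_LINKER,
    LinkerParams,
    filter_tracks,
    link_tracks,
)
from .motion import classify_tracks, summarize_motion
from .polarity import base_fraction, track_angles
from .tracks import TrackSet

# Instrument-specific intensity thresholds (a.u.) for the two counting
# modalities used live; config defaults per modality profile.
MODALITY_THRESHOLDS = {"nikon": 97.0, "airyscan": 28.0}


@dataclass
class DetectionConfig:
    expected_diameter_um: float = 0.427
    quality_threshold: float = 0.0


@dataclass
class MSDConfig:
    fit_fraction: float = 0.25
    min_spots_msd: int = MIN_SPOTS_MSD


@dataclass
class GeometryConfig:
    apex: list[float] = field(default_factory=lambda: [0.0, 0.0, 0.0])
    base: list[float] = field(default_factory=lambda: [10.0, 0.0, 0.0])
    nucleus_plane: float = 5.0

    def build(self) -> CellGeometry:
        return CellGeometry(self.apex, self.base, self.nucleus_plane)


@dataclass
class AnalysisConfig:
    """Every tunable of the pipeline, with the assay defaults."""

    profile: str = "ribbon"  # ribbon | eb3
    linker: LinkerParams = field(default_factory=lambda: dataclasses.replace(RIBBON_LINKER))
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    msd: MSDConfig = field(default_factory=MSDConfig)
    displacement_threshold_um: float = 1.0
    fusion: FusionParams = field(default_factory=FusionParams)
    staging_z_interval_um: float = DEFAULT_Z_INTERVAL_UM
    modality: str = "airyscan"
    seed: int = 0
    geometry: GeometryConfig | None = None
    tracks_csv: str | None = None
    spots_csv: str | None = None
    stack_tif: str | None = None
    out_dir: str = "results/run"

    def __post_init__(self) -> None:
        if self.profile not in ("ribbon", "eb3"):
            raise ValueError("profile must be 'ribbon' or 'eb3'")
        if self.modality not in MODALITY_THRESHOLDS:
            raise ValueError(f"modality must be one of {sorted(MODALITY_THRESHOLDS)}")
        if not 0 < self.msd.fit_fraction <= 1:
            raise ValueError("fit_fraction must be in (0, 1]")
        if self.displacement_threshold_um <= 0:
            raise ValueError("displacement_threshold_um must be positive")

    @property
    def min_spots(self) -> int:
        return MIN_SPOTS_RIBBON if self.profile == "ribbon" else MIN_SPOTS_EB3

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _build(cls, data: dict, path: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown config keys at {path}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = names[key].type
        nested = {
            "linker": LinkerParams,
            "detection": DetectionConfig,
            "msd": MSDConfig,
            "fusion": FusionParams,
            "geometry": GeometryConfig,
        }
        if key in nested and isinstance(value, dict):
            kwargs[key] = _build(nested[key], value, f"{path}.{key}")
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> AnalysisConfig:
    """Parse a YAML analysis config, rejecting unknown keys."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a YAML mapping")
    return _build(AnalysisConfig, data, "config")


@dataclass
class RunReport:
    stage_counts: dict
    attrition: dict
    summary: dict
    software_version: str
    config_hash: str
    seed: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True, default=float)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: AnalysisConfig, tracks: TrackSet | None = None) -> RunReport:
    """Execute the configured stages and write all intermediate tables.

    Input priority: explicit ``tracks`` argument, then tracks_csv, then
    spots_csv, then stack_tif (detection + linking).  Outputs go to
    ``config.out_dir``.  Identical config + seed yields identical
    outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    attrition: dict = {}

    stage = "load"
    try:
        if tracks is None:
            if config.tracks_csv:
                tracks = read_track_table(config.tracks_csv)
            elif config.spots_csv or config.stack_tif:
                if config.spots_csv:
                    spots = read_spot_table(config.spots_csv)
                else:
                    stage = "detect"
                    movie = read_stack(config.stack_tif)
                    spots = detect_spots_movie(
                        movie,
                        config.detection.expected_diameter_um,
                        config.detection.quality_threshold,
                    )
                counts["spots"] = int(len(spots))
                stage = "link"
                tracks = link_tracks(spots, config.linker)
            else:
                raise ValueError("no input: provide tracks, tracks_csv, spots_csv or stack_tif")
        counts["tracks_linked"] = len(tracks)

        stage = "filter"
        kept = filter_tracks(tracks, min_spots=config.min_spots)
        attrition["filter_short_tracks"] = {
            "input": len(tracks), "retained": len(kept),
            "removed": len(tracks) - len(kept),
            "reason": f"fewer than {config.min_spots} spots",
        }
        write_track_table(kept, out / "tracks_filtered.csv")

        geometry = config.geometry.build() if config.geometry else None

        stage = "motion"
        table = classify_tracks(kept, geometry, fit_fraction=config.msd.fit_fraction)
        table.to_csv(out / "per_track.csv", index=False)
        n_fit_excluded = int((table["excluded_reason"] != "").sum())
        attrition["msd_eligibility"] = {
            "input": len(kept), "retained": len(kept) - n_fit_excluded,
            "removed": n_fit_excluded,
            "reason": f"fewer than {config.msd.min_spots_msd} spots or degenerate MSD",
        }
        summary = summarize_motion(table) if len(table) else {}

        if geometry is not None:
            stage = "polarity"
            angles = track_angles(kept, geometry)
            if angles:
                summary["polarity"] = base_fraction(angles)

        stage = "fusion"
        if config.fusion.dt is None and len(kept) > 0:
            fp = dataclasses.replace(config.fusion, dt=kept[0].frame_interval())
        else:
            fp = config.fusion
        events = detect_fusions(kept, fp) if len(kept) > 1 else []
        counts["fusion_events"] = len(events)
        summary["fusion"] = fusion_rate([events], n_samples=1)

        stage = "report"
        report = RunReport(
            stage_counts=counts,
            attrition=attrition,
            summary=summary,
            software_version=__version__,
            config_hash=config.config_hash(),
            seed=config.seed,
        )
        (out / "report.json").write_text(report.to_json())
        return report
    except PipelineError:
        raise
    except Exception as e:  # fail fast, name the stage, keep partial outputs
        raise PipelineError(stage, e) from e


def compare_groups(groups: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Descriptive comparison of per-sample metrics across named groups.

    ``groups`` maps a group name to a DataFrame with one row per sample
    and numeric metric columns (e.g. directional_fraction,
    long_track_fraction, fusion_rate, puncta_count).  Returns per-group
    mean and SEM for every metric plus the difference of each group's
    mean from the first group.  Single-sample groups get NaN SEM and a
    flag.  No hypothesis testing is performed.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 named groups")
    rows = []
    names = list(groups)
    ref = None
    for name in names:
        df = groups[name]
        if len(df) == 0:
            raise ValueError(f"group {name!r} has zero samples")
        metrics = df.select_dtypes(include=[np.number])
        mean = metrics.mean()
        sem = metrics.sem(ddof=1) if len(df) > 1 else pd.Series(np.nan, index=metrics.columns)
        if ref is None:
            ref = mean
        for metric in metrics.columns:
            rows.append(
                {
                    "group": name,
                    "metric": metric,
                    "n_samples": len(df),
                    "mean": float(mean[metric]),
                    "sem": float(sem[metric]),
                    "sem_undefined": len(df) < 2,
                    "diff_vs_first": float(mean[metric] - ref[metric]),
                }
            )
    return pd.DataFrame(rows)
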