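"""End-to-end pipeline, configuration and tabular IO.

``run_pipeline`` executes, per replicate sequence: background
estimation, per-frame droplet detection, trajectory linking with
splits, ROI-traversal and focal qualification, and droplet-record
evaluation; replicates are merged and clustered into a spray-mode
result.  Blob, trajectory and record tables are written as CSV and a
JSON summary records the stage counts, the seed and a hash of the
configuration, so a run is reproducible from config + inputs alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .acquisition import AcquisitionGeometry, SprayParameters, roi_from_geometry
from .clustering import SprayModeResult, analyze_records, merge_replicates
from .detection import (DEFAULT_PIXEL_CUTOFF, DEFAULT_THRESHOLD_K,
                        BlobObservation, detect_stack)
from .linking import (DEFAULT_AREA_TOL, DEFAULT_MAX_VELOCITY, DropletRecord,
                      Trajectory, focal_filter, link, make_records, roi_filter)
from .volumetry import VolumeModel

__all__ = ["RunConfig", "load_config", "read_stack", "run_pipeline",
           "PipelineResult"]

log = logging.getLogger("spraymode")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one analysis run."""

    geometry: AcquisitionGeometry
    inputs: tuple[str, ...] = ()
    output_dir: str = "."
    spray: SprayParameters | None = None
    threshold_k: float = DEFAULT_THRESHOLD_K
    pixel_cutoff: int = DEFAULT_PIXEL_CUTOFF
    max_velocity_m_s: float = DEFAULT_MAX_VELOCITY
    area_tol: float = DEFAULT_AREA_TOL
    max_gap: int = 0
    focus_mode: str = "sharpness"
    sharpness_band: float = 0.4
    volume_floor_pl: float = 4.2
    #: evaluate impact velocity from the last two observations at or
    #: before the ROI exit instead of the overall last two
    velocity_at_roi_exit: bool = False
    k: int | None = None            # fixed cluster count; None = silhouette
    k_min: int = 1
    k_max: int = 6
    n_restarts: int = 10
    volume_scale: str = "diameter"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold_k <= 0:
            raise ValueError("threshold_k must be strictly positive")
        if self.pixel_cutoff < 1:
            raise ValueError("pixel_cutoff must be >= 1")
        if self.max_velocity_m_s <= 0:
            raise ValueError("max_velocity must be strictly positive")
        if self.area_tol < 0 or self.max_gap < 0:
            raise ValueError("area_tol and max_gap must be non-negative")
        if self.focus_mode not in ("sharpness", "exact", "none"):
            raise ValueError("focus_mode must be 'sharpness', 'exact' or 'none'")
        if not (1 <= self.k_min <= self.k_max <= 6):
            raise ValueError("require 1 <= k_min <= k_max <= 6")
        if self.volume_scale not in ("diameter", "raw", "log"):
            raise ValueError("volume_scale must be 'diameter', 'raw' or 'log'")

    @property
    def volume_model(self) -> VolumeModel:
        return VolumeModel(self.geometry.pixel_size_um, floor_pl=self.volume_floor_pl)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (the output
        location does not affect results and is excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        return hashlib.sha256(json.dumps(payload, sort_keys=True,
                                         default=str).encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Read a YAML run configuration (keys documented in the README)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    geo = AcquisitionGeometry(**raw["geometry"])
    spray = SprayParameters(**raw["spray"]) if "spray" in raw else None
    kwargs = {k: v for k, v in raw.items() if k not in ("geometry", "spray", "inputs")}
    inputs = tuple(raw.get("inputs", ()))
    return RunConfig(geometry=geo, spray=spray, inputs=inputs, **kwargs)


def read_stack(path) -> np.ndarray:
    """Read a frame stack: multi-page TIFF, or a directory of
    lexicographically ordered single-frame images."""
    import imageio.v3 as iio
    import tifffile

    p = Path(path)
    if p.is_dir():
        files = sorted(f for f in p.iterdir()
                       if f.suffix.lower() in (".tif", ".tiff", ".png", ".pgm", ".bmp"))
        if not files:
            raise ValueError(f"no frame images found in {p}")
        frames = [iio.imread(f) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise ValueError(f"mixed frame shapes in {p}: {sorted(shapes)}")
        return np.stack(frames)
    arr = tifffile.imread(p)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a grayscale stack, got shape {arr.shape}")
    return arr


@dataclass
class StageCounts:
    detected_blobs: int = 0
    trajectories: int = 0
    roi_qualified: int = 0
    focus_kept: int = 0
    records: int = 0


@dataclass
class PipelineResult:
    result: SprayModeResult
    records: list[DropletRecord]
    counts_by_replicate: dict[str, StageCounts]
    config_hash: str


def _blob_table(blobs_by_frame: Sequence[Sequence[BlobObservation]],
                replicate_id: str) -> pd.DataFrame:
    rows = [(replicate_id, b.frame_index, b.centroid[0], b.centroid[1],
             b.area, b.axial_extent, b.sharpness)
            for frame in blobs_by_frame for b in frame]
    return pd.DataFrame(rows, columns=["replicate_id", "frame", "row", "col",
                                       "area_px", "axial_extent_px", "sharpness"])


def _trajectory_table(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    rows = [(tr.replicate_id, tr.trajectory_id,
             tr.parent_id if tr.parent_id is not None else -1,
             int(tr.qualified), o.frame_index, o.centroid[0], o.centroid[1],
             o.area, o.axial_extent, o.sharpness)
            for tr in trajectories for o in tr.observations]
    return pd.DataFrame(rows, columns=[
        "replicate_id", "trajectory_id", "parent_id", "qualified", "frame",
        "row", "col", "area_px", "axial_extent_px", "sharpness"])


def _record_table(records: Sequence[DropletRecord]) -> pd.DataFrame:
    rows = [(r.replicate_id, r.trajectory_id, r.volume_nl, r.velocity_m_s,
             int(r.aspect_flagged)) for r in records]
    return pd.DataFrame(rows, columns=["replicate_id", "trajectory_id",
                                       "volume_nl", "velocity_m_s", "aspect_flagged"])


def result_table(result: SprayModeResult) -> pd.DataFrame:
    """Spray-mode group table (one row per group, descending V_%)."""
    rows = [(i + 1, g.count, g.volume_mean_nl, g.volume_sd_nl,
             g.velocity_mean_m_s, g.velocity_sd_m_s, g.group_volume_nl,
             g.volume_fraction_pct) for i, g in enumerate(result.groups)]
    return pd.DataFrame(rows, columns=[
        "group", "n", "volume_mean_nl", "volume_sd_nl", "velocity_mean_m_s",
        "velocity_sd_m_s", "group_volume_nl", "volume_fraction_pct"])


def analyze_replicate(frames: np.ndarray, config: RunConfig,
                      replicate_id: str = "r0",
                      z_offsets_mm=None
                      ) -> tuple[list[DropletRecord], StageCounts,
                                 list[Trajectory], list[list[BlobObservation]]]:
    """Run detection → linking → qualification → records on one sequence."""
    geo = config.geometry
    nominal = int(geo.frame_rate_hz * 2.0)
    if frames.shape[0] != nominal:
        log.warning("replicate %s: %d frames; a nominal 2 s recording at "
                    "%g Hz has %d", replicate_id, frames.shape[0],
                    geo.frame_rate_hz, nominal)
    counts = StageCounts()
    blobs = detect_stack(frames, geo, config.threshold_k, config.pixel_cutoff)
    counts.detected_blobs = sum(len(f) for f in blobs)
    trajectories = link(blobs, geo, config.max_velocity_m_s, config.area_tol,
                        config.max_gap, replicate_id)
    counts.trajectories = len(trajectories)
    roi = roi_from_geometry(geo)
    roi_filter(trajectories, roi, geo)
    qualified = [tr for tr in trajectories if tr.qualified]
    counts.roi_qualified = len(qualified)
    if config.focus_mode == "none":
        kept = qualified
    elif config.focus_mode == "exact":
        kept = focal_filter(qualified, mode="exact", z_offsets_mm=z_offsets_mm)
    else:
        # reference sharpness from all trajectories of the sequence, not
        # only the qualified subset
        all_sharp = np.array([o.sharpness for tr in trajectories
                              for o in tr.observations])
        ref = float(np.percentile(all_sharp, 95)) if all_sharp.size else None
        kept = focal_filter(qualified, config.sharpness_band,
                            reference_sharpness=ref)
    counts.focus_kept = len(kept)
    records = make_records(kept, geo, config.volume_model, config.max_velocity_m_s,
                           clip_roi=roi if config.velocity_at_roi_exit else None)
    counts.records = len(records)
    log.info("replicate %s: %d blobs -> %d trajectories -> %d ROI -> %d focus -> %d records",
             replicate_id, counts.detected_blobs, counts.trajectories,
             counts.roi_qualified, counts.focus_kept, counts.records)
    return records, counts, trajectories, blobs


def run_pipeline(config: RunConfig,
                 stacks: Sequence[np.ndarray] | None = None,
                 write_outputs: bool = True) -> PipelineResult:
    """Full spray-mode analysis over all replicate sequences.

    ``stacks`` may be passed directly (e.g. synthetic data); otherwise
    ``config.inputs`` are read from disk.  Outputs (CSV tables, group
    table, JSON summary) go to ``config.output_dir``.
    """
    if stacks is None:
        if not config.inputs:
            raise ValueError("no input stacks configured")
        stacks = [read_stack(p) for p in config.inputs]
    if not stacks:
        raise ValueError("no input stacks given")
    for s in stacks:
        if s.ndim != 3 or s.shape[0] == 0:
            raise ValueError("each stack must be a non-empty (n, h, w) array")

    out = Path(config.output_dir)
    chash = config.config_hash()
    record_sets = []
    counts_by_rep: dict[str, StageCounts] = {}
    blob_tables, traj_tables = [], []
    for i, frames in enumerate(stacks):
        rep = f"r{i}"
        records, counts, trajectories, blobs = analyze_replicate(frames, config, rep)
        record_sets.append(records)
        counts_by_rep[rep] = counts
        if write_outputs:
            blob_tables.append(_blob_table(blobs, rep))
            traj_tables.append(_trajectory_table(trajectories))

    records = merge_replicates(record_sets)
    k = config.k
    k_range = range(config.k_min, config.k_max + 1)
    result = analyze_records(records, config.seed, k=k, k_range=k_range,
                             n_restarts=config.n_restarts,
                             volume_scale=config.volume_scale)

    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
        header = f"# config_hash={chash}\n"
        for name, df in (("blobs.csv", pd.concat(blob_tables, ignore_index=True)),
                         ("trajectories.csv", pd.concat(traj_tables, ignore_index=True)),
                         ("records.csv", _record_table(records)),
                         ("groups.csv", result_table(result))):
            with open(out / name, "w") as fh:
                fh.write(header)
                df.to_csv(fh, index=False)
        scatter = _record_table(records)
        scatter["cluster"] = -1
        # re-cluster deterministically for the scatter labels
        from .clustering import cluster as _cluster
        scatter["cluster"] = _cluster(records, result.k, config.seed,
                                      config.n_restarts, config.volume_scale).labels
        with open(out / "scatter.csv", "w") as fh:
            fh.write(header)
            scatter.to_csv(fh, index=False)
        summary = {
            "config_hash": chash,
            "seed": config.seed,
            "k": result.k,
            "silhouette_by_k": result.silhouette_by_k,
            "n_records": result.n_records,
            "stage_counts": {r: dataclasses.asdict(c)
                             for r, c in counts_by_rep.items()},
            "groups": [dataclasses.asdict(g) for g in result.groups],
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    return PipelineResult(result, records, counts_by_rep, chash)
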