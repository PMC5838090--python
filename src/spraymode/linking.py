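"""Trajectory linking, splitting, qualification filters and droplet records.

Blobs are linked frame-to-frame by greedy nearest-neighbour assignment
inside a gating radius set by the maximum trackable velocity
(default 20 m/s).  Backward axial motion beyond one pixel is forbidden:
droplets propagate from the capillary tip toward the target.  When a
droplet image disappears and two or more new blobs appear inside its
gate with a combined area close to the parent's, an in-flight split is
recorded: the parent trajectory ends and child trajectories start with
``parent_id`` set.

A trajectory qualifies for evaluation only if it traverses the region
of interest completely — first appearance before the ROI entrance and
last appearance beyond its exit (split children inherit the parent's
entry position) — and stays within the focal range, judged either by
boundary sharpness or, on synthetic data, by the true distance from the
focal plane.  Each qualified trajectory yields one droplet record:
volume estimated at the first appearance (droplets are near the focal
plane when emitted) and velocity from the displacement between the last
two observations, i.e. the speed at impact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .acquisition import AcquisitionGeometry, RoiBounds
from .detection import BlobObservation
from .volumetry import VolumeModel, volume_from_projection

__all__ = [
    "Trajectory",
    "DropletRecord",
    "link",
    "roi_filter",
    "focal_filter",
    "impact_velocity",
    "make_record",
    "make_records",
]

#: maximum velocity (m/s) the frame rate / optics combination can track
DEFAULT_MAX_VELOCITY = 20.0
#: relative tolerance on child-area sub-additivity when accepting a split
DEFAULT_AREA_TOL = 0.3
#: a split child's area must not exceed this fraction of the parent's
#: (fission produces strictly smaller fragments)
CHILD_AREA_MAX_FRACTION = 0.8
#: allowed backward axial motion, px
BACKWARD_SLACK_PX = 1.0
#: motion-coherence factor: with >= 2 observations, a candidate's
#: per-frame displacement must lie within [1/f, f] times the
#: trajectory's own median displacement (droplets fly at constant
#: speed; links violating this are identity switches)
COHERENCE_FACTOR = 2.5
#: absolute slack (px) added to the coherence window for centroid noise
COHERENCE_SLACK_PX = 5.0


@dataclass
class Trajectory:
    """An ordered chain of blob observations for one droplet."""

    trajectory_id: int
    observations: list[BlobObservation]
    parent_id: int | None = None
    qualified: bool = False
    replicate_id: str = ""

    def __post_init__(self) -> None:
        frames = [o.frame_index for o in self.observations]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("observations must be strictly increasing in frame")

    @property
    def first(self) -> BlobObservation:
        return self.observations[0]

    @property
    def last(self) -> BlobObservation:
        return self.observations[-1]

    def __len__(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class DropletRecord:
    """One evaluated droplet: volume at first appearance, velocity at impact."""

    trajectory_id: int
    volume_nl: float
    velocity_m_s: float
    replicate_id: str = ""
    aspect_flagged: bool = False


def _gate_radius_px(geometry: AcquisitionGeometry, max_velocity: float) -> float:
    """Maximum credible frame-to-frame displacement, px."""
    return max_velocity / geometry.frame_rate_hz * 1e6 / geometry.pixel_size_um


def _median_frame_displacement_px(tr: "Trajectory") -> float:
    obs = tr.observations
    return float(np.median([
        math.hypot(b.centroid[0] - a.centroid[0],
                   b.centroid[1] - a.centroid[1]) / (b.frame_index - a.frame_index)
        for a, b in zip(obs, obs[1:])]))


def link(blobs_by_frame: Sequence[Sequence[BlobObservation]],
         geometry: AcquisitionGeometry,
         max_velocity: float = DEFAULT_MAX_VELOCITY,
         area_tol: float = DEFAULT_AREA_TOL,
         max_gap: int = 0,
         replicate_id: str = "") -> list[Trajectory]:
    """Link per-frame blobs into trajectories with split handling.

    ``blobs_by_frame`` is index-aligned with the frame stack.  Greedy
    assignment: candidate (trajectory, blob) pairs within the gating
    radius and with axial displacement >= -1 px are taken in order of
    increasing distance (ties: smaller area difference).  Trajectories
    with at least two observations additionally gate on motion
    coherence: the candidate displacement must be compatible with the
    trajectory's median per-frame displacement (droplets fly at
    constant speed, so a 10x jump is an identity switch, not motion).
    Unmatched blobs either become split children of a parent that just
    vanished (>= 2 blobs in its gate, summed area <= parent area * (1 +
    ``area_tol``)) or start new trajectories.
    """
    if max_velocity <= 0:
        raise ValueError("max_velocity must be strictly positive")
    gate = _gate_radius_px(geometry, max_velocity)
    axis = geometry.axis_index

    trajectories: list[Trajectory] = []
    active: list[Trajectory] = []
    next_id = 0
    n_frames = len(blobs_by_frame)
    for f in range(n_frames):
        blobs = list(blobs_by_frame[f])
        # retire trajectories whose last observation is too old to extend
        active = [tr for tr in active
                  if f - tr.last.frame_index <= max_gap + 1]

        candidates = []
        windows = []
        for tr in active:
            if len(tr) >= 2:
                med = _median_frame_displacement_px(tr)
                windows.append((max(0.0, med / COHERENCE_FACTOR - COHERENCE_SLACK_PX),
                                med * COHERENCE_FACTOR + COHERENCE_SLACK_PX))
            else:
                windows.append((0.0, math.inf))
        for ti, tr in enumerate(active):
            prev = tr.last
            span = f - prev.frame_index          # >= 1
            lo, hi = windows[ti]
            for bi, b in enumerate(blobs):
                d = math.hypot(b.centroid[0] - prev.centroid[0],
                               b.centroid[1] - prev.centroid[1])
                if d > gate * span or not lo * span <= d <= hi * span:
                    continue
                if b.centroid[axis] - prev.centroid[axis] < -BACKWARD_SLACK_PX:
                    continue
                candidates.append((d, abs(b.area - prev.area), ti, bi))
        candidates.sort()
        taken_t: set[int] = set()
        taken_b: set[int] = set()
        taken_splits: set[int] = set()
        extension: dict[int, int] = {}
        for d, _, ti, bi in candidates:
            if ti in taken_t or bi in taken_b:
                continue
            extension[ti] = bi
            taken_t.add(ti)
            taken_b.add(bi)

        # split reclassification: an extension whose blob, together with
        # unassigned blobs inside the parent's gate, accounts for the
        # parent's area (within +-area_tol) is a fission, not a
        # continuation -- the parent's image broke into fragments
        for ti in sorted(extension):
            tr = active[ti]
            prev = tr.last
            bi0 = extension[ti]
            span = f - prev.frame_index
            group = [(0.0, bi0)]
            for bi, b in enumerate(blobs):
                if bi in taken_b:
                    continue
                d = math.hypot(b.centroid[0] - prev.centroid[0],
                               b.centroid[1] - prev.centroid[1])
                if d > gate * span:
                    continue
                if b.centroid[axis] - prev.centroid[axis] < -BACKWARD_SLACK_PX:
                    continue
                group.append((d, bi))
            if len(group) < 2:
                continue
            group.sort()
            while len(group) >= 2 and                     sum(blobs[bi].area for _, bi in group) > prev.area * (1 + area_tol):
                group.pop()
            total = sum(blobs[bi].area for _, bi in group)
            if len(group) >= 2 and bi0 in {bi for _, bi in group} and                     total >= prev.area * (1 - area_tol):
                del extension[ti]
                taken_t.discard(ti)
                for _, bi in group:
                    taken_b.add(bi)
                for _, bi in group:
                    child = Trajectory(next_id, [blobs[bi]],
                                       parent_id=tr.trajectory_id,
                                       replicate_id=replicate_id)
                    next_id += 1
                    trajectories.append(child)
                # mark the parent as split so it is not revisited below
                taken_splits.add(ti)

        for ti, bi in extension.items():
            active[ti].observations.append(blobs[bi])

        # split detection among trajectories that failed to extend
        new_active: list[Trajectory] = [tr for ti, tr in enumerate(active)
                                        if ti in taken_t]
        new_active.extend(tr for tr in trajectories
                          if tr.observations[0].frame_index == f
                          and tr.parent_id is not None)
        for ti, tr in enumerate(active):
            if ti in taken_t or ti in taken_splits:
                continue
            if f - tr.last.frame_index > max_gap + 1:
                continue
            prev = tr.last
            span = f - prev.frame_index
            lo, hi = windows[ti]
            in_gate = []
            for bi, b in enumerate(blobs):
                if bi in taken_b:
                    continue
                d = math.hypot(b.centroid[0] - prev.centroid[0],
                               b.centroid[1] - prev.centroid[1])
                if d > gate * span or not lo * span <= d <= hi * span:
                    continue
                if b.centroid[axis] - prev.centroid[axis] < -BACKWARD_SLACK_PX:
                    continue
                in_gate.append((d, bi))
            in_gate.sort()
            # drop farthest candidates until the area budget is met
            while len(in_gate) >= 2 and \
                    sum(blobs[bi].area for _, bi in in_gate) > prev.area * (1 + area_tol):
                in_gate.pop()
            if len(in_gate) >= 2 and all(
                    blobs[bi].area <= CHILD_AREA_MAX_FRACTION * prev.area
                    for _, bi in in_gate):
                for _, bi in in_gate:
                    child = Trajectory(next_id, [blobs[bi]],
                                       parent_id=tr.trajectory_id,
                                       replicate_id=replicate_id)
                    next_id += 1
                    new_active.append(child)
                    trajectories.append(child)
                    taken_b.add(bi)
                # parent ends here (not re-activated)
            else:
                new_active.append(tr)   # may still extend within max_gap
        active = new_active

        for bi, b in enumerate(blobs):
            if bi in taken_b:
                continue
            tr = Trajectory(next_id, [b], replicate_id=replicate_id)
            next_id += 1
            active.append(tr)
            trajectories.append(tr)
    return trajectories


def _entry_axial_mm(tr: Trajectory, by_id: Mapping[int, Trajectory],
                    geometry: AcquisitionGeometry) -> float:
    """Axial first-appearance position, inherited from the root ancestor
    for split children."""
    seen = set()
    cur = tr
    while cur.parent_id is not None and cur.parent_id in by_id:
        if cur.trajectory_id in seen:
            break
        seen.add(cur.trajectory_id)
        cur = by_id[cur.parent_id]
    return geometry.axial_mm_beyond_tip(cur.first.centroid[geometry.axis_index])


def roi_filter(trajectories: Sequence[Trajectory], roi: RoiBounds,
               geometry: AcquisitionGeometry) -> list[Trajectory]:
    """Set the ``qualified`` flag: entry strictly before the ROI and exit
    strictly beyond it (children inherit the parent's entry position)."""
    by_id = {tr.trajectory_id: tr for tr in trajectories}
    axis = geometry.axis_index
    for tr in trajectories:
        entry = _entry_axial_mm(tr, by_id, geometry)
        exit_ = geometry.axial_mm_beyond_tip(tr.last.centroid[axis])
        tr.qualified = entry < roi.axial_start_mm and exit_ > roi.axial_end_mm
    return list(trajectories)


def focal_filter(trajectories: Sequence[Trajectory],
                 sharpness_band: float = 0.4,
                 mode: str = "sharpness",
                 reference_sharpness: float | None = None,
                 z_offsets_mm: Mapping[int, float] | None = None,
                 z_limit_mm: float = 0.25) -> list[Trajectory]:
    """Keep trajectories that stay within the focal range.

    ``mode="sharpness"`` (default): a trajectory is kept when its median
    observation sharpness lies within ``+-sharpness_band`` of the
    sequence's in-focus reference (95th percentile of all blob
    sharpness, unless given); the median is robust to single-frame
    sharpness fluctuations from noise or transient overlaps.  ``mode="exact"``: for synthetic data with
    ground truth, keep trajectories whose true ``|z_offset|`` (supplied
    per trajectory id) is within ``z_limit_mm`` — half of the ~0.5 mm
    focal depth of the optics.
    """
    if mode == "exact":
        if z_offsets_mm is None:
            raise ValueError("exact mode requires z_offsets_mm")
        return [tr for tr in trajectories
                if abs(z_offsets_mm.get(tr.trajectory_id, math.inf)) <= z_limit_mm]
    if mode != "sharpness":
        raise ValueError(f"unknown focal filter mode {mode!r}")
    sharps = np.array([o.sharpness for tr in trajectories for o in tr.observations])
    if sharps.size == 0:
        return []
    ref = (float(np.percentile(sharps, 95))
           if reference_sharpness is None else reference_sharpness)
    lo, hi = (1 - sharpness_band) * ref, (1 + sharpness_band) * ref
    return [tr for tr in trajectories
            if lo <= float(np.median([o.sharpness for o in tr.observations])) <= hi]


def impact_velocity(trajectory: Trajectory,
                    geometry: AcquisitionGeometry,
                    clip_roi: RoiBounds | None = None) -> float:
    """Droplet speed at impact, m/s: centroid displacement between the
    last two observations times pixel size times frame rate.

    With ``clip_roi`` given, the last two observations at or before the
    ROI exit are used instead (an alternative reading of "speed at
    impact" that excludes frames beyond the evaluation band); falls
    back to the overall last two when fewer than two qualify.
    """
    if len(trajectory) < 2:
        raise ValueError("impact velocity needs at least two observations")
    obs = trajectory.observations
    if clip_roi is not None:
        axis = geometry.axis_index
        inside = [o for o in obs
                  if geometry.axial_mm_beyond_tip(o.centroid[axis])
                  <= clip_roi.axial_end_mm]
        if len(inside) >= 2:
            obs = inside
    a, b = obs[-2], obs[-1]
    d_px = math.hypot(b.centroid[0] - a.centroid[0],
                      b.centroid[1] - a.centroid[1])
    span = b.frame_index - a.frame_index
    return d_px * geometry.pixel_size_um * 1e-6 * geometry.frame_rate_hz / span


#: impact velocity above this multiple of the trajectory's median
#: per-frame speed marks a linking artifact (default QC)
VELOCITY_CONSISTENCY_RATIO = 2.0
#: first-observation area above this multiple of the trajectory's median
#: area marks an overlapping-entry artifact (default QC)
ENTRY_AREA_RATIO = 1.5


def _median_frame_speed(trajectory: Trajectory,
                        geometry: AcquisitionGeometry) -> float:
    obs = trajectory.observations
    speeds = []
    for a, b in zip(obs, obs[1:]):
        d_px = math.hypot(b.centroid[0] - a.centroid[0],
                          b.centroid[1] - a.centroid[1])
        span = b.frame_index - a.frame_index
        speeds.append(d_px * geometry.pixel_size_um * 1e-6 *
                      geometry.frame_rate_hz / span)
    return float(np.median(speeds))


def make_record(trajectory: Trajectory, geometry: AcquisitionGeometry,
                model: VolumeModel,
                max_velocity: float = DEFAULT_MAX_VELOCITY,
                velocity_consistency: float | None = VELOCITY_CONSISTENCY_RATIO,
                entry_area_consistency: float | None = ENTRY_AREA_RATIO,
                clip_roi: RoiBounds | None = None,
                ) -> DropletRecord | None:
    """Evaluate one qualified trajectory into a droplet record.

    Volume from the first observation, velocity from the last two.
    Returns ``None`` for droplets outside the reliable evaluation window
    (volume at or below the 4.2 pl floor, or velocity above the maximum
    trackable 20 m/s), and — droplets travel at constant speed, so
    departures flag tracking artifacts — for trajectories whose impact
    velocity exceeds ``velocity_consistency`` times their median
    per-frame speed (a mislink at the trajectory end fabricates the
    impact velocity).  When the first observation's area exceeds
    ``entry_area_consistency`` times the trajectory's median area (two
    droplets overlapping at entry inflate the volume estimate), the
    volume is instead taken at the earliest observation consistent with
    the median.  Pass ``None`` for either ratio to disable that check.
    """
    if not trajectory.qualified:
        raise ValueError("record requested for an unqualified trajectory")
    if len(trajectory) < 2:
        raise ValueError("record needs at least two observations")
    first = trajectory.first
    if entry_area_consistency is not None and len(trajectory) >= 3:
        med_area = float(np.median([o.area for o in trajectory.observations]))
        for o in trajectory.observations:
            if o.area <= entry_area_consistency * med_area:
                first = o
                break
    est = volume_from_projection(first.area, first.axial_extent, model)
    v = impact_velocity(trajectory, geometry, clip_roi)
    if v > max_velocity or v <= 0:
        return None
    if est.volume_pl <= model.floor_pl:
        return None
    if len(trajectory) >= 3 and velocity_consistency is not None:
        med_v = _median_frame_speed(trajectory, geometry)
        if not med_v / velocity_consistency <= v <= velocity_consistency * med_v:
            return None
    return DropletRecord(trajectory.trajectory_id, est.volume_pl / 1000.0, v,
                         trajectory.replicate_id, est.aspect_flagged)


def make_records(trajectories: Sequence[Trajectory],
                 geometry: AcquisitionGeometry, model: VolumeModel,
                 max_velocity: float = DEFAULT_MAX_VELOCITY,
                 clip_roi: RoiBounds | None = None,
                 ) -> list[DropletRecord]:
    """Records for every qualified trajectory with >= 2 observations."""
    out = []
    for tr in trajectories:
        if not tr.qualified or len(tr) < 2:
            continue
        rec = make_record(tr, geometry, model, max_velocity, clip_roi=clip_roi)
        if rec is not None:
            out.append(rec)
    return out
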