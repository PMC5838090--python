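"""Synthetic spray-video generation with known ground truth.

The generator has two stages.  ``sample_ensemble`` draws a droplet
ensemble from a set of group specifications (mean/sd of volume and
velocity plus a share of the total delivered volume per group), the way
an electrospray source in a stable cone-jet / multi-jet regime emits a
mixture of large slow primary droplets and small fast satellite
droplets.  ``render_frames`` then renders that ensemble into a
high-speed grayscale frame stack — droplets as anti-aliased ellipses
advected frame to frame, with optional in-flight splitting, Gaussian
defocus blur growing with distance from the focal plane, and additive
sensor noise — together with a per-frame ground-truth table.

Distribution choices: droplet volumes are log-normal (moment-matched to
the requested mean/sd; strictly positive and right-skewed, as spray
droplet size distributions are), velocities are normal truncated below
at a small positive floor (droplets all travel toward the target).
Emission times are uniform over the recording (steady-state spray).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .acquisition import AcquisitionGeometry

__all__ = [
    "GroupSpec",
    "SplitEvent",
    "GroundTruthDroplet",
    "RenderSettings",
    "EnsembleSettings",
    "sample_ensemble",
    "render_frames",
    "write_stack",
    "REFERENCE_CONDITIONS",
]


@dataclass(frozen=True)
class GroupSpec:
    """One droplet sub-population of the spray mode.

    ``volume_fraction`` is the share of the total delivered volume this
    group carries; fractions over all groups must sum to 1.
    """

    name: str
    volume_mean_nl: float
    volume_sd_nl: float
    velocity_mean_m_s: float
    velocity_sd_m_s: float
    volume_fraction: float

    def __post_init__(self) -> None:
        if self.volume_mean_nl <= 0 or self.velocity_mean_m_s <= 0:
            raise ValueError("group means must be strictly positive")
        if self.volume_sd_nl < 0 or self.velocity_sd_m_s < 0:
            raise ValueError("group sds must be non-negative")
        if not 0 <= self.volume_fraction <= 1:
            raise ValueError("volume_fraction must lie in [0, 1]")


def _check_fractions(groups: Sequence[GroupSpec]) -> None:
    total = sum(g.volume_fraction for g in groups)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"group volume fractions sum to {total}, expected 1")


#: Measured spray-mode group structure of the reference electrospray
#: device (370 mOsm sucrose medium, d_wd = 4 mm, dV/dt = 20 ul/min) at
#: three applied voltages.  Used as realistic generator presets.
REFERENCE_CONDITIONS: dict[str, list[GroupSpec]] = {
    "2.7kV": [
        GroupSpec("group1", 1.1, 1.1, 2.8, 1.3, 0.42),
        GroupSpec("group2", 0.2, 0.7, 12.9, 3.9, 0.07),
        GroupSpec("group3", 9.9, 4.2, 3.2, 4.4, 0.51),
    ],
    "3.0kV": [
        GroupSpec("group1", 1.4, 1.5, 2.9, 1.3, 0.95),
        GroupSpec("group2", 0.2, 0.4, 14.3, 3.5, 0.05),
    ],
    "3.3kV": [
        GroupSpec("group1", 1.4, 1.5, 3.1, 0.9, 0.82),
        GroupSpec("group2", 0.7, 0.8, 15.5, 2.8, 0.18),
    ],
}


@dataclass(frozen=True)
class SplitEvent:
    """In-flight fission of a droplet into children.

    ``shares`` are the children's fractions of the parent volume and
    must sum to 1 (volume conservation).
    """

    time_s: float
    shares: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.shares) < 2:
            raise ValueError("a split needs at least two children")
        if any(s <= 0 for s in self.shares):
            raise ValueError("child volume shares must be strictly positive")
        if abs(sum(self.shares) - 1.0) > 1e-9:
            raise ValueError("child volume shares must sum to 1")


@dataclass(frozen=True)
class GroundTruthDroplet:
    """One droplet of the generated ensemble."""

    droplet_id: int
    group: str
    emission_time_s: float
    entry_axial_mm: float       # mm beyond the capillary tip
    entry_lateral_mm: float     # mm from the image edge, lateral axis
    velocity_m_s: float         # axial, toward the target
    volume_nl: float
    z_offset_mm: float          # distance from the focal plane
    lateral_velocity_m_s: float = 0.0
    split: SplitEvent | None = None

    def __post_init__(self) -> None:
        if self.volume_nl <= 0:
            raise ValueError("volume must be strictly positive")
        if self.velocity_m_s <= 0:
            raise ValueError("velocity must be strictly positive")


@dataclass(frozen=True)
class EnsembleSettings:
    """Knobs of the ensemble sampler that are not part of the group specs."""

    #: sd of the droplet distance from the focal plane, mm.
    z_sd_mm: float = 0.15
    #: fraction of droplets that undergo one in-flight split.
    split_fraction: float = 0.05
    #: lower truncation of the velocity distribution, m/s.
    velocity_min_m_s: float = 0.2
    #: sd of the lateral entry position around the image centre, mm.
    lateral_sd_mm: float = 0.3
    #: sd of the lateral velocity component, m/s (0 = purely axial).
    lateral_velocity_sd_m_s: float = 0.0


@dataclass(frozen=True)
class RenderSettings:
    """Rendering configuration for the synthetic frame stack.

    ``droplet_intensity`` is the contrast amplitude a droplet adds to
    (bright-on-dark) or subtracts from (dark-on-bright) the background;
    it must exceed 3x the sensor noise sd for the fixture to be usable.
    ``defocus_blur_scale_um_per_mm`` is the Gaussian blur sd, in
    micrometres, added per millimetre of defocus ``|z_offset|``.
    """

    background_level: float = 20.0
    noise_sd: float = 16.0
    droplet_intensity: float = 130.0
    aspect_ratio: float = 1.0
    defocus_blur_scale_um_per_mm: float = 25.0
    bit_depth: int = 8
    rng_seed: int = 0
    bright_on_dark: bool = True
    supersample: int = 4

    def __post_init__(self) -> None:
        if self.droplet_intensity <= 3.0 * self.noise_sd:
            raise ValueError(
                "droplet_intensity must exceed 3x noise_sd for a usable fixture")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.aspect_ratio <= 0:
            raise ValueError("aspect_ratio must be strictly positive")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a log-normal with given mean and sd."""
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _traverses_roi(t0: float, velocity: float,
                   geometry: AcquisitionGeometry, duration_s: float) -> bool:
    """Would a droplet emitted at ``t0`` traverse the ROI on observed frames?

    Mirrors the qualification rules on pure kinematics: at least two
    observed frames, first observation ahead of the ROI, last beyond
    it.  At high velocity this is phase-sensitive: a 14 m/s droplet
    advances 1.43 mm per frame at 10 kHz, so the 1.0 mm pre-ROI and
    0.5 mm post-ROI windows are each hit only for favourable emission
    phases (~1/3 of droplets).
    """
    from .acquisition import roi_from_geometry

    roi = roi_from_geometry(geometry)
    fr = geometry.frame_rate_hz
    t_impact = t0 + geometry.working_distance_mm / 1000.0 / velocity
    f0 = math.ceil(t0 * fr)
    f1 = math.floor(min(t_impact, duration_s) * fr)
    if f1 < f0 + 1:
        return False
    first = (f0 / fr - t0) * velocity * 1000.0
    last = (f1 / fr - t0) * velocity * 1000.0
    return first < roi.axial_start_mm and last > roi.axial_end_mm


def sample_ensemble(groups: Sequence[GroupSpec], duration_s: float,
                    total_volume_nl: float, geometry: AcquisitionGeometry,
                    seed: int,
                    settings: EnsembleSettings = EnsembleSettings(),
                    fractions_basis: str = "emitted",
                    max_velocity_m_s: float = 20.0,
                    floor_nl: float = 0.0042,
                    ) -> list[GroundTruthDroplet]:
    """Draw a droplet ensemble realising the requested group structure.

    Per group, droplets are drawn (log-normal volume, truncated-normal
    velocity) until the group's cumulative volume reaches its share of
    ``total_volume_nl``; the last draw may overshoot by at most one
    droplet.  Deterministic for a fixed seed.

    ``fractions_basis`` chooses which population the group specs
    describe.  ``"emitted"`` (default) applies them to every generated
    droplet.  ``"evaluable"`` draws droplets conditioned to be
    kinematically evaluable — volume above ``floor_nl``, velocity
    within the trackable maximum, and an emission phase whose observed
    frames traverse the ROI (first ahead of it, last beyond it).
    Reference spray-mode tables report statistics of EVALUATED
    droplets, and kinematic qualification is strongly
    velocity-selective (only ~1/3 of 14 m/s droplets traverse the ROI
    on observed frames at 10 kHz), so only the ``"evaluable"`` ensemble
    makes those tables recoverable by a downstream analysis: the
    emitted-population statistics would be distorted by the selection
    before any measurement error enters.
    """
    if fractions_basis not in ("emitted", "evaluable"):
        raise ValueError("fractions_basis must be 'emitted' or 'evaluable'")
    if duration_s <= 0:
        raise ValueError("duration must be strictly positive")
    if total_volume_nl <= 0:
        raise ValueError("total volume must be strictly positive")
    if not groups:
        raise ValueError("at least one group is required")
    _check_fractions(groups)

    rng = np.random.default_rng(seed)
    lateral_centre = geometry.lateral_extent_px * geometry.pixel_size_um / 2000.0
    lateral_max = geometry.lateral_extent_px * geometry.pixel_size_um / 1000.0
    droplets: list[GroundTruthDroplet] = []
    did = 0
    for g in groups:
        target = g.volume_fraction * total_volume_nl
        if target == 0:
            continue
        acc = 0.0
        guard = 0
        while acc < target:
            guard += 1
            if guard > 10_000_000:
                raise RuntimeError(f"volume target for group {g.name!r} unreachable")
            if g.volume_sd_nl > 0:
                mu, sig = _lognormal_params(g.volume_mean_nl, g.volume_sd_nl)
                vol = float(rng.lognormal(mu, sig))
            else:
                vol = g.volume_mean_nl
            if g.velocity_sd_m_s > 0:
                a = (settings.velocity_min_m_s - g.velocity_mean_m_s) / g.velocity_sd_m_s
                vel = float(stats.truncnorm.rvs(
                    a, np.inf, loc=g.velocity_mean_m_s, scale=g.velocity_sd_m_s,
                    random_state=rng))
            else:
                vel = g.velocity_mean_m_s
            if fractions_basis == "evaluable" and \
                    (vel > max_velocity_m_s or vol <= floor_nl):
                continue        # not evaluable at any phase: redraw
            t0 = float(rng.uniform(0.0, duration_s))
            if fractions_basis == "evaluable":
                tries = 0
                while not _traverses_roi(t0, vel, geometry, duration_s):
                    t0 = float(rng.uniform(0.0, duration_s))
                    tries += 1
                    if tries > 10_000:
                        raise RuntimeError(
                            f"no evaluable emission phase found for a "
                            f"{vel:.2f} m/s droplet")
            lat = float(np.clip(
                rng.normal(lateral_centre, settings.lateral_sd_mm),
                0.05 * lateral_max, 0.95 * lateral_max))
            z = float(rng.normal(0.0, settings.z_sd_mm))
            lat_v = (float(rng.normal(0.0, settings.lateral_velocity_sd_m_s))
                     if settings.lateral_velocity_sd_m_s > 0 else 0.0)
            split = None
            if settings.split_fraction > 0 and rng.uniform() < settings.split_fraction:
                # split mid-flight, somewhere between 30% and 70% of the
                # working distance, into two children
                frac = float(rng.uniform(0.3, 0.7))
                t_split = t0 + frac * geometry.working_distance_mm / 1000.0 / vel
                s = float(rng.uniform(0.35, 0.65))
                split = SplitEvent(t_split, (s, 1.0 - s))
            droplets.append(GroundTruthDroplet(
                droplet_id=did, group=g.name, emission_time_s=t0,
                entry_axial_mm=0.0, entry_lateral_mm=lat, velocity_m_s=vel,
                volume_nl=vol, z_offset_mm=z, lateral_velocity_m_s=lat_v,
                split=split))
            did += 1
            acc += vol
    return droplets


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Piece:
    """A renderable segment of a droplet's flight (parent, or one child)."""

    droplet_id: int
    piece: int                  # 0 = parent/whole droplet, 1.. = children
    parent_piece: int | None
    group: str
    t_start_s: float
    t_end_s: float
    axial0_mm: float            # axial position at t_start
    lateral0_mm: float
    velocity_m_s: float
    lateral_velocity_m_s: float
    volume_nl: float
    z_offset_mm: float


def _pieces(ensemble: Sequence[GroundTruthDroplet],
            geometry: AcquisitionGeometry,
            rng: np.random.Generator) -> list[_Piece]:
    wd = geometry.working_distance_mm
    out: list[_Piece] = []
    for d in ensemble:
        impact = d.emission_time_s + (wd - d.entry_axial_mm) / 1000.0 / d.velocity_m_s
        if d.split is None or d.split.time_s >= impact:
            out.append(_Piece(d.droplet_id, 0, None, d.group,
                              d.emission_time_s, impact, d.entry_axial_mm,
                              d.entry_lateral_mm, d.velocity_m_s,
                              d.lateral_velocity_m_s, d.volume_nl, d.z_offset_mm))
            continue
        ts = d.split.time_s
        ax_s = d.entry_axial_mm + d.velocity_m_s * (ts - d.emission_time_s) * 1000.0
        lat_s = d.entry_lateral_mm + d.lateral_velocity_m_s * (ts - d.emission_time_s) * 1000.0
        out.append(_Piece(d.droplet_id, 0, None, d.group,
                          d.emission_time_s, ts, d.entry_axial_mm,
                          d.entry_lateral_mm, d.velocity_m_s,
                          d.lateral_velocity_m_s, d.volume_nl, d.z_offset_mm))
        # children separate laterally: instant offset of one parent radius
        # plus a small diverging lateral velocity
        r_parent_mm = (3.0 * d.volume_nl * 1e6 / (4.0 * math.pi)) ** (1 / 3) / 1000.0
        for i, share in enumerate(d.split.shares):
            sign = 1.0 if i % 2 == 0 else -1.0
            child_impact = ts + (wd - ax_s) / 1000.0 / d.velocity_m_s
            out.append(_Piece(d.droplet_id, i + 1, 0, d.group,
                              ts, child_impact, ax_s,
                              lat_s + sign * r_parent_mm,
                              d.velocity_m_s,
                              d.lateral_velocity_m_s + sign * float(rng.uniform(0.1, 0.4)),
                              share * d.volume_nl, d.z_offset_mm))
    return out


def _droplet_semi_axes_um(volume_nl: float, aspect_ratio: float) -> tuple[float, float]:
    """Axial (a) and lateral (b) semi-axes in um of an ellipsoid of
    revolution with the given volume and a/b aspect ratio."""
    volume_um3 = volume_nl * 1e6
    b = (3.0 * volume_um3 / (4.0 * math.pi * aspect_ratio)) ** (1.0 / 3.0)
    return aspect_ratio * b, b


def _coverage_patch(r0: float, c0: float, rb_px: float, ra_px: float,
                    supersample: int) -> tuple[np.ndarray, int, int]:
    """Anti-aliased coverage of the ellipse centred at (r0, c0) with
    lateral (row) semi-axis rb_px and axial (col) semi-axis ra_px.

    Returns (patch, row_offset, col_offset) where patch[i, j] is the
    fraction of pixel (row_offset + i, col_offset + j) covered.
    """
    rmin = int(math.floor(r0 - rb_px - 1))
    rmax = int(math.ceil(r0 + rb_px + 1))
    cmin = int(math.floor(c0 - ra_px - 1))
    cmax = int(math.ceil(c0 + ra_px + 1))
    s = supersample
    # subpixel sample centres
    rr = (np.arange((rmax - rmin + 1) * s) + 0.5) / s + rmin - 0.5
    cc = (np.arange((cmax - cmin + 1) * s) + 0.5) / s + cmin - 0.5
    u = ((rr - r0) / rb_px) ** 2
    v = ((cc - c0) / ra_px) ** 2
    inside = (u[:, None] + v[None, :]) <= 1.0
    patch = inside.reshape(rmax - rmin + 1, s, cmax - cmin + 1, s).mean(axis=(1, 3))
    return patch.astype(np.float32), rmin, cmin


def render_frames(ensemble: Sequence[GroundTruthDroplet],
                  geometry: AcquisitionGeometry,
                  settings: RenderSettings = RenderSettings(),
                  duration_s: float | None = None,
                  ) -> tuple[np.ndarray, pd.DataFrame]:
    """Render an ensemble into a grayscale frame stack plus ground truth.

    Returns
    -------
    frames : ndarray, shape (n_frames, image_height, image_width)
        uint8 or uint16 stack.
    truth : DataFrame
        One row per droplet piece per frame: droplet_id, piece (0 =
        unsplit/parent, >=1 = child), group, frame, true centroid
        (row_px, col_px), true projected area (px), volume (nl),
        velocity (m/s), z_offset (mm).
    """
    rng = np.random.default_rng(settings.rng_seed)
    pieces = _pieces(ensemble, geometry, rng)
    px_um = geometry.pixel_size_um
    fr = geometry.frame_rate_hz
    if duration_s is None:
        duration_s = max((p.t_end_s for p in pieces), default=0.0)
    n_frames = max(1, int(round(duration_s * fr)))
    h, w = geometry.image_height, geometry.image_width

    # consistency check: fastest droplet must not out-run the image
    for p in pieces:
        step_px = p.velocity_m_s / fr * 1e6 / px_um
        if step_px >= geometry.axial_extent_px:
            raise ValueError(
                f"droplet {p.droplet_id} moves {step_px:.0f} px/frame, "
                "more than the image extent along the propagation axis")
        a_um, b_um = _droplet_semi_axes_um(p.volume_nl, settings.aspect_ratio)
        if 2 * a_um / px_um >= geometry.axial_extent_px or \
           2 * b_um / px_um >= geometry.lateral_extent_px:
            raise ValueError(f"droplet {p.droplet_id} is larger than the image")

    # bucket pieces by the frames they are alive in
    by_frame: dict[int, list[_Piece]] = {}
    for p in pieces:
        f0 = max(0, int(math.ceil(p.t_start_s * fr)))
        f1 = min(n_frames - 1, int(math.floor(p.t_end_s * fr)))
        for f in range(f0, f1 + 1):
            by_frame.setdefault(f, []).append(p)

    sign = 1.0 if settings.bright_on_dark else -1.0
    truth_rows: list[tuple] = []
    axis_is_col = geometry.propagation_axis == "col"
    maxval = 2 ** settings.bit_depth - 1
    out_dtype = np.uint8 if settings.bit_depth == 8 else np.uint16
    stack = np.empty((n_frames, h, w), dtype=out_dtype)
    for f in range(n_frames):
        img = np.zeros((h, w), dtype=np.float32)
        t = f / fr
        for p in by_frame.get(f, ()):
            dt = t - p.t_start_s
            axial_mm = p.axial0_mm + p.velocity_m_s * dt * 1000.0
            lateral_mm = p.lateral0_mm + p.lateral_velocity_m_s * dt * 1000.0
            ax_px = geometry.px_from_axial_mm(axial_mm)
            lat_px = lateral_mm * 1000.0 / px_um
            r0, c0 = (lat_px, ax_px) if axis_is_col else (ax_px, lat_px)
            a_um, b_um = _droplet_semi_axes_um(p.volume_nl, settings.aspect_ratio)
            ra, rb = a_um / px_um, b_um / px_um          # axial, lateral in px
            if axis_is_col:
                patch, roff, coff = _coverage_patch(r0, c0, rb, ra, settings.supersample)
            else:
                patch, roff, coff = _coverage_patch(r0, c0, ra, rb, settings.supersample)
            blur_px = settings.defocus_blur_scale_um_per_mm * abs(p.z_offset_mm) / px_um
            if blur_px > 0.05:
                pad = int(math.ceil(3 * blur_px))
                patch = np.pad(patch, pad)
                patch = ndimage.gaussian_filter(patch, blur_px)
                roff -= pad
                coff -= pad
            rs, re = max(0, roff), min(h, roff + patch.shape[0])
            cs, ce = max(0, coff), min(w, coff + patch.shape[1])
            if rs < re and cs < ce:
                img[rs:re, cs:ce] += settings.droplet_intensity * \
                    patch[rs - roff:re - roff, cs - coff:ce - coff]
            truth_rows.append((p.droplet_id, p.piece, p.group, f, r0, c0,
                               math.pi * ra * rb, p.volume_nl,
                               p.velocity_m_s, p.z_offset_mm))
        img *= sign
        img += settings.background_level
        img += rng.standard_normal((h, w), dtype=np.float32) * settings.noise_sd
        np.clip(img, 0, maxval, out=img)
        np.rint(img, out=img)
        stack[f] = img
    truth = pd.DataFrame(truth_rows, columns=[
        "droplet_id", "piece", "group", "frame", "row_px", "col_px",
        "area_px", "volume_nl", "velocity_m_s", "z_offset_mm"])
    return stack, truth


def write_stack(path, frames: np.ndarray, truth: pd.DataFrame | None = None,
                params: dict | None = None) -> None:
    """Write a frame stack as a multi-page TIFF, with optional ground-truth
    CSV and JSON parameter sidecar next to it."""
    import tifffile

    tifffile.imwrite(path, frames)
    base = str(path)
    if base.lower().endswith((".tif", ".tiff")):
        base = base.rsplit(".", 1)[0]
    if truth is not None:
        truth.to_csv(base + "_truth.csv", index=False)
    if params is not None:
        with open(base + "_params.json", "w") as fh:
            json.dump(params, fh, indent=2, default=str)
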