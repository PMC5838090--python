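"""Recording geometry, procedural parameters and closed-form calculators.

An electrospray delivery recording is characterised by the optics of the
high-speed camera (field of view, image size, frame rate), the device
geometry (working distance between capillary tip and target, position of
the tip in the image) and the procedural settings of the spray (applied
voltage, flow rate, delivered volume, medium osmolarity).  This module
holds those descriptions plus the small closed-form conversions the
analysis needs: pixel calibration, the axial region of interest used to
qualify trajectories, delivery time and sucrose osmolarity.

Unit conventions
----------------
Lengths in the geometry are millimetres, pixel size is reported in
micrometres per pixel, frame rate in hertz, axial coordinates in
millimetres beyond the capillary tip (increasing toward the target).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "AcquisitionGeometry",
    "SprayParameters",
    "RoiBounds",
    "pixel_size",
    "roi_from_geometry",
    "delivery_time",
    "sucrose_osmolarity",
    "SUCROSE_MOLAR_MASS",
]

#: Molar mass of sucrose (C12H22O11), g/mol.
SUCROSE_MOLAR_MASS = 342.30

#: Maximum allowed relative disagreement between the width- and
#: height-derived pixel sizes (near-square pixel gate).
PIXEL_ASPECT_TOLERANCE = 0.02


class ConfigurationError(ValueError):
    """Raised when an acquisition configuration is internally inconsistent."""


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Optical and temporal calibration of one high-speed recording.

    Parameters
    ----------
    fov_width_mm, fov_height_mm
        Physical extent of the field of view.
    image_width, image_height
        Frame size in pixels (width = columns, height = rows).
    frame_rate_hz
        Acquisition rate.
    working_distance_mm
        Axial distance from the capillary tip to the target electrode.
    tip_position_px
        Pixel coordinate of the capillary outlet along the propagation
        axis.
    propagation_axis
        ``"col"`` if droplets travel along increasing column index,
        ``"row"`` if along increasing row index.  Positive direction is
        always from tip toward target.
    """

    fov_width_mm: float
    fov_height_mm: float
    image_width: int
    image_height: int
    frame_rate_hz: float
    working_distance_mm: float
    tip_position_px: float = 0.0
    propagation_axis: str = "col"

    def __post_init__(self) -> None:
        for name in ("fov_width_mm", "fov_height_mm", "image_width",
                     "image_height", "frame_rate_hz", "working_distance_mm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.propagation_axis not in ("row", "col"):
            raise ConfigurationError("propagation_axis must be 'row' or 'col'")
        w = 1000.0 * self.fov_width_mm / self.image_width
        h = 1000.0 * self.fov_height_mm / self.image_height
        if abs(w - h) / ((w + h) / 2) > PIXEL_ASPECT_TOLERANCE:
            raise ConfigurationError(
                f"width- and height-derived pixel sizes disagree by more than "
                f"{PIXEL_ASPECT_TOLERANCE:.0%}: {w:.4g} vs {h:.4g} um/px")
        extent = self.image_width if self.propagation_axis == "col" else self.image_height
        if not (0 <= self.tip_position_px < extent):
            raise ConfigurationError("tip_position_px lies outside the image")

    @property
    def pixel_size_um(self) -> float:
        """Mean of width- and height-derived pixel sizes, um/px."""
        return pixel_size(self)

    @property
    def axial_extent_px(self) -> int:
        """Image extent along the propagation axis, pixels."""
        return self.image_width if self.propagation_axis == "col" else self.image_height

    @property
    def lateral_extent_px(self) -> int:
        return self.image_height if self.propagation_axis == "col" else self.image_width

    @property
    def axis_index(self) -> int:
        """Numpy axis index of the propagation axis in a (row, col) pair."""
        return 1 if self.propagation_axis == "col" else 0

    def axial_mm_beyond_tip(self, position_px: float) -> float:
        """Convert a pixel coordinate along the propagation axis to mm beyond the tip."""
        return (position_px - self.tip_position_px) * self.pixel_size_um / 1000.0

    def px_from_axial_mm(self, axial_mm: float) -> float:
        return self.tip_position_px + axial_mm * 1000.0 / self.pixel_size_um


@dataclass(frozen=True)
class SprayParameters:
    """Procedural settings of one electrospray delivery (run metadata).

    Carried into outputs for bookkeeping; not used in image computation.
    """

    voltage_kv: float
    flow_rate_ul_min: float
    delivered_volume_ul: float = 0.0
    plasmid_concentration_ug_ml: float = 0.0
    medium_osmolarity_mosm: float = 0.0

    def __post_init__(self) -> None:
        for name in ("voltage_kv", "flow_rate_ul_min", "delivered_volume_ul",
                     "plasmid_concentration_ug_ml", "medium_osmolarity_mosm"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.voltage_kv == 0 or self.flow_rate_ul_min == 0:
            raise ConfigurationError(
                "voltage and flow rate must be strictly positive for an active spray")

    @property
    def delivery_time_s(self) -> float:
        return delivery_time(self.delivered_volume_ul, self.flow_rate_ul_min)


@dataclass(frozen=True)
class RoiBounds:
    """Axial evaluation band, in mm beyond the capillary tip."""

    axial_start_mm: float
    axial_end_mm: float

    def __post_init__(self) -> None:
        if not (0 < self.axial_start_mm < self.axial_end_mm):
            raise ConfigurationError("require 0 < axial_start < axial_end")

    @property
    def length_mm(self) -> float:
        return self.axial_end_mm - self.axial_start_mm


def pixel_size(geometry: AcquisitionGeometry) -> float:
    """Pixel calibration in micrometres per pixel.

    Mean of the width-derived (``fov_width / image_width``) and
    height-derived (``fov_height / image_height``) values; the
    constructor already rejects configurations where the two disagree by
    more than 2%.
    """
    w = 1000.0 * geometry.fov_width_mm / geometry.image_width
    h = 1000.0 * geometry.fov_height_mm / geometry.image_height
    return 0.5 * (w + h)


# The evaluation band covers 62.5% of the working distance, starting 25%
# beyond the capillary tip and ending 12.5% ahead of the target.
ROI_START_FRACTION = 0.25
ROI_END_FRACTION = 0.875


def roi_from_geometry(geometry: AcquisitionGeometry) -> RoiBounds:
    """Standard region of interest: [0.25, 0.875] of the working distance."""
    d = geometry.working_distance_mm
    return RoiBounds(ROI_START_FRACTION * d, ROI_END_FRACTION * d)


def delivery_time(volume_ul: float, flow_rate_ul_min: float) -> float:
    """Time in seconds to deliver ``volume_ul`` at ``flow_rate_ul_min``.

    t_d = V / (dV/dt); e.g. 25 ul at 20 ul/min -> 75 s.
    """
    if flow_rate_ul_min <= 0:
        raise ValueError("flow rate must be strictly positive")
    if volume_ul < 0:
        raise ValueError("volume must be non-negative")
    return 60.0 * volume_ul / flow_rate_ul_min


def sucrose_osmolarity(grams_per_100ml: float) -> float:
    """Osmolarity (mOsm/l) of an aqueous sucrose solution.

    Sucrose does not dissociate, so osmolarity equals molarity:
    10 * g/100ml / 342.30 g/mol expressed in mOsm.  12.67 g per 100 ml
    gives 370 mOsm (nearest 10).
    """
    if grams_per_100ml < 0:
        raise ValueError("concentration must be non-negative")
    return 10.0 * grams_per_100ml / SUCROSE_MOLAR_MASS * 1000.0
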