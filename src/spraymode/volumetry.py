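"""Droplet volume from a single 2-D projection.

A droplet imaged side-on by the high-speed camera shows a projected
cross-sectional area A (pixel count) and an axial diameter d along the
direction of propagation.  Assuming rotational symmetry around the
propagation axis, the droplet is modelled as an ellipsoid of revolution
with axial semi-axis a = d/2 and lateral semi-axis b chosen so that the
projected ellipse area matches: pi * a * b = A, hence b = A / (pi * a)
and

    V = (4/3) * pi * a * b**2 .

For a sphere (pi * (d/2)**2 = A) this reduces to the sphere volume.
Volumes are returned in picolitres (1 pl = 1000 um^3); group tables
report nanolitres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "VolumeModel",
    "VolumeEstimate",
    "volume_from_projection",
    "detection_limit_volume",
    "UM3_PER_PL",
]

#: Cubic micrometres per picolitre.
UM3_PER_PL = 1000.0

#: Aspect ratio beyond which a measurement is flagged as dubious.
ASPECT_FLAG_RATIO = 10.0


@dataclass(frozen=True)
class VolumeModel:
    """Volumetry configuration.

    ``floor_pl`` is the lower resolution limit of the method: droplets
    at or below this volume are too close to the detection cutoff to be
    evaluated reliably and are dropped from the record stream.
    """

    pixel_size_um: float
    model: str = "ellipsoid-of-revolution"
    floor_pl: float = 4.2

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be strictly positive")
        if self.floor_pl < 0:
            raise ValueError("floor_pl must be non-negative")
        if self.model != "ellipsoid-of-revolution":
            raise ValueError(f"unknown volume model {self.model!r}")


class VolumeEstimate(NamedTuple):
    volume_pl: float
    #: True when the implied semi-axes are extreme (b > 10 a or b < a/10),
    #: i.e. the area and axial extent are mutually implausible.
    aspect_flagged: bool


def volume_from_projection(area_px: float, axial_extent_px: float,
                           model: VolumeModel) -> VolumeEstimate:
    """Ellipsoid-of-revolution volume (pl) from projected measurements.

    Parameters
    ----------
    area_px
        Projected cross-sectional area, pixels.
    axial_extent_px
        Diameter along the propagation axis, pixels.
    """
    if area_px < 1 or axial_extent_px < 1:
        raise ValueError("area and axial extent must each be >= 1 px")
    px = model.pixel_size_um
    a = axial_extent_px * px / 2.0           # axial semi-axis, um
    area_um2 = area_px * px * px
    b = area_um2 / (math.pi * a)             # lateral semi-axis, um
    volume = (4.0 / 3.0) * math.pi * a * b * b / UM3_PER_PL
    flagged = b > ASPECT_FLAG_RATIO * a or b < a / ASPECT_FLAG_RATIO
    return VolumeEstimate(volume, flagged)


def detection_limit_volume(pixel_cutoff: int, pixel_size_um: float,
                           shape: str = "sphere",
                           semi_axes_um: tuple[float, float] | None = None) -> float:
    """Volume (pl) of the smallest detectable droplet for a given pixel cutoff.

    The cutoff area A = pixel_cutoff * pixel_size**2 is converted to a
    volume under the stated shape:

    - ``"sphere"``: radius r = sqrt(A / pi), V = (4/3) pi r^3.
      10 px at 5.6 um/px -> 4.2 pl (r = 10 um).
    - ``"ellipsoid"``: semi-axes (a, b) must satisfy pi a b = A within
      5%; V = (4/3) pi a b^2.  10 px at 5.6 um/px with (20, 5) um ->
      2.1 pl.
    """
    if pixel_cutoff < 1:
        raise ValueError("pixel_cutoff must be >= 1")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be strictly positive")
    area_um2 = pixel_cutoff * pixel_size_um ** 2
    if shape == "sphere":
        r = math.sqrt(area_um2 / math.pi)
        return (4.0 / 3.0) * math.pi * r ** 3 / UM3_PER_PL
    if shape == "ellipsoid":
        if semi_axes_um is None:
            raise ValueError("ellipsoid shape requires semi_axes_um=(a, b)")
        a, b = semi_axes_um
        if a <= 0 or b <= 0:
            raise ValueError("semi-axes must be strictly positive")
        implied = math.pi * a * b
        if abs(implied - area_um2) / area_um2 > 0.05:
            raise ValueError(
                f"ellipsoid axes imply projected area {implied:.3g} um^2, "
                f"inconsistent (>5%) with cutoff area {area_um2:.3g} um^2")
        return (4.0 / 3.0) * math.pi * a * b * b / UM3_PER_PL
    raise ValueError(f"unknown shape {shape!r}")
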