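"""Fan-beam scan geometry, resolution/magnification relations and misalignment.

Coordinate convention (used consistently by the projector, the FBP and the
background reprojection):

* the isocenter (rotation center) sits at ``rotation_center`` in the fixed
  laboratory frame; x to the right, y up, angles counter-clockwise;
* at view angle ``beta`` the source is at ``rotation_center + a*(cos b, sin b)``;
* the flat detector passes through ``rotation_center - b*(cos b, sin b)``,
  perpendicular to the source-isocenter line; the detector coordinate ``u``
  increases along ``(-sin b, cos b)``;
* detector bin ``k`` (0-based) is centered at
  ``u_k = (k - (n_detector - 1) / 2) * detector_pitch + detector_offset``.

All lengths are millimetres, all angles degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "FanBeamGeometry",
    "MisalignmentParams",
    "SourceDetectorSpec",
    "magnifications",
    "system_resolution",
    "field_of_view",
    "apply_misalignment",
]


class InvalidGeometryError(ValueError):
    """Raised for non-physical scan geometry."""


@dataclass(frozen=True)
class FanBeamGeometry:
    """One circular fan-beam scan with a flat, equispaced detector.

    Parameters
    ----------
    source_to_iso : float
        Distance ``a`` from the focal spot to the rotation center (mm).
    iso_to_detector : float
        Distance ``b`` from the rotation center to the detector plane (mm).
    detector_pitch : float
        Bin size at the detector plane (mm).
    n_detector : int
        Number of detector bins.
    n_views : int
        Number of equally spaced view angles covering ``angular_range``
        (endpoint excluded).
    angular_range : float
        Angular span of the scan in degrees, in (0, 360].
    initial_angle : float
        Angle of the first view (degrees).
    detector_offset : float
        Lateral shift of the detector center from the central ray (mm).
    rotation_center : tuple of float
        Laboratory coordinates of the rotation center (mm).
    """

    source_to_iso: float
    iso_to_detector: float
    detector_pitch: float
    n_detector: int
    n_views: int
    angular_range: float = 360.0
    initial_angle: float = 0.0
    detector_offset: float = 0.0
    rotation_center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.source_to_iso <= 0 or self.iso_to_detector <= 0:
            raise InvalidGeometryError("source_to_iso and iso_to_detector must be > 0")
        if self.detector_pitch <= 0:
            raise InvalidGeometryError("detector_pitch must be > 0")
        if self.n_detector < 1 or self.n_views < 1:
            raise InvalidGeometryError("n_detector and n_views must be >= 1")
        if not (0.0 < self.angular_range <= 360.0):
            raise InvalidGeometryError("angular_range must be in (0, 360]")
        object.__setattr__(self, "rotation_center", tuple(self.rotation_center))

    @property
    def source_to_detector(self) -> float:
        """Distance ``c = a + b`` (mm)."""
        return self.source_to_iso + self.iso_to_detector

    @property
    def detector_width(self) -> float:
        """Physical width of the detector, ``n_detector * detector_pitch`` (mm)."""
        return self.n_detector * self.detector_pitch

    def detector_coords(self):
        """Bin-center coordinates ``u_k`` along the detector (mm)."""
        import numpy as np

        k = np.arange(self.n_detector, dtype=float)
        return (k - (self.n_detector - 1) / 2.0) * self.detector_pitch + self.detector_offset

    def view_angles_deg(self):
        """View angles in degrees (endpoint of the range excluded)."""
        import numpy as np

        i = np.arange(self.n_views, dtype=float)
        return self.initial_angle + i * (self.angular_range / self.n_views)

    def fov_radius(self) -> float:
        """Radius of the disk around the rotation center seen by every view (mm).

        A ray at detector coordinate ``u`` passes the rotation center at
        distance ``a * |u| / sqrt(c^2 + u^2)``; the FOV radius is that of the
        most lateral bin edge.
        """
        u = self.detector_width / 2.0 + abs(self.detector_offset)
        c = self.source_to_detector
        return self.source_to_iso * u / math.hypot(c, u)


@dataclass(frozen=True)
class MisalignmentParams:
    """Registration error injected into the background-estimation chain.

    ``isocenter_offset`` shifts the assumed rotation center along the fixed
    laboratory x-axis (mm); ``angle_offset`` tilts the assumed initial view
    angle (degrees); ``magnification_error`` is the fractional error of the
    assumed magnification (the assumed detector-coordinate scale is
    ``1 + magnification_error``). All default to zero (aligned case).
    """

    isocenter_offset: float = 0.0
    angle_offset: float = 0.0
    magnification_error: float = 0.0

    def __post_init__(self) -> None:
        if self.magnification_error <= -1.0:
            raise ValueError("magnification_error must be > -1")

    @property
    def is_aligned(self) -> bool:
        return (
            self.isocenter_offset == 0.0
            and self.angle_offset == 0.0
            and self.magnification_error == 0.0
        )


@dataclass(frozen=True)
class SourceDetectorSpec:
    """Focal spot and detector pixel of the source/detector pair (micrometres)."""

    focal_spot: float = 50.0
    native_pixel: float = 55.0
    binning: int = 2

    def __post_init__(self) -> None:
        if self.focal_spot < 0:
            raise ValueError("focal_spot must be >= 0")
        if self.native_pixel <= 0:
            raise ValueError("native_pixel must be > 0")
        if self.binning < 1:
            raise ValueError("binning must be >= 1")

    @property
    def effective_pixel(self) -> float:
        """Binned detector pixel ``d = binning * native_pixel`` (um)."""
        return self.binning * self.native_pixel


def magnifications(geom: FanBeamGeometry) -> tuple[float, float]:
    """Geometric magnification factors ``(M, M')``.

    ``M = c / a`` magnifies the object (and the detector aperture referred to
    the object plane); ``M' = c / b`` magnifies the focal spot onto the
    detector. Both exceed 1 for a source-object-detector arrangement.
    """
    a, b, c = geom.source_to_iso, geom.iso_to_detector, geom.source_to_detector
    if a <= 0 or b <= 0:
        raise InvalidGeometryError("distances must be positive")
    return c / a, c / b


def system_resolution(spec: SourceDetectorSpec, M: float, M_prime: float) -> float:
    """Approximate system spatial resolution at the object plane (um).

    The detector aperture ``d`` referred to the object is ``d / M`` and the
    focal-spot penumbra referred to the object is ``x / M'``; the two blur
    kernels combine in quadrature::

        r = sqrt((x / M')**2 + (d / M)**2)
    """
    if M <= 0 or M_prime <= 0:
        raise ValueError("magnifications must be > 0")
    x = spec.focal_spot
    d = spec.effective_pixel
    return math.hypot(x / M_prime, d / M)


def field_of_view(sensor_width: float, M: float) -> float:
    """Diameter of the imaging field of view (mm) for a sensor of given width.

    The sensor spans ``sensor_width`` at the detector plane; demagnified to
    the object plane the field of view is ``sensor_width / M``.
    """
    if M <= 0:
        raise ValueError("magnification must be > 0")
    if sensor_width < 0:
        raise ValueError("sensor_width must be >= 0")
    return sensor_width / M


def apply_misalignment(geom: FanBeamGeometry, mis: MisalignmentParams) -> FanBeamGeometry:
    """Return the *assumed* geometry used for background reprojection.

    The rotation center is shifted by ``isocenter_offset`` along the
    laboratory x-axis, the initial view angle incremented by ``angle_offset``
    and the assumed image-to-detector magnification multiplied by
    ``1 + magnification_error`` (realized by dividing the detector sampling
    pitch and lateral offset by that factor: a higher assumed magnification
    means the object is believed to project onto proportionally more
    detector bins, so the region whose rays the background estimate covers
    consistently scales by ``1 + magnification_error``). With all-zero
    parameters the input geometry is returned unchanged.
    """
    if mis.magnification_error <= -1.0:
        raise ValueError("magnification_error must be > -1")
    if mis.is_aligned:
        return geom
    scale = 1.0 + mis.magnification_error
    cx, cy = geom.rotation_center
    return replace(
        geom,
        rotation_center=(cx + mis.isocenter_offset, cy),
        initial_angle=geom.initial_angle + mis.angle_offset,
        detector_pitch=geom.detector_pitch / scale,
        detector_offset=geom.detector_offset / scale,
    )
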