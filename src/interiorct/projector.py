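"""Fan-beam forward model: line integrals, truncation, noise and source blur.

Line integrals are dimensionless: attenuation is stored in cm^-1 and path
lengths in mm are divided by 10, so a 10 mm water path at 0.2 cm^-1 gives
p = 0.2. The projector is ray-driven with bilinear (Joseph-style)
interpolation at a step of half the image pixel, and is exactly linear in
the image, which the background-compensation identities rely on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import _kernels
from .geometry import FanBeamGeometry, SourceDetectorSpec
from .phantom import AttenuationImage

__all__ = ["Sinogram", "forward_project", "trunc", "add_poisson_noise", "focal_spot_blur"]


@dataclass(frozen=True)
class Sinogram:
    """Views x detector-bins array of dimensionless line integrals."""

    values: np.ndarray
    geometry: FanBeamGeometry

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("sinogram values must be 2D (n_views, n_detector)")
        if v.shape != (self.geometry.n_views, self.geometry.n_detector):
            raise ValueError(
                f"sinogram shape {v.shape} does not match geometry "
                f"({self.geometry.n_views}, {self.geometry.n_detector})"
            )
        object.__setattr__(self, "values", v)

    def save(self, path) -> None:
        """Persist values + full geometry metadata in one NPZ container."""
        from dataclasses import asdict

        np.savez_compressed(
            Path(path),
            values=self.values,
            geometry=np.frombuffer(
                json.dumps(asdict(self.geometry)).encode(), dtype=np.uint8
            ),
        )

    @classmethod
    def load(cls, path) -> "Sinogram":
        with np.load(Path(path)) as z:
            meta = json.loads(bytes(z["geometry"]).decode())
            meta["rotation_center"] = tuple(meta["rotation_center"])
            return cls(z["values"], FanBeamGeometry(**meta))


def _view_vectors(geom: FanBeamGeometry):
    beta = np.deg2rad(geom.view_angles_deg())
    cb, sb = np.cos(beta), np.sin(beta)
    rcx, rcy = geom.rotation_center
    a, b = geom.source_to_iso, geom.iso_to_detector
    sx, sy = rcx + a * cb, rcy + a * sb
    dx0, dy0 = rcx - b * cb, rcy - b * sb
    ex, ey = -sb, cb
    return sx, sy, dx0, dy0, ex, ey


def forward_project(
    img: AttenuationImage, geom: FanBeamGeometry, step: float | None = None
) -> Sinogram:
    """Fan-beam line integrals of an attenuation image.

    The image need not cover the full field of view (lateral truncation is
    allowed and simply integrates whatever the rays cross). ``step`` is the
    sampling step along each ray in mm; the default is half the image pixel.
    """
    values = np.ascontiguousarray(img.values, dtype=float)
    if values.size == 0 or not np.any(np.isfinite(values)):
        raise ValueError("empty or non-finite attenuation image")
    if step is None:
        step = img.pixel_size / 2.0
    if step <= 0:
        raise ValueError("step must be > 0")
    sx, sy, dx0, dy0, ex, ey = _view_vectors(geom)
    u = geom.detector_coords()
    out = np.zeros((geom.n_views, geom.n_detector), dtype=float)
    _kernels.forward_kernel(
        values,
        img.pixel_size,
        img.center[0],
        img.center[1],
        sx,
        sy,
        dx0,
        dy0,
        ex,
        ey,
        u,
        step,
        out,
    )
    out /= 10.0  # mm path lengths -> cm, so integrals are dimensionless
    return Sinogram(out, geom)


def trunc(sino: Sinogram, keep_width: float) -> Sinogram:
    """Keep the central contiguous detector bins spanning ``keep_width`` mm.

    Centering is about the central ray (detector coordinate u = 0), honoring
    any detector offset; the returned sinogram carries the reduced geometry.
    """
    if keep_width <= 0:
        raise ValueError("keep_width must be > 0")
    g = sino.geometry
    u = g.detector_coords()
    keep = np.abs(u) <= keep_width / 2.0 + 1e-12
    if not keep.any():
        raise ValueError("keep_width does not cover any detector bin")
    idx = np.flatnonzero(keep)
    k0, k1 = int(idx[0]), int(idx[-1])
    n_new = k1 - k0 + 1
    new_offset = g.detector_offset + (k0 + (n_new - 1) / 2.0 - (g.n_detector - 1) / 2.0) * g.detector_pitch
    new_geom = replace(g, n_detector=n_new, detector_offset=new_offset)
    return Sinogram(sino.values[:, k0 : k1 + 1].copy(), new_geom)


def add_poisson_noise(sino: Sinogram, I0: float, seed: int) -> Sinogram:
    """Photon-counting Poisson noise on the line integrals.

    Each bin's expected count is ``I0 * exp(-p)``; the noisy integral is
    ``-ln(N / I0)`` with zero counts clamped to 0.5 so the log stays finite.
    Reproducible for a fixed seed.
    """
    if I0 <= 0:
        raise ValueError("I0 must be > 0")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(I0 * np.exp(-sino.values)).astype(float)
    counts[counts == 0.0] = 0.5
    return Sinogram(-np.log(counts / I0), sino.geometry)


def focal_spot_blur(sino: Sinogram, spec: SourceDetectorSpec) -> Sinogram:
    """Geometric penumbra of a finite focal spot, as a detector-axis blur.

    A focal spot of width ``x`` projects a penumbra of width ``x * b / a`` at
    the detector plane; each view is convolved along the detector axis with
    the corresponding normalized rectangular kernel. A point source (x = 0)
    is the identity.
    """
    if spec.focal_spot < 0:
        raise ValueError("focal spot must be >= 0")
    g = sino.geometry
    width_mm = spec.focal_spot * 1e-3 * g.iso_to_detector / g.source_to_iso
    w_bins = width_mm / g.detector_pitch
    if w_bins <= 1e-12:
        return Sinogram(sino.values.copy(), g)
    half = w_bins / 2.0
    m = int(np.ceil(half - 0.5))
    j = np.arange(-m, m + 1, dtype=float)
    overlap = np.minimum(j + 0.5, half) - np.maximum(j - 0.5, -half)
    kernel = np.maximum(overlap, 0.0) / w_bins
    from scipy.ndimage import convolve1d

    blurred = convolve1d(sino.values, kernel, axis=1, mode="nearest")
    return Sinogram(blurred, g)
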