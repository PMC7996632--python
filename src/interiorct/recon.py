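"""Fan-beam filtered backprojection for a flat, equispaced detector.

The classic equispaced-detector FBP: rows are rescaled to a virtual detector
through the rotation center, cosine pre-weighted, ramp filtered via a
zero-padded FFT and backprojected with the fan distance weight. The default
apodization is a Hann window on the ramp; a pure band-limited ramp
("ram-lak") is available for sharper, noisier reconstructions.

``direct_interior_fbp`` applies the same algorithm to laterally truncated
data after constant edge extrapolation; it exists to demonstrate the
cupping/offset failure mode of naive interior reconstruction that the
background compensation in :mod:`interiorct.compensation` removes.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .phantom import AttenuationImage
from .projector import Sinogram

__all__ = ["fan_fbp", "direct_interior_fbp", "UnsupportedScanError", "ramp_filter"]


class UnsupportedScanError(ValueError):
    """Raised for scans the reconstructor does not handle (e.g. short scans)."""


def ramp_filter(n_detector: int, tau: float, window: str = "hann") -> np.ndarray:
    """Frequency response of the band-limited ramp for rows of ``n_detector``.

    Built from the spatial-domain band-limited ramp kernel (h[0] = 1/(4 tau^2),
    h[odd n] = -1/(pi n tau)^2) on an FFT grid of length >= 2 * n_detector so
    the circular convolution equals the linear one to interperiod accuracy.
    Returns the rfft response of length nfft//2 + 1.
    """
    nfft = 1 << int(np.ceil(np.log2(max(2 * n_detector, 16))))
    h = np.zeros(nfft)
    h[0] = 1.0 / (4.0 * tau * tau)
    n_odd = np.arange(1, nfft // 2, 2)
    val = -1.0 / (np.pi * n_odd * tau) ** 2
    h[n_odd] = val
    h[-n_odd] = val
    H = np.fft.rfft(h).real
    if window == "hann":
        k = np.arange(H.size)
        H = H * 0.5 * (1.0 + np.cos(np.pi * k / (H.size - 1)))
    elif window != "ram-lak":
        raise ValueError(f"unknown filter window {window!r}")
    return H


def _filter_rows(p_weighted: np.ndarray, tau: float, window: str) -> np.ndarray:
    n = p_weighted.shape[1]
    H = ramp_filter(n, tau, window)
    nfft = 2 * (H.size - 1)
    spec = np.fft.rfft(p_weighted, nfft, axis=1)
    q = np.fft.irfft(spec * H[None, :], nfft, axis=1)[:, :n]
    return q * tau


def fan_fbp(
    sino: Sinogram,
    grid_size: int,
    pixel_size: float,
    *,
    filter_window: str = "hann",
    grid_center: tuple[float, float] | None = None,
    mask_outside_fov: bool = True,
) -> AttenuationImage:
    """Filtered backprojection of a full 360-degree fan-beam scan.

    Returns attenuation in cm^-1 on a ``grid_size`` square grid of
    ``pixel_size`` mm pixels centered on the assumed rotation center (or on
    ``grid_center``, in laboratory mm, if given). Linear in the sinogram.

    Pixels outside the scanned field of view (the disk around the rotation
    center seen by every detector row) receive incomplete data and are set
    to zero unless ``mask_outside_fov=False``.
    """
    g = sino.geometry
    if abs(g.angular_range - 360.0) > 1e-9:
        raise UnsupportedScanError("fan_fbp requires a full 360-degree scan")
    if grid_size < 1 or pixel_size <= 0:
        raise ValueError("invalid reconstruction grid")
    # work in cm so the output is cm^-1 for dimensionless line integrals
    a = g.source_to_iso / 10.0
    scale = g.source_to_iso / g.source_to_detector  # detector -> virtual detector
    s = g.detector_coords() * scale / 10.0
    tau = g.detector_pitch * scale / 10.0
    weight = a / np.sqrt(a * a + s * s)
    q = _filter_rows(sino.values * weight[None, :], tau, filter_window)

    beta = np.deg2rad(g.view_angles_deg())
    out = np.zeros((grid_size, grid_size))
    center = g.rotation_center if grid_center is None else tuple(grid_center)
    gx0 = (center[0] - g.rotation_center[0]) / 10.0
    gy0 = (center[1] - g.rotation_center[1]) / 10.0
    _kernels.backproject_kernel(
        np.ascontiguousarray(q),
        np.cos(beta),
        np.sin(beta),
        a,
        s[0],
        tau,
        grid_size,
        pixel_size / 10.0,
        gx0,
        gy0,
        out,
    )
    dbeta = np.deg2rad(g.angular_range) / g.n_views
    out *= dbeta / 2.0
    if mask_outside_fov:
        k = (np.arange(grid_size) - (grid_size - 1) / 2.0) * pixel_size
        dx = center[0] - g.rotation_center[0] + k[None, :]
        dy = center[1] - g.rotation_center[1] + k[:, None]
        out[dx * dx + dy * dy > g.fov_radius() ** 2] = 0.0
    return AttenuationImage(out, pixel_size=pixel_size, center=center)


def direct_interior_fbp(
    sino: Sinogram,
    grid_size: int,
    pixel_size: float,
    *,
    filter_window: str = "hann",
    grid_center: tuple[float, float] | None = None,
) -> AttenuationImage:
    """Naive FBP of a laterally truncated sinogram.

    Each row is extended on both sides by its edge value over one full
    detector width before filtering, which tames the worst edge blow-up but
    leaves the characteristic cupping and attenuation offset of interior
    tomography. Untruncated data (rows ending in zeros) pass through
    unchanged and reproduce ``fan_fbp`` exactly.
    """
    g = sino.geometry
    v = sino.values
    edge_mag = max(np.abs(v[:, 0]).max(), np.abs(v[:, -1]).max()) if v.size else 0.0
    if edge_mag < 1e-12:
        return fan_fbp(
            sino,
            grid_size,
            pixel_size,
            filter_window=filter_window,
            grid_center=grid_center,
        )
    pad = g.n_detector
    padded = np.concatenate(
        [np.repeat(v[:, :1], pad, axis=1), v, np.repeat(v[:, -1:], pad, axis=1)], axis=1
    )
    from dataclasses import replace

    g_pad = replace(g, n_detector=g.n_detector + 2 * pad)
    return fan_fbp(
        Sinogram(padded, g_pad),
        grid_size,
        pixel_size,
        filter_window=filter_window,
        grid_center=grid_center,
    )
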