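"""Numba-compiled inner loops for the fan-beam projector and backprojector.

Everything here works on plain float64 arrays; unit handling, geometry
bookkeeping and validation live in :mod:`interiorct.projector` and
:mod:`interiorct.recon`.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def forward_kernel(
    img,
    pixel,
    cx0,
    cy0,
    sx,
    sy,
    dx0,
    dy0,
    ex,
    ey,
    u,
    step,
    out,
):
    """Ray-driven line integrals with uniform-step bilinear sampling.

    ``img[j, i]`` sits at ``(cx0 + (i-(n-1)/2)*pixel, cy0 + (j-(n-1)/2)*pixel)``.
    Per view ``iv`` the ray runs from source ``(sx, sy)`` to detector point
    ``(dx0 + u_k*ex, dy0 + u_k*ey)``; the segment is clipped to the image
    bounding box and sampled at midpoints spaced ``step`` (all lengths in the
    same unit as ``pixel``). ``out`` receives sums already multiplied by the
    step length; the caller applies unit conversion.
    """
    n_views = sx.shape[0]
    n_det = u.shape[0]
    n = img.shape[0]
    half = n * pixel / 2.0
    xmin, xmax = cx0 - half, cx0 + half
    ymin, ymax = cy0 - half, cy0 + half
    for iv in range(n_views):
        svx, svy = sx[iv], sy[iv]
        for k in range(n_det):
            px = dx0[iv] + u[k] * ex[iv]
            py = dy0[iv] + u[k] * ey[iv]
            rx = px - svx
            ry = py - svy
            length = np.sqrt(rx * rx + ry * ry)
            t0, t1 = 0.0, 1.0
            # slab clipping against the bounding box
            if rx != 0.0:
                ta = (xmin - svx) / rx
                tb = (xmax - svx) / rx
                if ta > tb:
                    ta, tb = tb, ta
                if ta > t0:
                    t0 = ta
                if tb < t1:
                    t1 = tb
            elif svx < xmin or svx > xmax:
                out[iv, k] = 0.0
                continue
            if ry != 0.0:
                ta = (ymin - svy) / ry
                tb = (ymax - svy) / ry
                if ta > tb:
                    ta, tb = tb, ta
                if ta > t0:
                    t0 = ta
                if tb < t1:
                    t1 = tb
            elif svy < ymin or svy > ymax:
                out[iv, k] = 0.0
                continue
            if t1 <= t0:
                out[iv, k] = 0.0
                continue
            seg = (t1 - t0) * length
            nstep = int(np.ceil(seg / step))
            if nstep < 1:
                nstep = 1
            dt = (t1 - t0) / nstep
            ds = dt * length
            acc = 0.0
            for m in range(nstep):
                t = t0 + (m + 0.5) * dt
                x = svx + t * rx
                y = svy + t * ry
                fx = (x - cx0) / pixel + (n - 1) / 2.0
                fy = (y - cy0) / pixel + (n - 1) / 2.0
                i0 = int(np.floor(fx))
                j0 = int(np.floor(fy))
                if i0 < -1 or i0 > n - 1 or j0 < -1 or j0 > n - 1:
                    continue
                wx = fx - i0
                wy = fy - j0
                v00 = img[j0, i0] if (0 <= i0 < n and 0 <= j0 < n) else 0.0
                v01 = img[j0, i0 + 1] if (0 <= i0 + 1 < n and 0 <= j0 < n) else 0.0
                v10 = img[j0 + 1, i0] if (0 <= i0 < n and 0 <= j0 + 1 < n) else 0.0
                v11 = img[j0 + 1, i0 + 1] if (0 <= i0 + 1 < n and 0 <= j0 + 1 < n) else 0.0
                acc += (
                    v00 * (1.0 - wx) * (1.0 - wy)
                    + v01 * wx * (1.0 - wy)
                    + v10 * (1.0 - wx) * wy
                    + v11 * wx * wy
                )
            out[iv, k] = acc * ds


@njit(cache=True, fastmath=True)
def backproject_kernel(q, cosb, sinb, a, s0, tau, npix, pixel, gx0, gy0, out):
    """Distance-weighted fan-beam backprojection onto a square grid.

    ``q`` holds the filtered rows sampled on the virtual detector through the
    rotation center (spacing ``tau``, first sample at ``s0``). The grid pixel
    ``(j, i)`` sits at ``(gx0 + (i-(npix-1)/2)*pixel, gy0 + ...)`` relative to
    the rotation center. The caller multiplies by the angular step / 2.
    """
    n_views, n_det = q.shape
    for iv in range(n_views):
        cb = cosb[iv]
        sb = sinb[iv]
        for j in range(npix):
            y = gy0 + (j - (npix - 1) / 2.0) * pixel
            for i in range(npix):
                x = gx0 + (i - (npix - 1) / 2.0) * pixel
                t = -x * sb + y * cb
                ell = a - (x * cb + y * sb)
                if ell < 1e-9:
                    continue
                s = a * t / ell
                f = (s - s0) / tau
                i0 = int(np.floor(f))
                if i0 < 0 or i0 >= n_det - 1:
                    continue
                w = f - i0
                val = q[iv, i0] * (1.0 - w) + q[iv, i0 + 1] * w
                out[j, i] += val * (a * a) / (ell * ell)
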