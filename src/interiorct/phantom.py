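"""Synthetic head phantom with embedded resolution bar patterns.

The phantom stands in for a real head CT slice: an elliptical cortical-bone
skull ring around a soft-tissue interior, air cavities (sinus-like), and a
dense temporal-bone-like disk that serves as the region of interest for the
local high-resolution scan. Resolution bar patterns of configurable width and
amplitude can be embedded inside the ROI. The phantom is defined analytically
(a list of ellipse/rectangle primitives in Hounsfield units) and can be
rasterized at any pixel size on any grid, which keeps the multi-resolution
virtual scans of the study mutually consistent.

Attenuation images store the linear attenuation coefficient in cm^-1 on a
square grid of square pixels; the grid center coincides with ``center`` in
the laboratory frame (y up, matching :mod:`interiorct.geometry`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AttenuationImage",
    "CircularROI",
    "HeadModel",
    "BarGroup",
    "hu_to_mu",
    "head_model",
    "rasterize",
    "make_head_phantom",
    "bar_pattern_groups",
    "embed_bar_patterns",
]

AIR_HU = -1000.0


def hu_to_mu(hu, mu_water: float = 0.2):
    """Convert Hounsfield units to linear attenuation (cm^-1).

    ``mu = mu_water * (1 + hu / 1000)``, clamped below at 0 so air maps to
    exactly zero and nothing is ever negative.
    """
    if mu_water <= 0:
        raise ValueError("mu_water must be > 0")
    return np.maximum(mu_water * (1.0 + np.asarray(hu, dtype=float) / 1000.0), 0.0)


@dataclass(frozen=True)
class AttenuationImage:
    """Square grid of linear attenuation values (cm^-1).

    ``values[j, i]`` sits at laboratory position
    ``(center[0] + (i-(N-1)/2)*pixel_size, center[1] + (j-(N-1)/2)*pixel_size)``;
    the row index increases with y (mathematical orientation).
    """

    values: np.ndarray
    pixel_size: float
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("attenuation image must be a square 2D grid")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "center", tuple(self.center))

    @property
    def grid_size(self) -> int:
        return self.values.shape[0]

    @property
    def extent(self) -> float:
        """Physical side length of the grid (mm)."""
        return self.grid_size * self.pixel_size

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """1D pixel-center coordinates ``(x, y)`` in the laboratory frame (mm)."""
        n = self.grid_size
        k = (np.arange(n) - (n - 1) / 2.0) * self.pixel_size
        return self.center[0] + k, self.center[1] + k

    def value_at(self, x, y):
        """Bilinear sample of the image at laboratory points (mm)."""
        xs, ys = self.coords()
        fx = np.clip((np.asarray(x, float) - xs[0]) / self.pixel_size, 0, self.grid_size - 1)
        fy = np.clip((np.asarray(y, float) - ys[0]) / self.pixel_size, 0, self.grid_size - 1)
        i0 = np.minimum(fx.astype(int), self.grid_size - 2)
        j0 = np.minimum(fy.astype(int), self.grid_size - 2)
        tx, ty = fx - i0, fy - j0
        v = self.values
        return (
            v[j0, i0] * (1 - tx) * (1 - ty)
            + v[j0, i0 + 1] * tx * (1 - ty)
            + v[j0 + 1, i0] * (1 - tx) * ty
            + v[j0 + 1, i0 + 1] * tx * ty
        )

    def save(self, path) -> None:
        """Write a 32-bit float TIFF plus a JSON sidecar with the metadata."""
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.values.astype(np.float32))
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps({"pixel_size_mm": self.pixel_size, "center_mm": list(self.center)})
        )

    @classmethod
    def load(cls, path) -> "AttenuationImage":
        import tifffile

        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            tifffile.imread(path).astype(float),
            pixel_size=float(meta["pixel_size_mm"]),
            center=tuple(meta.get("center_mm", (0.0, 0.0))),
        )

    def to_png(self, path, window: tuple[float, float] = (0.0, 0.4)) -> None:
        """16-bit PNG preview with a declared display window (cm^-1)."""
        from PIL import Image

        lo, hi = window
        scaled = np.clip((self.values - lo) / (hi - lo), 0.0, 1.0)
        arr = (scaled[::-1] * 65535.0).astype(np.uint16)  # flip: y-up -> display
        Image.fromarray(arr).save(path)


@dataclass(frozen=True)
class CircularROI:
    """Circular region of interest in the laboratory frame (mm)."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        object.__setattr__(self, "center", tuple(self.center))

    def mask(self, img: AttenuationImage, radius: float | None = None) -> np.ndarray:
        """Boolean mask of pixels whose centers lie inside the circle."""
        r = self.radius if radius is None else radius
        xs, ys = img.coords()
        dx = xs[None, :] - self.center[0]
        dy = ys[:, None] - self.center[1]
        return dx * dx + dy * dy <= r * r

    def inside(self, img: AttenuationImage) -> bool:
        """Whether the full circle lies within the image grid."""
        half = img.extent / 2.0
        return (
            abs(self.center[0] - img.center[0]) + self.radius <= half
            and abs(self.center[1] - img.center[1]) + self.radius <= half
        )


# --------------------------------------------------------------------------
# analytic primitives


@dataclass(frozen=True)
class _Ellipse:
    cx: float
    cy: float
    rx: float
    ry: float
    hu: float
    mode: str = "set"  # "set" overwrites, "add" accumulates

    def mask(self, X, Y):
        return ((X - self.cx) / self.rx) ** 2 + ((Y - self.cy) / self.ry) ** 2 <= 1.0


@dataclass(frozen=True)
class _Rect:
    cx: float
    cy: float
    w: float
    h: float
    hu: float
    mode: str = "add"

    def mask(self, X, Y):
        return (np.abs(X - self.cx) <= self.w / 2.0) & (np.abs(Y - self.cy) <= self.h / 2.0)


@dataclass(frozen=True)
class HeadModel:
    """Analytic description of the head phantom (shapes in HU)."""

    shapes: tuple
    roi_center: tuple[float, float]
    outer_rx: float
    outer_ry: float
    air_ref_disks: tuple  # ((cx, cy, r), ...) air pockets usable as bias reference
    bar_anchor: tuple[float, float]


def head_model(seed: int = 0) -> HeadModel:
    """Build the analytic head phantom.

    Soft tissue 40 HU inside a 1500 HU cortical skull ring (outer semi-axes
    80 x 95 mm), two sinus-like air cavities, and a 700 HU temporal-bone-like
    disk centered 49 mm lateral of the head center which hosts mastoid-like
    air pockets and fine air cells. The seed jitters only the small air-cell
    positions/sizes; the gross anatomy is fixed.
    """
    rng = np.random.default_rng(seed)
    roi_center = (48.0, -10.0)
    shapes: list = [
        _Ellipse(0, 0, 80.0, 95.0, 1500.0),          # skull ring (outer)
        _Ellipse(0, 0, 72.0, 87.0, 40.0),            # soft-tissue interior
        _Ellipse(0, 30.0, 18.0, 11.0, 20.0),         # ventricle-like region
        _Ellipse(0, 62.0, 14.0, 8.0, AIR_HU),        # frontal-sinus air cavity
        _Ellipse(-22.0, 48.0, 6.0, 6.0, AIR_HU),     # second air cavity
        _Ellipse(-48.0, -10.0, 10.0, 10.0, 700.0),   # contralateral dense bone
        _Ellipse(roi_center[0], roi_center[1], 14.0, 14.0, 700.0),  # temporal bone
        _Ellipse(roi_center[0] + 4.0, roi_center[1] + 3.0, 3.0, 3.0, 100.0),  # cochlea-like
    ]
    # mastoid-like air pockets: fixed radii, jitter-free centers well inside
    # the ROI so they survive the effective-ROI shrinkage and serve as the
    # air reference for bias correction
    air_ref = []
    for ang in (25.0, 150.0, 265.0):
        r = 9.0
        cx = roi_center[0] + r * math.cos(math.radians(ang))
        cy = roi_center[1] + r * math.sin(math.radians(ang))
        shapes.append(_Ellipse(cx, cy, 2.5, 2.5, AIR_HU))
        air_ref.append((cx, cy, 2.5))
    # fine air cells, jittered by the seed; kept away from the bar-pattern zone
    bar_anchor = (roi_center[0] - 6.0, roi_center[1] - 5.5)
    n_cells = 0
    while n_cells < 8:
        ang = rng.uniform(0, 360.0)
        rad = rng.uniform(4.0, 13.0)
        cr = rng.uniform(0.5, 1.1)
        cx = roi_center[0] + rad * math.cos(math.radians(ang))
        cy = roi_center[1] + rad * math.sin(math.radians(ang))
        if math.hypot(cx - bar_anchor[0], cy - bar_anchor[1]) < 4.0:
            continue
        if any(math.hypot(cx - ax, cy - ay) < ar + cr + 0.5 for ax, ay, ar in air_ref):
            continue
        shapes.append(_Ellipse(cx, cy, cr, cr, AIR_HU))
        n_cells += 1
    return HeadModel(
        shapes=tuple(shapes),
        roi_center=roi_center,
        outer_rx=80.0,
        outer_ry=95.0,
        air_ref_disks=tuple(air_ref),
        bar_anchor=bar_anchor,
    )


def rasterize(
    shapes,
    grid_size: int,
    pixel_size: float,
    center: tuple[float, float] = (0.0, 0.0),
    mu_water: float = 0.2,
    supersample: int = 2,
    background_hu: float = AIR_HU,
) -> AttenuationImage:
    """Rasterize HU shapes onto a grid and convert to attenuation (cm^-1).

    Shapes are applied in order; ``set`` shapes overwrite, ``add`` shapes
    accumulate. Each pixel is sampled on a ``supersample x supersample``
    subgrid and averaged, which anti-aliases the material boundaries.
    """
    n = grid_size * supersample
    sub = pixel_size / supersample
    k = (np.arange(n) - (n - 1) / 2.0) * sub
    X = center[0] + k[None, :]
    Y = center[1] + k[:, None]
    canvas = np.full((n, n), background_hu, dtype=float)
    for s in shapes:
        m = s.mask(X, Y)
        if s.mode == "set":
            canvas[m] = s.hu
        else:
            canvas[m] += s.hu
    mu = hu_to_mu(canvas, mu_water)
    if supersample > 1:
        mu = mu.reshape(grid_size, supersample, grid_size, supersample).mean(axis=(1, 3))
    return AttenuationImage(mu, pixel_size=pixel_size, center=center)


def make_head_phantom(
    grid_size: int,
    pixel_size: float,
    seed: int = 0,
    *,
    center: tuple[float, float] = (0.0, 0.0),
    mu_water: float = 0.2,
    allow_crop: bool = False,
) -> AttenuationImage:
    """Rasterize the synthetic head phantom.

    Deterministic for a fixed seed. By default the grid must contain the
    whole head (outer skull ellipse); pass ``allow_crop=True`` to rasterize a
    sub-region, e.g. the high-resolution patch around the ROI.
    """
    if grid_size < 64:
        raise ValueError("grid_size must be >= 64")
    model = head_model(seed)
    if not allow_crop:
        half = grid_size * pixel_size / 2.0
        if model.outer_rx + abs(center[0]) > half or model.outer_ry + abs(center[1]) > half:
            raise ValueError(
                "grid too small to contain the head; enlarge it or pass allow_crop=True"
            )
    return rasterize(model.shapes, grid_size, pixel_size, center=center, mu_water=mu_water)


# --------------------------------------------------------------------------
# resolution bar patterns


@dataclass(frozen=True)
class BarGroup:
    """One group of parallel bars of equal width separated by equal gaps.

    ``orientation`` is 'h' for bars running horizontally (stacked along y)
    and 'v' for bars running vertically (stacked along x).
    """

    center: tuple[float, float]
    bar_width: float  # mm
    n_bars: int
    length: float  # mm, bar extent along its long axis
    orientation: str
    amplitude_mu: float  # cm^-1 added on top of the local background

    def rects(self) -> tuple:
        w = self.bar_width
        offs = (np.arange(self.n_bars) - (self.n_bars - 1) / 2.0) * 2.0 * w
        out = []
        for o in offs:
            if self.orientation == "h":
                out.append(_Rect(self.center[0], self.center[1] + o, self.length, w, 0.0))
            else:
                out.append(_Rect(self.center[0] + o, self.center[1], w, self.length, 0.0))
        return tuple(out)

    def probe_points(self, n_along: int = 9) -> tuple[np.ndarray, np.ndarray]:
        """Sample points at bar centers and gap centers (for modulation).

        Returns ``(bar_pts, gap_pts)`` arrays of shape (n, 2) spanning the
        central 60% of the bar length.
        """
        w = self.bar_width
        bar_off = (np.arange(self.n_bars) - (self.n_bars - 1) / 2.0) * 2.0 * w
        gap_off = (np.arange(self.n_bars - 1) - (self.n_bars - 2) / 2.0) * 2.0 * w
        along = np.linspace(-0.3 * self.length, 0.3 * self.length, n_along)

        def pts(offsets):
            if self.orientation == "h":
                return np.array(
                    [[self.center[0] + a, self.center[1] + o] for o in offsets for a in along]
                )
            return np.array(
                [[self.center[0] + o, self.center[1] + a] for o in offsets for a in along]
            )

        return pts(bar_off), pts(gap_off)

    @property
    def footprint(self) -> tuple[float, float, float, float]:
        """Axis-aligned bounding box (xmin, xmax, ymin, ymax) of the group."""
        span = (2 * self.n_bars - 1) * self.bar_width
        if self.orientation == "h":
            w, h = self.length, span
        else:
            w, h = span, self.length
        return (
            self.center[0] - w / 2,
            self.center[0] + w / 2,
            self.center[1] - h / 2,
            self.center[1] + h / 2,
        )


def bar_pattern_groups(
    anchor: tuple[float, float],
    bar_widths_um=(50.0, 75.0),
    amplitude_hu: float = 600.0,
    mu_water: float = 0.2,
    n_bars: int = 4,
    bar_length: float = 1.2,
    spacing: float = 1.6,
) -> tuple[BarGroup, ...]:
    """Lay out one horizontal and one vertical bar group per width.

    Groups are arranged on a small grid around ``anchor``: one column per
    bar width, the horizontal-orientation group above the vertical one.
    """
    amp_mu = mu_water * amplitude_hu / 1000.0
    groups = []
    for i, w_um in enumerate(bar_widths_um):
        w = w_um / 1000.0
        x = anchor[0] + (i - (len(bar_widths_um) - 1) / 2.0) * spacing
        for j, orient in enumerate(("h", "v")):
            y = anchor[1] + (0.5 - j) * spacing
            groups.append(
                BarGroup(
                    center=(x, y),
                    bar_width=w,
                    n_bars=n_bars,
                    length=bar_length,
                    orientation=orient,
                    amplitude_mu=amp_mu,
                )
            )
    return tuple(groups)


def embed_bar_patterns(
    img: AttenuationImage,
    anchor: tuple[float, float],
    bar_widths_um=(50.0, 75.0),
    amplitude_hu: float = 600.0,
    mu_water: float = 0.2,
) -> AttenuationImage:
    """Add resolution bar patterns to an attenuation image.

    For each bar width one horizontal and one vertical group of parallel
    bars (width = gap) is added, each bar raising the local attenuation by
    ``mu_water * amplitude_hu / 1000`` on top of the existing background.
    Only pixels inside the bar footprints change.
    """
    groups = bar_pattern_groups(anchor, bar_widths_um, amplitude_hu, mu_water)
    min_w = min(g.bar_width for g in groups)
    if min_w < img.pixel_size:
        raise ValueError(
            f"narrowest bar ({min_w} mm) is below the image pixel size ({img.pixel_size} mm)"
        )
    half = img.extent / 2.0
    for g in groups:
        x0, x1, y0, y1 = g.footprint
        if (
            x0 < img.center[0] - half
            or x1 > img.center[0] + half
            or y0 < img.center[1] - half
            or y1 > img.center[1] + half
        ):
            raise ValueError("bar pattern footprint does not fit inside the image")
    if amplitude_hu == 0.0:
        return AttenuationImage(img.values.copy(), img.pixel_size, img.center)
    # supersampled coverage of the bar rectangles, added in attenuation units;
    # rasterized only over the bounding box of the cluster to stay cheap on
    # large grids
    xs, ys = img.coords()
    x0 = min(g.footprint[0] for g in groups) - img.pixel_size
    x1 = max(g.footprint[1] for g in groups) + img.pixel_size
    y0 = min(g.footprint[2] for g in groups) - img.pixel_size
    y1 = max(g.footprint[3] for g in groups) + img.pixel_size
    i0, i1 = np.searchsorted(xs, [x0, x1])
    j0, j1 = np.searchsorted(ys, [y0, y1])
    i1, j1 = min(i1 + 1, img.grid_size), min(j1 + 1, img.grid_size)
    ss = 4
    sub = img.pixel_size / ss
    kx = xs[i0] + (np.arange((i1 - i0) * ss) + 0.5) * sub - img.pixel_size / 2.0
    ky = ys[j0] + (np.arange((j1 - j0) * ss) + 0.5) * sub - img.pixel_size / 2.0
    X = kx[None, :]
    Y = ky[:, None]
    add = np.zeros((ky.size, kx.size), dtype=float)
    for g in groups:
        for r in g.rects():
            add[r.mask(X, Y)] = g.amplitude_mu
    cov = add.reshape(j1 - j0, ss, i1 - i0, ss).mean(axis=(1, 3))
    out = img.values.copy()
    out[j0:j1, i0:i1] += cov
    return AttenuationImage(out, img.pixel_size, img.center)
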