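"""Z-stack I/O, Z-projection, and well-boundary detection.

A :class:`ZStack` is an ordered list of 2D grayscale planes (index 0 = top
plane, where cells are seeded) with physical metadata: the Z step between
planes and the pixel size, both in micrometres.  Five projection methods
reduce a stack to a single 2D image; ``focus_stack`` builds an
all-in-focus image by selecting, per pixel, the plane with the highest
local sharpness.

The well boundary of a Z-projection is modelled as a superellipse
``|x/a|^n + |y/b|^n = 1`` fitted to Canny edges; when the fit is not
supported by the edges, a centred circle of configurable radius is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import gamma
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage as ndi
from scipy.optimize import least_squares
from skimage.feature import canny
from skimage.filters import threshold_otsu

from mpmtools.errors import ConfigurationError, EmptyInputError, ShapeMismatchError

PROJECTION_METHODS = ("focus_stack", "min", "max", "median", "mean")


@dataclass
class ZStack:
    """Ordered grayscale planes with physical Z and pixel metadata.

    Plane 0 is the *top* plane.  All planes share one shape; intensity
    scale is arbitrary (8-bit, 16-bit or float all accepted).
    """

    planes: list[np.ndarray]
    z_step_um: float
    pixel_size_um: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        if len(self.planes) == 0:
            raise EmptyInputError("a ZStack needs at least one plane")
        shape = self.planes[0].shape
        for i, p in enumerate(self.planes):
            if p.ndim != 2:
                raise ShapeMismatchError(f"plane {i} is not 2D (shape {p.shape})")
            if p.shape != shape:
                raise ShapeMismatchError(f"plane {i} shape {p.shape} != plane 0 shape {shape}")
        if not self.z_step_um > 0:
            raise ConfigurationError("z_step_um must be positive")
        if not self.pixel_size_um > 0:
            raise ConfigurationError("pixel_size_um must be positive")

    def __len__(self) -> int:
        return len(self.planes)

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes[0].shape

    def as_array(self) -> np.ndarray:
        """Stack planes into a (k, H, W) float array, top plane first."""
        return np.stack([np.asarray(p, dtype=np.float64) for p in self.planes])


@dataclass
class Projection:
    """A 2D reduction of a Z-stack."""

    image: np.ndarray
    method: str
    source_plane_count: int


@dataclass
class WellBoundary:
    """Superellipse (or fallback circle) delimiting the analyzable well region."""

    kind: str                      # "superellipse" | "circle"
    center: tuple[float, float]    # (x, y) in px
    a: float = 0.0                 # semi-axis along x, px
    b: float = 0.0                 # semi-axis along y, px
    n: float = 2.0                 # superellipse exponent
    radius: float = 0.0            # circle radius, px
    mask: np.ndarray = field(default=None, repr=False)

    @property
    def interior_area_px(self) -> int:
        return int(np.count_nonzero(self.mask))

    def analytic_area(self) -> float:
        """Continuum interior area of the parametric boundary, in px^2."""
        if self.kind == "circle":
            return float(np.pi * self.radius**2)
        # area of |x/a|^n + |y/b|^n <= 1
        return float(4.0 * self.a * self.b * gamma(1 + 1 / self.n) ** 2 / gamma(1 + 2 / self.n))


def read_zstack(
    paths: Sequence[str],
    z_step_um: float,
    pixel_size_um: float,
    channel_label: str = "",
) -> ZStack:
    """Read an ordered list of TIFF files into a :class:`ZStack`.

    Files may be single-plane or multi-page TIFF; multi-page files
    contribute their pages in order.  The caller supplies the top-first
    ordering (filename conventions vary between instruments).
    """
    if len(paths) == 0:
        raise EmptyInputError("no input files given")
    planes: list[np.ndarray] = []
    for path in paths:
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            planes.append(arr)
        elif arr.ndim == 3:
            planes.extend(list(arr))
        else:
            raise ShapeMismatchError(f"{path}: unsupported TIFF dimensionality {arr.ndim}")
    return ZStack(planes=planes, z_step_um=z_step_um, pixel_size_um=pixel_size_um, channel_label=channel_label)


def _local_sharpness(plane: np.ndarray, window: int) -> np.ndarray:
    """Local variance of the Laplacian in a ``window`` x ``window`` box."""
    lap = ndi.laplace(np.asarray(plane, dtype=np.float64))
    mean = ndi.uniform_filter(lap, size=window)
    mean_sq = ndi.uniform_filter(lap * lap, size=window)
    return np.maximum(mean_sq - mean * mean, 0.0)


def project_zstack(stack: ZStack, method: str, focus_window: int = 11) -> Projection:
    """Project a Z-stack to 2D by one of five methods.

    ``min``/``max``/``median``/``mean`` are pixelwise reductions.
    ``focus_stack`` selects, per pixel, the value from the plane with the
    largest local sharpness (variance of the Laplacian in an
    ``focus_window`` x ``focus_window`` neighbourhood), yielding an
    all-in-focus composite.  The output dtype follows the input for the
    selection-based methods and is float for ``mean``/``median``.
    """
    if method not in PROJECTION_METHODS:
        raise ConfigurationError(f"unknown projection method {method!r}; choose from {PROJECTION_METHODS}")
    arr = stack.as_array()
    if method == "min":
        out = arr.min(axis=0)
    elif method == "max":
        out = arr.max(axis=0)
    elif method == "median":
        out = np.median(arr, axis=0)
    elif method == "mean":
        out = arr.mean(axis=0)
    else:  # focus_stack
        sharp = np.stack([_local_sharpness(p, focus_window) for p in arr])
        best = np.argmax(sharp, axis=0)
        out = np.take_along_axis(arr, best[None], axis=0)[0]
    return Projection(image=out, method=method, source_plane_count=len(stack))


def _superellipse_residuals(theta: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    cx, cy, a, b, n = theta
    return np.abs((x - cx) / a) ** n + np.abs((y - cy) / b) ** n - 1.0


def _render_boundary_mask(shape: tuple[int, int], boundary: WellBoundary) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cx, cy = boundary.center
    if boundary.kind == "circle":
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= boundary.radius**2
    n = boundary.n
    return np.abs((xx - cx) / boundary.a) ** n + np.abs((yy - cy) / boundary.b) ** n <= 1.0


def detect_well_boundary(
    image: np.ndarray,
    min_edge_points: int = 100,
    residual_cap: float = 0.05,
    fallback_radius_fraction: float = 0.95,
    canny_sigma: float = 2.0,
    angular_bins: int = 180,
) -> WellBoundary:
    """Fit a superellipse well boundary around the Canny edges of a projection.

    The well footprint is first separated from the dark out-of-well
    plastic with a multi-Otsu threshold (the lowest of two class
    boundaries, so bright cells inside the well do not matter); Canny
    edges of that footprint trace the well rim.  Because cells touching
    the rim also generate interior edges, the implicit form
    ``|x/a|^n + |y/b|^n = 1`` is fitted (bounded least squares) to the
    *outermost* edge point in each of ``angular_bins`` directions around
    the edge centroid — the boundary that fits around the edges.

    The fit is declared failed — and a centred circle of radius
    ``fallback_radius_fraction * min(H, W) / 2`` returned instead — when
    fewer than ``min_edge_points`` edge pixels are found or the RMS
    implicit-form residual exceeds ``residual_cap``.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 64:
        raise ConfigurationError("well-boundary detection needs a 2D image of at least 64x64")
    h, w = img.shape

    def fallback() -> WellBoundary:
        boundary = WellBoundary(
            kind="circle",
            center=((w - 1) / 2.0, (h - 1) / 2.0),
            radius=fallback_radius_fraction * min(h, w) / 2.0,
        )
        boundary.mask = _render_boundary_mask(img.shape, boundary)
        return boundary

    span = img.max() - img.min()
    if span <= 0:
        return fallback()
    norm = (img - img.min()) / span
    candidates: list[float] = []
    try:
        from skimage.filters import threshold_multiotsu

        candidates.extend(float(t) for t in threshold_multiotsu(norm, classes=3))
        candidates.extend(float(t) for t in threshold_multiotsu(norm, classes=4))
    except ValueError:
        pass
    try:
        candidates.append(float(threshold_otsu(norm)))
    except ValueError:
        pass
    if not candidates:
        return fallback()

    def well_footprint(threshold: float) -> np.ndarray | None:
        fp = ndi.binary_opening(norm > threshold, iterations=2)
        fp = ndi.binary_fill_holes(fp)
        labels, nlab = ndi.label(fp)
        if nlab == 0:
            return None
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, nlab + 1))
        return labels == (1 + int(np.argmax(sizes)))

    # the well is the largest fillable footprint any threshold produces
    footprint = None
    for t in sorted(set(candidates)):
        fp = well_footprint(t)
        if fp is not None and (footprint is None or fp.sum() > footprint.sum()):
            footprint = fp
    if footprint is None or footprint.sum() < min_edge_points:
        return fallback()
    edges = canny(ndi.gaussian_filter(footprint.astype(float), 1.0), sigma=canny_sigma)
    ys, xs = np.nonzero(edges)
    if xs.size < min_edge_points:
        return fallback()

    # outermost edge point per angular bin around the edge centroid
    cx0, cy0 = xs.mean(), ys.mean()
    ang = np.arctan2(ys - cy0, xs - cx0)
    rad = np.hypot(xs - cx0, ys - cy0)
    bins = ((ang + np.pi) / (2 * np.pi) * angular_bins).astype(int) % angular_bins
    outer: dict[int, int] = {}
    for i, b in enumerate(bins):
        if b not in outer or rad[i] > rad[outer[b]]:
            outer[b] = i
    sel = np.fromiter(outer.values(), dtype=int)
    X, Y = xs[sel].astype(float), ys[sel].astype(float)

    a0 = max((X.max() - X.min()) / 2.0, 1.0)
    b0 = max((Y.max() - Y.min()) / 2.0, 1.0)
    try:
        fit = least_squares(
            _superellipse_residuals,
            x0=np.array([X.mean(), Y.mean(), a0, b0, 2.0]),
            args=(X, Y),
            bounds=([0.0, 0.0, 2.0, 2.0, 0.5], [float(w), float(h), float(2 * w), float(2 * h), 20.0]),
            max_nfev=2000,
        )
    except Exception:
        return fallback()
    rms = float(np.sqrt(np.mean(fit.fun**2)))
    if not fit.success or rms > residual_cap:
        return fallback()
    cx, cy, a, b, n = fit.x
    boundary = WellBoundary(kind="superellipse", center=(float(cx), float(cy)), a=float(a), b=float(b), n=float(n))
    boundary.mask = _render_boundary_mask(img.shape, boundary)
    if boundary.interior_area_px == 0:
        return fallback()
    return boundary
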