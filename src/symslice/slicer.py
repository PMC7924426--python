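"""Extraction of the representative 2D image lying on the symmetry plane.

The slice raster is anchored on the symmetry plane: the eight corner
vertices of the volume box are projected onto the in-plane axes (u, v),
the raster bounds are their min/max, and the raster origin is the midpoint
of those bounds (equivalently, the orthogonal projection of the box center
onto the plane).  The pixel step is chosen so the longer projected extent
spans the raster width; sampling uses nearest-neighbour lookup with zero
fill outside the volume.  The sampled image is then zero-padded to square,
linearly rescaled to 8 bits, and resized to the classifier's 224 x 224
input.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .symmetry import SymmetryPlane
from .volume import VolumeGrid

RASTER_SIZE = 224


class SlicerError(Exception):
    pass


class FrameError(SlicerError):
    """The slice frame axes are degenerate or non-orthogonal."""


@dataclass
class SliceFrame:
    """Sampling frame of the planar raster, all quantities in voxel units.

    Sample (i, j) lies at ``origin + (u_range[0] + i*pixel_step)*axis_u +
    (v_range[0] + j*pixel_step)*axis_v``; ranges are symmetric about the
    origin.
    """

    origin: np.ndarray
    axis_u: np.ndarray
    axis_v: np.ndarray
    u_range: tuple[float, float]
    v_range: tuple[float, float]
    pixel_step: float

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        u = np.asarray(self.axis_u, dtype=np.float64).reshape(3)
        v = np.asarray(self.axis_v, dtype=np.float64).reshape(3)
        if abs(np.linalg.norm(u) - 1) > 1e-6 or abs(np.linalg.norm(v) - 1) > 1e-6:
            raise FrameError("frame axes must be unit vectors")
        if abs(u @ v) > 1e-6:
            raise FrameError("frame axes must be orthogonal")
        for rng in (self.u_range, self.v_range):
            if not (np.isfinite(rng).all() and rng[0] < rng[1]):
                raise FrameError(f"invalid range {rng}")
        if not (np.isfinite(self.pixel_step) and self.pixel_step > 0):
            raise FrameError(f"invalid pixel step {self.pixel_step}")
        self.axis_u, self.axis_v = u, v


@dataclass
class RepresentativeImage:
    """The 224 x 224 8-bit image sampled on the symmetry plane."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.shape != (RASTER_SIZE, RASTER_SIZE):
            raise SlicerError(f"pixels must be {RASTER_SIZE}x{RASTER_SIZE}, got {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise SlicerError("pixel values must lie in [0, 255]")
        self.pixels = px.astype(np.uint8)

    def to_png(self, path: str | os.PathLike) -> None:
        from PIL import Image

        Image.fromarray(self.pixels, mode="L").save(path)

    @classmethod
    def from_png(cls, path: str | os.PathLike) -> "RepresentativeImage":
        from PIL import Image

        return cls(np.asarray(Image.open(path).convert("L")))


def build_frame(
    v: VolumeGrid,
    s: SymmetryPlane,
    raster: int = RASTER_SIZE,
    center: np.ndarray | None = None,
) -> SliceFrame:
    """Square sampling frame on the symmetry plane.

    The raster origin is the midpoint of the volume box-corner projections
    on the slice axes (equivalently the box center projected onto the
    plane); passing ``center`` instead anchors the origin on that point's
    orthogonal projection, which makes the raster follow the imaged
    content rather than the sampling box.  The window is square with side
    equal to the volume's longest edge, so the physical pixel step is
    invariant under rigid motions and axis permutations of the content —
    the property the representative image exists to provide.  (Bounding
    the window by the corner projections themselves would rescale the
    raster as the plane tilts.)
    """
    n = s.plane.n
    u, v_axis = s.axis_u, s.axis_v
    if np.linalg.norm(np.cross(u, v_axis)) < 1e-9:
        raise FrameError("degenerate slice axes")
    base = s.plane.offset * n  # a point on the plane
    if center is None:
        corners = np.array(list(product(*[(0.0, sz - 1.0) for sz in v.shape])))
        rel = corners - base
        pu = rel @ u
        pv = rel @ v_axis
        origin = base + 0.5 * (pu.min() + pu.max()) * u + 0.5 * (pv.min() + pv.max()) * v_axis
    else:
        center = np.asarray(center, dtype=np.float64).reshape(3)
        origin = center - (center @ n - s.plane.offset) * n
    side = float(max(v.shape) - 1)
    if side <= 0:
        raise FrameError("volume projects to a degenerate extent on the slice axes")
    half = side / 2.0
    step = side / (raster - 1)
    return SliceFrame(
        origin=origin,
        axis_u=u,
        axis_v=v_axis,
        u_range=(-half, half),
        v_range=(-half, half),
        pixel_step=step,
    )


def _n_samples(extent: float, step: float) -> int:
    return int(round(extent / step)) + 1


def extract_plane_image(v: VolumeGrid, f: SliceFrame) -> np.ndarray:
    """Sample the volume on the frame's raster with nearest-neighbour lookup.

    Returns an (n_u, n_v) float array; samples outside the volume are 0.
    Every in-volume sample equals some voxel's intensity exactly.
    """
    n_u = _n_samples(f.u_range[1] - f.u_range[0], f.pixel_step)
    n_v = _n_samples(f.v_range[1] - f.v_range[0], f.pixel_step)
    offs_u = f.u_range[0] + f.pixel_step * np.arange(n_u)
    offs_v = f.v_range[0] + f.pixel_step * np.arange(n_v)
    pts = (
        f.origin[None, None, :]
        + offs_u[:, None, None] * f.axis_u[None, None, :]
        + offs_v[None, :, None] * f.axis_v[None, None, :]
    )
    coords = np.moveaxis(pts, -1, 0)  # (3, n_u, n_v)
    return ndimage.map_coordinates(v.intensities, coords, order=0, mode="constant", cval=0.0)


def pad_to_square(img: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Zero-pad the shorter axis symmetrically so the image becomes square."""
    h, w = img.shape
    side = max(h, w)
    out = np.full((side, side), fill, dtype=img.dtype)
    r0 = (side - h) // 2
    c0 = (side - w) // 2
    out[r0 : r0 + h, c0 : c0 + w] = img
    return out


def normalize_image(img: np.ndarray) -> RepresentativeImage:
    """Rescale to [0, 255], round, and resize to 224 x 224 (bilinear).

    A constant image maps to all zeros.  Inputs already at 224 x 224 whose
    values span [0, 255] pass through unchanged.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.size == 0:
        raise SlicerError("cannot normalize an empty image")
    lo, hi = float(img.min()), float(img.max())
    if hi > lo:
        scaled = (img - lo) * (255.0 / (hi - lo))
    else:
        scaled = np.zeros_like(img)
    scaled = np.rint(scaled)
    if scaled.shape != (RASTER_SIZE, RASTER_SIZE):
        scaled = _sk_resize(
            scaled, (RASTER_SIZE, RASTER_SIZE), order=1, preserve_range=True, anti_aliasing=False
        )
        scaled = np.rint(scaled)
    return RepresentativeImage(np.clip(scaled, 0, 255))


def normalized_cross_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-mean normalized cross-correlation of two equal-shape images."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(a @ b / denom)
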