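"""Synthetic organ phantoms with a known plane of bilateral symmetry.

Four classes — head, thorax, breast, abdomen — mimic the gross geometry of
body regions at three intensity tiers: background around 5, soft organ
tissue around 108-128, and bright bone-like structures, scanner table and
artifact specks at 205-250 (an arbitrary scalar scale).  The tiers are
separated by wide gaps so a two-threshold Otsu band isolates the soft
tissue while rejecting the background, the bright structures and the
intensity-extreme artifacts; the excluded bright structures leave crisp,
class-distinctive holes in the segmented cloud and stay visible in the
extracted slice.  Every class is built mirror-symmetric about the
mid-x plane; each also carries an off-center on-plane marker blob so that
only the x mirror is a true symmetry (otherwise an ellipsoid would admit
three symmetry planes and the estimator's multi-start could legitimately
pick the wrong one).

Geometry is specified in millimetres on an anisotropic grid (default
spacing 0.8 x 0.8 x 2.4 mm) so that the isotropic resampling step is
genuinely exercised.  ``asymmetry_jitter`` displaces the mirrored halves of
paired structures by up to that many voxels, emulating the imperfect
left/right symmetry of real anatomy; ``noise_sd`` adds Gaussian intensity
noise.  With both at zero the voxel lattice is mirror-symmetric exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .symmetry import Plane
from .volume import VolumeGrid

CLASSES: tuple[str, ...] = ("head", "thorax", "breast", "abdomen")

BACKGROUND_TIER = 5.0
ARTIFACT_TIER = 250.0


class PhantomError(Exception):
    pass


@dataclass(frozen=True)
class PhantomSpec:
    class_id: str = "head"
    grid_shape: tuple[int, int, int] = (56, 56, 24)
    spacing: tuple[float, float, float] = (0.8, 0.8, 2.4)
    noise_sd: float = 5.0
    asymmetry_jitter: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_id not in CLASSES:
            raise PhantomError(f"unknown class {self.class_id!r}; expected one of {CLASSES}")
        if self.noise_sd < 0 or self.asymmetry_jitter < 0:
            raise PhantomError("noise_sd and asymmetry_jitter must be >= 0")
        if min(self.grid_shape) < 12:
            raise PhantomError(f"grid {self.grid_shape} too small to contain the phantom geometry")


@dataclass
class _Geometry:
    """Per-item randomized geometry parameters (mm, relative to grid center)."""

    scale: np.ndarray = field(default_factory=lambda: np.ones(3))
    shift_yz: np.ndarray = field(default_factory=lambda: np.zeros(2))
    x_shift: float = 0.0


def _coords_mm(spec: PhantomSpec, geo: _Geometry) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Physical coordinates relative to the (possibly shifted) phantom center.

    Returns broadcastable dx, dy, dz in mm and the plane x offset in
    original-grid voxel units.
    """
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.spacing
    cx_mm = (nx - 1) / 2.0 * sx + geo.x_shift
    cy_mm = (ny - 1) / 2.0 * sy + geo.shift_yz[0]
    cz_mm = (nz - 1) / 2.0 * sz + geo.shift_yz[1]
    dx = (np.arange(nx) * sx - cx_mm)[:, None, None]
    dy = (np.arange(ny) * sy - cy_mm)[None, :, None]
    dz = (np.arange(nz) * sz - cz_mm)[None, None, :]
    return dx, dy, dz, cx_mm / sx


def _ellipsoid(dx, dy, dz, center, radii) -> np.ndarray:
    return (
        ((dx - center[0]) / radii[0]) ** 2
        + ((dy - center[1]) / radii[1]) ** 2
        + ((dz - center[2]) / radii[2]) ** 2
    ) <= 1.0


def _mirrored_pair(dx, dy, dz, center, radii, jitter_mm, rng) -> np.ndarray:
    """Union of a feature at +x center and its mirror at -x, with jitter.

    With jitter 0 the pair is exactly mirror-symmetric on the lattice.
    Jitter acts mostly along x (asymmetric depth of the two members): an
    x displacement shifts the best symmetry plane by at most half of it,
    whereas a differential in-plane displacement of a pair tilts the best
    plane by ~(displacement / pair separation), which would make the
    nominal mid-plane a poor ground truth long before the jitter reaches
    a voxel.  In-plane jitter is therefore applied at quarter strength.
    """
    cx, cy, cz = center
    scale = np.array([1.0, 0.25, 0.25])
    j1 = jitter_mm * scale * rng.uniform(-1, 1, 3) if jitter_mm > 0 else np.zeros(3)
    j2 = jitter_mm * scale * rng.uniform(-1, 1, 3) if jitter_mm > 0 else np.zeros(3)
    right = _ellipsoid(dx, dy, dz, (cx + j1[0], cy + j1[1], cz + j1[2]), radii)
    left = _ellipsoid(dx, dy, dz, (-cx + j2[0], cy + j2[1], cz + j2[2]), radii)
    return right | left


def _egg(dx, dy, dz, rx, ry_lo, ry_hi, rz_lo, rz_hi) -> np.ndarray:
    """Ellipsoid with asymmetric y/z semi-axes (egg shape), x-symmetric.

    The unequal radii above/below the y and z midlines break the spurious
    coronal and axial mirror symmetries a plain ellipsoid would have, so
    the sagittal plane is the unique plane of symmetry by a wide margin.
    """
    ry = np.where(dy >= 0, ry_hi, ry_lo)
    rz = np.where(dz >= 0, rz_hi, rz_lo)
    return (dx / rx) ** 2 + (dy / ry) ** 2 + (dz / rz) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec, _geo: _Geometry | None = None) -> tuple[VolumeGrid, Plane]:
    """Build one phantom volume plus its ground-truth symmetry plane.

    The returned plane is expressed in voxel units of the grid along x
    (which isotropic resampling leaves unchanged): normal (1, 0, 0) and
    offset at the phantom's mirror plane.
    """
    rng = np.random.default_rng(spec.seed)
    geo = _geo or _Geometry()
    dx, dy, dz, plane_x = _coords_mm(spec, geo)
    sc = geo.scale
    jit_mm = spec.asymmetry_jitter * spec.spacing[0]

    vol = np.full(spec.grid_shape, BACKGROUND_TIER, dtype=np.float64)
    cls = spec.class_id

    # scanner-table slab: bright, below the body, present for every class.
    # Together with the head's skull-like rim it gives the high intensity
    # tier real mass, so the two-threshold histogram split cleanly isolates
    # the organ tier instead of splitting the broad background mode.
    table = (np.abs(dy - 14.5) <= 1.2) & (np.abs(dz) <= 12.0) & (np.abs(dx) <= 11.0)

    if cls == "head":
        body = _egg(dx, dy, dz, 10.5 * sc[0], 12.5 * sc[1], 8.5 * sc[1], 14.5 * sc[2], 12.0 * sc[2])
        # skull-like rim several voxels thick: thin bright shells smear
        # away under interpolated rotation and destabilize the slice
        rim = (
            _egg(dx, dy, dz, 12.6 * sc[0], 14.0 * sc[1], 9.5 * sc[1], 17.4 * sc[2], 14.4 * sc[2])
            & ~body
        )
        cavities = _mirrored_pair(dx, dy, dz, (4.5, -4.0, -5.0), (3.0, 3.0, 3.8), jit_mm, rng)
        marker = _ellipsoid(dx, dy, dz, (0, 5.0, 6.0), (2.4, 2.4, 3.0))
        vol[body] = 120.0
        vol[marker & body] = 205.0
        vol[cavities & body] = BACKGROUND_TIER
        vol[rim] = ARTIFACT_TIER
    elif cls == "thorax":
        body = _egg(dx, dy, dz, 13.0 * sc[0], 10.0 * sc[1], 8.0 * sc[1], 18.0 * sc[2], 15.5 * sc[2])
        lungs = _mirrored_pair(dx, dy, dz, (6.0, -1.5, -2.0), (4.8, 5.2, 10.0), jit_mm, rng)
        column = (dx**2 + (dy + 5.5) ** 2) <= 2.8**2  # bright column along z
        marker = _ellipsoid(dx, dy, dz, (0, -4.5, -9.5), (2.6, 2.6, 3.2))
        vol[body] = 112.0
        vol[column & body] = 210.0
        vol[marker & body] = 205.0
        vol[lungs & body] = BACKGROUND_TIER
    elif cls == "breast":
        slab = (np.abs(dy - 5.0) <= 5.0) & (
            (dx / (13.0 * sc[0])) ** 2 + (dz / np.where(dz >= 0, 21.0 * sc[2], 14.5 * sc[2])) ** 2
            <= 1.0
        )
        mounds = _mirrored_pair(
            dx, dy, dz, (5.5, -1.0, 6.0), (7.5 * sc[0], 7.0 * sc[1], 8.0 * sc[2]), jit_mm, rng
        ) & (dy <= 1.5)
        marker = _ellipsoid(dx, dy, dz, (0, 2.5, -12.0), (3.0, 3.0, 3.6))
        vol[slab] = 110.0
        vol[mounds] = 128.0
        vol[marker] = 205.0
    elif cls == "abdomen":
        body = _egg(dx, dy, dz, 14.0 * sc[0], 13.0 * sc[1], 10.0 * sc[1], 18.5 * sc[2], 16.0 * sc[2])
        organs = _mirrored_pair(dx, dy, dz, (6.0, -3.0, -7.0), (4.2, 4.2, 5.2), jit_mm, rng)
        central = _ellipsoid(dx, dy, dz, (0, 4.0, 5.0), (3.2, 3.0, 3.8))
        vol[body] = 108.0
        vol[organs & body] = 210.0
        vol[central & body] = 205.0

    vol[table] = ARTIFACT_TIER

    # scanner point-spread function: band-limit the piecewise-constant
    # geometry so interpolated resampling behaves as it would on real,
    # already-blurred acquisitions (symmetric kernel, so lattice mirror
    # symmetry is preserved exactly).  The axial width matches the slice
    # spacing — the slice-profile blur of clinical scans — which keeps
    # the coarsely sampled z direction free of reconstruction aliasing
    from scipy import ndimage as _ndi

    vol = _ndi.gaussian_filter(vol, (0.7, 0.7, 1.0))

    # artifact specks at the extremes of the intensity spectrum; kept in
    # the background (salt-and-pepper in the air around the body, placed
    # after the PSF so they stay point-like) and mirrored so they never
    # break the constructed symmetry.  Specks inside the organ would punch
    # holes whose mirror lives on the voxel lattice rather than the
    # phantom's plane, contaminating the organ boundary.
    nx = spec.grid_shape[0]
    n_specks = max(8, vol.size // 8000)
    is_bg = vol < BACKGROUND_TIER + 25.0
    bg = np.argwhere(is_bg & is_bg[::-1, :, :])  # both the voxel and its mirror
    bg = bg[bg[:, 0] < nx // 2]
    picks = bg[rng.choice(len(bg), size=2 * n_specks, replace=False)]
    ix, iy, iz = picks[:, 0], picks[:, 1], picks[:, 2]
    values = np.where(np.arange(2 * n_specks) < n_specks, ARTIFACT_TIER, 0.0)
    vol[ix, iy, iz] = values
    vol[nx - 1 - ix, iy, iz] = values

    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape)

    plane = Plane((1.0, 0.0, 0.0), float(plane_x))
    return VolumeGrid(vol, spec.spacing), plane


def generate_cohort(
    n_per_class: int,
    spec_template: PhantomSpec | None = None,
    seed: int = 0,
) -> tuple[list[VolumeGrid], list[int], list[Plane]]:
    """Balanced cohort with per-item shape variation within each class.

    Each item varies the global scale (about +/-8%), per-axis aspect
    (+/-5%), and the phantom center (up to ~1.5 mm) so in-class variation is
    moderate while between-class geometry stays distinctive.  Labels are
    indices into :data:`CLASSES`.
    """
    if n_per_class < 2:
        raise PhantomError("need at least 2 phantoms per class")
    template = spec_template or PhantomSpec()
    rng = np.random.default_rng(seed)
    volumes: list[VolumeGrid] = []
    labels: list[int] = []
    planes: list[Plane] = []
    for label, cls in enumerate(CLASSES):
        for _ in range(n_per_class):
            geo = _Geometry(
                scale=rng.uniform(0.92, 1.08) * rng.uniform(0.95, 1.05, size=3),
                shift_yz=rng.uniform(-1.5, 1.5, size=2),
                x_shift=float(rng.uniform(-1.0, 1.0)),
            )
            spec = replace(template, class_id=cls, seed=int(rng.integers(2**31 - 1)))
            vol, plane = generate_phantom(spec, _geo=geo)
            volumes.append(vol)
            labels.append(label)
            planes.append(plane)
    return volumes, labels, planes
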