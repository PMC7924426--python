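"""Orientation perturbations and dataset assembly.

Two perturbation families emulate acquisition variability: small random
rigid motions (rotation up to +/-15 degrees per axis about the volume
center, translation up to +/-5 voxels per axis) model patient orientation,
and random axis permutations (equivalent to 90-degree rotations) model a
changed imaging direction.  ``build_datasets`` assembles the train/test
grid: a stratified 70/30 split, the two perturbed copies of the test set,
and an augmented training set in which half the items are rigidly
perturbed and half are axis-swapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import ndimage

from .symmetry import RigidTransform
from .volume import VolumeGrid


class SplitError(Exception):
    pass


# the five non-identity permutations of (x, y, z); identity would not be a change
AXIS_PERMUTATIONS: tuple[tuple[int, int, int], ...] = (
    (0, 2, 1),
    (1, 0, 2),
    (1, 2, 0),
    (2, 0, 1),
    (2, 1, 0),
)


@dataclass(frozen=True)
class PerturbationSpec:
    """Bounds of the random rigid perturbation (degrees / voxels, +/- per axis)."""

    rotation_range_deg: float = 15.0
    translation_range: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rotation_range_deg < 0 or self.translation_range < 0:
            raise ValueError("perturbation bounds must be non-negative")


def rotation_xyz(angles_deg: Sequence[float]) -> np.ndarray:
    """Rotation applying x, then y, then z axis rotations (R = Rz Ry Rx)."""
    ax, ay, az = np.deg2rad(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def rigid_resample(v: VolumeGrid, transform: RigidTransform, order: int = 1) -> VolumeGrid:
    """Resample ``v`` under ``transform`` (voxel coords), zero fill outside."""
    R, t = transform.rotation, transform.translation
    # output voxel y samples input at x = R^T (y - t)
    Rinv = R.T
    offset = -Rinv @ t
    out = ndimage.affine_transform(
        v.intensities, Rinv, offset=offset, order=order, mode="constant", cval=0.0
    )
    return VolumeGrid(out, v.spacing)


def random_rigid_volume(
    v: VolumeGrid,
    spec: PerturbationSpec,
    rng: np.random.Generator | None = None,
) -> tuple[VolumeGrid, RigidTransform]:
    """Apply one random rotation+translation about the volume center.

    Angles are uniform in +/-rotation_range_deg per axis (composed x, y, z),
    offsets uniform in +/-translation_range per axis; resampling is linear
    with zero fill.  Returns the perturbed volume and the applied transform
    (voxel coordinates) so tests can invert it.
    """
    if not v.is_isotropic:
        raise ValueError("rigid perturbations are defined on isotropic volumes; resample first")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    angles = rng.uniform(-spec.rotation_range_deg, spec.rotation_range_deg, size=3)
    offsets = rng.uniform(-spec.translation_range, spec.translation_range, size=3)
    R = rotation_xyz(angles)
    ctr = (np.asarray(v.shape, dtype=np.float64) - 1.0) / 2.0
    t = ctr + offsets - R @ ctr
    applied = RigidTransform(R, t)
    return rigid_resample(v, applied, order=1), applied


def apply_axis_permutation(v: VolumeGrid, perm: tuple[int, int, int]) -> VolumeGrid:
    """Pure index permutation of the axes; no interpolation."""
    out = np.transpose(v.intensities, perm).copy()
    spacing = tuple(v.spacing[p] for p in perm)
    return VolumeGrid(out, spacing)


def invert_permutation(perm: tuple[int, int, int]) -> tuple[int, int, int]:
    inv = [0, 0, 0]
    for i, p in enumerate(perm):
        inv[p] = i
    return tuple(inv)  # type: ignore[return-value]


def random_axis_swap(
    v: VolumeGrid, seed: int | None = None, rng: np.random.Generator | None = None
) -> tuple[VolumeGrid, tuple[int, int, int]]:
    """Apply one axis permutation drawn uniformly from the 5 non-identity ones."""
    if not v.is_isotropic:
        raise ValueError("axis swaps are defined on isotropic volumes; resample first")
    if rng is None:
        rng = np.random.default_rng(seed)
    perm = AXIS_PERMUTATIONS[int(rng.integers(len(AXIS_PERMUTATIONS)))]
    return apply_axis_permutation(v, perm), perm


@dataclass
class DatasetItem:
    """One volume with its class label and the perturbation that produced it."""

    volume: VolumeGrid
    label: int
    source_index: int
    kind: str = "original"  # original | transformed | axis_swapped
    record: dict[str, Any] = field(default_factory=dict)


@dataclass
class DatasetSplit:
    train: list[DatasetItem]
    test_original: list[DatasetItem]
    test_transformed: list[DatasetItem]
    test_axis_swapped: list[DatasetItem]
    augmented_train: list[DatasetItem]


def _rigid_item(item: DatasetItem, spec: PerturbationSpec, rng: np.random.Generator) -> DatasetItem:
    angles = rng.uniform(-spec.rotation_range_deg, spec.rotation_range_deg, size=3)
    offsets = rng.uniform(-spec.translation_range, spec.translation_range, size=3)
    R = rotation_xyz(angles)
    ctr = (np.asarray(item.volume.shape, dtype=np.float64) - 1.0) / 2.0
    t = ctr + offsets - R @ ctr
    vol = rigid_resample(item.volume, RigidTransform(R, t), order=1)
    return DatasetItem(
        volume=vol,
        label=item.label,
        source_index=item.source_index,
        kind="transformed",
        record={"angles_deg": angles.tolist(), "offsets": offsets.tolist()},
    )


def _swap_item(item: DatasetItem, rng: np.random.Generator) -> DatasetItem:
    vol, perm = random_axis_swap(item.volume, rng=rng)
    return DatasetItem(
        volume=vol,
        label=item.label,
        source_index=item.source_index,
        kind="axis_swapped",
        record={"permutation": list(perm)},
    )


def build_datasets(
    volumes: Sequence[VolumeGrid],
    labels: Sequence[int],
    train_fraction: float = 0.7,
    spec: PerturbationSpec = PerturbationSpec(),
) -> DatasetSplit:
    """Stratified split plus perturbed test copies and augmented training set.

    Per class, round(train_fraction * n) volumes go to training, the rest to
    test.  ``test_transformed`` and ``test_axis_swapped`` are derived 1:1
    from ``test_original``; ``augmented_train`` perturbs a copy of the
    training set, half rigidly, half by axis swap.  All randomness derives
    from ``spec.seed``.
    """
    if len(volumes) != len(labels):
        raise SplitError("volumes and labels must have equal length")
    labels = [int(l) for l in labels]
    rng = np.random.default_rng(spec.seed)

    by_class: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)
    for lab, idxs in by_class.items():
        if len(idxs) < 2:
            raise SplitError(f"class {lab} has fewer than 2 volumes")

    train_idx: list[int] = []
    test_idx: list[int] = []
    for lab in sorted(by_class):
        idxs = np.array(by_class[lab])
        rng.shuffle(idxs)
        n_train = int(round(train_fraction * len(idxs)))
        if n_train == len(idxs) or n_train == 0:
            raise SplitError(
                f"train_fraction {train_fraction} leaves an empty train or test set for class {lab}"
            )
        train_idx.extend(idxs[:n_train].tolist())
        test_idx.extend(idxs[n_train:].tolist())

    train = [DatasetItem(volumes[i], labels[i], i) for i in train_idx]
    test = [DatasetItem(volumes[i], labels[i], i) for i in test_idx]
    test_transformed = [_rigid_item(it, spec, rng) for it in test]
    test_axis_swapped = [_swap_item(it, rng) for it in test]

    order = np.arange(len(train))
    rng.shuffle(order)
    n_rigid = len(train) // 2
    augmented = []
    for pos, k in enumerate(order):
        item = train[int(k)]
        augmented.append(_rigid_item(item, spec, rng) if pos < n_rigid else _swap_item(item, rng))
    return DatasetSplit(
        train=train,
        test_original=test,
        test_transformed=test_transformed,
        test_axis_swapped=test_axis_swapped,
        augmented_train=augmented,
    )
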