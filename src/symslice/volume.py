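"""Volume I/O and isotropic resampling.

A 3D scan arrives either as a directory of single-frame DICOM slices or as
a NIfTI / ``.npz`` array-container file.  Slices are stacked by ascending
``InstanceNumber`` into an (x, y, z) lattice whose physical voxel spacing is
generally anisotropic: in-plane ``PixelSpacing`` differs from the
``SliceThickness`` between slices.  ``resample_isotropic`` interpolates the
lattice so every axis has the in-plane x spacing, restoring the organ's
real-world proportions before any geometry is computed on it.

The resampled array size is

    [n_x,  round(n_y * ps_y / ps_x),  round(n_z * st / ps_x)]

with cubic interpolation, edge-clamped at the borders.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage


class VolumeError(Exception):
    """Base class for volume construction/IO failures."""


class MetadataError(VolumeError):
    """A required DICOM tag is missing, duplicated, or inconsistent."""


class ShapeError(VolumeError):
    """Slices of one series disagree in their in-plane dimensions."""


class FormatError(VolumeError):
    """A volume file could not be parsed in the requested format."""


_ISO_RTOL = 1e-9


@dataclass
class DicomSeriesMeta:
    """Slice-ordering and spacing metadata of one DICOM series.

    ``pixel_spacing`` is (ps_x, ps_y) in mm/pixel, ``slice_thickness`` in mm.
    """

    instance_numbers: list[int]
    pixel_spacing: tuple[float, float]
    slice_thickness: float

    def __post_init__(self) -> None:
        ps_x, ps_y = self.pixel_spacing
        if not (ps_x > 0 and ps_y > 0 and self.slice_thickness > 0):
            raise MetadataError("pixel spacing and slice thickness must be positive")
        if len(set(self.instance_numbers)) != len(self.instance_numbers):
            raise MetadataError("InstanceNumber values are not distinct")


@dataclass
class VolumeGrid:
    """A 3D scalar intensity lattice with per-axis physical spacing (mm/voxel)."""

    intensities: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ShapeError(f"expected a 3D array, got ndim={self.intensities.ndim}")
        s = tuple(float(x) for x in self.spacing)
        if len(s) != 3 or any((not math.isfinite(x)) or x <= 0 for x in s):
            raise VolumeError(f"spacing must be three positive finite numbers, got {self.spacing}")
        self.spacing = s

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    @property
    def is_isotropic(self) -> bool:
        s = self.spacing
        ref = s[0]
        return all(abs(x - ref) <= _ISO_RTOL * max(abs(x), abs(ref)) for x in s)


def _round_half_away(x: float) -> int:
    """Round half away from zero, clipped below at 1 (array sizes)."""
    return max(1, int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1))


def load_dicom_series(directory: str | os.PathLike) -> tuple[VolumeGrid, DicomSeriesMeta]:
    """Stack the single-frame DICOM files of ``directory`` into a volume.

    Slices are ordered by ascending ``InstanceNumber`` along z; the on-disk
    file order is irrelevant.  Pixel data are promoted to float and the
    standard RescaleSlope/RescaleIntercept is applied when present.
    Returns the volume with spacing ``(ps_x, ps_y, slice_thickness)``
    together with the series metadata.
    """
    import pydicom

    directory = Path(directory)
    if not directory.is_dir():
        raise FormatError(f"not a directory: {directory}")
    paths = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in paths:
        try:
            ds = pydicom.dcmread(p)
        except Exception:
            continue  # ignore non-DICOM files in the directory
        datasets.append(ds)
    if len(datasets) < 2:
        raise FormatError(f"need at least 2 DICOM slices to form a volume, found {len(datasets)}")

    for tag in ("InstanceNumber", "PixelSpacing", "SliceThickness"):
        for ds in datasets:
            if getattr(ds, tag, None) is None:
                raise MetadataError(f"missing required DICOM tag {tag}")

    rows = {int(ds.Rows) for ds in datasets}
    cols = {int(ds.Columns) for ds in datasets}
    if len(rows) != 1 or len(cols) != 1:
        raise ShapeError(f"inconsistent in-plane dimensions: Rows={sorted(rows)}, Columns={sorted(cols)}")

    instance_numbers = [int(ds.InstanceNumber) for ds in datasets]
    if len(set(instance_numbers)) != len(instance_numbers):
        raise MetadataError("duplicate InstanceNumber values in series")
    datasets.sort(key=lambda ds: int(ds.InstanceNumber))

    ref = datasets[0]
    # DICOM PixelSpacing is (row spacing, column spacing) = (ps_y, ps_x).
    ps_y, ps_x = (float(v) for v in ref.PixelSpacing)
    st = float(ref.SliceThickness)

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
        intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
        if slope != 1.0 or intercept != 0.0:
            arr = arr * slope + intercept
        slices.append(arr.T)  # (rows, cols) -> (x, y)

    vol = np.stack(slices, axis=2)
    meta = DicomSeriesMeta(
        instance_numbers=sorted(instance_numbers),
        pixel_spacing=(ps_x, ps_y),
        slice_thickness=st,
    )
    return VolumeGrid(vol, (ps_x, ps_y, st)), meta


def resample_isotropic(v: VolumeGrid, order: int = 3) -> VolumeGrid:
    """Resample ``v`` onto an isotropic grid of spacing ``ps_x`` everywhere.

    The output array size is ``[n_x, round(n_y*ps_y/ps_x), round(n_z*st/ps_x)]``
    (round half away from zero, minimum 1).  Interpolation is cubic by
    default; samples falling outside the grid are clamped to the nearest
    edge voxel.
    """
    ps_x, ps_y, st = v.spacing
    n_x, n_y, n_z = v.shape
    new_shape = (
        n_x,
        _round_half_away(n_y * ps_y / ps_x),
        _round_half_away(n_z * st / ps_x),
    )
    if new_shape == v.shape and v.is_isotropic:
        return VolumeGrid(v.intensities.copy(), (ps_x, ps_x, ps_x))

    # new voxel j on axis a sits at physical position j*ps_x -> old index j*ps_x/s_a
    scales = [ps_x / s for s in v.spacing]
    axes = [np.arange(n) * sc for n, sc in zip(new_shape, scales)]
    coords = np.meshgrid(*axes, indexing="ij", sparse=False)
    out = ndimage.map_coordinates(v.intensities, coords, order=order, mode="nearest")
    return VolumeGrid(out.reshape(new_shape), (ps_x, ps_x, ps_x))


def save_volume(v: VolumeGrid, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a volume as NIfTI (``.nii``/``.nii.gz``) or npz array container."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        import nibabel as nib

        affine = np.diag(list(v.spacing) + [1.0])
        nib.save(nib.Nifti1Image(v.intensities, affine), str(path))
    elif fmt == "array_container":
        np.savez_compressed(path, intensities=v.intensities, spacing=np.asarray(v.spacing))
    else:
        raise FormatError(f"unknown volume format {fmt!r}")


def load_volume(path: str | os.PathLike, format: str | None = None) -> VolumeGrid:
    """Read a volume from NIfTI or the npz array container written by save_volume."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        import nibabel as nib

        try:
            img = nib.load(str(path))
            data = np.asarray(img.dataobj, dtype=np.float64)
            zooms = img.header.get_zooms()[:3]
        except Exception as exc:
            raise FormatError(f"could not read NIfTI file {path}: {exc}") from exc
        return VolumeGrid(data, tuple(float(z) for z in zooms))
    if fmt == "array_container":
        try:
            with np.load(path) as npz:
                data = npz["intensities"]
                spacing = tuple(float(x) for x in npz["spacing"])
        except Exception as exc:
            raise FormatError(f"could not read array container {path}: {exc}") from exc
        return VolumeGrid(data, spacing)
    raise FormatError(f"unknown volume format {fmt!r}")


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".npz"):
        return "array_container"
    raise FormatError(f"cannot infer volume format from file name {path.name!r}")


def save_dicom_series(
    v: VolumeGrid,
    directory: str | os.PathLike,
    instance_numbers: Sequence[int] | None = None,
) -> list[Path]:
    """Write ``v`` as a minimal single-frame DICOM series (uint16 pixels).

    Intended for exercising :func:`load_dicom_series` end-to-end on
    synthetic volumes; intensities are clipped to [0, 65535] and rounded.
    ``instance_numbers`` lets callers shuffle the slice/file association to
    test order recovery (default 1..n_z in file order).
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n_z = v.shape[2]
    if instance_numbers is None:
        instance_numbers = list(range(1, n_z + 1))
    if len(instance_numbers) != n_z:
        raise MetadataError("instance_numbers must have one entry per slice")

    series_uid = generate_uid()
    study_uid = generate_uid()
    ps_x, ps_y, st = v.spacing
    data = np.clip(np.rint(v.intensities), 0, 65535).astype(np.uint16)
    # slice k of the volume gets the k-th smallest instance number, so a
    # reader ordering by InstanceNumber recovers the original z order
    rank = {inst: k for k, inst in enumerate(sorted(instance_numbers))}
    written = []
    for file_idx, inst in enumerate(instance_numbers):
        sl = data[:, :, rank[inst]].T  # (x, y) -> (rows=y, cols=x)
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = SecondaryCaptureImageStorage
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "OT"
        ds.InstanceNumber = int(inst)
        ds.PixelSpacing = [f"{ps_y:g}", f"{ps_x:g}"]
        ds.SliceThickness = f"{st:g}"
        ds.Rows, ds.Columns = sl.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = np.ascontiguousarray(sl).tobytes()
        out = directory / f"slice_{file_idx:04d}.dcm"
        pydicom.dcmwrite(out, ds, enforce_file_format=True)
        written.append(out)
    return written
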