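"""End-to-end orchestration: volume -> representative image -> experiment.

``extract_representative`` chains the stages in order — isotropic
resampling, two-threshold Otsu segmentation, symmetry-plane estimation,
planar slice extraction, and 8-bit normalization — and records per-stage
diagnostics (thresholds, ICP residual, wall times).

``run_experiment`` reproduces the evaluation grid on a cohort: a
stratified split, three test conditions (original, rigidly transformed,
axis swapped), and optionally two training regimes (with and without
orientation augmentation), each summarized by a macro-averaged metric
report.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from . import dcnn as _dcnn
from .hog_svm import hog_svm_classify
from .metrics import ConfusionMatrix, MetricReport, compute_metrics
from .segmentation import IntensityThresholds, otsu_two_thresholds, segment_band
from .slicer import (
    RepresentativeImage,
    build_frame,
    extract_plane_image,
    normalize_image,
    pad_to_square,
)
from .symmetry import SymmetryPlane, best_symmetry_plane
from .transforms import DatasetItem, DatasetSplit, PerturbationSpec, build_datasets
from .volume import VolumeGrid, resample_isotropic


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters, derived deterministically from one global seed."""

    otsu_bins: int = 256
    icp_max_iter: int = 50
    icp_tol: float = 1e-4
    icp_max_points: int = 5000
    train_fraction: float = 0.7
    perturbation: PerturbationSpec = PerturbationSpec()
    backend: str = "dcnn"  # dcnn | hog_svm
    train: _dcnn.TrainConfig = _dcnn.TrainConfig()
    seed: int = 0

    def reseeded(self, seed: int) -> "PipelineConfig":
        """Derive every stage seed from one global seed."""
        return replace(
            self,
            seed=seed,
            perturbation=replace(self.perturbation, seed=seed + 1),
            train=replace(self.train, seed=seed + 2),
        )


def _isosurface_cloud(intensities, thresholds, organ_mask):
    """Sub-voxel boundary vertices of the organ component, or None.

    Marching cubes at t_low catches the organ/background interface and at
    t_high the interface with bright excluded structures; vertices are
    kept only within one voxel of the organ component so that crossings
    belonging to other structures (tables, detached shells) are dropped.
    Callers pass a lightly smoothed copy of the intensity field: the
    registration and plane scoring behave markedly better on smooth,
    alias-free boundaries, while thresholds, cloud statistics and the
    extracted slice all remain on the original data.
    """
    from scipy import ndimage as _ndi
    from skimage import measure

    from .segmentation import PointCloud as _PC

    near = _ndi.binary_dilation(organ_mask)
    verts = []
    for level in (thresholds.t_low, thresholds.t_high):
        lo, hi = float(intensities.min()), float(intensities.max())
        if not lo < level < hi:
            continue
        try:
            v, _, _, _ = measure.marching_cubes(intensities, level=level)
        except (ValueError, RuntimeError):
            continue
        idx = np.clip(np.rint(v).astype(int), 0, np.array(intensities.shape) - 1)
        keep = near[idx[:, 0], idx[:, 1], idx[:, 2]]
        if keep.any():
            verts.append(v[keep])
    if not verts:
        return None
    pts = np.vstack(verts)
    return _PC(pts) if len(pts) >= 4 else None


@dataclass
class ExtractResult:
    image: RepresentativeImage
    plane: SymmetryPlane
    thresholds: IntensityThresholds
    timings: dict[str, float] = field(default_factory=dict)


def extract_representative(v: VolumeGrid, config: PipelineConfig = PipelineConfig()) -> ExtractResult:
    """Run reconstruction -> segmentation -> symmetry -> slice on one volume."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    iso = v if v.is_isotropic else resample_isotropic(v)
    timings["resample"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    thresholds = otsu_two_thresholds(iso, bins=config.otsu_bins)
    mask, cloud = segment_band(iso, thresholds)
    timings["segment"] = time.perf_counter() - t0

    # the organ is the largest connected in-band component: partial-volume
    # voxels at the edges of bright excluded structures (tables, bone
    # shells) fall inside the band as thin detached shells and would skew
    # the cloud statistics
    t0 = time.perf_counter()
    from scipy import ndimage as _ndi
    from .segmentation import PointCloud as _PC

    labelled, n_comp = _ndi.label(mask)
    if n_comp > 1:
        sizes = np.bincount(labelled.ravel())[1:]
        mask = labelled == (int(np.argmax(sizes)) + 1)
    organ_cloud = _PC(np.argwhere(mask).astype(float))

    # register on the organ's boundary at sub-voxel accuracy: interior
    # voxels of a thick cloud match trivially under any reflection and
    # only dilute the ICP correspondences, and a binary voxel surface has
    # a ~0.5-voxel staircase mismatch floor that hides small tilts on
    # small organs.  Iso-surface vertices of the (smooth) intensity field
    # at the band thresholds resolve the boundary to a fraction of a voxel.
    smoothed = _ndi.gaussian_filter(iso.intensities, 1.0)
    surf_cloud = _isosurface_cloud(smoothed, thresholds, mask) or organ_cloud
    plane = best_symmetry_plane(
        surf_cloud,
        max_iter=config.icp_max_iter,
        tol=config.icp_tol,
        max_points=config.icp_max_points,
        seed=config.seed,
        frame_cloud=organ_cloud,
    )
    timings["symmetry"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    frame = build_frame(iso, plane, center=organ_cloud.centroid)
    raw = extract_plane_image(iso, frame)
    image = normalize_image(pad_to_square(raw))
    timings["slice"] = time.perf_counter() - t0
    return ExtractResult(image=image, plane=plane, thresholds=thresholds, timings=timings)


def _extract_items(items: list[DatasetItem], config: PipelineConfig) -> list[RepresentativeImage]:
    return [extract_representative(it.volume, config).image for it in items]


@dataclass
class ExperimentResult:
    reports: dict[str, MetricReport]
    confusion: dict[str, ConfusionMatrix]
    training_logs: dict[str, list] = field(default_factory=dict)


def run_experiment(
    volumes,
    labels,
    config: PipelineConfig = PipelineConfig(),
    regimes: tuple[str, ...] = ("original", "augmented"),
    split: DatasetSplit | None = None,
) -> ExperimentResult:
    """Train per regime and evaluate on the three test conditions.

    Produces one metric report per (regime, condition) pair, keyed
    ``"<regime>/<condition>"``.  The augmented regime trains on the
    original training images plus their perturbed copies.
    """
    if split is None:
        # perturbations model patient orientation in physical space, so they
        # act on the reconstructed isotropic volumes
        volumes = [v if v.is_isotropic else resample_isotropic(v) for v in volumes]
        split = build_datasets(
            volumes, labels, train_fraction=config.train_fraction, spec=config.perturbation
        )
    n_classes = len(set(int(l) for l in labels))

    train_imgs = _extract_items(split.train, config)
    train_labels = [it.label for it in split.train]
    test_sets = {
        "original": split.test_original,
        "transformed": split.test_transformed,
        "axis_swapped": split.test_axis_swapped,
    }
    test_imgs = {name: _extract_items(items, config) for name, items in test_sets.items()}
    test_labels = {name: [it.label for it in items] for name, items in test_sets.items()}

    reports: dict[str, MetricReport] = {}
    confusion: dict[str, ConfusionMatrix] = {}
    logs: dict[str, list] = {}
    for regime in regimes:
        imgs, labs = list(train_imgs), list(train_labels)
        if regime == "augmented":
            imgs += _extract_items(split.augmented_train, config)
            labs += [it.label for it in split.augmented_train]
        elif regime != "original":
            raise ValueError(f"unknown training regime {regime!r}")

        if config.backend == "dcnn":
            model = _dcnn.build_dcnn(
                _dcnn.DcnnConfig(n_classes=n_classes, seed=config.seed)
            )
            logs[regime] = _dcnn.train(model, imgs, labs, config.train)
            predict = lambda test: _dcnn.predict(model, test)[0]  # noqa: E731
        elif config.backend == "hog_svm":
            predict = lambda test: hog_svm_classify(imgs, labs, test, seed=config.seed)  # noqa: E731
        else:
            raise ValueError(f"unknown backend {config.backend!r}")

        for name in test_sets:
            y_pred = predict(test_imgs[name])
            cm = ConfusionMatrix.from_predictions(test_labels[name], y_pred, n_classes)
            key = f"{regime}/{name}"
            confusion[key] = cm
            reports[key] = compute_metrics(cm)
    return ExperimentResult(reports=reports, confusion=confusion, training_logs=logs)
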