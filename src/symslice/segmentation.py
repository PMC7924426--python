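"""Two-threshold global Otsu segmentation and point-cloud conversion.

The organ is isolated by a *band* of intensities: multi-level Otsu with two
thresholds partitions the global histogram into three classes, and voxels
whose intensity lies within [t_low, t_high] — the middle class — are taken
to be the organ.  Discarding the outer classes also drops imaging artifacts
living at the extremes of the intensity spectrum.  The segmentation is
deliberately simple: it only needs to be good enough to support symmetry
estimation on the resulting point cloud, not anatomically exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import VolumeGrid


class SegmentationError(Exception):
    pass


class DegenerateHistogramError(SegmentationError):
    """Fewer than three distinct intensities: no 3-class split exists."""


class EmptySegmentationError(SegmentationError):
    """The threshold band contains no voxel."""


@dataclass(frozen=True)
class IntensityThresholds:
    """The two Otsu band limits, in the volume's intensity units."""

    t_low: float
    t_high: float

    def __post_init__(self) -> None:
        if not self.t_low < self.t_high:
            raise SegmentationError(f"t_low must be < t_high, got ({self.t_low}, {self.t_high})")


@dataclass
class PointCloud:
    """N x 3 coordinates of segmented voxels, in isotropic-voxel units."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got {self.points.shape}")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def save_xyz(self, path) -> None:
        np.savetxt(path, self.points, fmt="%.6f")


def otsu_two_thresholds(v: VolumeGrid, bins: int = 256) -> IntensityThresholds:
    """Exhaustive two-threshold Otsu on the volume's global histogram.

    The (t_low, t_high) pair maximizes the between-class variance of the
    three-class histogram partition (equivalently minimizes within-class
    variance).  All bin pairs are searched; on ties the lexicographically
    smallest pair wins.  Returned thresholds are bin edges so that the
    closed band [t_low, t_high] selects exactly the middle class.
    """
    data = v.intensities.ravel()
    lo, hi = float(data.min()), float(data.max())
    if hi == lo or np.unique(data).size < 3:
        raise DegenerateHistogramError("volume has fewer than 3 distinct intensity values")

    counts, edges = np.histogram(data, bins=bins, range=(lo, hi))
    i, j = _best_pair(counts, edges)
    return IntensityThresholds(t_low=float(edges[i + 1]), t_high=float(edges[j + 1]))


def _best_pair(counts: np.ndarray, edges: np.ndarray) -> tuple[int, int]:
    """Arg-max of between-class variance over all threshold bin pairs (i < j).

    Classes are bins [0..i], [i+1..j], [j+1..]; maximizing sum_k m_k^2 / w_k
    is equivalent to maximizing the between-class variance since the total
    mean is fixed.
    """
    nbins = counts.size
    p = counts.astype(np.float64) / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = np.cumsum(p)
    m = np.cumsum(p * centers)
    m_tot = m[-1]

    best = (-np.inf, 0, 1)
    for i in range(nbins - 2):
        j = np.arange(i + 1, nbins - 1)
        w0, m0 = w[i], m[i]
        w1 = w[j] - w0
        m1 = m[j] - m0
        w2 = 1.0 - w[j]
        m2 = m_tot - m[j]
        with np.errstate(divide="ignore", invalid="ignore"):
            crit = (
                np.where(w0 > 0, m0 * m0 / max(w0, 1e-300), 0.0)
                + np.where(w1 > 0, m1 * m1 / np.where(w1 > 0, w1, 1.0), 0.0)
                + np.where(w2 > 0, m2 * m2 / np.where(w2 > 0, w2, 1.0), 0.0)
            )
        k = int(np.argmax(crit))  # first occurrence -> smallest j in the row
        if crit[k] > best[0]:
            best = (float(crit[k]), i, i + 1 + k)
    return best[1], best[2]


def segment_band(v: VolumeGrid, t: IntensityThresholds) -> tuple[np.ndarray, PointCloud]:
    """Binary mask and point cloud of voxels with t_low <= intensity <= t_high."""
    mask = (v.intensities >= t.t_low) & (v.intensities <= t.t_high)
    if not mask.any():
        raise EmptySegmentationError(
            f"no voxel falls in the intensity band [{t.t_low}, {t.t_high}]"
        )
    cloud = PointCloud(np.argwhere(mask).astype(np.float64))
    return mask, cloud
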