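"""Slice frame geometry, nearest-neighbour extraction, 8-bit normalization."""

import numpy as np
import pytest

from symslice.slicer import (
    FrameError,
    RepresentativeImage,
    SliceFrame,
    build_frame,
    extract_plane_image,
    normalize_image,
    normalized_cross_correlation,
    pad_to_square,
)
from symslice.symmetry import Plane, SymmetryPlane
from symslice.volume import VolumeGrid


def axis_plane(n_x, offset=None):
    """Symmetry frame for the plane x = offset with axes along y and z."""
    return SymmetryPlane(
        plane=Plane((1.0, 0.0, 0.0), (n_x - 1) / 2 if offset is None else offset),
        axis_u=np.array([0.0, 1.0, 0.0]),
        axis_v=np.array([0.0, 0.0, 1.0]),
        residual_rms=0.0,
    )


class TestBuildFrame:
    def test_axis_aligned_plane_on_cube_spans_volume_extents(self, rng):
        v = VolumeGrid(rng.normal(size=(21, 21, 21)), (1, 1, 1))
        f = build_frame(v, axis_plane(21))
        assert f.u_range == (-10.0, 10.0)
        assert f.v_range == (-10.0, 10.0)
        np.testing.assert_allclose(f.origin, [10, 10, 10])

    def test_doubling_volume_doubles_ranges(self, rng):
        small = VolumeGrid(np.zeros((11, 11, 11)), (1, 1, 1))
        big = VolumeGrid(np.zeros((21, 21, 21)), (1, 1, 1))
        fs = build_frame(small, axis_plane(11))
        fb = build_frame(big, axis_plane(21))
        assert fb.u_range[1] == pytest.approx(2 * fs.u_range[1])
        assert fb.pixel_step == pytest.approx(2 * fs.pixel_step)

    def test_pixel_step_invariant_under_axis_permutation(self, rng):
        v = VolumeGrid(np.zeros((20, 30, 40)), (1, 1, 1))
        f1 = build_frame(v, axis_plane(20))
        vp = VolumeGrid(np.transpose(v.intensities, (2, 0, 1)), (1, 1, 1))
        sp = SymmetryPlane(
            plane=Plane((0.0, 1.0, 0.0), 9.5),
            axis_u=np.array([0.0, 0.0, 1.0]),
            axis_v=np.array([1.0, 0.0, 0.0]),
            residual_rms=0.0,
        )
        f2 = build_frame(vp, sp)
        assert f1.pixel_step == pytest.approx(f2.pixel_step)

    def test_content_center_anchoring(self):
        v = VolumeGrid(np.zeros((30, 30, 30)), (1, 1, 1))
        center = np.array([20.0, 12.0, 18.0])
        f = build_frame(v, axis_plane(30, offset=14.5), center=center)
        # origin is the orthogonal projection of the center onto the plane
        np.testing.assert_allclose(f.origin, [14.5, 12.0, 18.0])

    def test_degenerate_axes_rejected(self):
        v = VolumeGrid(np.zeros((8, 8, 8)), (1, 1, 1))
        with pytest.raises(FrameError):
            SliceFrame(
                origin=np.zeros(3),
                axis_u=np.array([0.0, 1.0, 0.0]),
                axis_v=np.array([0.0, 1.0, 0.0]),
                u_range=(-1, 1),
                v_range=(-1, 1),
                pixel_step=1.0,
            )
        del v


class TestExtractPlaneImage:
    def test_mid_plane_extraction_equals_array_slab(self, rng):
        n = 17
        v = VolumeGrid(rng.integers(0, 255, size=(n, n, n)).astype(float), (1, 1, 1))
        mid = (n - 1) / 2  # integer index 8
        f = SliceFrame(
            origin=np.array([mid, mid, mid]),
            axis_u=np.array([0.0, 1.0, 0.0]),
            axis_v=np.array([0.0, 0.0, 1.0]),
            u_range=(-mid, mid),
            v_range=(-mid, mid),
            pixel_step=1.0,
        )
        img = extract_plane_image(v, f)
        np.testing.assert_array_equal(img, v.intensities[int(mid)])

    def test_plane_outside_volume_is_all_zero(self):
        v = VolumeGrid(np.full((10, 10, 10), 9.0), (1, 1, 1))
        f = SliceFrame(
            origin=np.array([100.0, 100.0, 100.0]),
            axis_u=np.array([0.0, 1.0, 0.0]),
            axis_v=np.array([0.0, 0.0, 1.0]),
            u_range=(-4, 4),
            v_range=(-4, 4),
            pixel_step=1.0,
        )
        assert extract_plane_image(v, f).max() == 0.0

    def test_every_in_volume_sample_is_an_exact_voxel_value(self, rng):
        v = VolumeGrid(rng.normal(size=(12, 12, 12)), (1, 1, 1))
        f = SliceFrame(
            origin=np.array([5.2, 5.7, 5.1]),
            axis_u=np.array([0.0, 1.0, 0.0]),
            axis_v=np.array([0.0, 0.0, 1.0]),
            u_range=(-3, 3),
            v_range=(-3, 3),
            pixel_step=0.7,
        )
        img = extract_plane_image(v, f)
        voxels = set(np.round(v.intensities.ravel(), 12)) | {0.0}
        assert all(round(x, 12) in voxels for x in img.ravel())

    def test_swapping_axes_transposes_image(self, rng):
        v = VolumeGrid(rng.normal(size=(15, 15, 15)), (1, 1, 1))
        kw = dict(origin=np.array([7.0, 7.0, 7.0]), u_range=(-5, 5), v_range=(-5, 5), pixel_step=1.0)
        f1 = SliceFrame(axis_u=np.array([0.0, 1.0, 0.0]), axis_v=np.array([0.0, 0.0, 1.0]), **kw)
        f2 = SliceFrame(axis_u=np.array([0.0, 0.0, 1.0]), axis_v=np.array([0.0, 1.0, 0.0]), **kw)
        np.testing.assert_array_equal(extract_plane_image(v, f1), extract_plane_image(v, f2).T)

    def test_rotating_volume_and_frame_together_is_equivariant(self, iso_head, pipeline_config):
        from symslice.pipeline import extract_representative
        from symslice.transforms import rigid_resample, rotation_xyz
        from symslice.symmetry import RigidTransform

        iso, _ = iso_head
        res = extract_representative(iso, pipeline_config)
        R = rotation_xyz((6.0, -9.0, 12.0))
        ctr = (np.asarray(iso.shape) - 1) / 2
        moved = rigid_resample(iso, RigidTransform(R, ctr - R @ ctr), order=1)
        res2 = extract_representative(moved, pipeline_config)
        assert normalized_cross_correlation(res.image.pixels, res2.image.pixels) >= 0.95


class TestNormalizeImage:
    def test_linear_rescale_to_eight_bits(self):
        img = np.linspace(0, 510, 224 * 224).reshape(224, 224)
        out = normalize_image(img)
        np.testing.assert_array_equal(out.pixels, np.rint(img / 2).astype(np.uint8))

    def test_constant_image_becomes_all_zero(self):
        out = normalize_image(np.full((50, 80), 7.3))
        assert out.pixels.shape == (224, 224)
        assert out.pixels.max() == 0

    def test_full_range_224_input_unchanged(self, rng):
        img = rng.integers(0, 256, size=(224, 224)).astype(float)
        img[0, 0], img[0, 1] = 0, 255  # pin the range
        out = normalize_image(img)
        np.testing.assert_array_equal(out.pixels, img.astype(np.uint8))

    def test_resize_to_raster_size(self, rng):
        out = normalize_image(rng.uniform(0, 1, size=(60, 100)))
        assert out.pixels.shape == (224, 224)

    def test_pad_to_square_is_symmetric(self):
        img = np.ones((4, 8))
        out = pad_to_square(img)
        assert out.shape == (8, 8)
        assert out[:2].sum() == 0 and out[-2:].sum() == 0
        np.testing.assert_array_equal(out[2:6], img)


class TestRepresentativeImage:
    def test_png_roundtrip(self, tmp_path, rng):
        img = RepresentativeImage(rng.integers(0, 256, size=(224, 224)).astype(np.uint8))
        path = tmp_path / "slice.png"
        img.to_png(path)
        back = RepresentativeImage.from_png(path)
        np.testing.assert_array_equal(back.pixels, img.pixels)

    def test_shape_and_range_invariants(self):
        with pytest.raises(Exception):
            RepresentativeImage(np.zeros((100, 100)))
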