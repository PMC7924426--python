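"""Rigid perturbations, axis swaps, and dataset assembly."""

import numpy as np
import pytest

from symslice.phantoms import PhantomSpec, generate_phantom
from symslice.symmetry import RigidTransform
from symslice.transforms import (
    AXIS_PERMUTATIONS,
    PerturbationSpec,
    SplitError,
    apply_axis_permutation,
    build_datasets,
    invert_permutation,
    random_axis_swap,
    random_rigid_volume,
    rigid_resample,
    rotation_xyz,
)
from symslice.volume import VolumeGrid


@pytest.fixture
def smooth_volume(rng):
    from scipy.ndimage import gaussian_filter

    data = gaussian_filter(rng.uniform(0, 100, size=(24, 24, 24)), 2.0)
    return VolumeGrid(data, (1, 1, 1))


class TestRandomRigidVolume:
    def test_zero_ranges_are_identity(self, smooth_volume):
        out, applied = random_rigid_volume(
            smooth_volume, PerturbationSpec(rotation_range_deg=0, translation_range=0, seed=1)
        )
        np.testing.assert_allclose(applied.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(out.intensities, smooth_volume.intensities, atol=1e-6)

    def test_fixed_seed_reproducible(self, smooth_volume):
        spec = PerturbationSpec(seed=9)
        out1, t1 = random_rigid_volume(smooth_volume, spec)
        out2, t2 = random_rigid_volume(smooth_volume, spec)
        np.testing.assert_array_equal(out1.intensities, out2.intensities)
        np.testing.assert_array_equal(t1.rotation, t2.rotation)

    def test_inverse_transform_restores_interior(self, smooth_volume):
        out, applied = random_rigid_volume(smooth_volume, PerturbationSpec(seed=4))
        R, t = applied.rotation, applied.translation
        back = rigid_resample(out, RigidTransform(R.T, -R.T @ t), order=1)
        sl = slice(7, 17)  # interior voxels, away from the zero fill
        orig = smooth_volume.intensities[sl, sl, sl]
        rest = back.intensities[sl, sl, sl]
        assert np.abs(orig - rest).max() < 0.12 * np.ptp(smooth_volume.intensities)
        assert np.corrcoef(orig.ravel(), rest.ravel())[0, 1] > 0.99

    def test_drawn_parameters_respect_bounds(self):
        spec = PerturbationSpec(rotation_range_deg=15, translation_range=5, seed=0)
        rng = np.random.default_rng(spec.seed)
        for _ in range(1000):
            angles = rng.uniform(-spec.rotation_range_deg, spec.rotation_range_deg, size=3)
            offsets = rng.uniform(-spec.translation_range, spec.translation_range, size=3)
            assert np.all(np.abs(angles) <= 15) and np.all(np.abs(offsets) <= 5)

    def test_rotation_composition_order(self):
        # R = Rz Ry Rx: applying only an x rotation leaves the x axis fixed
        R = rotation_xyz((30, 0, 0))
        np.testing.assert_allclose(R @ [1, 0, 0], [1, 0, 0], atol=1e-12)
        R = rotation_xyz((0, 0, 90))
        np.testing.assert_allclose(R @ [1, 0, 0], [0, 1, 0], atol=1e-12)


class TestAxisSwap:
    def test_permutation_universe_is_the_five_non_identities(self):
        assert len(AXIS_PERMUTATIONS) == 5
        assert (0, 1, 2) not in AXIS_PERMUTATIONS
        assert len(set(AXIS_PERMUTATIONS)) == 5

    def test_swap_preserves_intensity_multiset(self, rng):
        v = VolumeGrid(rng.normal(size=(5, 6, 7)), (1, 1, 1))
        out, perm = random_axis_swap(v, seed=3)
        assert sorted(out.intensities.ravel()) == sorted(v.intensities.ravel())
        assert out.shape == tuple(v.shape[p] for p in perm)

    def test_cyclic_permutation_has_order_three(self, rng):
        v = VolumeGrid(rng.normal(size=(4, 5, 6)), (1, 1, 1))
        perm = (1, 2, 0)
        out = v
        for _ in range(3):
            out = apply_axis_permutation(out, perm)
        np.testing.assert_array_equal(out.intensities, v.intensities)

    @pytest.mark.parametrize("perm", AXIS_PERMUTATIONS)
    def test_inverse_permutation_restores_exactly(self, perm, rng):
        v = VolumeGrid(rng.normal(size=(4, 6, 8)), (1, 1, 1))
        swapped = apply_axis_permutation(v, perm)
        back = apply_axis_permutation(swapped, invert_permutation(perm))
        np.testing.assert_array_equal(back.intensities, v.intensities)
        assert back.spacing == v.spacing

    def test_swap_of_isotropic_phantom_runs_endtoend(self):
        vol, _ = generate_phantom(PhantomSpec(grid_shape=(24, 24, 12), noise_sd=0.0))
        from symslice.volume import resample_isotropic

        iso = resample_isotropic(vol)
        out, perm = random_axis_swap(iso, seed=1)
        assert out.is_isotropic


def tiny_cohort(n_per_class=4, n_classes=4, rng=None):
    rng = rng or np.random.default_rng(0)
    volumes, labels = [], []
    for lab in range(n_classes):
        for _ in range(n_per_class):
            volumes.append(VolumeGrid(rng.normal(size=(6, 6, 6)), (1, 1, 1)))
            labels.append(lab)
    return volumes, labels


class TestBuildDatasets:
    def test_stratified_split_fractions(self):
        volumes, labels = tiny_cohort(n_per_class=10)
        split = build_datasets(volumes, labels, train_fraction=0.7, spec=PerturbationSpec(seed=0))
        for lab in range(4):
            n_train = sum(1 for it in split.train if it.label == lab)
            n_test = sum(1 for it in split.test_original if it.label == lab)
            assert (n_train, n_test) == (7, 3)

    def test_train_and_test_disjoint_by_source(self):
        volumes, labels = tiny_cohort()
        split = build_datasets(volumes, labels, spec=PerturbationSpec(seed=1))
        train_src = {it.source_index for it in split.train}
        test_src = {it.source_index for it in split.test_original}
        assert train_src.isdisjoint(test_src)

    def test_perturbed_test_sets_derived_one_to_one(self):
        volumes, labels = tiny_cohort()
        split = build_datasets(volumes, labels, spec=PerturbationSpec(seed=2))
        assert [it.source_index for it in split.test_transformed] == [
            it.source_index for it in split.test_original
        ]
        assert [it.source_index for it in split.test_axis_swapped] == [
            it.source_index for it in split.test_original
        ]
        assert all(it.kind == "transformed" for it in split.test_transformed)
        assert all("permutation" in it.record for it in split.test_axis_swapped)

    def test_augmented_train_kinds_split_half_and_half(self):
        volumes, labels = tiny_cohort(n_per_class=10)
        split = build_datasets(volumes, labels, spec=PerturbationSpec(seed=3))
        kinds = [it.kind for it in split.augmented_train]
        assert kinds.count("transformed") == len(kinds) // 2
        assert kinds.count("axis_swapped") == len(kinds) - len(kinds) // 2

    def test_full_train_fraction_rejected(self):
        volumes, labels = tiny_cohort()
        with pytest.raises(SplitError):
            build_datasets(volumes, labels, train_fraction=1.0)

    def test_single_volume_class_rejected(self):
        volumes, labels = tiny_cohort(n_per_class=2)
        volumes.append(volumes[0])
        labels.append(9)
        with pytest.raises(SplitError):
            build_datasets(volumes, labels)

    def test_fixed_seed_reproducible_split(self):
        volumes, labels = tiny_cohort()
        s1 = build_datasets(volumes, labels, spec=PerturbationSpec(seed=5))
        s2 = build_datasets(volumes, labels, spec=PerturbationSpec(seed=5))
        assert [it.source_index for it in s1.train] == [it.source_index for it in s2.train]
        np.testing.assert_array_equal(
            s1.test_transformed[0].volume.intensities, s2.test_transformed[0].volume.intensities
        )
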