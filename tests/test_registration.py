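"""Diffeomorphic registration, local affine refinement, resampling."""

import numpy as np
import pytest

from dtiparc.registration import (
    AffinePrior,
    AffineTransform12,
    DeformationField,
    compose_and_resample,
    diffeo_prior,
    diffeo_weights,
    optimize_local_affine,
    register_two_channel,
)
from dtiparc.volumes import LabelMap, ScalarVolume


def _blob_pair(shape=(24, 24, 24), centers=((9, 12, 12), (16, 12, 12)), sigma=2.5):
    """Two smooth Gaussian blobs; second channel with swapped amplitudes."""
    grids = np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")
    c0, c1 = centers
    d0 = sum((g - c) ** 2 for g, c in zip(grids, c0))
    d1 = sum((g - c) ** 2 for g, c in zip(grids, c1))
    ch1 = np.exp(-d0 / (2 * sigma**2)) + 0.6 * np.exp(-d1 / (2 * sigma**2))
    ch2 = 0.5 * np.exp(-d0 / (2 * sigma**2)) + np.exp(-d1 / (2 * sigma**2))
    return ch1, ch2


def _translate(vol, shift):
    from scipy.ndimage import shift as ndshift

    return ndshift(vol, shift, order=1, mode="nearest")


class TestDeformationField:
    def test_identity_properties(self):
        f = DeformationField.identity((8, 8, 8))
        assert f.max_displacement == 0.0
        assert f.geodesic_proxy == 0.0
        np.testing.assert_allclose(f.jacobian_determinant(), 1.0)

    def test_transform_points_identity(self):
        f = DeformationField.identity((8, 8, 8))
        pts = np.array([[1.5, 2.5, 3.5]])
        np.testing.assert_allclose(f.transform_points(pts), pts)


class TestRegisterTwoChannel:
    def test_identical_images_fixpoint(self):
        ch1, ch2 = _blob_pair()
        f = register_two_channel([ch1, ch2], [ch1, ch2])
        assert f.max_displacement < 1e-6
        assert f.geodesic_proxy == pytest.approx(0.0, abs=1e-9)
        assert f.jacobian_determinant().min() > 0

    def test_translation_recovery(self):
        subj1, subj2 = _blob_pair()
        # atlas(x) = subject(x - 2 e_x), so the pull-back field must map
        # subject coords to x + 2 e_x inside the blobs
        atl1, atl2 = _translate(subj1, (2.0, 0, 0)), _translate(subj2, (2.0, 0, 0))
        f = register_two_channel([atl1, atl2], [subj1, subj2])
        assert f.jacobian_determinant().min() > 0
        interior = subj1 > 0.3
        mean_disp = [f.disp[i][interior].mean() for i in range(3)]
        np.testing.assert_allclose(mean_disp, [2.0, 0.0, 0.0], atol=0.5)

    def test_energy_not_worse_than_identity(self):
        rng = np.random.default_rng(0)
        subj1, subj2 = _blob_pair()
        atl1 = subj1 + 0.05 * rng.normal(size=subj1.shape)
        atl2 = subj2 + 0.05 * rng.normal(size=subj2.shape)
        f = register_two_channel([atl1, atl2], [subj1, subj2])

        def energy(disp):
            from scipy.ndimage import map_coordinates

            grid = np.array(np.meshgrid(*(np.arange(n, dtype=float) for n in subj1.shape),
                                        indexing="ij"))
            e = 0.0
            for a, s in ((atl1, subj1), (atl2, subj2)):
                mu, sd = s.mean(), s.std()
                an, sn = (a - mu) / sd, (s - mu) / sd
                w = map_coordinates(an, grid + disp, order=1, mode="nearest")
                e += 0.5 * ((w - sn) ** 2).sum()
            return e

        assert energy(f.disp) <= energy(np.zeros_like(f.disp)) + 1e-9

    def test_symmetric_round_trip_small_residual(self, tiny_library):
        a = tiny_library.atlases[0].image
        b = tiny_library.subject.image
        fab = register_two_channel([a.fa, a.md], [b.fa, b.md])
        fba = register_two_channel([b.fa, b.md], [a.fa, a.md])
        # compose: x -> x + d_ab(x) -> + d_ba at the mapped point
        pts = np.array(np.meshgrid(*(np.arange(n, dtype=float) for n in a.shape),
                                   indexing="ij")).reshape(3, -1).T
        mapped = fab.transform_points(pts)
        total = mapped + fba.displacement_at(mapped) - pts
        interior = (tiny_library.subject.labels.data.ravel() > 0)
        assert np.linalg.norm(total[interior], axis=1).mean() < 1.0


class TestComposeAndResample:
    def test_identity_unchanged(self, rng):
        vol = ScalarVolume(rng.normal(size=(8, 8, 8)))
        out = compose_and_resample(DeformationField.identity((8, 8, 8)), None, vol)
        np.testing.assert_allclose(out.data, vol.data, atol=1e-12)

    def test_translation_of_ramp_is_analytic(self):
        ramp = np.fromfunction(lambda x, y, z: x, (10, 10, 10))
        disp = np.zeros((3, 10, 10, 10))
        disp[0] = 1.5
        out = compose_and_resample(DeformationField(disp), None, ScalarVolume(ramp))
        # interior: ramp(x + 1.5) = x + 1.5
        np.testing.assert_allclose(out.data[:8], ramp[:8] + 1.5, atol=1e-12)

    def test_label_indicators_partition(self, rng):
        labels = LabelMap(rng.integers(0, 3, (8, 8, 8)))
        disp = rng.normal(scale=0.5, size=(3, 8, 8, 8))
        field = DeformationField(disp)
        total = np.zeros((8, 8, 8))
        for lab in (0, 1, 2):
            ind = ScalarVolume((labels.data == lab).astype(float))
            from dtiparc.registration import compose_transform_points, _grid_points
            from scipy.ndimage import map_coordinates

            pts = _grid_points((8, 8, 8)).reshape(3, -1).T
            mapped = compose_transform_points(field, None, pts).T
            cval = 1.0 if lab == 0 else 0.0
            total += map_coordinates(ind.data, mapped, order=1, mode="constant",
                                     cval=cval).reshape(8, 8, 8)
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_nearest_mode_for_labels(self, rng):
        labels = LabelMap(rng.integers(0, 4, (8, 8, 8)))
        out = compose_and_resample(DeformationField.identity((8, 8, 8)), None, labels)
        assert isinstance(out, LabelMap)
        np.testing.assert_array_equal(out.data, labels.data)


class TestAffine:
    def test_singular_linear_part_rejected(self):
        p = np.zeros(12)
        p[0] = -1.0  # first diagonal entry becomes 0
        p[4] = -1.0
        with pytest.raises(ValueError):
            AffineTransform12(p)

    def test_apply_centered(self):
        p = np.zeros(12)
        p[9:] = [1.0, 0.0, 0.0]
        aff = AffineTransform12(p, center=(5.0, 5.0, 5.0))
        np.testing.assert_allclose(aff.apply(np.array([[5.0, 5.0, 5.0]])), [[6.0, 5.0, 5.0]])

    def test_prior_log_density_formula(self):
        prior = AffinePrior()
        p = np.zeros(12)
        p[9] = 2.0
        assert prior.log_density(p) == pytest.approx(-0.5 * 4.0 / 100.0)
        p2 = np.zeros(12)
        p2[0] = 0.1
        assert prior.log_density(p2) == pytest.approx(-0.5 * 0.01 / 0.01)


class TestOptimizeLocalAffine:
    def _cube_labels(self, shift=(0, 0, 0)):
        data = np.zeros((20, 20, 20), dtype=int)
        s = tuple(slice(6 + d, 13 + d) for d in shift)
        data[s] = 1
        return LabelMap(data)

    def test_aligned_structures_return_identity(self):
        atlas = self._cube_labels()
        field = DeformationField.identity(atlas.shape)
        aff = optimize_local_affine(1, atlas, field, atlas)
        assert aff.is_identity

    def test_offset_recovery_and_dice_increase(self):
        from dtiparc.quantify import dice
        from dtiparc.registration import compose_and_resample

        atlas = self._cube_labels()
        target = self._cube_labels(shift=(3, 0, 0))
        field = DeformationField.identity(atlas.shape)
        aff = optimize_local_affine(1, atlas, field, target)
        # pull-back: sampling atlas at x + t aligns with a target shifted by +3
        assert abs(aff.translation[0] - (-3.0)) < 1.0
        before = compose_and_resample(field, None, atlas)
        after = compose_and_resample(field, aff, atlas)
        d_before = dice(before.data == 1, target.data == 1)
        d_after = dice(after.data == 1, target.data == 1)
        assert d_after >= d_before

    def test_tight_prior_forces_identity(self):
        atlas = self._cube_labels()
        target = self._cube_labels(shift=(3, 0, 0))
        field = DeformationField.identity(atlas.shape)
        prior = AffinePrior(np.full(12, 1e-12))
        aff = optimize_local_affine(1, atlas, field, target, prior=prior)
        np.testing.assert_allclose(aff.params, 0.0)

    def test_empty_structure_identity_with_warning(self, caplog):
        atlas = self._cube_labels()
        empty = LabelMap(np.zeros((20, 20, 20), dtype=int))
        field = DeformationField.identity(atlas.shape)
        with caplog.at_level("WARNING"):
            aff = optimize_local_affine(1, atlas, field, empty)
        assert aff.is_identity


class TestDiffeoPrior:
    def test_identity_scores_one(self):
        assert diffeo_prior(DeformationField.identity((4, 4, 4))) == 1.0

    def test_monotone_in_deformation_size(self):
        small = DeformationField(np.zeros((3, 4, 4, 4)), geodesic_proxy=0.5)
        large = DeformationField(np.zeros((3, 4, 4, 4)), geodesic_proxy=2.0)
        assert diffeo_prior(large) < diffeo_prior(small)

    def test_weight_ratio_is_exponential_gap(self):
        f1 = DeformationField(np.zeros((3, 4, 4, 4)), geodesic_proxy=0.3)
        f2 = DeformationField(np.zeros((3, 4, 4, 4)), geodesic_proxy=1.1)
        w = diffeo_weights([f1, f2])
        assert w.sum() == pytest.approx(1.0)
        assert w[0] / w[1] == pytest.approx(np.exp(1.1 - 0.3), rel=1e-12)
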