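"""Fusion loop building blocks vs brute-force oracles on tiny instances."""

import numpy as np
import pytest

from dtiparc.fusion import (
    FusionConfig,
    FusionState,
    MultiAtlasFusion,
    compute_likelihood_cube,
    compute_selector,
    initialize,
    label_prior_cube,
    majority_vote,
    run,
    update_parcellation,
    update_transforms,
)
from dtiparc.intensity import AtlasSignature, GaussianMixture1D, fit_atlas_signature
from dtiparc.phantom import AtlasPair
from dtiparc.registration import DeformationField, diffeo_weights
from dtiparc.volumes import (
    LabelMap,
    MultiContrastImage,
    interpolate_label_probability,
)


def _uniform_signature(structures, loc=0.5):
    """Identical single-Gaussian models for every structure and channel."""
    model = GaussianMixture1D([1.0], [loc], [0.05])
    return AtlasSignature(
        {s: (model,) * 5 for s in structures}, {s: 1000.0 for s in structures}
    )


def _random_image(rng, shape):
    fa = rng.uniform(0.1, 0.9, shape)
    md = rng.uniform(3e-4, 3e-3, shape)
    v = np.abs(rng.normal(size=shape + (3,)))
    v /= np.linalg.norm(v, axis=-1, keepdims=True)
    return MultiContrastImage.from_arrays(fa, md, v[..., 0], v[..., 1], v[..., 2])


def _quantized_field(rng, shape, scale=1.0):
    """Smooth random field with displacements on a 1/4-voxel lattice, so
    trilinear weights are exact dyadic rationals (bit-stable oracles)."""
    from scipy.ndimage import gaussian_filter

    disp = np.stack([gaussian_filter(rng.normal(size=shape), 2.0) for _ in range(3)])
    disp *= scale / max(np.abs(disp).max(), 1e-12)
    return DeformationField(np.round(disp * 4) / 4)


class TestConfig:
    def test_zero_iterations_rejected(self):
        with pytest.raises(ValueError):
            FusionConfig(max_iterations=0)

    def test_empty_channel_mask_rejected(self):
        with pytest.raises(ValueError):
            FusionConfig(channel_mask=())


class TestInitialize:
    def test_single_atlas_identity_field(self, rng):
        shape = (8, 8, 8)
        labels = LabelMap(rng.integers(0, 3, shape))
        atlas = AtlasPair(_random_image(rng, shape), labels)
        cfg = FusionConfig(init_atlas=0)
        state = initialize([atlas], _random_image(rng, shape),
                           [DeformationField.identity(shape)], cfg)
        np.testing.assert_array_equal(state.parcellation.data, labels.data)

    def test_majority_vote_oracle(self, rng):
        shape = (8, 8, 8)
        maps = [LabelMap(rng.integers(0, 4, shape)) for _ in range(3)]
        voted = majority_vote(maps, (0, 1, 2, 3))
        # brute-force vote with smallest-label tie-break
        for idx in np.ndindex(shape):
            votes = np.bincount([m.data[idx] for m in maps], minlength=4)
            assert voted.data[idx] == int(np.flatnonzero(votes == votes.max())[0])

    def test_empty_atlas_list_rejected(self, rng):
        with pytest.raises(ValueError):
            initialize([], _random_image(rng, (4, 4, 4)), [], FusionConfig())


class TestSelector:
    def _make_state(self, atlases, subject, fields, cfg):
        return initialize(atlases, subject, fields, cfg)

    def test_identical_atlases_uniform_weights(self, rng):
        shape = (6, 6, 6)
        labels = LabelMap(rng.integers(0, 3, shape))
        img = _random_image(rng, shape)
        atlases = [AtlasPair(img, labels), AtlasPair(img, labels)]
        sigs = [_uniform_signature((0, 1, 2))] * 2
        fields = [DeformationField.identity(shape)] * 2
        cfg = FusionConfig()
        state = self._make_state(atlases, img, fields, cfg)
        lik = compute_likelihood_cube(img, sigs, state.labels_all, cfg.channel_mask)
        sel = compute_selector(state, lik, diffeo_weights(fields), cfg)
        np.testing.assert_allclose(sel, 0.5, atol=1e-12)

    def test_zero_likelihood_shifts_weight_to_other_atlas(self, rng):
        shape = (6, 6, 6)
        labels = LabelMap(np.ones(shape, dtype=int))
        img = _random_image(rng, shape)
        atlases = [AtlasPair(img, labels), AtlasPair(img, labels)]
        fields = [DeformationField.identity(shape)] * 2
        cfg = FusionConfig(channel_mask=(0,))
        state = self._make_state(atlases, img, fields, cfg)
        good = _uniform_signature((0, 1), loc=0.5)
        # atlas 1's FA model is centred impossibly far away -> ~zero density
        far = GaussianMixture1D([1.0], [1e6], [1e-6])
        bad = AtlasSignature({0: (far,) * 5, 1: (far,) * 5}, {0: 1.0, 1: 1.0})
        lik = compute_likelihood_cube(img, [good, bad], state.labels_all, cfg.channel_mask)
        sel = compute_selector(state, lik, diffeo_weights(fields), cfg)
        np.testing.assert_allclose(sel[0], 1.0, atol=1e-12)

    def test_matches_bruteforce_product_formula(self, rng):
        shape = (6, 6, 6)
        subject = _random_image(rng, shape)
        atlases, fields, sigs = [], [], []
        for k in range(2):
            lab = np.zeros(shape, dtype=int)
            lab[1:4, 1:5, 1:5] = 1
            lab[4 - k:6, 1:4, 1:4] = 2
            atlases.append(AtlasPair(_random_image(rng, shape), LabelMap(lab)))
            fields.append(DeformationField(
                rng.normal(scale=0.3, size=(3,) + shape), geodesic_proxy=0.1 * (k + 1)))
            sigs.append(fit_atlas_signature(atlases[-1].image, atlases[-1].labels, seed=k))
        cfg = FusionConfig()
        state = initialize(atlases, subject, fields, cfg)
        lik = compute_likelihood_cube(subject, sigs, state.labels_all, cfg.channel_mask)
        dw = diffeo_weights(fields)
        sel = compute_selector(state, lik, dw, cfg)
        # brute force: per voxel, product of intensity likelihood at the
        # current label, structure Dice factor, diffeo weight (affines are
        # identity so their prior factor is constant and cancels)
        from dtiparc.intensity import voxel_likelihood

        stacked = subject.stacked()
        for idx in [tuple(rng.integers(0, 6, 3)) for _ in range(30)]:
            lab = int(state.parcellation.data[idx])
            j = state.labels_all.index(lab)
            raw = np.array([
                voxel_likelihood(stacked[(slice(None),) + idx], lab, sigs[a])
                * state.structure_dice[a, j] * dw[a]
                for a in range(2)
            ])
            np.testing.assert_allclose(sel[(slice(None),) + idx], raw / raw.sum(),
                                       atol=1e-10)


class TestUpdateParcellation:
    def test_self_atlas_fixpoint(self, rng):
        shape = (8, 8, 8)
        labels = LabelMap(rng.integers(0, 3, shape))
        img = _random_image(rng, shape)
        atlas = AtlasPair(img, labels)
        sig = fit_atlas_signature(img, labels, seed=0)
        cfg = FusionConfig(init_atlas=0)
        state = initialize([atlas], img, [DeformationField.identity(shape)], cfg)
        lik = compute_likelihood_cube(img, [sig], state.labels_all, cfg.channel_mask)
        state.selector = np.ones((1,) + shape)
        new, _ = update_parcellation(state, lik, cfg)
        np.testing.assert_array_equal(new.data, labels.data)

    def test_matches_bruteforce_fused_posterior(self, rng):
        # <= 10^3 voxels, 2 atlases, 3 labels: exhaustive per-voxel argmax
        shape = (10, 10, 10)
        subject = _random_image(rng, shape)
        atlases, fields, sigs = [], [], []
        for k in range(2):
            lab = np.zeros(shape, dtype=int)
            lab[2:7, 2:8, 2:8] = 1
            lab[5 + k:9, 3:7, 3:7] = 2
            pair = AtlasPair(_random_image(rng, shape), LabelMap(lab))
            atlases.append(pair)
            fields.append(_quantized_field(rng, shape, scale=1.0))
            sigs.append(fit_atlas_signature(pair.image, pair.labels, seed=k))
        cfg = FusionConfig()
        state = initialize(atlases, subject, fields, cfg)
        state.selector = np.stack([
            np.full(shape, 0.3), np.full(shape, 0.7)
        ])
        lik = compute_likelihood_cube(subject, sigs, state.labels_all, cfg.channel_mask)
        new, _ = update_parcellation(state, lik, cfg)

        from dtiparc.intensity import voxel_likelihood

        stacked = subject.stacked()
        expected = np.zeros(shape, dtype=int)
        for idx in np.ndindex(shape):
            pt = np.array([idx], dtype=float)
            best_lab, best_score = 0, -1.0
            for lab in state.labels_all:
                score = 0.0
                support = False
                for a in range(2):
                    p = interpolate_label_probability(
                        atlases[a].labels, fields[a].transform_points(pt), lab)[0]
                    if p > 0:
                        support = True
                    score += state.selector[a][idx] * voxel_likelihood(
                        stacked[(slice(None),) + idx], lab, sigs[a]) * p
                if support and score > best_score:
                    best_lab, best_score = lab, score
            expected[idx] = best_lab
        np.testing.assert_array_equal(new.data, expected)

    def test_vote_reduction_with_uninformative_models(self, rng):
        # identical intensity models + uniform selector -> the update equals
        # a trilinear-probability-weighted majority vote, exactly
        shape = (10, 10, 10)
        subject = _random_image(rng, shape)
        atlases, fields = [], []
        for k in range(2):
            lab = np.zeros(shape, dtype=int)
            lab[2:6 + k, 2:8, 2:8] = 1
            lab[6 + k:9, 2:6, 2:6] = 2
            atlases.append(AtlasPair(_random_image(rng, shape), LabelMap(lab)))
            fields.append(_quantized_field(rng, shape, scale=1.5))
        sigs = [_uniform_signature((0, 1, 2))] * 2
        cfg = FusionConfig()
        state = initialize(atlases, subject, fields, cfg)
        state.selector = np.full((2,) + shape, 0.5)
        lik = compute_likelihood_cube(subject, sigs, state.labels_all, cfg.channel_mask)
        new, _ = update_parcellation(state, lik, cfg)

        expected = np.zeros(shape, dtype=int)
        for idx in np.ndindex(shape):
            pt = np.array([idx], dtype=float)
            probs = []
            for lab in (0, 1, 2):
                probs.append(sum(
                    interpolate_label_probability(
                        atlases[a].labels, fields[a].transform_points(pt), lab)[0]
                    for a in range(2)
                ))
            expected[idx] = int(np.argmax(probs))  # first max = smallest label
        np.testing.assert_array_equal(new.data, expected)

    def test_tie_breaks_to_smallest_label(self):
        shape = (4, 4, 4)
        img = MultiContrastImage.from_arrays(
            np.full(shape, 0.5), np.full(shape, 1e-3),
            np.full(shape, 1.0), np.zeros(shape), np.zeros(shape),
        )
        # two atlases, labels 1 and 2 fully covering the grid
        a1 = AtlasPair(img, LabelMap(np.full(shape, 1)))
        a2 = AtlasPair(img, LabelMap(np.full(shape, 2)))
        sigs = [_uniform_signature((0, 1)), _uniform_signature((0, 2))]
        fields = [DeformationField.identity(shape)] * 2
        cfg = FusionConfig()
        state = initialize([a1, a2], img, fields, cfg)
        state.selector = np.full((2,) + shape, 0.5)
        lik = compute_likelihood_cube(img, sigs, state.labels_all, cfg.channel_mask)
        new, _ = update_parcellation(state, lik, cfg)
        assert np.all(new.data == 1)


class TestRun:
    def test_self_atlas_converges_first_iteration(self, tiny_truth):
        ident = DeformationField.identity(tiny_truth.labels.shape)
        sig = fit_atlas_signature(tiny_truth.image, tiny_truth.labels, seed=0)
        labels, state = run([tiny_truth], tiny_truth.image, [sig], [ident],
                            FusionConfig(init_atlas=0))
        assert state.iteration == 1
        assert state.history[0]["changed_fraction"] == 0.0
        np.testing.assert_array_equal(labels.data, tiny_truth.labels.data)

    def test_stop_tolerance_one_runs_single_iteration(self, tiny_library):
        lib = tiny_library
        fields = [DeformationField.identity(lib.subject.labels.shape)] * 2
        sigs = [fit_atlas_signature(a.image, a.labels, seed=i)
                for i, a in enumerate(lib.atlases)]
        _, state = run(lib.atlases, lib.subject.image, sigs, fields,
                       FusionConfig(stop_tolerance=1.0))
        assert state.iteration == 1

    def test_transforms_idempotent_at_optimum(self, rng):
        shape = (12, 12, 12)
        lab = np.zeros(shape, dtype=int)
        lab[3:9, 3:9, 3:9] = 1
        labels = LabelMap(lab)
        img = _random_image(rng, shape)
        atlas = AtlasPair(img, labels)
        cfg = FusionConfig(init_atlas=0)
        state = initialize([atlas], img, [DeformationField.identity(shape)], cfg)
        update_transforms(state, [atlas], [DeformationField.identity(shape)], cfg)
        assert state.affines[(0, 1)].is_identity

    def test_history_and_model_surface(self, tiny_library):
        lib = tiny_library
        model = MultiAtlasFusion(lib.subject.image, lib.atlases,
                                 config=FusionConfig(max_iterations=3))
        res = model.fit()
        assert res.n_iterations <= 3
        assert {"iteration", "changed_fraction", "objective"} <= set(res.history.columns)
        text = res.summary()
        assert "atlases" in text and "iterations" in text
        dv = res.dice_vs(lib.subject.labels)
        assert (dv["dice"] > 0.5).all()
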