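import numpy as np
import pytest

from neurocatmap import features as feat
from neurocatmap import synth
from neurocatmap._utils import pearson


@pytest.fixture(scope="module")
def cfg():
    return synth.GeneratorConfig(
        n_layers=6, units_per_layer=(20, 22, 24, 26, 28, 30), n_voxels=80,
        session_length=40, n_train_sessions=2, n_test_sessions=1,
        n_test_repeats=3, seed=9)


@pytest.fixture(scope="module")
def hier():
    return synth.CategoryHierarchySpec(categories_per_subgroup=2,
                                       exemplars_per_category_mean=8)


class TestGeneratorConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            synth.GeneratorConfig(n_layers=1, units_per_layer=(4,))
        with pytest.raises(ValueError):
            synth.GeneratorConfig(tr=0.0)
        with pytest.raises(ValueError):
            synth.GeneratorConfig(noise_sd=-1.0)
        with pytest.raises(ValueError):
            synth.GeneratorConfig(n_voxels=0)

    def test_band_assignment_covers_thirds(self):
        c = synth.GeneratorConfig()
        bands = [c.band_of(l) for l in range(1, 7)]
        assert bands == ["bottom", "bottom", "middle", "middle", "top", "top"]


class TestHierarchySpec:
    def test_default_structure(self):
        h = synth.CategoryHierarchySpec()
        assert set(h.superordinate_groups) == {
            "biological_objects", "nonbiological_objects", "background_scenes"}
        assert h.subgroups["biological_objects"] == [
            "terrestrial_animals", "aquatic_animals", "plants", "humans"]
        assert h.subgroups["background_scenes"] == ["artificial_scenes", "natural_scenes"]

    def test_within_must_dominate_between(self):
        with pytest.raises(ValueError):
            synth.CategoryHierarchySpec(
                within_block_corr={"bottom": 0.1, "middle": 0.2, "top": 0.2},
                between_block_corr={"bottom": 0.2, "middle": 0.1, "top": 0.1})

    def test_duplicate_subgroups_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            synth.CategoryHierarchySpec(
                superordinate_groups=("a", "b"),
                subgroups={"a": ["x"], "b": ["x"]})


class TestMakeLayeredFeatures:
    def test_shapes(self, hier):
        c = synth.GeneratorConfig(n_layers=2, units_per_layer=(4, 4),
                                  session_length=25, n_train_sessions=1,
                                  n_test_sessions=1, seed=0)
        s = synth.make_layered_features(c, hier)
        n_native = c.total_volumes * c.steps_per_tr
        assert [m.shape for m in s.layers] == [(n_native, 4), (n_native, 4)]
        assert all(np.all(np.isfinite(m)) for m in s.layers)

    def test_determinism(self, cfg, hier):
        a = synth.make_layered_features(cfg, hier)
        b = synth.make_layered_features(cfg, hier)
        for x, y in zip(a.layers, b.layers):
            np.testing.assert_array_equal(x, y)

    def test_within_block_correlation_exceeds_between(self, cfg):
        # empirical correlation oracle on the planted signatures in the top band
        hier = synth.CategoryHierarchySpec(
            categories_per_subgroup=3,
            within_block_corr={"bottom": 0.1, "middle": 0.3, "top": 0.8},
            between_block_corr={"bottom": 0.05, "middle": 0.2, "top": 0.1})
        sigs = synth.planted_signatures(cfg, hier)
        top_layer = cfg.n_layers  # top band
        cats = hier.category_labels
        vecs = {c: synth._category_signature(cfg, hier, sigs, top_layer, c)
                for c in cats}
        same, diff = [], []
        for i, a in enumerate(cats):
            for b in cats[i + 1:]:
                r = pearson(vecs[a], vecs[b])
                if hier.subgroup_of[a] == hier.subgroup_of[b]:
                    same.append(r)
                elif hier.group_of[a] != hier.group_of[b]:
                    diff.append(r)
        assert np.mean(same) > np.mean(diff)

    def test_planted_monotonicity(self, cfg):
        # raising within_block_corr strictly raises measured within-block corr
        measured = []
        for w in (0.2, 0.5, 0.8):
            hier = synth.CategoryHierarchySpec(
                categories_per_subgroup=3,
                within_block_corr={"bottom": w, "middle": w, "top": w},
                between_block_corr={"bottom": 0.1, "middle": 0.1, "top": 0.1})
            sigs = synth.planted_signatures(cfg, hier)
            cats = hier.category_labels
            vecs = {c: synth._category_signature(cfg, hier, sigs, 1, c) for c in cats}
            vals = [pearson(vecs[a], vecs[b])
                    for i, a in enumerate(cats) for b in cats[i + 1:]
                    if hier.subgroup_of[a] == hier.subgroup_of[b]]
            measured.append(np.mean(vals))
        assert measured[0] < measured[1] < measured[2]


class TestMakeVoxelPopulation:
    def test_preferred_layers_in_range(self, hier):
        c = synth.GeneratorConfig(n_layers=3, units_per_layer=(5, 5, 5),
                                  n_voxels=10, seed=1)
        truth = synth.make_voxel_population(c)
        assert set(truth.preferred_layer) <= {1, 2, 3}

    def test_zero_snr_profile_zeroes_weights(self, cfg):
        c = synth.GeneratorConfig(**{**cfg.__dict__, "snr_profile": (0.0,) * 6})
        truth = synth.make_voxel_population(c)
        np.testing.assert_array_equal(truth.weights, 0.0)

    def test_high_concentration_mass_fraction(self, cfg):
        c = synth.GeneratorConfig(**{**cfg.__dict__, "n_voxels": 200,
                                     "weight_concentration": 0.99})
        truth = synth.make_voxel_population(c)
        for v in range(truth.n_voxels):
            sl = truth.layer_slice(truth.preferred_layer[v])
            frac = (truth.weights[v, sl]**2).sum() / (truth.weights[v]**2).sum()
            assert frac > 0.9

    def test_determinism(self, cfg):
        a = synth.make_voxel_population(cfg)
        b = synth.make_voxel_population(cfg)
        np.testing.assert_array_equal(a.weights, b.weights)


class TestSimulateResponses:
    def test_zero_noise_repeats_identical(self, hier):
        c = synth.GeneratorConfig(n_layers=2, units_per_layer=(6, 6), n_voxels=5,
                                  session_length=30, n_train_sessions=1,
                                  n_test_sessions=1, n_test_repeats=2,
                                  noise_sd=0.0, seed=2)
        movie = synth.make_layered_features(c, hier)
        truth = synth.make_voxel_population(c)
        kernel = feat.hrf_kernel(c.time_step)
        _, test = synth.simulate_responses(movie, truth, kernel, c)
        np.testing.assert_array_equal(test.repeats[0], test.repeats[1])

    def test_zero_weights_gives_pure_noise_variance(self, hier):
        c = synth.GeneratorConfig(n_layers=2, units_per_layer=(6, 6), n_voxels=4,
                                  session_length=500, n_train_sessions=2,
                                  n_test_sessions=1, noise_sd=1.0, seed=3,
                                  snr_profile=(0.0, 0.0))
        movie = synth.make_layered_features(c, hier)
        truth = synth.make_voxel_population(c)
        kernel = feat.hrf_kernel(c.time_step)
        train, _ = synth.simulate_responses(movie, truth, kernel, c)
        n = train.values.shape[1]
        assert n >= 1000
        for v in range(truth.n_voxels):
            sample_var = train.values[v].var(ddof=1)
            se = truth.noise_variance[v] * np.sqrt(2.0 / (n - 1))
            assert abs(sample_var - truth.noise_variance[v]) < 3 * se

    def test_noise_halves_correlation_per_ceiling_formula(self, hier):
        # closed-form limit: corr(signal, signal + noise) = s / sqrt(s^2 + n^2)
        base = synth.GeneratorConfig(n_layers=2, units_per_layer=(6, 6), n_voxels=3,
                                     session_length=1000, n_train_sessions=2,
                                     n_test_sessions=1, seed=4)
        kernel = feat.hrf_kernel(base.time_step)
        movie = synth.make_layered_features(base, hier)
        truth = synth.make_voxel_population(base)
        for v in range(truth.n_voxels):
            truth.noise_variance[v] = 1.0
        prepared, _ = feat.prepare_series(movie, kernel, base.tr)
        signal = np.concatenate(prepared.layers, axis=1) @ truth.weights.T
        t_train = base.n_train_sessions * base.session_length
        for scale in (1.0, 2.0):
            cfg_s = synth.GeneratorConfig(**{**base.__dict__})
            truth_s = synth.GroundTruthVoxels(
                weights=truth.weights, preferred_layer=truth.preferred_layer,
                noise_variance=truth.noise_variance * scale**2,
                units_per_layer=truth.units_per_layer)
            train, _ = synth.simulate_responses(movie, truth_s, kernel, cfg_s)
            for v in range(truth.n_voxels):
                s_sd = signal[:t_train, v].std()
                expected = s_sd / np.sqrt(s_sd**2 + scale**2)
                got = np.corrcoef(signal[:t_train, v], train.values[v])[0, 1]
                assert got == pytest.approx(expected, abs=0.05)

    def test_mismatched_layout_rejected(self, cfg, hier):
        movie = synth.make_layered_features(cfg, hier)
        bad = synth.GeneratorConfig(n_layers=2, units_per_layer=(6, 6), n_voxels=5)
        truth = synth.make_voxel_population(bad)
        with pytest.raises(ValueError):
            synth.simulate_responses(movie, truth, feat.hrf_kernel(cfg.time_step), cfg)

    def test_session_structure(self, cfg, hier):
        movie = synth.make_layered_features(cfg, hier)
        truth = synth.make_voxel_population(cfg)
        train, test = synth.simulate_responses(movie, truth,
                                               feat.hrf_kernel(cfg.time_step), cfg)
        assert len(np.unique(train.sessions)) == cfg.n_train_sessions
        assert len(np.unique(test.sessions)) == cfg.n_test_sessions
        assert test.repeats.shape[0] == cfg.n_test_repeats


class TestMakeCategoryExemplars:
    def test_fixed_count_total_is_exact(self):
        # 80 categories x exactly 800 exemplars = 64,000
        h = synth.CategoryHierarchySpec(categories_per_subgroup=10,
                                        exemplars_per_category_mean=800)
        assert len(h.category_labels) == 80
        c = synth.GeneratorConfig(n_layers=2, units_per_layer=(3, 3), seed=0)
        atlas = synth.make_category_exemplars(h, c, fixed_count=800)
        assert sum(atlas.exemplar_counts.values()) == 64_000

    def test_poisson_counts_near_mean(self, cfg):
        h = synth.CategoryHierarchySpec(categories_per_subgroup=4,
                                        exemplars_per_category_mean=20)
        atlas = synth.make_category_exemplars(h, cfg)
        counts = np.array(list(atlas.exemplar_counts.values()))
        total = sum(atlas.exemplar_counts.values())
        assert total == sum(s.n_rows for s in atlas.exemplar_features.values())
        assert abs(counts.mean() - 20) < 3 * np.sqrt(20 / len(counts))

    def test_zero_noise_exemplars_identical(self, cfg):
        h = synth.CategoryHierarchySpec(categories_per_subgroup=2,
                                        exemplars_per_category_mean=5,
                                        exemplar_noise=0.0)
        atlas = synth.make_category_exemplars(h, cfg)
        s = atlas.exemplar_features[atlas.categories[0]]
        for m in s.layers:
            assert np.ptp(m, axis=0).max() == 0.0

    def test_signature_correlations_follow_hierarchy(self, cfg, hier):
        atlas = synth.make_category_exemplars(hier, cfg)
        means = {c: np.concatenate([m.mean(axis=0) for m in
                                    atlas.exemplar_features[c].layers])
                 for c in atlas.categories}
        same_sub, cross_group = [], []
        cats = atlas.categories
        for i, a in enumerate(cats):
            for b in cats[i + 1:]:
                r = pearson(means[a], means[b])
                if hier.subgroup_of[a] == hier.subgroup_of[b]:
                    same_sub.append(r)
                elif hier.group_of[a] != hier.group_of[b]:
                    cross_group.append(r)
        assert np.mean(same_sub) > np.mean(cross_group)

    def test_determinism(self, cfg, hier):
        a = synth.make_category_exemplars(hier, cfg)
        b = synth.make_category_exemplars(hier, cfg)
        for c in a.categories:
            for x, y in zip(a.exemplar_features[c].layers,
                            b.exemplar_features[c].layers):
                np.testing.assert_array_equal(x, y)


class TestTaxonomyAndVectors:
    def test_toy_taxonomy_depth_three(self, hier):
        tax = synth.make_toy_taxonomy(hier)
        assert tax.depth == 3
        assert all(c in tax.nodes for c in hier.category_labels)

    def test_path_lengths_follow_hierarchy(self, hier):
        import networkx as nx

        tax = synth.make_toy_taxonomy(hier)
        cats = hier.category_labels
        a, b = cats[0], cats[1]  # same subgroup
        far = next(c for c in cats if hier.group_of[c] != hier.group_of[a])
        g = tax.undirected
        assert nx.shortest_path_length(g, a, b) < nx.shortest_path_length(g, a, far)

    def test_vectors_cosine_follows_hierarchy(self, hier):
        vecs = synth.make_label_vectors(hier.category_labels, hier, dim=64, seed=3)

        def cos(a, b):
            return float(vecs[a] @ vecs[b] /
                         (np.linalg.norm(vecs[a]) * np.linalg.norm(vecs[b])))

        cats = hier.category_labels
        same, cross = [], []
        for i, a in enumerate(cats):
            for b in cats[i + 1:]:
                if hier.subgroup_of[a] == hier.subgroup_of[b]:
                    same.append(cos(a, b))
                elif hier.group_of[a] != hier.group_of[b]:
                    cross.append(cos(a, b))
        assert np.mean(same) > np.mean(cross)

    def test_duplicate_labels_rejected(self, hier):
        with pytest.raises(ValueError, match="duplicate"):
            synth.make_label_vectors(["a", "a"], hier)


class TestTunedVoxels:
    def test_kinds_validated(self, cfg, hier):
        with pytest.raises(ValueError):
            synth.make_tuned_voxels(cfg, hier, [("category", "x")], 2)

    def test_concat_voxels(self, cfg, hier):
        a = synth.make_voxel_population(cfg)
        b = synth.make_tuned_voxels(cfg, hier, [("group", "biological_objects")], 3)
        both = synth.concat_voxels(a, b)
        assert both.n_voxels == a.n_voxels + 3
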