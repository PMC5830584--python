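"""Shared synthetic scenarios used by unit and acceptance tests.

Each builder runs the generator + feature pipeline + encoding fit once for a
given configuration and returns the intermediate artifacts in a dict.
"""
from __future__ import annotations

import numpy as np

from neurocatmap import catmap as cm
from neurocatmap import cluster as cl
from neurocatmap import encoding as enc
from neurocatmap import features as feat
from neurocatmap import synth


def split_movie(movie, config):
    tn = config.n_train_sessions * config.session_length * config.steps_per_tr
    train = feat.LayeredFeatureSeries([m[:tn] for m in movie.layers], movie.time_step)
    test = feat.LayeredFeatureSeries([m[tn:] for m in movie.layers], movie.time_step)
    return train, test


def build_world(config, hierarchy, truth=None, fit_model=True, exemplars=True):
    kernel = feat.hrf_kernel(config.time_step)
    movie = synth.make_layered_features(config, hierarchy)
    if truth is None:
        truth = synth.make_voxel_population(config)
    sim_cfg = config if truth.n_voxels == config.n_voxels else synth.GeneratorConfig(
        **{**config.__dict__, "n_voxels": truth.n_voxels})
    train_raw, test_raw = synth.simulate_responses(movie, truth, kernel, sim_cfg)
    train_feats, test_feats = split_movie(movie, config)
    prep_train, std = feat.prepare_series(train_feats, kernel, config.tr)
    prep_test, _ = feat.prepare_series(test_feats, kernel, config.tr, standardizers=std)
    bases = feat.fit_pca(prep_train, 0.99, standardizers=std)
    world = dict(config=config, hierarchy=hierarchy, kernel=kernel, movie=movie,
                 truth=truth, train_raw=train_raw, test_raw=test_raw,
                 prep_train=prep_train, prep_test=prep_test, standardizers=std,
                 bases=bases,
                 design_train=feat.transform(prep_train, bases),
                 design_test=feat.transform(prep_test, bases))
    if fit_model:
        world["train"] = enc.preprocess_responses(train_raw)
        world["test"] = enc.preprocess_responses(test_raw)
        world["model"] = enc.fit_ridge(world["design_train"], world["train"])
    if exemplars and fit_model:
        atlas = synth.make_category_exemplars(hierarchy, config)
        world["atlas"] = cm.build_maps(world["model"], bases, atlas, std)
        world["exemplar_resp"] = cm.exemplar_responses(world["model"], bases,
                                                       world["atlas"], std)
    return world


def coarse_recovery_scenario(seed=7, n_voxels=500):
    """Random layer-concentrated voxels; planted 3-group coarse structure."""
    config = synth.GeneratorConfig(n_voxels=n_voxels, seed=seed)
    hierarchy = synth.CategoryHierarchySpec()
    return build_world(config, hierarchy)


FINE_HIERARCHY_KW = dict(
    categories_per_subgroup=6,
    exemplars_per_category_mean=60,
    within_block_corr={"bottom": 0.10, "middle": 0.55, "top": 0.85},
    between_block_corr={"bottom": 0.05, "middle": 0.50, "top": 0.05},
)


def fine_recovery_scenario(seed=7, n_rand=300, n_tuned=40):
    """Random voxels plus voxels tuned to the 4 biological subgroups; used
    for cluster-specific-region and sub-clustering recovery."""
    config = synth.GeneratorConfig(n_voxels=n_rand, seed=seed)
    hierarchy = synth.CategoryHierarchySpec(**FINE_HIERARCHY_KW)
    rand_vox = synth.make_voxel_population(config)
    subs = [("subgroup", s) for s in hierarchy.subgroups["biological_objects"]]
    tuned = synth.make_tuned_voxels(config, hierarchy, subs, n_per_target=n_tuned,
                                    gain=4.0, group_mix=0.4, jitter=1.0, seed=seed)
    truth = synth.concat_voxels(rand_vox, tuned)
    world = build_world(config, hierarchy, truth=truth)
    world["tuned_mask"] = np.arange(truth.n_voxels) >= n_rand
    return world


def fine_region_and_subclusters(world, n_random_exemplars=2000, seed=1):
    """Region t-test + sub-clustering for the planted biological cluster."""
    config, hierarchy = world["config"], world["hierarchy"]
    atlas = world["atlas"]
    members = [c for c in atlas.categories
               if hierarchy.group_of[c] == "biological_objects"]
    cluster_resp = np.concatenate([world["exemplar_resp"][c] for c in members])
    rnd = synth.make_random_exemplars(config, n_random_exemplars, seed=config.seed + 99)
    rnd_std = feat.standardize_static(rnd, world["standardizers"])
    rnd_resp = feat.transform(rnd_std, world["bases"]).matrix @ world["model"].weights.T
    region = cl.cluster_specific_region(cluster_resp, rnd_resp, alpha=0.01)
    idx = [atlas.categories.index(c) for c in members]
    result = cl.subcluster(atlas.maps, region, idx, atlas.categories,
                           k_range=range(2, 9), n_restarts=30, seed=seed)
    subs_truth = [hierarchy.subgroup_of[atlas.categories[i]] for i in idx]
    return dict(region=region, random_responses=rnd_resp, members=members,
                result=result, subgroup_truth=subs_truth)


LAYER_HIERARCHY_KW = dict(
    categories_per_subgroup=2,
    within_block_corr={"bottom": 0.0, "middle": 0.6, "top": 0.0},
    between_block_corr={"bottom": 0.0, "middle": 0.6, "top": 0.0},
)


def middle_band_only_scenario(seed, n_voxels=300):
    """Category structure planted only in the middle layer band."""
    config = synth.GeneratorConfig(n_voxels=n_voxels, seed=seed)
    hierarchy = synth.CategoryHierarchySpec(**LAYER_HIERARCHY_KW)
    return build_world(config, hierarchy)


def planted_group_labels(world):
    hierarchy, atlas = world["hierarchy"], world["atlas"]
    groups = sorted(set(hierarchy.group_of.values()))
    return np.array([groups.index(hierarchy.group_of[c]) + 1
                     for c in atlas.categories])
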