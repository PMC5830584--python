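"""Synthetic data generation: layered feature dynamics with a planted
category hierarchy, ground-truth voxel populations, noisy session-structured
responses, category exemplar sets, a toy is-a taxonomy, and label vectors.

The planted structure is controlled per layer band (bottom / middle / top
thirds of the layer stack): within each band, ``between_block_corr`` sets the
expected feature correlation of categories sharing a superordinate group and
``within_block_corr`` the correlation of categories sharing a subgroup. The
defaults put superordinate structure in the middle band and subgroup
structure in the top band, so recovery tests have known truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import features as feat
from ._utils import rng_from
from .semantics import Taxonomy

__all__ = [
    "GeneratorConfig",
    "CategoryHierarchySpec",
    "GroundTruthVoxels",
    "planted_signatures",
    "make_layered_features",
    "make_voxel_population",
    "make_tuned_voxels",
    "concat_voxels",
    "simulate_responses",
    "make_category_exemplars",
    "make_random_exemplars",
    "make_toy_taxonomy",
    "make_label_vectors",
]

BANDS = ("bottom", "middle", "top")

_DEFAULT_GROUPS = {
    "biological_objects": ["terrestrial_animals", "aquatic_animals", "plants", "humans"],
    "nonbiological_objects": ["tools", "vehicles"],
    "background_scenes": ["artificial_scenes", "natural_scenes"],
}
_DEFAULT_WITHIN = {"bottom": 0.10, "middle": 0.55, "top": 0.75}
_DEFAULT_BETWEEN = {"bottom": 0.05, "middle": 0.50, "top": 0.15}


@dataclass
class GeneratorConfig:
    """Sizes, timing and noise scales for the synthetic world."""

    n_layers: int = 6
    units_per_layer: tuple = (40, 44, 48, 52, 56, 60)
    n_voxels: int = 500
    tr: float = 2.0
    time_step: float = 1.0  # native feature sampling step, seconds
    session_length: int = 240  # volumes per session (8 min at TR = 2 s)
    n_train_sessions: int = 4
    n_test_sessions: int = 1
    n_test_repeats: int = 4
    noise_sd: float = 1.0
    snr_profile: tuple | None = None  # per-layer weight scale, default all ones
    weight_concentration: float = 0.95
    feature_noise_sd: float = 1.0
    segment_steps: int = 8  # native steps per category segment of the "movie"
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 2:
            raise ValueError("need at least two layers")
        self.units_per_layer = tuple(int(p) for p in self.units_per_layer)
        if len(self.units_per_layer) != self.n_layers:
            raise ValueError("units_per_layer length must equal n_layers")
        if any(p < 1 for p in self.units_per_layer):
            raise ValueError("all unit counts must be >= 1")
        for name in ("n_voxels", "session_length", "n_train_sessions", "n_test_sessions",
                     "n_test_repeats", "segment_steps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.tr <= 0 or self.time_step <= 0:
            raise ValueError("tr and time_step must be positive")
        if self.noise_sd < 0 or self.feature_noise_sd < 0:
            raise ValueError("noise scales must be non-negative")
        if not (0.0 < self.weight_concentration <= 1.0):
            raise ValueError("weight_concentration must be in (0, 1]")
        if self.snr_profile is None:
            self.snr_profile = (1.0,) * self.n_layers
        self.snr_profile = tuple(float(s) for s in self.snr_profile)
        if len(self.snr_profile) != self.n_layers:
            raise ValueError("snr_profile length must equal n_layers")

    @property
    def n_sessions(self) -> int:
        return self.n_train_sessions + self.n_test_sessions

    @property
    def total_volumes(self) -> int:
        return self.n_sessions * self.session_length

    @property
    def steps_per_tr(self) -> int:
        ratio = self.tr / self.time_step
        n = int(round(ratio))
        if abs(ratio - n) > 1e-9:
            raise ValueError("time_step must divide tr")
        return n

    def band_of(self, layer: int) -> str:
        """Band of a 1-based layer index: bottom/middle/top thirds."""
        if not (1 <= layer <= self.n_layers):
            raise ValueError("layer out of range")
        third = self.n_layers / 3.0
        if layer <= third:
            return "bottom"
        if layer <= 2 * third:
            return "middle"
        return "top"


@dataclass
class CategoryHierarchySpec:
    """Planted superordinate -> subgroup -> category hierarchy."""

    superordinate_groups: tuple = tuple(_DEFAULT_GROUPS)
    subgroups: dict = field(default_factory=lambda: {g: list(s) for g, s in _DEFAULT_GROUPS.items()})
    categories_per_subgroup: int = 4
    exemplars_per_category_mean: int = 40
    exemplar_noise: float = 1.0
    within_block_corr: dict = field(default_factory=lambda: dict(_DEFAULT_WITHIN))
    between_block_corr: dict = field(default_factory=lambda: dict(_DEFAULT_BETWEEN))

    def __post_init__(self):
        self.superordinate_groups = tuple(self.superordinate_groups)
        if len(set(self.superordinate_groups)) != len(self.superordinate_groups):
            raise ValueError("superordinate group names must be unique")
        all_subs = [s for g in self.superordinate_groups for s in self.subgroups[g]]
        if len(set(all_subs)) != len(all_subs):
            raise ValueError("subgroup names must be unique")
        if self.categories_per_subgroup < 1 or self.exemplars_per_category_mean < 1:
            raise ValueError("counts must be >= 1")
        if self.exemplar_noise < 0:
            raise ValueError("exemplar_noise must be non-negative")
        for band in BANDS:
            w = self.within_block_corr[band]
            b = self.between_block_corr[band]
            if not (-1.0 <= b <= w <= 1.0):
                raise ValueError(f"band {band!r}: need -1 <= between <= within <= 1")
            if w > 1.0:
                raise ValueError("correlations cannot exceed 1")

    @property
    def subgroup_list(self) -> list:
        return [s for g in self.superordinate_groups for s in self.subgroups[g]]

    @property
    def category_labels(self) -> list:
        return [f"{s}_{i + 1:02d}" for s in self.subgroup_list
                for i in range(self.categories_per_subgroup)]

    @property
    def subgroup_of(self) -> dict:
        return {c: "_".join(c.split("_")[:-1]) for c in self.category_labels}

    @property
    def group_of_subgroup(self) -> dict:
        return {s: g for g in self.superordinate_groups for s in self.subgroups[g]}

    @property
    def group_of(self) -> dict:
        gos = self.group_of_subgroup
        return {c: gos[s] for c, s in self.subgroup_of.items()}

    def mixing(self, band: str) -> tuple:
        """(alpha, beta, gamma) amplitudes for group / subgroup / category
        components so pairwise correlations hit the planted levels."""
        w = float(self.within_block_corr[band])
        b = float(self.between_block_corr[band])
        b = max(b, 0.0)
        w = max(w, b)
        return np.sqrt(b), np.sqrt(w - b), np.sqrt(max(1.0 - w, 0.0))


@dataclass
class GroundTruthVoxels:
    """Generative voxel weights over the concatenated (standardized) units."""

    weights: np.ndarray  # (n_voxels, sum p_l)
    preferred_layer: np.ndarray  # 1-based, (n_voxels,)
    noise_variance: np.ndarray  # (n_voxels,)
    units_per_layer: tuple

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.preferred_layer = np.asarray(self.preferred_layer, dtype=int)
        self.noise_variance = np.asarray(self.noise_variance, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        n_layers = len(self.units_per_layer)
        if np.any(self.preferred_layer < 1) or np.any(self.preferred_layer > n_layers):
            raise ValueError("preferred_layer out of range")
        if self.weights.shape[1] != sum(self.units_per_layer):
            raise ValueError("weight columns must cover all units")
        if np.any(self.noise_variance < 0):
            raise ValueError("noise_variance must be non-negative")

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[0]

    def layer_slice(self, layer: int) -> slice:
        offs = np.concatenate([[0], np.cumsum(self.units_per_layer)])
        return slice(int(offs[layer - 1]), int(offs[layer]))


def planted_signatures(config: GeneratorConfig, hierarchy: CategoryHierarchySpec) -> dict:
    """Per-layer latent direction vectors for groups, subgroups and categories.

    Deterministic in ``config.seed`` so the movie features and the exemplar
    sets share the same planted category signatures.
    """
    rng = rng_from(config.seed, 0x516)
    sigs = {"group": [], "subgroup": [], "category": []}
    for p in config.units_per_layer:
        sigs["group"].append({g: rng.standard_normal(p) for g in hierarchy.superordinate_groups})
        sigs["subgroup"].append({s: rng.standard_normal(p) for s in hierarchy.subgroup_list})
        sigs["category"].append({c: rng.standard_normal(p) for c in hierarchy.category_labels})
    return sigs


def _category_signature(config, hierarchy, sigs, layer: int, category: str) -> np.ndarray:
    """Planted mean feature vector of a category in one layer (unit variance)."""
    band = config.band_of(layer)
    alpha, beta, gamma = hierarchy.mixing(band)
    sub = hierarchy.subgroup_of[category]
    grp = hierarchy.group_of[category]
    li = layer - 1
    return (alpha * sigs["group"][li][grp]
            + beta * sigs["subgroup"][li][sub]
            + gamma * sigs["category"][li][category])


def make_layered_features(config: GeneratorConfig, hierarchy: CategoryHierarchySpec) -> feat.LayeredFeatureSeries:
    """Native-resolution unit activations for the synthetic "movie".

    Time is split into segments of ``segment_steps`` native samples; each
    segment shows a random category, injecting that category's planted
    signature into every layer plus i.i.d. unit noise.
    """
    sigs = planted_signatures(config, hierarchy)
    rng = rng_from(config.seed, 0xFEA7)
    n_native = config.total_volumes * config.steps_per_tr
    n_seg = int(np.ceil(n_native / config.segment_steps))
    labels = hierarchy.category_labels
    seg_cats = rng.integers(0, len(labels), size=n_seg)
    cat_of_t = np.repeat(seg_cats, config.segment_steps)[:n_native]
    layers = []
    for l in range(1, config.n_layers + 1):
        p = config.units_per_layer[l - 1]
        sig_table = np.stack([_category_signature(config, hierarchy, sigs, l, c) for c in labels])
        x = sig_table[cat_of_t] + config.feature_noise_sd * rng.standard_normal((n_native, p))
        layers.append(x)
    return feat.LayeredFeatureSeries(layers, time_step=config.time_step)


def make_voxel_population(config: GeneratorConfig, seed: int | None = None) -> GroundTruthVoxels:
    """Random voxels whose true weights concentrate on one preferred layer.

    A fraction ``weight_concentration`` of each voxel's expected squared
    weight mass lies on its preferred layer; the whole vector is scaled by
    ``snr_profile[preferred layer]``. Noise variances are uniform on
    [0.5, 1.5] x noise_sd^2.
    """
    rng = rng_from(config.seed if seed is None else seed, 0x0BE1)
    n_units = sum(config.units_per_layer)
    offs = np.concatenate([[0], np.cumsum(config.units_per_layer)])
    pref = rng.integers(1, config.n_layers + 1, size=config.n_voxels)
    w = rng.standard_normal((config.n_voxels, n_units))
    kappa = config.weight_concentration
    for v in range(config.n_voxels):
        l = pref[v]
        p_pref = config.units_per_layer[l - 1]
        scale = np.full(n_units, np.sqrt((1.0 - kappa) / max(n_units - p_pref, 1)))
        scale[offs[l - 1]: offs[l]] = np.sqrt(kappa / p_pref)
        w[v] *= scale * config.snr_profile[l - 1]
    noise_var = config.noise_sd**2 * rng.uniform(0.5, 1.5, size=config.n_voxels)
    return GroundTruthVoxels(weights=w, preferred_layer=pref, noise_variance=noise_var,
                             units_per_layer=config.units_per_layer)


def make_tuned_voxels(
    config: GeneratorConfig,
    hierarchy: CategoryHierarchySpec,
    targets: list,
    n_per_target: int,
    gain: float = 1.0,
    noise_sd: float | None = None,
    group_mix: float = 1.0,
    jitter: float = 0.0,
    seed: int = 0,
) -> GroundTruthVoxels:
    """Voxels whose weights align with a planted group/subgroup signature.

    ``targets`` is a list of ``("group", name)`` or ``("subgroup", name)``
    pairs. Each target contributes ``n_per_target`` voxels whose weights in
    layer l equal the target's latent direction scaled by that band's planted
    amplitude (alpha for groups, beta for subgroups), so the tuning lives in
    the layers where the corresponding structure is planted. Subgroup-tuned
    voxels also carry the parent group's component — they behave like an
    idealized member of the subgroup, responding to the whole superordinate
    group and maximally to their own subgroup.
    """
    sigs = planted_signatures(config, hierarchy)
    gos = hierarchy.group_of_subgroup
    rng = rng_from(seed, 0x7D4E)
    rows, pref = [], []
    for kind, name in targets:
        if kind not in ("group", "subgroup"):
            raise ValueError("target kind must be 'group' or 'subgroup'")
        parts, band_amp = [], []
        for l in range(1, config.n_layers + 1):
            alpha, beta, _ = hierarchy.mixing(config.band_of(l))
            if kind == "group":
                amp = alpha
                vec = alpha * sigs["group"][l - 1][name]
            else:
                amp = beta
                vec = (group_mix * alpha * sigs["group"][l - 1][gos[name]]
                       + beta * sigs["subgroup"][l - 1][name])
            parts.append(vec / np.sqrt(len(vec)))
            band_amp.append(amp)
        w = gain * np.concatenate(parts)
        best_layer = int(np.argmax(band_amp)) + 1
        wnorm = np.linalg.norm(w)
        for _ in range(n_per_target):
            vox = w
            if jitter > 0:
                noise = rng.standard_normal(w.size)
                vox = w + jitter * wnorm * noise / np.linalg.norm(noise)
            rows.append(vox)
            pref.append(best_layer)
    weights = np.stack(rows)
    nv = (config.noise_sd if noise_sd is None else noise_sd) ** 2
    return GroundTruthVoxels(weights=weights, preferred_layer=np.array(pref),
                             noise_variance=np.full(len(rows), nv),
                             units_per_layer=config.units_per_layer)


def concat_voxels(*populations: GroundTruthVoxels) -> GroundTruthVoxels:
    upl = populations[0].units_per_layer
    if any(p.units_per_layer != upl for p in populations):
        raise ValueError("unit layouts differ")
    return GroundTruthVoxels(
        weights=np.concatenate([p.weights for p in populations]),
        preferred_layer=np.concatenate([p.preferred_layer for p in populations]),
        noise_variance=np.concatenate([p.noise_variance for p in populations]),
        units_per_layer=upl,
    )


def simulate_responses(
    features: feat.LayeredFeatureSeries,
    truth: GroundTruthVoxels,
    kernel: feat.Kernel,
    config: GeneratorConfig,
):
    """HRF-convolved linear readout of the features plus per-repeat Gaussian
    noise, split into training and test portions with session structure.

    Returns ``(train, test)`` :class:`~neurocatmap.encoding.VoxelResponses`;
    the test portion carries ``n_test_repeats`` noisy repeats (its ``values``
    are the raw repeat mean).
    """
    from .encoding import VoxelResponses

    if features.units_per_layer != tuple(truth.units_per_layer):
        raise ValueError("feature unit layout does not match the voxel population")
    prepared, _ = feat.prepare_series(features, kernel, config.tr)
    if prepared.n_rows != config.total_volumes:
        raise ValueError(
            f"feature series yields {prepared.n_rows} volumes, expected {config.total_volumes}"
        )
    z = np.concatenate(prepared.layers, axis=1)  # (T, sum p_l)
    signal = z @ truth.weights.T  # (T, V)
    sd = np.sqrt(truth.noise_variance)  # (V,)
    rng = rng_from(config.seed, 0x5E55)
    sessions = np.repeat(np.arange(config.n_sessions), config.session_length)
    t_train = config.n_train_sessions * config.session_length
    sig_train, sig_test = signal[:t_train], signal[t_train:]
    train_vals = sig_train + rng.standard_normal(sig_train.shape) * sd
    reps = np.stack([
        sig_test + rng.standard_normal(sig_test.shape) * sd
        for _ in range(config.n_test_repeats)
    ])  # (R, T_test, V)
    reps = np.transpose(reps, (0, 2, 1))  # (R, V, T_test)
    train = VoxelResponses(values=train_vals.T, sessions=sessions[:t_train], tr=config.tr)
    test = VoxelResponses(values=reps.mean(axis=0), sessions=sessions[t_train:],
                          tr=config.tr, repeats=reps)
    return train, test


def make_category_exemplars(
    hierarchy: CategoryHierarchySpec,
    config: GeneratorConfig,
    seed: int | None = None,
    fixed_count: int | None = None,
):
    """Static layered feature vectors per category: planted signature plus
    i.i.d. exemplar noise. Counts are Poisson around the configured mean
    (floored at 2), or exactly ``fixed_count`` when given."""
    from .catmap import CategoryAtlas

    labels = hierarchy.category_labels
    if not labels:
        raise ValueError("hierarchy defines no categories")
    sigs = planted_signatures(config, hierarchy)
    rng = rng_from(config.seed if seed is None else seed, 0xE8E3)
    exemplar_features, counts = {}, {}
    for c in labels:
        n_ex = fixed_count if fixed_count is not None else max(
            2, int(rng.poisson(hierarchy.exemplars_per_category_mean)))
        layers = []
        for l in range(1, config.n_layers + 1):
            sig = _category_signature(config, hierarchy, sigs, l, c)
            layers.append(sig[None, :] + hierarchy.exemplar_noise
                          * rng.standard_normal((n_ex, len(sig))))
        exemplar_features[c] = feat.LayeredFeatureSeries(layers, time_step=None)
        counts[c] = n_ex
    return CategoryAtlas(categories=labels, exemplar_features=exemplar_features,
                         exemplar_counts=counts)


def make_random_exemplars(config: GeneratorConfig, n: int, seed: int = 0) -> feat.LayeredFeatureSeries:
    """Unstructured ("random and non-selective") exemplar feature vectors."""
    if n < 1:
        raise ValueError("need at least one exemplar")
    rng = rng_from(seed, 0xAD0)
    return feat.LayeredFeatureSeries(
        [rng.standard_normal((n, p)) for p in config.units_per_layer], time_step=None)


def make_toy_taxonomy(hierarchy: CategoryHierarchySpec) -> Taxonomy:
    """is-a taxonomy mirroring the planted hierarchy:
    category -> subgroup -> superordinate group -> root (depth 3)."""
    nodes = {"root"}
    edges = []
    for g in hierarchy.superordinate_groups:
        nodes.add(g)
        edges.append((g, "root"))
        for s in hierarchy.subgroups[g]:
            nodes.add(s)
            edges.append((s, g))
    for c in hierarchy.category_labels:
        if c in nodes:
            raise ValueError(f"duplicate label {c!r}")
        nodes.add(c)
        edges.append((c, hierarchy.subgroup_of[c]))
    return Taxonomy(nodes=nodes, edges=edges, root="root")


def make_label_vectors(labels: list, hierarchy: CategoryHierarchySpec, dim: int = 50,
                       seed: int = 0) -> dict:
    """Label vectors as group centroid + subgroup centroid + category noise,
    so cosine similarity mirrors the planted hierarchy."""
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    rng = rng_from(seed, 0x7EC)
    g_vec = {g: rng.standard_normal(dim) for g in hierarchy.superordinate_groups}
    s_vec = {s: rng.standard_normal(dim) for s in hierarchy.subgroup_list}
    out = {}
    for c in labels:
        if c not in hierarchy.subgroup_of:
            raise KeyError(f"label {c!r} not in hierarchy")
        sub = hierarchy.subgroup_of[c]
        grp = hierarchy.group_of[c]
        out[c] = 1.5 * g_vec[grp] + 1.0 * s_vec[sub] + 0.7 * rng.standard_normal(dim)
    return out
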