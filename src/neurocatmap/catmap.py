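"""Model-synthesized category representations and category selectivity.

A category's cortical map is the mean model-predicted response over its
exemplars. Selectivity of a voxel to category i against the pooled exemplars
of all other categories is
d'_i = (mean_i - mean_ic) / sqrt((var_i + var_ic) / 2),
and the voxel's overall selectivity is max_i d'_i.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import features as feat
from .encoding import EncodingModel

__all__ = [
    "CategoryAtlas",
    "SelectivityProfile",
    "category_map",
    "build_maps",
    "exemplar_responses",
    "dprime",
    "selectivity_profile",
    "roi_selectivity",
]


@dataclass
class CategoryAtlas:
    """Per-category exemplar features and model-synthesized voxel maps."""

    categories: list
    exemplar_features: dict  # label -> LayeredFeatureSeries (static rows)
    exemplar_counts: dict
    maps: np.ndarray | None = None  # (n_categories, n_voxels)

    def __post_init__(self):
        if self.maps is not None:
            self.maps = np.asarray(self.maps, dtype=float)
            if self.maps.shape[0] != len(self.categories):
                raise ValueError("maps must have one row per category")
            if not np.all(np.isfinite(self.maps)):
                raise ValueError("maps must be finite")


@dataclass
class SelectivityProfile:
    dprime_by_category: np.ndarray  # (n_voxels, n_categories)
    categories: list
    zero_variance: np.ndarray  # flags where pooled variance was zero

    @property
    def selectivity(self) -> np.ndarray:
        return self.dprime_by_category.max(axis=1)

    @property
    def top_categories(self) -> list:
        """Per-voxel labels ranked by d', descending (ties alphabetical)."""
        order = []
        cats = np.array(self.categories)
        for row in self.dprime_by_category:
            idx = sorted(range(len(cats)), key=lambda i: (-row[i], cats[i]))
            order.append([str(cats[i]) for i in idx])
        return order


def category_map(
    model: EncodingModel,
    bases: feat.PcaBases,
    exemplars: feat.LayeredFeatureSeries,
) -> np.ndarray:
    """Mean predicted voxel response over a category's (standardized)
    exemplar features; one value per voxel."""
    if exemplars.n_rows < 1:
        raise ValueError("empty exemplar set")
    design = feat.transform(exemplars, bases)
    return (design.matrix @ model.weights.T).mean(axis=0)


def exemplar_responses(
    model: EncodingModel,
    bases: feat.PcaBases,
    atlas: CategoryAtlas,
    standardizers: feat.Standardizers,
) -> dict:
    """Per-category matrices of predicted responses, one row per exemplar."""
    out = {}
    for c in atlas.categories:
        std = feat.standardize_static(atlas.exemplar_features[c], standardizers)
        design = feat.transform(std, bases)
        out[c] = design.matrix @ model.weights.T  # (n_ex, V)
    return out


def build_maps(
    model: EncodingModel,
    bases: feat.PcaBases,
    atlas: CategoryAtlas,
    standardizers: feat.Standardizers,
) -> CategoryAtlas:
    """Fill ``atlas.maps`` with the mean predicted response per category."""
    rows = []
    for c in atlas.categories:
        std = feat.standardize_static(atlas.exemplar_features[c], standardizers)
        rows.append(category_map(model, bases, std))
    return CategoryAtlas(categories=atlas.categories,
                         exemplar_features=atlas.exemplar_features,
                         exemplar_counts=atlas.exemplar_counts,
                         maps=np.stack(rows))


def dprime(responses_by_category: dict, categories: list | None = None) -> SelectivityProfile:
    """d' selectivity of every voxel for every category.

    ``responses_by_category`` maps label -> (n_exemplars, n_voxels) predicted
    responses. Complement statistics pool the exemplars of all other
    categories (not their means). Sample variances use ddof = 1. Voxels where
    the pooled variance term vanishes get d' = 0 and are flagged.
    """
    cats = list(categories) if categories is not None else sorted(responses_by_category)
    mats = [np.asarray(responses_by_category[c], dtype=float) for c in cats]
    for c, m in zip(cats, mats):
        if m.shape[0] < 2:
            raise ValueError(f"category {c!r} needs at least two exemplars")
    n_vox = mats[0].shape[1]
    counts = np.array([m.shape[0] for m in mats])
    sums = np.stack([m.sum(axis=0) for m in mats])  # (C, V)
    sumsqs = np.stack([(m**2).sum(axis=0) for m in mats])
    tot_n = counts.sum()
    tot_sum = sums.sum(axis=0)
    tot_sumsq = sumsqs.sum(axis=0)
    d = np.zeros((n_vox, len(cats)))
    flags = np.zeros(n_vox, dtype=bool)
    for i, c in enumerate(cats):
        n_i = counts[i]
        mean_i = sums[i] / n_i
        var_i = (sumsqs[i] - n_i * mean_i**2) / (n_i - 1)
        n_c = tot_n - n_i
        mean_c = (tot_sum - sums[i]) / n_c
        var_c = (tot_sumsq - sumsqs[i] - n_c * mean_c**2) / (n_c - 1)
        pooled = (np.maximum(var_i, 0.0) + np.maximum(var_c, 0.0)) / 2.0
        ok = pooled > 0
        d[ok, i] = (mean_i - mean_c)[ok] / np.sqrt(pooled[ok])
        flags |= ~ok
    return SelectivityProfile(dprime_by_category=d, categories=cats, zero_variance=flags)


def selectivity_profile(atlas: CategoryAtlas, voxel: int, top_k: int = 10) -> list:
    """Top-k category labels at a voxel by map value, descending; ties break
    alphabetically (stable)."""
    if atlas.maps is None:
        raise ValueError("atlas maps not built")
    vals = atlas.maps[:, voxel]
    idx = sorted(range(len(atlas.categories)), key=lambda i: (-vals[i], atlas.categories[i]))
    return [atlas.categories[i] for i in idx[: min(top_k, len(idx))]]


def roi_selectivity(selectivity: np.ndarray, roi_labels) -> dict:
    """Mean and standard error of voxel selectivity per ROI.

    ``roi_labels`` assigns each voxel one ROI label (None / '' = unassigned).
    Single-voxel ROIs report SE = 0 with a flag; ROIs with no voxels are
    reported as missing (mean = nan).
    """
    selectivity = np.asarray(selectivity, dtype=float)
    roi_labels = list(roi_labels)
    out = {}
    for roi in sorted({r for r in roi_labels if r}):
        vals = selectivity[[i for i, r in enumerate(roi_labels) if r == roi]]
        if vals.size == 0:
            out[roi] = {"mean": float("nan"), "se": float("nan"), "n": 0, "flag": "empty"}
        elif vals.size == 1:
            out[roi] = {"mean": float(vals[0]), "se": 0.0, "n": 1, "flag": "single_voxel"}
        else:
            out[roi] = {"mean": float(vals.mean()),
                        "se": float(vals.std(ddof=1) / np.sqrt(vals.size)),
                        "n": int(vals.size), "flag": ""}
    return out
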