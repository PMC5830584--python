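"""Layer-wise attribution: re-evaluate category maps, representational
similarity, modularity (at the full-model partition) and semantic correlation
with all feature layers but one zeroed."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features as feat
from .catmap import CategoryAtlas, category_map
from .cluster import SimilarityNetwork, cluster_categories, signed_modularity, similarity_matrix
from .encoding import EncodingModel
from .semantics import representational_semantic_correlation

__all__ = ["LayerProfile", "layerwise_category_maps", "layer_profile"]


@dataclass
class LayerProfile:
    """Per-layer similarity, modularity and semantic-correlation summary."""

    layers: list  # 1-based layer indices
    Q: np.ndarray
    Q_plus: np.ndarray
    Q_minus: np.ndarray
    semantic_r: dict  # method -> per-layer r
    semantic_p: dict  # method -> per-layer p
    similarity: list = field(default_factory=list)  # per-layer SimilarityNetwork

    @property
    def argmax_Q_layer(self) -> int:
        return int(self.layers[int(np.argmax(self.Q))])

    @property
    def argmax_r_layer(self) -> dict:
        return {m: int(self.layers[int(np.argmax(r))]) for m, r in self.semantic_r.items()}

    def to_frame(self) -> pd.DataFrame:
        data = {"layer": self.layers, "Q": self.Q, "Q_plus": self.Q_plus,
                "Q_minus": self.Q_minus}
        for m in self.semantic_r:
            data[f"r_{m}"] = self.semantic_r[m]
            data[f"p_{m}"] = self.semantic_p[m]
        return pd.DataFrame(data)


def layerwise_category_maps(
    model: EncodingModel,
    bases: feat.PcaBases,
    atlas: CategoryAtlas,
    standardizers: feat.Standardizers,
    layer: int,
) -> np.ndarray:
    """Category maps computed from exemplar features ablated to one layer."""
    rows = []
    for c in atlas.categories:
        std = feat.standardize_static(atlas.exemplar_features[c], standardizers)
        rows.append(category_map(model, bases, feat.ablate_to_layer(std, layer)))
    return np.stack(rows)


def layer_profile(
    model: EncodingModel,
    bases: feat.PcaBases,
    atlas: CategoryAtlas,
    standardizers: feat.Standardizers,
    mask: np.ndarray,
    cluster_labels: np.ndarray | None,
    semantic_sources: dict | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    recluster: bool = False,
    k_range=range(2, 9),
) -> LayerProfile:
    """Evaluate each layer's contribution.

    By default modularity is evaluated at the fixed full-model partition
    (``cluster_labels``); ``recluster=True`` re-runs the clustering per layer
    instead. ``semantic_sources`` maps a name to an already-computed semantic
    similarity matrix (aligned with ``atlas.categories``).
    """
    if cluster_labels is None and not recluster:
        raise ValueError("cluster_labels required unless recluster=True")
    n_layers = bases.n_layers
    layer_ids = list(range(1, n_layers + 1))
    qs, qps, qms, sims = [], [], [], []
    sem_r = {m: [] for m in (semantic_sources or {})}
    sem_p = {m: [] for m in (semantic_sources or {})}
    for l in layer_ids:
        maps_l = layerwise_category_maps(model, bases, atlas, standardizers, l)
        net = similarity_matrix(maps_l, mask, atlas.categories, mask_id=f"layer{l}")
        if recluster:
            res = cluster_categories(net, k_range=k_range, seed=seed)
            q, qp, qm = res.Q, res.Q_plus, res.Q_minus
        else:
            q, qp, qm = signed_modularity(net, cluster_labels)
        qs.append(q)
        qps.append(qp)
        qms.append(qm)
        sims.append(net)
        for m, sem in (semantic_sources or {}).items():
            r, p = representational_semantic_correlation(net.S, sem, n_perm=n_perm,
                                                         seed=seed)
            sem_r[m].append(r)
            sem_p[m].append(p)
    return LayerProfile(layers=layer_ids, Q=np.array(qs), Q_plus=np.array(qps),
                        Q_minus=np.array(qms),
                        semantic_r={m: np.array(v) for m, v in sem_r.items()},
                        semantic_p={m: np.array(v) for m, v in sem_p.items()},
                        similarity=sims)
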