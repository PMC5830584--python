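"""Semantic similarity between category labels and its permutation-tested
correlation with representational similarity.

Two similarity sources are supported: a path-based measure on an is-a
taxonomy, s = -log(p / 2d) with p the shortest-path length (node-counting
convention by default) and d the maximum taxonomy depth, and cosine
similarity on an arbitrary label -> vector table.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ._utils import rng_from

__all__ = [
    "Taxonomy",
    "SemanticSimilarity",
    "lch_similarity",
    "vector_cosine",
    "semantic_matrix",
    "representational_semantic_correlation",
]

FISHER_CLIP = 1.0 - 1e-7


@dataclass
class Taxonomy:
    """Rooted is-a DAG over labels, edges directed child -> parent."""

    nodes: set
    edges: list  # (child, parent) pairs
    root: str = "root"
    depth: int = field(init=False)

    def __post_init__(self):
        self.nodes = set(self.nodes)
        if self.root not in self.nodes:
            raise ValueError("root must be a node")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for child, parent in self.edges:
            if child not in self.nodes or parent not in self.nodes:
                raise ValueError(f"edge ({child}, {parent}) references unknown node")
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("taxonomy must be acyclic")
        lengths = {}
        for n in self.nodes:
            if n == self.root:
                lengths[n] = 0
                continue
            try:
                lengths[n] = nx.shortest_path_length(g, n, self.root)
            except nx.NetworkXNoPath:
                raise ValueError(f"node {n!r} cannot reach the root")
        self._graph = g
        self.depth = max(lengths.values())
        if self.depth < 1:
            raise ValueError("taxonomy depth must be at least 1")

    @property
    def undirected(self) -> nx.Graph:
        return self._graph.to_undirected(as_view=True)


@dataclass
class SemanticSimilarity:
    matrix: np.ndarray
    labels: list
    method: str  # "lch" | "vector_cosine"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if np.abs(self.matrix - self.matrix.T).max() > 1e-12:
            raise ValueError("semantic similarity must be symmetric")


def lch_similarity(taxonomy: Taxonomy, a: str, b: str, path_convention: str = "nodes") -> float:
    """Path-based label similarity -log(p / 2d).

    ``path_convention="nodes"`` counts nodes on the shortest undirected path
    (identical labels give p = 1); ``"edges"`` counts edges (p >= 1 enforced
    by flooring identical labels at 1 to keep the log finite).
    """
    for label in (a, b):
        if label not in taxonomy.nodes:
            raise KeyError(f"label {label!r} not in taxonomy")
    hops = nx.shortest_path_length(taxonomy.undirected, a, b)
    if path_convention == "nodes":
        p = hops + 1
    elif path_convention == "edges":
        p = max(hops, 1)
    else:
        raise ValueError("path_convention must be 'nodes' or 'edges'")
    return float(-np.log(p / (2.0 * taxonomy.depth)))


def vector_cosine(vectors: dict, a: str, b: str) -> float:
    """Cosine similarity between the vectors of two labels."""
    for label in (a, b):
        if label not in vectors:
            raise KeyError(f"label {label!r} not in vector table")
    va = np.asarray(vectors[a], dtype=float)
    vb = np.asarray(vectors[b], dtype=float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.dot(va, vb) / (na * nb))


def semantic_matrix(labels: list, method: str, source) -> SemanticSimilarity:
    """Full pairwise similarity matrix for the given labels.

    ``source`` is a :class:`Taxonomy` for ``method="lch"`` or a label->vector
    mapping for ``method="vector_cosine"``.
    """
    labels = list(labels)
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if method == "lch":
                s = lch_similarity(source, labels[i], labels[j])
            elif method == "vector_cosine":
                s = vector_cosine(source, labels[i], labels[j])
            else:
                raise ValueError("method must be 'lch' or 'vector_cosine'")
            mat[i, j] = mat[j, i] = s
    return SemanticSimilarity(matrix=mat, labels=labels, method=method)


def representational_semantic_correlation(
    cortical_matrix: np.ndarray,
    semantic: SemanticSimilarity | np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple:
    """Mantel-style correlation between cortical and semantic similarity.

    Cortical similarities (correlations) are Fisher z-transformed (clipped at
    |r| = 1 - 1e-7); Pearson r is computed over the upper triangle. The null
    relabels rows and columns of the cortical matrix with a common random
    permutation; p = (1 + #{null >= r}) / (1 + n_perm).
    """
    s_cort = np.asarray(cortical_matrix, dtype=float)
    s_sem = semantic.matrix if isinstance(semantic, SemanticSimilarity) else np.asarray(semantic, float)
    if s_cort.shape != s_sem.shape or s_cort.shape[0] != s_cort.shape[1]:
        raise ValueError("matrices must be square and matched")
    n = s_cort.shape[0]
    z = np.arctanh(np.clip(s_cort, -FISHER_CLIP, FISHER_CLIP))
    iu = np.triu_indices(n, k=1)
    sem_flat = s_sem[iu]
    sem_c = sem_flat - sem_flat.mean()
    sem_norm = np.linalg.norm(sem_c)

    def corr_with(zm):
        zf = zm[iu]
        zc = zf - zf.mean()
        den = np.linalg.norm(zc) * sem_norm
        return float(zc @ sem_c / den) if den > 0 else 0.0

    r_obs = corr_with(z)
    rng = rng_from(seed, 0x5E3A)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr_with(z[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return r_obs, p
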