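"""Inter-category representational similarity, signed-modularity clustering,
permutation tests, and fine-scale (cluster-specific region) analysis.

Modularity treats the similarity matrix as a signed weighted undirected
network. With off-diagonal weights W and total weight S = sum_{i != j} W_ij,
Q = sum_{i != j} (W_ij / S - (row_i / S)(col_j / S)) delta(C_i, C_j),
computed separately on the positive and negative parts and combined as
Q = (S+/(S+ + S-)) Q+ - (S-/(S+ + S-)) Q-.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from ._utils import rng_from
from .encoding import AccuracyReport

__all__ = [
    "SimilarityNetwork",
    "ClusteringResult",
    "predictable_mask",
    "similarity_matrix",
    "signed_modularity",
    "cluster_categories",
    "modularity_permutation_test",
    "cluster_specific_region",
    "subcluster",
    "best_partition_exhaustive",
]


@dataclass
class SimilarityNetwork:
    """Symmetric category x category Pearson-correlation network."""

    S: np.ndarray
    labels: list
    mask_id: str = ""
    zero_variance: np.ndarray | None = None

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.labels)
        if self.S.shape != (n, n):
            raise ValueError("similarity matrix must be labels x labels")
        if np.abs(self.S - self.S.T).max() > 1e-10:
            raise ValueError("similarity matrix must be symmetric")
        self.S = (self.S + self.S.T) / 2.0

    @property
    def S_plus(self) -> np.ndarray:
        return np.maximum(self.S, 0.0)

    @property
    def S_minus(self) -> np.ndarray:
        return np.maximum(-self.S, 0.0)

    @property
    def n(self) -> int:
        return self.S.shape[0]


@dataclass
class ClusteringResult:
    labels: np.ndarray  # per-category cluster id, 1..k
    k: int
    Q: float
    Q_plus: float
    Q_minus: float
    k_scan: list = field(default_factory=list)  # (k, Q) pairs
    p_perm: float | None = None
    unstable: bool = False

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 1 or self.labels.max() > self.k:
            raise ValueError("cluster labels must lie in 1..k")


def predictable_mask(report: AccuracyReport, q_threshold: float = 0.01,
                     r_threshold: float = 0.2) -> np.ndarray:
    """Voxels with q < q_threshold and r > r_threshold (both strict)."""
    if report.q is None:
        raise ValueError("report lacks FDR-adjusted q values")
    mask = (report.q < q_threshold) & (report.r > r_threshold)
    if not mask.any():
        raise ValueError(
            f"no predictable voxels at q < {q_threshold} and r > {r_threshold} "
            f"(best q = {report.q.min():.3g}, best r = {report.r.max():.3g})")
    return mask


def similarity_matrix(maps: np.ndarray, mask: np.ndarray, labels: list,
                      mask_id: str = "") -> SimilarityNetwork:
    """Pairwise Pearson correlation of category maps restricted to the masked
    voxels. Zero-variance maps correlate 0 with everything (flagged); the
    diagonal is 1 by definition."""
    maps = np.asarray(maps, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("need at least three masked voxels")
    x = maps[:, mask]
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((xc**2).sum(axis=1))
    flags = norms == 0
    if flags.any():
        warnings.warn("zero-variance category maps; correlations set to 0")
    safe = np.where(flags, 1.0, norms)
    s = (xc / safe[:, None]) @ (xc / safe[:, None]).T
    s[flags, :] = 0.0
    s[:, flags] = 0.0
    np.fill_diagonal(s, 1.0)
    return SimilarityNetwork(S=np.clip(s, -1.0, 1.0), labels=list(labels),
                             mask_id=mask_id, zero_variance=flags)


def _modularity_part(w: np.ndarray, labels: np.ndarray) -> float:
    """Newman modularity of one non-negative part.

    Diagonal weights are excluded (self-similarity is not an edge), but the
    i = j term of the expected-weight product is kept, so p_ij and q_ij both
    sum to 1 and any single-cluster partition scores exactly 0.
    """
    w = np.array(w, dtype=float)
    np.fill_diagonal(w, 0.0)
    tot = w.sum()
    if tot <= 0:
        return 0.0
    same = labels[:, None] == labels[None, :]
    row = w.sum(axis=1) / tot
    col = w.sum(axis=0) / tot
    return float((w[same] / tot).sum() - (row[:, None] * col[None, :])[same].sum())


def signed_modularity(net: SimilarityNetwork, labels: np.ndarray) -> tuple:
    """(Q, Q+, Q-) for a partition of the signed similarity network."""
    labels = np.asarray(labels)
    if labels.shape != (net.n,):
        raise ValueError("one label per category required")
    wp = np.array(net.S_plus)
    wm = np.array(net.S_minus)
    np.fill_diagonal(wp, 0.0)
    np.fill_diagonal(wm, 0.0)
    sp, sm = wp.sum(), wm.sum()
    qp = _modularity_part(wp, labels)
    qm = _modularity_part(wm, labels)
    if sp + sm == 0:
        warnings.warn("all-zero network weights; Q = 0")
        return 0.0, 0.0, 0.0
    q = (sp / (sp + sm)) * qp - (sm / (sp + sm)) * qm
    return float(q), float(qp), float(qm)


def cluster_categories(
    net: SimilarityNetwork,
    k_range=range(2, 9),
    n_restarts: int = 50,
    seed: int = 0,
    unstable_q: float = 0.05,
) -> ClusteringResult:
    """k-means on the rows of S with restarts; for each k the restart labeling
    maximizing signed Q is kept, and k is selected by maximum Q (ties to the
    smallest k)."""
    ks = [int(k) for k in k_range]
    if not ks or min(ks) < 2 or max(ks) > net.n - 1:
        raise ValueError("k_range must lie within 2 .. n_categories - 1")
    if not np.all(np.isfinite(net.S)):
        raise ValueError("degenerate similarity matrix")
    rng = rng_from(seed, 0xC1A5)
    best = None
    k_scan = []
    for k in ks:
        best_k = None
        for _ in range(n_restarts):
            rs = int(rng.integers(0, 2**31 - 1))
            km = KMeans(n_clusters=k, n_init=1, random_state=rs)
            lab = km.fit_predict(net.S) + 1
            q, qp, qm = signed_modularity(net, lab)
            if best_k is None or q > best_k[0]:
                best_k = (q, qp, qm, lab)
        k_scan.append((k, best_k[0]))
        if best is None or best_k[0] > best[0]:
            best = best_k + (k,)
    q, qp, qm, labels, k = best
    return ClusteringResult(labels=labels, k=k, Q=q, Q_plus=qp, Q_minus=qm,
                            k_scan=k_scan, unstable=q < unstable_q)


def modularity_permutation_test(net: SimilarityNetwork, labels: np.ndarray,
                                n_perm: int = 10_000, seed: int = 0) -> float:
    """p-value of Q against a null built by shuffling the off-diagonal pair
    weights (signed values jointly, symmetry preserved)."""
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    labels = np.asarray(labels)
    q_obs, _, _ = signed_modularity(net, labels)
    iu = np.triu_indices(net.n, k=1)
    vals = net.S[iu]
    rng = rng_from(seed, 0x9E27)
    count = 0
    shuf = np.zeros_like(net.S)
    for _ in range(n_perm):
        v = rng.permutation(vals)
        shuf[iu] = v
        s_null = shuf + shuf.T
        np.fill_diagonal(s_null, 1.0)
        q_null, _, _ = signed_modularity(
            SimilarityNetwork(S=s_null, labels=net.labels), labels)
        if q_null >= q_obs:
            count += 1
    return (1.0 + count) / (1.0 + n_perm)


def cluster_specific_region(
    cluster_exemplar_responses: np.ndarray,
    random_exemplar_responses: np.ndarray,
    alpha: float = 0.01,
) -> np.ndarray:
    """Voxels responding significantly more to a cluster's exemplars than to
    random exemplars: per-voxel two-sample pooled-variance t-test (one-sided,
    greater), Bonferroni-corrected over voxels at ``alpha``."""
    a = np.asarray(cluster_exemplar_responses, dtype=float)
    b = np.asarray(random_exemplar_responses, dtype=float)
    if b.shape[0] < 2 or a.shape[0] < 2:
        raise ValueError("need at least two exemplars per sample")
    if a.shape[1] != b.shape[1]:
        raise ValueError("voxel counts differ")
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=True, alternative="greater")
    n_vox = a.shape[1]
    return (p * n_vox < alpha) & (t > 0)


def subcluster(
    maps: np.ndarray,
    region_mask: np.ndarray,
    category_indices,
    labels: list,
    k_range=range(2, 9),
    n_restarts: int = 50,
    seed: int = 0,
) -> ClusteringResult:
    """Re-cluster a subset of categories over a restricted voxel region."""
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("empty region mask")
    idx = list(category_indices)
    if len(idx) < 3:
        raise ValueError("need at least three categories to sub-cluster")
    sub_labels = [labels[i] for i in idx]
    net = similarity_matrix(np.asarray(maps)[idx], region_mask, sub_labels,
                            mask_id="cluster_region")
    return cluster_categories(net, k_range=k_range, n_restarts=n_restarts, seed=seed)


def _partitions(items, max_parts):
    """All set partitions of ``items`` into at most ``max_parts`` blocks."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest, max_parts):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1:]
        if len(part) < max_parts:
            yield part + [[first]]


def best_partition_exhaustive(net: SimilarityNetwork, max_clusters: int = 4) -> tuple:
    """Max-Q partition by exhaustive enumeration (oracle; n <= ~10 only)."""
    items = list(range(net.n))
    best_q, best_labels = -np.inf, None
    for part in _partitions(items, max_clusters):
        labels = np.zeros(net.n, dtype=int)
        for ci, block in enumerate(part, start=1):
            labels[block] = ci
        q, _, _ = signed_modularity(net, labels)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_q, best_labels
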