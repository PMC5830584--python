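"""Feature pipeline: hemodynamic convolution, downsampling, standardization,
two-stage PCA dimension reduction, and single-layer ablation.

The design matrix is built in two reduction stages: a per-layer PCA keeping
enough components to retain at least ``variance_threshold`` of that layer's
variance, followed by a second PCA on the concatenation of the per-layer
scores (each layer scaled by 1/sqrt(p_l)) at the same threshold.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import gamma as gamma_dist

__all__ = [
    "LayeredFeatureSeries",
    "Kernel",
    "Standardizers",
    "PcaBases",
    "FeatureDesign",
    "hrf_kernel",
    "prepare_series",
    "standardize_static",
    "fit_pca",
    "transform",
    "ablate_to_layer",
]


@dataclass
class LayeredFeatureSeries:
    """Per-layer unit activations over time (or one row per static exemplar)."""

    layers: list  # list of (n, p_l) float arrays, ordered bottom -> top
    time_step: float | None = None  # seconds between rows; None for static rows

    def __post_init__(self):
        self.layers = [np.asarray(m, dtype=float) for m in self.layers]
        if len(self.layers) < 1:
            raise ValueError("at least one layer required")
        n = self.layers[0].shape[0]
        for i, m in enumerate(self.layers):
            if m.ndim != 2:
                raise ValueError(f"layer {i + 1} is not a matrix")
            if m.shape[0] != n:
                raise ValueError("inconsistent row counts across layers")
            if m.shape[1] < 1:
                raise ValueError(f"layer {i + 1} has no units")
        if self.time_step is not None and self.time_step <= 0:
            raise ValueError("time_step must be positive")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def n_rows(self) -> int:
        return self.layers[0].shape[0]

    @property
    def units_per_layer(self) -> tuple:
        return tuple(m.shape[1] for m in self.layers)

    def copy(self) -> "LayeredFeatureSeries":
        return LayeredFeatureSeries([m.copy() for m in self.layers], self.time_step)


@dataclass
class Kernel:
    """Sampled hemodynamic impulse response."""

    taps: np.ndarray
    resolution: float
    peak_time: float

    def __post_init__(self):
        self.taps = np.asarray(self.taps, dtype=float)
        if not np.all(np.isfinite(self.taps)):
            raise ValueError("kernel taps must be finite")
        t_argmax = float(np.argmax(self.taps)) * self.resolution
        if abs(t_argmax - self.peak_time) > self.resolution + 1e-12:
            raise ValueError("kernel peak inconsistent with peak_time")


@dataclass
class Standardizers:
    """Per-layer column means and SDs estimated on the fitting data.

    Columns whose SD fell below ``eps`` are flagged; their standardized
    values are defined as all-zero (guarded division).
    """

    means: list
    sds: list
    eps: float = 1e-12

    @property
    def zero_variance_flags(self) -> list:
        return [sd <= self.eps for sd in self.sds]


UNDERSHOOT_RATIO = 1.0 / 6.0


def _double_gamma(t: np.ndarray, shape_resp: float, shape_under: float) -> np.ndarray:
    # scale fixed at 1 s for both gamma densities
    return gamma_dist.pdf(t, shape_resp) - UNDERSHOOT_RATIO * gamma_dist.pdf(t, shape_under)


def hrf_kernel(resolution: float, peak_time: float = 4.0, duration: float = 32.0) -> Kernel:
    """Double-gamma hemodynamic kernel with its analytic mode at ``peak_time``.

    The response gamma's shape (scale 1 s) is solved so that the derivative of
    the response-minus-undershoot difference vanishes exactly at ``peak_time``;
    the undershoot gamma has its mode at 3x the peak time and amplitude ratio
    1/6. Taps are normalized to unit peak amplitude, and the kernel is zero at
    t = 0.
    """
    if resolution <= 0 or peak_time <= 0 or duration <= 0:
        raise ValueError("resolution, peak_time and duration must be positive")
    shape_under = 3.0 * peak_time + 1.0  # mode at 3 * peak_time

    def dslope(shape_resp):
        # d/dt gamma.pdf(t, a) = pdf * ((a - 1)/t - 1) for scale 1
        g1 = gamma_dist.pdf(peak_time, shape_resp) * ((shape_resp - 1.0) / peak_time - 1.0)
        g2 = gamma_dist.pdf(peak_time, shape_under) * ((shape_under - 1.0) / peak_time - 1.0)
        return g1 - UNDERSHOOT_RATIO * g2

    shape_resp = brentq(dslope, peak_time + 1.0, peak_time + 2.0, xtol=1e-12)
    t = np.arange(0.0, duration + resolution / 2, resolution)
    taps = _double_gamma(t, shape_resp, shape_under)
    taps /= _double_gamma(np.array([peak_time]), shape_resp, shape_under)[0]
    return Kernel(taps=taps, resolution=resolution, peak_time=peak_time)


def _convolve_downsample(x: np.ndarray, kernel: Kernel, dt: float, tr: float) -> np.ndarray:
    """Causal convolution at native resolution, then TR-window averaging."""
    if abs(kernel.resolution - dt) > 1e-9:
        raise ValueError("kernel resolution must match the feature time step")
    n = x.shape[0]
    from scipy.signal import fftconvolve

    conv = fftconvolve(x, kernel.taps[:, None], axes=0)[:n]
    ratio = tr / dt
    n_per = int(round(ratio))
    if abs(ratio - n_per) > 1e-9 or n_per < 1:
        raise ValueError("feature time_step must divide the TR")
    n_vol = n // n_per
    conv = conv[: n_vol * n_per]
    return conv.reshape(n_vol, n_per, x.shape[1]).mean(axis=1)


def _standardize(x: np.ndarray, mean: np.ndarray, sd: np.ndarray, eps: float) -> np.ndarray:
    out = x - mean
    ok = sd > eps
    out[:, ok] /= sd[ok]
    out[:, ~ok] = 0.0
    return out


def prepare_series(
    features: LayeredFeatureSeries,
    kernel: Kernel,
    tr: float,
    standardizers: Standardizers | None = None,
):
    """Convolve each unit with the kernel, average within TR windows, and
    standardize columns.

    When ``standardizers`` is None, means/SDs are estimated from this series
    (the fitting data) and returned for reuse on held-out data. Zero-variance
    units become all-zero columns and are flagged.

    Returns ``(prepared, standardizers)``.
    """
    if features.time_step is None:
        raise ValueError("prepare_series requires a time series; use standardize_static for exemplars")
    downsampled = [
        _convolve_downsample(m, kernel, features.time_step, tr) for m in features.layers
    ]
    if standardizers is None:
        means = [m.mean(axis=0) for m in downsampled]
        sds = [m.std(axis=0) for m in downsampled]
        standardizers = Standardizers(means=means, sds=sds)
        if any(np.any(f) for f in standardizers.zero_variance_flags):
            warnings.warn("zero-variance units standardized to all-zero columns")
    prepared = [
        _standardize(m, mu, sd, standardizers.eps)
        for m, mu, sd in zip(downsampled, standardizers.means, standardizers.sds)
    ]
    return LayeredFeatureSeries(prepared, time_step=tr), standardizers


def standardize_static(features: LayeredFeatureSeries, standardizers: Standardizers) -> LayeredFeatureSeries:
    """Standardize static exemplar rows with training-set parameters (no
    convolution: exemplars are single stimuli, not time series)."""
    prepared = [
        _standardize(np.array(m, dtype=float), mu, sd, standardizers.eps)
        for m, mu, sd in zip(features.layers, standardizers.means, standardizers.sds)
    ]
    return LayeredFeatureSeries(prepared, time_step=None)


@dataclass
class PcaBases:
    """Two-stage PCA bases fitted on the (standardized) training features."""

    layer_bases: list  # B_l, (p_l, q_l), orthonormal columns
    layer_kept: list  # q_l
    cross_basis: np.ndarray  # (sum q_l, k)
    cross_kept: int
    variance_threshold: float
    units_per_layer: tuple
    layer_means: list = field(default_factory=list)  # standardization params, if known
    layer_sds: list = field(default_factory=list)
    layer_explained: list = field(default_factory=list)  # per-layer retained variance ratio
    cross_explained: float = float("nan")

    def __post_init__(self):
        self.layer_bases = [np.ascontiguousarray(b, dtype=float) for b in self.layer_bases]
        self.cross_basis = np.ascontiguousarray(self.cross_basis, dtype=float)
        for b in self.layer_bases + [self.cross_basis]:
            err = np.abs(b.T @ b - np.eye(b.shape[1])).max()
            if err > 1e-8:
                raise ValueError("PCA basis columns are not orthonormal")

    @property
    def n_layers(self) -> int:
        return len(self.layer_bases)

    @property
    def score_offsets(self) -> list:
        """Column offset of each layer's block in the concatenated score space."""
        offs = np.concatenate([[0], np.cumsum(self.layer_kept)])
        return offs.tolist()


@dataclass
class FeatureDesign:
    """Final N x k regressor matrix."""

    matrix: np.ndarray
    row_times: np.ndarray | None = None
    exemplar_ids: list | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("design matrix must be finite")


def _pca_keep(x: np.ndarray, threshold: float):
    """SVD-based PCA on the mean-centered matrix; smallest q whose cumulative
    explained-variance ratio reaches the threshold."""
    xc = x - x.mean(axis=0)
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        return np.eye(x.shape[1], 1), 1, 1.0  # degenerate all-constant input
    ratio = np.cumsum(var) / total
    q = int(np.searchsorted(ratio, threshold - 1e-12) + 1)
    q = min(q, len(s))
    return vt[:q].T, q, float(ratio[q - 1])


def fit_pca(
    series: LayeredFeatureSeries,
    variance_threshold: float = 0.99,
    standardizers: Standardizers | None = None,
) -> PcaBases:
    """Fit the two-stage dimension reduction on standardized training features.

    Stage one reduces each layer to the smallest component count retaining at
    least ``variance_threshold`` of its variance; stage two reduces the
    1/sqrt(p_l)-scaled concatenation of the per-layer scores at the same
    threshold. The projection itself is purely linear (the input contract is
    zero-mean standardized features), so ablation identities are exact.
    """
    if not (0.0 < variance_threshold <= 1.0):
        raise ValueError("variance_threshold must be in (0, 1]")
    if series.n_rows < 2:
        raise ValueError("need at least two rows to fit PCA")
    layer_bases, layer_kept, layer_explained, scores = [], [], [], []
    for m in series.layers:
        b, q, expl = _pca_keep(m, variance_threshold)
        layer_bases.append(b)
        layer_kept.append(q)
        layer_explained.append(expl)
        scores.append((m @ b) / np.sqrt(m.shape[1]))
    concat = np.concatenate(scores, axis=1)
    cross_basis, cross_kept, cross_explained = _pca_keep(concat, variance_threshold)
    std_means = standardizers.means if standardizers is not None else []
    std_sds = standardizers.sds if standardizers is not None else []
    return PcaBases(
        layer_bases=layer_bases,
        layer_kept=layer_kept,
        cross_basis=cross_basis,
        cross_kept=cross_kept,
        variance_threshold=variance_threshold,
        units_per_layer=series.units_per_layer,
        layer_means=std_means,
        layer_sds=std_sds,
        layer_explained=layer_explained,
        cross_explained=cross_explained,
    )


def transform(features: LayeredFeatureSeries, bases: PcaBases) -> FeatureDesign:
    """Project standardized features through both PCA stages (pure linear map)."""
    if features.n_layers != bases.n_layers:
        raise ValueError("layer count mismatch with fitted bases")
    scores = []
    for m, b in zip(features.layers, bases.layer_bases):
        if m.shape[1] != b.shape[0]:
            raise ValueError("unit count mismatch with fitted bases")
        scores.append((m @ b) / np.sqrt(m.shape[1]))
    concat = np.concatenate(scores, axis=1)
    mat = concat @ bases.cross_basis
    times = None
    if features.time_step is not None:
        times = np.arange(features.n_rows) * features.time_step
    return FeatureDesign(matrix=mat, row_times=times)


def ablate_to_layer(features: LayeredFeatureSeries, layer: int) -> LayeredFeatureSeries:
    """Zero every layer except ``layer`` (1-based) in standardized space."""
    if not (1 <= layer <= features.n_layers):
        raise ValueError(f"layer must be in 1..{features.n_layers}")
    out = []
    for i, m in enumerate(features.layers, start=1):
        out.append(m.copy() if i == layer else np.zeros_like(m))
    return LayeredFeatureSeries(out, time_step=features.time_step)
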