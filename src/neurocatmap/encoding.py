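"""Voxel-wise encoding models: L2-regularized regression with 9-fold
cross-validation, session-wise prediction accuracy, block-permutation
significance with FDR control, Monte-Carlo noise ceiling, and per-voxel
layer assignment.

The ridge objective is (1/N) sum_i (r_v(x_i) - f(x_i) w_v)^2 + lambda ||w_v||^2,
so the normal equations read (X'X/N + lambda I) w = X'y / N.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from . import features as feat
from ._utils import rng_from

__all__ = [
    "VoxelResponses",
    "EncodingModel",
    "AccuracyReport",
    "preprocess_responses",
    "fit_ridge",
    "predict",
    "accuracy",
    "block_permutation_test",
    "fdr",
    "noise_ceiling",
    "layer_explained_variance",
    "assign_layer",
]

DEFAULT_LAMBDA_GRID = np.logspace(-3, 3, 10)  # 10 points spanning 6 decades


@dataclass
class VoxelResponses:
    """Voxel x time responses with session (and optional repeat) structure."""

    values: np.ndarray  # (n_voxels, n_time)
    sessions: np.ndarray  # (n_time,) integer session ids, contiguous blocks
    tr: float
    repeats: np.ndarray | None = None  # (n_repeats, n_voxels, n_time), pre-averaging

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.sessions = np.asarray(self.sessions, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be voxel x time")
        if self.sessions.shape != (self.values.shape[1],):
            raise ValueError("sessions must label every time point")
        changes = np.flatnonzero(np.diff(self.sessions) != 0)
        ids_in_order = self.sessions[np.concatenate([[0], changes + 1])]
        if len(set(ids_in_order.tolist())) != len(ids_in_order):
            raise ValueError("session ids must form contiguous blocks")
        if self.repeats is not None:
            self.repeats = np.asarray(self.repeats, dtype=float)
            if self.repeats.shape[1:] != self.values.shape:
                raise ValueError("repeats must be (n_repeats, n_voxels, n_time)")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]

    @property
    def session_ids(self) -> np.ndarray:
        return np.unique(self.sessions)


def preprocess_responses(resp: VoxelResponses) -> VoxelResponses:
    """Average over repeats (if present) and standardize each voxel within
    each session (zero mean, unit variance; flat series stay zero)."""
    vals = resp.repeats.mean(axis=0) if resp.repeats is not None else resp.values.copy()
    out = np.zeros_like(vals)
    for s in np.unique(resp.sessions):
        m = resp.sessions == s
        block = vals[:, m]
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, keepdims=True)
        sd[sd == 0] = np.inf
        out[:, m] = (block - mu) / sd
    return VoxelResponses(values=out, sessions=resp.sessions, tr=resp.tr)


@dataclass
class EncodingModel:
    weights: np.ndarray  # (n_voxels, k)
    lam: np.ndarray | float  # shared scalar or per-voxel
    cv_table: np.ndarray | None = None  # (n_lambda, n_folds) mean correlation
    lambda_grid: np.ndarray | None = None
    bases_ref: str | None = None

    def __post_init__(self):
        # C-contiguous layout keeps downstream matmuls bit-reproducible
        # whether the model came from a fit or from disk
        self.weights = np.ascontiguousarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if np.any(np.asarray(self.lam) < 0):
            raise ValueError("lambda must be non-negative")


@dataclass
class AccuracyReport:
    r: np.ndarray
    r_by_session: np.ndarray  # (n_sessions, n_voxels)
    zero_variance: np.ndarray  # flags where r was forced to 0
    p: np.ndarray | None = None
    q: np.ndarray | None = None
    ceiling: np.ndarray | None = None
    assigned_layer: np.ndarray | None = None
    layer_r2: np.ndarray | None = None
    layer_confident: np.ndarray | None = None

    @property
    def r_normalized(self) -> np.ndarray | None:
        if self.ceiling is None:
            return None
        out = np.full_like(self.r, np.nan)
        ok = self.ceiling > 0
        out[ok] = self.r[ok] / self.ceiling[ok]
        return out


def _ridge_solve(x: np.ndarray, y: np.ndarray, lam) -> np.ndarray:
    """Solve (X'X/N + lam I) w = X'y/N via SVD; at lam = 0 singular directions
    fall back to the pseudo-inverse solution (with a warning).

    ``lam`` may be a scalar or a per-column-of-y vector. Returns (k, n_targets).
    """
    n = x.shape[0]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    uty = u.T @ y  # (k', V)
    lam_arr = np.atleast_1d(np.asarray(lam, dtype=float))
    if lam_arr.ndim > 1:
        raise ValueError("lam must be scalar or 1-D")
    rcond = np.finfo(float).eps * max(x.shape) * (s[0] if s.size else 1.0)
    if np.any(lam_arr == 0) and np.any(s <= rcond):
        warnings.warn("singular design at lambda = 0; using pseudo-inverse solution")
    if lam_arr.size == 1:
        denom = s**2 + n * lam_arr[0]
        factor = np.where((lam_arr[0] == 0) & (s <= rcond), 0.0, s / np.where(denom == 0, 1.0, denom))
        return vt.T @ (factor[:, None] * uty)
    # per-target lambda
    denom = s[:, None] ** 2 + n * lam_arr[None, :]
    factor = s[:, None] / np.where(denom == 0, 1.0, denom)
    factor[(denom == 0)] = 0.0
    zero_lam = lam_arr[None, :] == 0
    factor = np.where(zero_lam & (s[:, None] <= rcond), 0.0, factor)
    return vt.T @ (factor * uty)


def _fold_bounds(n: int, n_folds: int) -> list:
    """Contiguous, nearly equal row blocks (temporal cross-validation)."""
    edges = np.linspace(0, n, n_folds + 1).round().astype(int)
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:]) if b > a]


def fit_ridge(
    design: feat.FeatureDesign,
    responses: VoxelResponses,
    lambda_grid=None,
    n_folds: int = 9,
    per_voxel: bool = False,
) -> EncodingModel:
    """Fit per-voxel ridge weights with the regularization strength selected
    by n-fold cross-validation on contiguous temporal blocks.

    The selection score is the mean validation correlation across folds; by
    default one shared lambda (mean further taken across voxels) is used,
    ``per_voxel=True`` selects a separate lambda per voxel.
    """
    x = design.matrix
    y = responses.values.T  # (N, V)
    if x.shape[0] != y.shape[0]:
        raise ValueError("design rows must match response time points")
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid must be non-empty")
    n, v = y.shape
    folds = _fold_bounds(n, n_folds)
    cv_voxel = np.zeros((grid.size, len(folds), v))
    for f, (a, b) in enumerate(folds):
        mask = np.zeros(n, dtype=bool)
        mask[a:b] = True
        xtr, ytr = x[~mask], y[~mask]
        xva, yva = x[mask], y[mask]
        u, s, vt = np.linalg.svd(xtr, full_matrices=False)
        uty = u.T @ ytr
        yva_c = yva - yva.mean(axis=0)
        yva_n = np.sqrt((yva_c**2).sum(axis=0))
        for gi, lam in enumerate(grid):
            denom = s**2 + xtr.shape[0] * lam
            w = vt.T @ ((s / np.where(denom == 0, np.inf, denom))[:, None] * uty)
            pred = xva @ w
            pc = pred - pred.mean(axis=0)
            pn = np.sqrt((pc**2).sum(axis=0))
            den = pn * yva_n
            ok = den > 0
            rr = np.zeros(v)
            rr[ok] = (pc * yva_c).sum(axis=0)[ok] / den[ok]
            cv_voxel[gi, f] = rr
    cv_table = cv_voxel.mean(axis=2)  # (n_lambda, n_folds)
    if per_voxel:
        score = cv_voxel.mean(axis=1)  # (n_lambda, V)
        lam = grid[np.argmax(score, axis=0)]
    else:
        lam = float(grid[int(np.argmax(cv_table.mean(axis=1)))])
    w = _ridge_solve(x, y, lam).T  # (V, k)
    return EncodingModel(weights=w, lam=lam, cv_table=cv_table, lambda_grid=grid)


def predict(model: EncodingModel, design: feat.FeatureDesign,
            sessions: np.ndarray | None = None, tr: float = 1.0) -> VoxelResponses:
    """Linear prediction f(x) w_v for every voxel."""
    x = design.matrix
    if x.shape[1] != model.weights.shape[1]:
        raise ValueError("design columns do not match model weights")
    vals = (x @ model.weights.T).T
    if sessions is None:
        sessions = np.zeros(x.shape[0], dtype=int)
    return VoxelResponses(values=vals, sessions=sessions, tr=tr)


def _session_corr(pred: np.ndarray, obs: np.ndarray, sessions: np.ndarray):
    """Per-session Pearson r per voxel; zero-variance series give r = 0."""
    sess_ids = np.unique(sessions)
    out = np.zeros((sess_ids.size, pred.shape[0]))
    flags = np.zeros(pred.shape[0], dtype=bool)
    for i, s in enumerate(sess_ids):
        m = sessions == s
        pc = pred[:, m] - pred[:, m].mean(axis=1, keepdims=True)
        oc = obs[:, m] - obs[:, m].mean(axis=1, keepdims=True)
        num = (pc * oc).sum(axis=1)
        den = np.sqrt((pc**2).sum(axis=1) * (oc**2).sum(axis=1))
        ok = den > 0
        out[i, ok] = num[ok] / den[ok]
        flags |= ~ok
    return out, flags


def accuracy(predicted: VoxelResponses, observed: VoxelResponses) -> AccuracyReport:
    """Prediction accuracy: Pearson r per voxel within each session, then
    averaged across sessions."""
    if predicted.values.shape != observed.values.shape:
        raise ValueError("predicted and observed shapes differ")
    if not np.array_equal(predicted.sessions, observed.sessions):
        raise ValueError("session structure differs")
    r_by_session, flags = _session_corr(predicted.values, observed.values, observed.sessions)
    return AccuracyReport(r=r_by_session.mean(axis=0), r_by_session=r_by_session,
                         zero_variance=flags)


def block_permutation_test(
    predicted: VoxelResponses,
    observed: VoxelResponses,
    block_length: float = 20.0,
    n_perm: int = 1000,
    seed: int = 0,
    scheme: str = "block_shuffle",
) -> np.ndarray:
    """Permutation p-values for the session-averaged prediction accuracy.

    The null permutes contiguous blocks of the *predicted* series within each
    session (``scheme="block_shuffle"``) or applies a random circular shift in
    whole blocks (``scheme="circular_shift"``), then recomputes r.
    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    tr = observed.tr
    if block_length < 2 * tr:
        raise ValueError("block_length must be at least 2 TRs")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    block_len = int(round(block_length / tr))
    for s in observed.session_ids:
        if (observed.sessions == s).sum() < 2 * block_len:
            raise ValueError("each session must span at least two blocks")
    obs_report = accuracy(predicted, observed)
    rng = rng_from(seed, 0xB10C)
    sess_ids = observed.session_ids
    sess_blocks = {}
    for s in sess_ids:
        idx = np.flatnonzero(observed.sessions == s)
        starts = np.arange(0, idx.size, block_len)
        sess_blocks[s] = [idx[a:a + block_len] for a in starts]
    count = np.zeros(observed.n_voxels)
    for _ in range(n_perm):
        perm_index = np.empty(observed.n_time, dtype=int)
        for s in sess_ids:
            blocks = sess_blocks[s]
            if scheme == "block_shuffle":
                order = rng.permutation(len(blocks))
            elif scheme == "circular_shift":
                shift = rng.integers(len(blocks))
                order = np.roll(np.arange(len(blocks)), shift)
            else:
                raise ValueError("scheme must be 'block_shuffle' or 'circular_shift'")
            src = np.concatenate([blocks[o] for o in order])
            dst = np.concatenate(blocks)
            perm_index[dst] = src
        null_pred = VoxelResponses(values=predicted.values[:, perm_index],
                                   sessions=observed.sessions, tr=tr)
        null_r = accuracy(null_pred, observed).r
        count += null_r >= obs_report.r
    return (1.0 + count) / (1.0 + n_perm)


def fdr(p: np.ndarray, alpha: float = 0.01) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    p = np.asarray(p, dtype=float)
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q


def noise_ceiling(test_responses: VoxelResponses, n_sim: int = 1000, seed: int = 0) -> np.ndarray:
    """Monte-Carlo noise ceiling per voxel from repeated test responses.

    Per session: the noise variance of the repeat-averaged response is the
    across-repeat variance averaged over time divided by the repeat count; the
    signal variance is the variance of the repeat mean minus that quantity
    (floored at 0). Each simulation draws a Gaussian signal and adds Gaussian
    noise; the ceiling is the median correlation over ``n_sim`` draws,
    averaged across sessions.
    """
    if test_responses.repeats is None or test_responses.repeats.shape[0] < 2:
        raise ValueError("noise ceiling requires at least two repeats; supply VoxelResponses.repeats")
    reps = test_responses.repeats  # (R, V, T)
    n_rep = reps.shape[0]
    rng = rng_from(seed, 0xCE11)
    sess_ids = test_responses.session_ids
    ceilings = np.zeros((sess_ids.size, test_responses.n_voxels))
    for si, s in enumerate(sess_ids):
        m = test_responses.sessions == s
        block = reps[:, :, m]  # (R, V, Ts)
        ts = int(m.sum())
        noise_var_rep = block.var(axis=0, ddof=1).mean(axis=1)  # (V,)
        mean_resp = block.mean(axis=0)  # (V, Ts)
        noise_var_avg = noise_var_rep / n_rep
        sig_var = np.maximum(mean_resp.var(axis=1, ddof=1) - noise_var_avg, 0.0)
        sig_mean = mean_resp.mean(axis=1)
        sig_sd = np.sqrt(sig_var)
        noise_sd = np.sqrt(noise_var_avg)
        corrs = np.zeros((n_sim, test_responses.n_voxels))
        chunk = max(1, min(n_sim, int(5e6 // max(ts * test_responses.n_voxels, 1)) or 1))
        done = 0
        while done < n_sim:
            c = min(chunk, n_sim - done)
            sig = (sig_mean[None, :, None]
                   + sig_sd[None, :, None] * rng.standard_normal((c, test_responses.n_voxels, ts)))
            data = sig + noise_sd[None, :, None] * rng.standard_normal(sig.shape)
            sc = sig - sig.mean(axis=2, keepdims=True)
            dc = data - data.mean(axis=2, keepdims=True)
            num = (sc * dc).sum(axis=2)
            den = np.sqrt((sc**2).sum(axis=2) * (dc**2).sum(axis=2))
            rr = np.zeros_like(num)
            ok = den > 0
            rr[ok] = num[ok] / den[ok]
            corrs[done:done + c] = rr
            done += c
        ceilings[si] = np.median(corrs, axis=0)
    return np.clip(ceilings.mean(axis=0), 0.0, 1.0)


def layer_explained_variance(
    model: EncodingModel,
    bases: feat.PcaBases,
    prepared_features: feat.LayeredFeatureSeries,
    observed: VoxelResponses,
) -> np.ndarray:
    """R-squared (squared session-wise correlation, averaged over sessions)
    of each voxel's response explained by each single layer's features alone
    (all other layers zeroed before projection)."""
    n_layers = prepared_features.n_layers
    r2 = np.zeros((observed.n_voxels, n_layers))
    for l in range(1, n_layers + 1):
        design_l = feat.transform(feat.ablate_to_layer(prepared_features, l), bases)
        pred = predict(model, design_l, sessions=observed.sessions, tr=observed.tr)
        r_by_sess, _ = _session_corr(pred.values, observed.values, observed.sessions)
        r2[:, l - 1] = (r_by_sess**2).mean(axis=0)
    return r2


def assign_layer(layer_r2: np.ndarray, min_r2: float = 0.01):
    """Per-voxel best layer (1-based argmax, ties to the lowest index) and a
    confidence flag (max R-squared at or above ``min_r2``)."""
    layer_r2 = np.asarray(layer_r2, dtype=float)
    assigned = np.argmax(layer_r2, axis=1) + 1
    confident = layer_r2.max(axis=1) >= min_r2
    return assigned, confident
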