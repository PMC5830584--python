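"""Small numeric helpers shared across modules."""
from __future__ import annotations

import numpy as np


def rng_from(seed, *salt) -> np.random.Generator:
    """Independent generator derived from an integer seed and a salt tuple."""
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(s) for s in salt)))


def columnwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between matching columns of two (n, m) arrays.

    Columns with zero variance on either side yield r = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    num = (ac * bc).sum(axis=0)
    den = np.sqrt((ac**2).sum(axis=0) * (bc**2).sum(axis=0))
    out = np.zeros(a.shape[1])
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return np.clip(out, -1.0, 1.0)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    return float(columnwise_pearson(x[:, None], y[:, None])[0])
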