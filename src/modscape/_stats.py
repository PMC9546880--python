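"""Small shared statistical helpers."""

from __future__ import annotations

import numpy as np


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1, where p_(1) <= ... <= p_(m).
    NaN entries propagate as NaN and are excluded from the family size m.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    finite = np.isfinite(p)
    pf = p[finite]
    m = pf.size
    if m == 0:
        return q
    order = np.argsort(pf, kind="mergesort")
    ranked = pf[order] * m / np.arange(1, m + 1)
    qf = np.minimum.accumulate(ranked[::-1])[::-1]
    qf = np.minimum(qf, 1.0)
    out = np.empty(m)
    out[order] = qf
    q[finite] = out
    return q


def zscore(x: np.ndarray, axis: int = -1, ddof: int = 1) -> np.ndarray:
    """Standardize along an axis; raises on zero variance."""
    x = np.asarray(x, dtype=float)
    mu = np.nanmean(x, axis=axis, keepdims=True)
    sd = np.nanstd(x, axis=axis, keepdims=True, ddof=ddof)
    if np.any(sd == 0):
        raise ValueError("cannot z-score a zero-variance vector")
    return (x - mu) / sd
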