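"""p-value adjustment: Bonferroni and Holm (FWER), Benjamini-Hochberg (FDR)."""

from __future__ import annotations

import numpy as np

__all__ = ["adjust"]

_METHODS = ("bonferroni", "holm", "bh", "none")


def adjust(p, method: str = "holm") -> np.ndarray:
    """Adjusted p-values controlling the family-wise error rate or the FDR.

    ``bonferroni``: min(1, m * p_i).  ``holm``: step-down with a running
    maximum over the ascending order.  ``bh``: Benjamini-Hochberg step-up with
    a running minimum of ``m * p_(i) / i`` from the largest p downwards.
    ``none``: identity.  Ties are processed in stable sorted order.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}; got {method!r}")
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(m * p, 1.0)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    if method == "holm":
        adj = np.maximum.accumulate((m - np.arange(m)) * ranked)
    else:  # bh
        adj = np.minimum.accumulate(((m / np.arange(m, 0, -1)) * ranked[::-1]))[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out
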