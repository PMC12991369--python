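"""Exact null distribution of the longest insertion-free run within a gene.

A Tn5 transposon can insert at every base pair, so under non-essentiality the
``h`` insertion sites (IS) observed in a gene of ``b`` bp are modelled as an
unordered uniform draw of ``h`` of the ``b`` positions.  The length ``L`` of an
insertion-free consecutive sequence then has probability mass

    P(L = i) = C(b - i - 1, b - h - i) / C(b - 1, b - h - 1),   1 <= i <= b - h.

The essentiality evidence for an observed longest run ``l`` is the tail
probability ``P(L >= l)``, optionally computed with a *weighted* expected IS
count ``round(h_hat * w)`` (``0 < w <= 1``) so that genes sitting in
low-density genomic regions need a longer run to be called essential.

All binomial coefficients are evaluated through log-gamma, so gene and genome
lengths up to 1e7 are safe.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import gammaln

__all__ = ["iround", "gap_pmf", "connis_sf", "connis_tail"]


def iround(x):
    """Round to the nearest integer, ties going up (0.5 -> 1, 1.5 -> 2).

    The nearest-integer operator used for expected IS counts.  Defined with a
    fixed tie rule so results are reproducible across platforms.
    """
    return np.asarray(np.floor(np.asarray(x, dtype=float) + 0.5), dtype=np.int64)


def _log_binom(n, k):
    """log C(n, k) for integer arrays; -inf outside the support."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    with np.errstate(invalid="ignore"):
        out = gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)
    invalid = (k < 0) | (k > n) | (n < 0)
    return np.where(invalid, -np.inf, out)


def gap_pmf(i, b, h_hat):
    """P(L = i): pmf of the longest-run length for a gene of ``b`` bp with
    ``h_hat`` expected insertion sites.

    Parameters
    ----------
    i : int or array-like
        Run length(s); the support is ``1 <= i <= b - h_hat``.  Values outside
        the support return 0.
    b : int
        Gene length in bp (``b >= 2``).
    h_hat : int
        Expected number of IS in the gene, ``1 <= h_hat < b``.
    """
    b = int(b)
    h_hat = int(h_hat)
    if h_hat < 1 or h_hat >= b:
        raise ValueError(
            f"gap_pmf requires 1 <= h_hat < b; got h_hat={h_hat}, b={b}"
        )
    i_arr = np.atleast_1d(np.asarray(i, dtype=np.int64))
    log_num = _log_binom(b - i_arr - 1, b - h_hat - i_arr)
    log_den = _log_binom(b - 1, b - h_hat - 1)
    pmf = np.exp(log_num - log_den)
    pmf = np.where((i_arr >= 1) & (i_arr <= b - h_hat), pmf, 0.0)
    if np.isscalar(i) or np.ndim(i) == 0:
        return float(pmf[0])
    return pmf


def connis_sf(l, b, h):
    """Exact tail ``P(L >= l)`` for integer effective IS count ``h >= 1``.

    Vectorised over equally shaped ``l``, ``b``, ``h``.  Uses the closed form

        P(L >= l) = C(b - l, h) / C(b - 1, h),

    which is the partial-sum complement of :func:`gap_pmf` (hockey-stick
    identity); ``l <= 1`` gives 1 and ``l > b - h`` gives exactly 0.
    """
    l = np.asarray(l, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    h = np.asarray(h, dtype=np.int64)
    with np.errstate(invalid="ignore"):
        log_sf = _log_binom(b - l, h) - _log_binom(b - 1, h)
    sf = np.exp(log_sf)
    sf = np.where(l <= 1, 1.0, sf)
    sf = np.where(l > b - h, 0.0, sf)
    return np.clip(sf, 0.0, 1.0)


def connis_tail(l, b, h_hat, w=1.0):
    """Weighted ConNIS tail probability of a longest insertion-free run.

    ``P(L >= l)`` for a gene of effective length ``b`` whose expected IS count
    is ``h_hat``, evaluated at the weighted count ``h_eff = round(h_hat * w)``.

    Degenerate regimes: ``h_eff == 0`` (no insertions expected) returns 1;
    ``h_eff >= b`` (weighted density at or above saturation) returns 0 for any
    ``l >= 1`` with a warning.  Scalar inputs return a scalar.

    Parameters
    ----------
    l : observed longest insertion-free run (bp), ``0 <= l <= b``.
    b : effective gene length (bp).
    h_hat : (unweighted) expected IS count, ``>= 0``.
    w : weight in ``(0, 1]`` applied to the expected count.
    """
    if not 0 < w <= 1:
        raise ValueError(f"weight w must be in (0, 1]; got {w}")
    scalar = np.ndim(l) == 0 and np.ndim(b) == 0 and np.ndim(h_hat) == 0
    l = np.atleast_1d(np.asarray(l, dtype=np.int64))
    b = np.atleast_1d(np.asarray(b, dtype=np.int64))
    h_hat = np.atleast_1d(np.asarray(h_hat))
    l, b, h_hat = np.broadcast_arrays(l, b, h_hat)
    h_eff = iround(np.asarray(h_hat, dtype=float) * w)

    out = np.ones(l.shape, dtype=float)
    saturated = h_eff >= b
    if np.any(saturated):
        warnings.warn(
            "weighted expected IS count reaches the gene length for "
            f"{int(saturated.sum())} gene(s); tail probability set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        out[saturated & (l >= 1)] = 0.0
    ok = (~saturated) & (h_eff >= 1)
    if np.any(ok):
        out[ok] = connis_sf(l[ok], b[ok], h_eff[ok])
    if scalar:
        return float(out[0])
    return out
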