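"""Labeling-instability criterion for data-driven tuning-parameter selection.

Observed insertion sites are one realisation of a random process; a good
tuning value should label genes consistently across such realisations.  The
criterion draws ``m`` subsamples of the observed IS (without replacement,
default 50%), labels every gene in every subsample for each candidate tuning
value, models the per-gene label as Bernoulli and averages the estimated
Bernoulli variances over the genes that were labeled essential at least once:

    phi = sum_j pi_j * (1 - pi_j) / q,    q = #{j : pi_j > 0},

so ``phi = 0`` means perfectly consistent labeling and ``phi = 0.25`` is
coin-flip instability.  Very small tuning values that label (nearly) nothing
are uninformative; candidates below the smallest value maximising ``phi``
are discarded, and the selected value minimises ``phi`` over the rest.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone

from .genome import GeneSet, InsertionSiteSet

__all__ = [
    "subsample_insertions",
    "label_matrix",
    "instability_phi",
    "select_tuning",
    "InstabilityTuner",
]


def subsample_insertions(iss: InsertionSiteSet, fraction=0.5, rng=None) -> InsertionSiteSet:
    """Draw ``floor(h * fraction)`` distinct IS positions without replacement.

    Read counts travel with their positions unchanged; the subsample's ``h``
    and ``theta`` follow from the reduced position set.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n_sub = int(np.floor(iss.h * fraction))
    if n_sub < 1:
        raise ValueError(f"fraction {fraction} of h={iss.h} insertion sites is empty")
    rng = np.random.default_rng(rng)
    idx = rng.choice(iss.h, size=n_sub, replace=False)
    idx.sort()
    return InsertionSiteSet(iss.genome_length, iss.positions[idx], iss.counts[idx])


def _subsample_rng(seed, d):
    # per-subsample stream: independent of execution order
    return np.random.default_rng([0 if seed is None else int(seed), int(d)])


def label_matrix(caller, genes: GeneSet, insertions: InsertionSiteSet,
                 m=500, fraction=0.5, seed=0) -> np.ndarray:
    """Boolean genes x m matrix: entry (j, d) is True iff gene ``j`` is called
    essential in subsample ``d`` by ``caller`` (at its current tuning value)."""
    if m < 2:
        raise ValueError("need at least 2 subsamples")
    caller = clone(caller)
    out = np.empty((len(genes), m), dtype=bool)
    for d in range(m):
        sub = subsample_insertions(insertions, fraction, _subsample_rng(seed, d))
        state = caller._prepare(genes, sub)
        out[:, d] = caller._labels_from_state(state)[0]
    return out


def instability_phi(labels: np.ndarray):
    """Evaluate the instability criterion on a genes x m label matrix.

    Returns ``(phi, q, pi_hat)`` where ``pi_hat`` are the per-gene essential
    frequencies, ``q`` counts genes with ``pi_hat > 0`` and ``phi`` is the
    normalised mean Bernoulli variance (0 when ``q`` is 0).
    """
    labels = np.asarray(labels)
    if labels.ndim != 2 or labels.shape[1] < 2:
        raise ValueError("need a genes x m matrix with m >= 2")
    pi_hat = labels.mean(axis=1)
    q = int((pi_hat > 0).sum())
    phi = float((pi_hat * (1.0 - pi_hat)).sum() / q) if q > 0 else 0.0
    return phi, q, pi_hat


def select_tuning(grid, phi):
    """Pick the tuning value by the instability rule.

    ``w_max`` is the smallest grid value attaining the maximum of ``phi``;
    candidates below it are discarded as uninformative, and the selected
    value is the argmin of ``phi`` over the remainder (ties towards the
    smallest value).  Returns ``(selected, w_max)``.
    """
    grid = np.asarray(grid, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if grid.size == 0:
        raise ValueError("empty tuning grid")
    if grid.shape != phi.shape:
        raise ValueError("grid and phi must have the same length")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly ascending")
    i_max = int(np.argmax(phi))  # first index attaining the max
    candidates = phi[i_max:]
    selected = grid[i_max + int(np.argmin(candidates))]  # first argmin = smallest value
    return float(selected), float(grid[i_max])


class InstabilityTuner(BaseEstimator):
    """Meta-estimator selecting a caller's tuning value by labeling instability.

    Parameters
    ----------
    caller : estimator
        Any caller from :mod:`connis.callers`; its ``tuning_param`` attribute
        names the parameter scanned over ``grid``.
    grid : sequence or None
        Candidate tuning values (ascending); defaults to the caller's
        ``default_grid`` (weights 0.1..1.0, or thresholds 2..12).
    m : int, default 500
        Number of IS subsamples.
    fraction : float, default 0.5
        Share of IS drawn (without replacement) into each subsample.
    seed : int, default 0
        Master seed; subsample ``d`` uses the derived stream ``(seed, d)``.
    refit : bool, default True
        Refit the caller on the full data at the selected value.

    Attributes
    ----------
    profile_ : DataFrame with one row per grid value (phi, q, selected flag)
    pi_hat_ : genes x grid matrix of per-gene essential frequencies
    selected_ : the chosen tuning value; ``w_max_`` the informativeness cutoff
    caller_ : the refitted caller (when ``refit``); ``labels_``, ``results_``
        forwarded from it
    """

    def __init__(self, caller, grid=None, m=500, fraction=0.5, seed=0, refit=True):
        self.caller = caller
        self.grid = grid
        self.m = m
        self.fraction = fraction
        self.seed = seed
        self.refit = refit

    def fit(self, genes: GeneSet, insertions: InsertionSiteSet):
        grid = list(self.caller.default_grid if self.grid is None else self.grid)
        if self.m < 2:
            raise ValueError("need at least 2 subsamples")
        param = self.caller.tuning_param
        worker = clone(self.caller)
        p = len(genes)
        counts = np.zeros((p, len(grid)), dtype=np.int64)
        # the same m subsamples are reused across the whole grid; per-subsample
        # work that does not depend on the tuning value is computed once
        for d in range(self.m):
            sub = subsample_insertions(insertions, self.fraction, _subsample_rng(self.seed, d))
            state = worker._prepare(genes, sub)
            for y, value in enumerate(grid):
                worker.set_params(**{param: value})
                counts[:, y] += worker._labels_from_state(state)[0]
        pi_hat = counts / float(self.m)
        q = (pi_hat > 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            phi = np.where(q > 0, (pi_hat * (1.0 - pi_hat)).sum(axis=0) / np.maximum(q, 1), 0.0)
        self.selected_, self.w_max_ = select_tuning(grid, phi)
        self.pi_hat_ = pi_hat
        self.profile_ = pd.DataFrame(
            {
                "value": grid,
                "phi": phi,
                "q": q,
                "informative": np.asarray(grid) >= self.w_max_,
                "selected": np.isclose(grid, self.selected_),
            }
        )
        if self.refit:
            self.caller_ = clone(self.caller).set_params(**{param: self.selected_})
            self.caller_.fit(genes, insertions)
            self.labels_ = self.caller_.labels_
            self.results_ = self.caller_.results_
        return self
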