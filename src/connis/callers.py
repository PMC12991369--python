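"""Essentiality callers as scikit-learn-style estimators.

Every caller is fitted on a ``(GeneSet, InsertionSiteSet)`` pair and exposes
per-gene fitted attributes: ``pvalues_`` (where the method is test-based),
``padjusted_``, boolean ``labels_`` (True = essential) and a ``results_``
DataFrame.  The density-based callers (ConNIS, Binomial, Geometric, Tn5Gaps)
share a weight ``w`` in (0, 1] that down-scales the genome-wide insertion
density, making essential calls harder in sparse regions; the Exp-vs-Gamma
classifier is tuned by a log2 likelihood-ratio threshold ``t`` instead.

Internally ``fit`` splits into ``_prepare`` (everything independent of the
tuning parameter: gene summaries, density, mixture fit) and ``_labels_from_state``
(the tuning-dependent decision), which the instability tuner and the grid
sweep exploit to avoid recomputation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.base import BaseEstimator

from .genome import GeneSet, InsertionSiteSet, filter_min_reads, genome_density, summarize_genes
from .mixture import exp_gamma_label, fit_exp_gamma
from .multitest import adjust
from .nulldist import connis_tail, iround

__all__ = [
    "ConnisCaller",
    "BinomialCaller",
    "GeometricCaller",
    "Tn5GapsCaller",
    "ExpGammaCaller",
    "binomial_pvalue",
    "geometric_pvalue",
    "tn5gaps_pvalue",
    "longest_overlapping_run",
]

_EULER_GAMMA = 0.5772156649015329

WEIGHT_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))
THRESHOLD_GRID = tuple(range(2, 13))


# ---------------------------------------------------------------------------
# stand-alone p-value primitives
# ---------------------------------------------------------------------------

def binomial_pvalue(k, b_eff, theta, w=1.0):
    """Lower-tail binomial p-value: P(X <= k), X ~ Binomial(b_eff, theta*w).

    Essential genes carry fewer insertion sites than expected, hence the
    lower tail.
    """
    p_ins = theta * w
    if not 0 < p_ins < 1:
        raise ValueError(f"need 0 < theta*w < 1; got {p_ins}")
    return binom.cdf(k, b_eff, p_ins)


def geometric_pvalue(l, theta, w=1.0):
    """Geometric tail P(L >= l) = (1 - theta*w)^(l-1), the large-genome limit
    of the exact ConNIS distribution; 1 for l <= 1."""
    p_ins = theta * w
    if not 0 < p_ins < 1:
        raise ValueError(f"need 0 < theta*w < 1; got {p_ins}")
    l = np.asarray(l)
    return np.power(1.0 - p_ins, np.maximum(l - 1, 0))


def tn5gaps_pvalue(l_ov, n, theta, w=1.0):
    """Gumbel (extreme-value) tail for the longest failure run in ``n``
    Bernoulli trials with success (insertion) probability ``theta*w``.

    With q = 1 - p and beta = 1/ln(1/q), the longest failure run is
    approximately Gumbel with location ``mu = ln(n p) * beta`` and scale
    ``beta`` (the expected longest run is ``mu + gamma_Euler * beta - 1/2``);
    the p-value is ``1 - exp(-exp(-(l_ov - mu)/beta))``, clamped to [0, 1].
    This form agrees with direct Monte-Carlo longest-run tail frequencies.
    """
    p_ins = theta * w
    if not 0 < p_ins < 1:
        raise ValueError(f"need 0 < theta*w < 1; got {p_ins}")
    n = np.asarray(n, dtype=float)
    l_ov = np.asarray(l_ov, dtype=float)
    beta = 1.0 / np.log1p(p_ins / (1.0 - p_ins))  # 1 / ln(1/q)
    mu = np.log(n * p_ins) * beta
    with np.errstate(over="ignore"):
        p = -np.expm1(-np.exp(-(l_ov - mu) / beta))
    return np.clip(p, 0.0, 1.0)


def longest_overlapping_run(eff_start, eff_end, iss: InsertionSiteSet):
    """Longest genome-wide insertion-free run intersecting a gene interval.

    Returns ``(l_ov, n)``: the full (non-clipped) length of the longest
    maximal run that overlaps ``[eff_start, eff_end]``, and the trial count
    ``n`` = effective length plus the part of that run falling outside the
    gene.  ``l_ov = 0`` if every overlapping position carries an IS.
    """
    run_starts, run_ends = _genome_runs(iss)
    return _overlap_run_single(eff_start, eff_end, run_starts, run_ends)


def _genome_runs(iss: InsertionSiteSet):
    """Maximal insertion-free runs over the whole (linear) genome."""
    pos = iss.positions
    b = iss.genome_length
    if len(pos) == 0:
        warnings.warn("no insertion sites in the genome; one run spans it all",
                      RuntimeWarning, stacklevel=2)
        return np.array([1]), np.array([b])
    bounds = np.concatenate(([0], pos, [b + 1]))
    starts = bounds[:-1] + 1
    ends = bounds[1:] - 1
    keep = ends >= starts
    return starts[keep], ends[keep]


def _overlap_run_single(s, e, run_starts, run_ends):
    eff_len = e - s + 1
    if len(run_starts) == 0:
        return 0, eff_len
    a = np.searchsorted(run_ends, s, side="left")
    z = np.searchsorted(run_starts, e, side="right")
    if z <= a:
        return 0, eff_len
    lengths = run_ends[a:z] - run_starts[a:z] + 1
    best = a + int(np.argmax(lengths))
    l_ov = int(run_ends[best] - run_starts[best] + 1)
    overlap = min(run_ends[best], e) - max(run_starts[best], s) + 1
    return l_ov, eff_len + (l_ov - overlap)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class _BaseCaller(BaseEstimator):
    """Shared fitting scaffold; subclasses implement the decision rule."""

    #: name of the tunable parameter (targeted by the instability tuner)
    tuning_param: str = "weight"
    #: default candidate grid for that parameter
    default_grid: tuple = WEIGHT_GRID

    def fit(self, genes: GeneSet, insertions: InsertionSiteSet):
        """Compute per-gene essentiality calls.

        Parameters
        ----------
        genes : GeneSet
        insertions : InsertionSiteSet on the same genome
        """
        if not isinstance(genes, GeneSet) or not isinstance(insertions, InsertionSiteSet):
            raise TypeError("fit expects (GeneSet, InsertionSiteSet)")
        if genes.genome_length is not None and genes.genome_length != insertions.genome_length:
            raise ValueError("gene set and insertion set disagree on genome length")
        state = self._prepare(genes, insertions)
        self._store(state, self._labels_from_state(state))
        return self

    def _prepare(self, genes, insertions):
        if self.min_reads > 1:
            insertions = filter_min_reads(insertions, self.min_reads)
        theta = genome_density(insertions)
        summary = summarize_genes(genes, insertions, self.trunc_frac)
        return {"summary": summary, "theta": theta, "insertions": insertions}

    def _store(self, state, labels_and_extras):
        labels, extras = labels_and_extras
        self.summary_ = state["summary"]
        self.theta_ = state["theta"]
        self.labels_ = labels
        self.n_essential_ = int(labels.sum())
        results = state["summary"].copy()
        for col, values in extras.items():
            results[col] = values
        results["label"] = np.where(labels, "essential", "non-essential")
        self.results_ = results
        if "p_value" in extras:
            self.pvalues_ = extras["p_value"]
        if "p_adjusted" in extras:
            self.padjusted_ = extras["p_adjusted"]

    def _adjusted_call(self, p):
        padj = adjust(p, self.correction)
        return padj, padj <= self.alpha


class ConnisCaller(_BaseCaller):
    """Exact test on the longest insertion-free run within each gene.

    For gene ``j`` with effective length ``b_j`` the expected IS count is
    ``h_hat_j = round(b_j * theta)``; the p-value is the exact tail
    probability of a run of at least the observed ``l_j`` under
    ``round(h_hat_j * w)`` uniformly placed insertion sites.  A gene is
    essential when its corrected p-value is at most ``alpha``.

    Parameters
    ----------
    weight : float in (0, 1], default 1.0
        Down-weighting of the genome-wide insertion density.
    alpha : float, default 0.05
        Significance level applied to the corrected p-values.
    correction : {"holm", "bonferroni", "bh", "none"}, default "holm"
    trunc_frac : float in [0, 0.5), default 0.05
        Fraction of each distal gene end excluded before summarising.
    min_reads : int, default 1
        Minimum read count for an insertion site to be retained.
    """

    def __init__(self, weight=1.0, alpha=0.05, correction="holm", trunc_frac=0.05, min_reads=1):
        self.weight = weight
        self.alpha = alpha
        self.correction = correction
        self.trunc_frac = trunc_frac
        self.min_reads = min_reads

    def _labels_from_state(self, state):
        summary, theta = state["summary"], state["theta"]
        b_eff = summary["effective_length"].to_numpy()
        h_hat = iround(b_eff * theta)
        if theta == 0:
            warnings.warn("theta = 0: every ConNIS p-value is 1", RuntimeWarning, stacklevel=2)
            p = np.ones(len(summary))
        else:
            p = connis_tail(summary["l"].to_numpy(), b_eff, h_hat, self.weight)
        padj, labels = self._adjusted_call(p)
        return labels, {
            "h_hat": h_hat,
            "h_eff": iround(h_hat.astype(float) * self.weight),
            "p_value": p,
            "p_adjusted": padj,
        }


class BinomialCaller(_BaseCaller):
    """Lower-tail binomial test on the per-gene insertion-site count."""

    def __init__(self, weight=1.0, alpha=0.05, correction="holm", trunc_frac=0.05, min_reads=1):
        self.weight = weight
        self.alpha = alpha
        self.correction = correction
        self.trunc_frac = trunc_frac
        self.min_reads = min_reads

    def _labels_from_state(self, state):
        summary, theta = state["summary"], state["theta"]
        if theta == 0:
            p = np.ones(len(summary))
        else:
            p = binomial_pvalue(
                summary["k"].to_numpy(), summary["effective_length"].to_numpy(),
                theta, self.weight,
            )
        padj, labels = self._adjusted_call(p)
        return labels, {"p_value": p, "p_adjusted": padj}


class GeometricCaller(_BaseCaller):
    """Geometric tail test on the longest run (large-genome ConNIS limit)."""

    def __init__(self, weight=1.0, alpha=0.05, correction="holm", trunc_frac=0.05, min_reads=1):
        self.weight = weight
        self.alpha = alpha
        self.correction = correction
        self.trunc_frac = trunc_frac
        self.min_reads = min_reads

    def _labels_from_state(self, state):
        summary, theta = state["summary"], state["theta"]
        if theta == 0:
            p = np.ones(len(summary))
        else:
            p = geometric_pvalue(summary["l"].to_numpy(), theta, self.weight)
        padj, labels = self._adjusted_call(p)
        return labels, {"p_value": p, "p_adjusted": padj}


class Tn5GapsCaller(_BaseCaller):
    """Gumbel approximation on the longest genome-wide run overlapping a gene."""

    def __init__(self, weight=1.0, alpha=0.05, correction="holm", trunc_frac=0.05, min_reads=1):
        self.weight = weight
        self.alpha = alpha
        self.correction = correction
        self.trunc_frac = trunc_frac
        self.min_reads = min_reads

    def _prepare(self, genes, insertions):
        state = super()._prepare(genes, insertions)
        summary = state["summary"]
        run_starts, run_ends = _genome_runs(state["insertions"])
        l_ov = np.empty(len(summary), dtype=np.int64)
        n = np.empty(len(summary), dtype=np.int64)
        eff_s = summary["effective_start"].to_numpy()
        eff_e = summary["effective_end"].to_numpy()
        for j in range(len(summary)):
            l_ov[j], n[j] = _overlap_run_single(eff_s[j], eff_e[j], run_starts, run_ends)
        state["l_ov"], state["n_trials"] = l_ov, n
        return state

    def _labels_from_state(self, state):
        theta = state["theta"]
        if theta == 0:
            p = np.ones(len(state["summary"]))
        else:
            p = tn5gaps_pvalue(state["l_ov"], np.maximum(state["n_trials"], 1), theta, self.weight)
        padj, labels = self._adjusted_call(p)
        return labels, {
            "l_ov": state["l_ov"],
            "n_trials": state["n_trials"],
            "p_value": p,
            "p_adjusted": padj,
        }


class ExpGammaCaller(_BaseCaller):
    """Exponential + gamma mixture classifier on gene-wise insertion indices.

    Labels are three-way (essential / ambiguous / non-essential) from the
    log2 component-likelihood ratio against the threshold ``t``; the binary
    ``labels_`` treat ambiguous as non-essential.  No p-values are produced,
    so ``alpha``/``correction`` do not apply to this caller.
    """

    tuning_param = "threshold"
    default_grid = THRESHOLD_GRID

    def __init__(self, threshold=2.0, trunc_frac=0.05, min_reads=1):
        self.threshold = threshold
        self.trunc_frac = trunc_frac
        self.min_reads = min_reads

    def _prepare(self, genes, insertions):
        state = super()._prepare(genes, insertions)
        state["fit"] = fit_exp_gamma(state["summary"]["insertion_index"].to_numpy())
        return state

    def _labels_from_state(self, state):
        labels3, lr = exp_gamma_label(
            state["summary"]["insertion_index"].to_numpy(), state["fit"], self.threshold
        )
        labels = labels3 == "essential"
        self.mixture_ = state["fit"]
        return labels, {"log2_lr": lr, "label3": labels3}


CALLERS = {
    "connis": ConnisCaller,
    "binomial": BinomialCaller,
    "geometric": GeometricCaller,
    "tn5gaps": Tn5GapsCaller,
    "exp_gamma": ExpGammaCaller,
}
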