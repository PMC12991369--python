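"""Confusion metrics (MCC, precision, recall) and tuning-grid sweeps."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone

__all__ = ["ConfusionCounts", "confusion", "mcc", "precision_recall", "sweep"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _as_bool(labels, ids=None):
    if isinstance(labels, pd.Series):
        ids = labels.index.to_numpy() if ids is None else ids
        labels = labels.to_numpy()
    labels = np.asarray(labels)
    if labels.dtype != bool:
        labels = np.char.lower(labels.astype(str)) == "essential"
    return labels, ids


def confusion(truth, predicted) -> ConfusionCounts:
    """Confusion counts with 'essential' as the positive class.

    ``truth`` and ``predicted`` are boolean arrays or Series/arrays of
    'essential'/'non-essential' labels (anything not 'essential', including
    'ambiguous', counts as negative).  Series are aligned on gene_id.
    """
    t, t_ids = _as_bool(truth)
    p, p_ids = _as_bool(predicted)
    if t_ids is not None and p_ids is not None:
        if set(t_ids) != set(p_ids):
            raise ValueError("truth and prediction cover different gene sets")
        order = pd.Series(np.arange(len(p_ids)), index=p_ids)
        p = p[order.loc[t_ids].to_numpy()]
    elif len(t) != len(p):
        raise ValueError("truth and prediction have different lengths")
    return ConfusionCounts(
        tp=int(np.sum(t & p)), fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)), tn=int(np.sum(~t & ~p)),
    )


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1]; 0 when any marginal is 0."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def precision_recall(counts: ConfusionCounts) -> tuple[float, float]:
    """(precision, recall) with the 0/0 -> 0 convention."""
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    return precision, recall


def sweep(caller, genes, insertions, truth, grid=None) -> pd.DataFrame:
    """Evaluate a caller across its tuning grid against ground truth.

    Returns one row per grid value: ``value, n_called, mcc, precision,
    recall``.  The tuning-independent preparation (gene summaries, density,
    mixture fit) is computed once and shared across the grid.
    """
    grid = list(caller.default_grid if grid is None else grid)
    truth_bool, t_ids = _as_bool(truth)
    if t_ids is not None:
        order = pd.Series(np.arange(len(t_ids)), index=t_ids)
        truth_bool = truth_bool[order.loc[genes.ids].to_numpy()]
    worker = clone(caller)
    state = worker._prepare(genes, insertions)
    rows = []
    for value in grid:
        worker.set_params(**{worker.tuning_param: value})
        labels = worker._labels_from_state(state)[0]
        counts = confusion(truth_bool, labels)
        precision, recall = precision_recall(counts)
        rows.append(
            {"value": value, "n_called": int(labels.sum()), "mcc": mcc(counts),
             "precision": precision, "recall": recall}
        )
    return pd.DataFrame(rows)
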