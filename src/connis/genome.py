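"""Data model for gene annotations and insertion-site sets.

Coordinates are 1-based and inclusive throughout (BED input is converted on
read).  An insertion site (IS) is a genome position with at least one mapped
read; the methods model *sites*, so duplicated positions are merged and read
counts only matter for read-count filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GeneAnnotation",
    "GeneSet",
    "InsertionSiteSet",
    "GeneSummary",
    "truncate_gene",
    "filter_min_reads",
    "genome_density",
    "summarize_gene",
    "summarize_genes",
]


@dataclass(frozen=True)
class GeneAnnotation:
    """A single gene interval; ``start``/``end`` 1-based inclusive."""

    gene_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: need 1 <= start <= end, "
                f"got [{self.start}, {self.end}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class GeneSet:
    """An ordered collection of gene intervals with unique identifiers."""

    def __init__(self, ids, starts, ends, strands=None, genome_length=None):
        self.ids = np.asarray(ids, dtype=object)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        if strands is None:
            strands = np.full(len(self.ids), ".", dtype=object)
        self.strands = np.asarray(strands, dtype=object)
        self.genome_length = None if genome_length is None else int(genome_length)
        if not (len(self.ids) == len(self.starts) == len(self.ends) == len(self.strands)):
            raise ValueError("ids, starts, ends, strands must have equal length")
        if len(self.ids) == 0:
            raise ValueError("no gene features")
        if np.any(self.starts < 1) or np.any(self.starts > self.ends):
            raise ValueError("every gene needs 1 <= start <= end")
        if self.genome_length is not None and np.any(self.ends > self.genome_length):
            raise ValueError("gene end exceeds genome length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("gene_id values must be unique")

    @classmethod
    def from_records(cls, genes, genome_length=None):
        genes = list(genes)
        return cls(
            [g.gene_id for g in genes],
            [g.start for g in genes],
            [g.end for g in genes],
            [g.strand for g in genes],
            genome_length=genome_length,
        )

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts + 1

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, j) -> GeneAnnotation:
        return GeneAnnotation(
            str(self.ids[j]), int(self.starts[j]), int(self.ends[j]), str(self.strands[j])
        )

    def __iter__(self):
        for j in range(len(self)):
            yield self[j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.ids,
                "start": self.starts,
                "end": self.ends,
                "strand": self.strands,
                "length": self.lengths,
            }
        )


class InsertionSiteSet:
    """Unique insertion positions with read counts on a genome of ``b`` bp.

    Duplicate positions passed to the constructor have their read counts
    summed.  ``h`` is the number of distinct positions and ``theta = h / b``
    the genome-wide insertion density.
    """

    def __init__(self, genome_length, positions, counts=None):
        self.genome_length = int(genome_length)
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")
        positions = np.asarray(positions, dtype=np.int64)
        if counts is None:
            counts = np.ones(len(positions), dtype=np.int64)
        counts = np.asarray(counts, dtype=np.int64)
        if len(counts) != len(positions):
            raise ValueError("positions and counts must have equal length")
        if len(positions) and (positions.min() < 1 or positions.max() > self.genome_length):
            bad = positions[(positions < 1) | (positions > self.genome_length)][0]
            raise ValueError(
                f"insertion position {bad} outside genome [1, {self.genome_length}]"
            )
        if np.any(counts < 1):
            raise ValueError("read counts must be >= 1")
        # merge duplicate positions, summing reads; keep positions sorted
        if len(positions):
            order = np.argsort(positions, kind="stable")
            positions, counts = positions[order], counts[order]
            uniq, inv = np.unique(positions, return_inverse=True)
            summed = np.zeros(len(uniq), dtype=np.int64)
            np.add.at(summed, inv, counts)
            positions, counts = uniq, summed
        self.positions = positions
        self.counts = counts

    @property
    def h(self) -> int:
        return len(self.positions)

    @property
    def theta(self) -> float:
        return genome_density(self)

    @property
    def sites(self) -> dict:
        return dict(zip(self.positions.tolist(), self.counts.tolist()))


def genome_density(iss: InsertionSiteSet) -> float:
    """Genome-wide insertion density theta = h / b; 0 (with warning) if h = 0."""
    if iss.h == 0:
        warnings.warn(
            "insertion-site set is empty; theta = 0 and every essentiality "
            "method is degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return iss.h / iss.genome_length


def filter_min_reads(iss: InsertionSiteSet, min_reads: int) -> InsertionSiteSet:
    """Drop insertion sites supported by fewer than ``min_reads`` reads."""
    min_reads = int(min_reads)
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    keep = iss.counts >= min_reads
    if not keep.any():
        warnings.warn(
            f"min_reads={min_reads} removed every insertion site",
            RuntimeWarning,
            stacklevel=2,
        )
    return InsertionSiteSet(iss.genome_length, iss.positions[keep], iss.counts[keep])


def truncate_gene(start: int, end: int, trunc_frac: float) -> tuple[int, int]:
    """Trim ``floor(trunc_frac * length)`` bp from each distal end of a gene.

    ``trunc_frac`` must lie in [0, 0.5); the effective interval is therefore
    never empty.  Small genes where the floor evaluates to 0 are unchanged.
    """
    if not 0 <= trunc_frac < 0.5:
        raise ValueError(f"trunc_frac must be in [0, 0.5); got {trunc_frac}")
    b = end - start + 1
    cut = int(np.floor(trunc_frac * b))
    eff_start, eff_end = start + cut, end - cut
    if eff_end < eff_start:  # unreachable for trunc_frac < 0.5; guard anyway
        raise ValueError("truncation emptied the gene interval")
    return eff_start, eff_end


@dataclass(frozen=True)
class GeneSummary:
    """Per-gene effective interval with IS count and longest insertion-free run."""

    gene_id: str
    effective_start: int
    effective_end: int
    k: int  # insertion sites inside the effective interval
    l: int  # longest run of consecutive bp with no insertion site

    @property
    def effective_length(self) -> int:
        return self.effective_end - self.effective_start + 1

    @property
    def insertion_index(self) -> float:
        return self.k / self.effective_length


def summarize_gene(gene: GeneAnnotation, iss: InsertionSiteSet, trunc_frac=0.0) -> GeneSummary:
    """Summarise one gene: IS count ``k`` and longest insertion-free run ``l``.

    Runs are bounded by insertion sites and by the (truncated) interval ends.
    """
    s, e = truncate_gene(gene.start, gene.end, trunc_frac)
    pos = iss.positions
    i0, i1 = np.searchsorted(pos, [s, e + 1])
    seg = pos[i0:i1]
    k = len(seg)
    if k == 0:
        l = e - s + 1
    else:
        l = max(int(seg[0]) - s, e - int(seg[-1]))
        if k > 1:
            l = max(l, int(np.max(np.diff(seg))) - 1)
    return GeneSummary(gene.gene_id, s, e, k, l)


def summarize_genes(
    genes: GeneSet, iss: InsertionSiteSet, trunc_frac: float = 0.0
) -> pd.DataFrame:
    """Vectorised per-gene summaries after distal-end truncation.

    Returns a DataFrame with one row per gene: ``gene_id, start, end, strand,
    effective_start, effective_end, effective_length, k, l, insertion_index``.
    """
    if not 0 <= trunc_frac < 0.5:
        raise ValueError(f"trunc_frac must be in [0, 0.5); got {trunc_frac}")
    b = genes.lengths
    cut = np.floor(trunc_frac * b).astype(np.int64)
    eff_start = genes.starts + cut
    eff_end = genes.ends - cut
    eff_len = eff_end - eff_start + 1

    pos = iss.positions
    i0 = np.searchsorted(pos, eff_start, side="left")
    i1 = np.searchsorted(pos, eff_end, side="right")
    k = i1 - i0
    gaps = np.diff(pos) if len(pos) > 1 else np.empty(0, dtype=np.int64)

    l = np.empty(len(genes), dtype=np.int64)
    for j in range(len(genes)):
        if k[j] == 0:
            l[j] = eff_len[j]
            continue
        first, last = pos[i0[j]], pos[i1[j] - 1]
        lj = max(first - eff_start[j], eff_end[j] - last)
        if k[j] > 1:
            inner = gaps[i0[j] : i1[j] - 1].max() - 1
            if inner > lj:
                lj = inner
        l[j] = lj

    return pd.DataFrame(
        {
            "gene_id": genes.ids,
            "start": genes.starts,
            "end": genes.ends,
            "strand": genes.strands,
            "effective_start": eff_start,
            "effective_end": eff_end,
            "effective_length": eff_len,
            "k": k,
            "l": l,
            "insertion_index": k / eff_len,
        }
    )
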