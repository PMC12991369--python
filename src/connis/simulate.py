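"""Synthetic TraDIS library simulator with known ground truth.

The simulator emulates a bacterial Tn5 library at E. coli scale: a single
linear genome densely packed with genes, an insertion-intensity profile that
is uniform, sinusoidal, or uniform with randomly placed cold spots of reduced
intensity, a subset of essential genes each carrying a contiguous reserved
insertion-free block covering at least a fraction ``c`` of the gene, and an
optional layer of uniformly placed noise insertion sites that ignores the
reserved blocks (label-violating contamination).

Insertion sites are distinct positions drawn without replacement with
probability proportional to the intensity profile (exponential-key weighted
reservoir draw); per-site read counts are geometric.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .genome import GeneSet, InsertionSiteSet

__all__ = ["SimulationConfig", "SimulatedLibrary", "intensity_profile",
           "simulate_gene_layout", "simulate_library", "write_truth", "read_truth"]

from .io import read_truth, write_truth  # re-exported for convenience


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic library.

    Defaults emulate an E. coli-scale genome: 4.6 Mb, 4,000 genes with
    log-normal lengths (median ~900 bp), 300 essential genes.  ``free_fraction``
    is the minimum insertion-free share of each essential gene; ``n_is`` are
    profile-driven insertion sites and ``n_noise`` uniform noise sites.
    """

    genome_length: int = 4_600_000
    n_genes: int = 4_000
    gene_length_median: float = 900.0
    gene_length_sigma: float = 0.45
    min_gene_length: int = 120
    n_essential: int = 300
    free_fraction: float = 0.75
    n_is: int = 200_000
    n_noise: int = 0
    profile: str = "uniform"  # uniform | sinusoidal | coldspots
    amplitude: float = 0.5    # sinusoidal
    cycles: float = 3.0       # sinusoidal
    n_spots: int = 25         # coldspots
    spot_length: int = 10_000
    reduction_factor: float = 10.0
    read_count_p: float = 0.1  # geometric success probability for read counts
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.free_fraction <= 1:
            raise ValueError("free_fraction must be in (0, 1]")
        if self.n_is + self.n_noise > self.genome_length:
            raise ValueError("more insertion sites requested than genome positions")
        if self.profile not in {"uniform", "sinusoidal", "coldspots"}:
            raise ValueError(f"unknown profile {self.profile!r}")

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimulatedLibrary:
    insertions: InsertionSiteSet
    genes: GeneSet
    truth: pd.Series  # index gene_id, values 'essential' / 'non-essential'
    reserved_blocks: dict = field(default_factory=dict)  # gene_id -> (start, end)
    cold_spots: list = field(default_factory=list)  # [(start, end)] when profile=coldspots
    config: SimulationConfig | None = None

    @property
    def essential_ids(self):
        return list(self.truth.index[self.truth == "essential"])


def intensity_profile(config: SimulationConfig, rng=None, return_spots=False):
    """Per-bp insertion intensity (length ``genome_length``), mean ~1.

    ``uniform``: all ones.  ``sinusoidal``: ``1 + A sin(2 pi kappa x / B)``,
    clipped below at 0.01 (amplitudes >= 1 are clipped with a warning).
    ``coldspots``: ones, divided by ``reduction_factor`` inside ``n_spots``
    non-overlapping windows of ``spot_length`` bp placed uniformly (requires
    an rng).  With ``return_spots=True`` also returns the realized
    ``[(start, end)]`` cold-spot windows (empty for the other profiles).
    """
    B = config.genome_length
    if config.profile == "uniform":
        w, spots = np.ones(B), []
    elif config.profile == "sinusoidal":
        A = config.amplitude
        if A >= 1:
            warnings.warn(f"sinusoidal amplitude {A} >= 1; troughs clipped at 0.01",
                          RuntimeWarning, stacklevel=2)
        x = np.arange(1, B + 1)
        w = np.clip(1.0 + A * np.sin(2.0 * np.pi * config.cycles * x / B), 0.01, None)
        spots = []
    else:  # cold spots
        rng = np.random.default_rng(rng)
        w = np.ones(B)
        starts = _place_nonoverlapping(rng, B, config.n_spots, config.spot_length)
        spots = [(s, s + config.spot_length - 1) for s in starts]
        for s, e in spots:
            w[s - 1 : e] /= config.reduction_factor
    if return_spots:
        return w, spots
    return w


def _place_nonoverlapping(rng, B, n_spots, spot_length, max_tries=10_000):
    if n_spots * spot_length > B:
        raise ValueError("cold spots do not fit in the genome")
    placed = []
    for _ in range(max_tries):
        if len(placed) == n_spots:
            break
        s = int(rng.integers(1, B - spot_length + 2))
        if all(s + spot_length <= t or t + spot_length <= s for t in placed):
            placed.append(s)
    if len(placed) < n_spots:
        raise RuntimeError("could not place non-overlapping cold spots")
    return placed


def simulate_gene_layout(config: SimulationConfig, rng) -> GeneSet:
    """Non-overlapping genes tiled along the genome with log-normal lengths
    and exponential-ish intergenic gaps rescaled to fill the genome."""
    p, B = config.n_genes, config.genome_length
    lengths = rng.lognormal(np.log(config.gene_length_median), config.gene_length_sigma, p)
    lengths = np.maximum(np.round(lengths).astype(np.int64), config.min_gene_length)
    total = int(lengths.sum())
    slack = B - total
    if slack < p + 1:
        raise ValueError("genes do not fit into the genome; reduce n_genes or lengths")
    raw_gaps = rng.exponential(1.0, p + 1)
    gaps = np.floor(raw_gaps / raw_gaps.sum() * slack).astype(np.int64)
    gaps[-1] += slack - gaps.sum()  # exact fill
    starts = np.empty(p, dtype=np.int64)
    cursor = 1
    for j in range(p):
        cursor += gaps[j]
        starts[j] = cursor
        cursor += lengths[j]
    ids = np.array([f"g{j + 1:05d}" for j in range(p)], dtype=object)
    strands = np.where(rng.random(p) < 0.5, "+", "-").astype(object)
    return GeneSet(ids, starts, starts + lengths - 1, strands, genome_length=B)


def _weighted_sample_without_replacement(rng, weights, n):
    """Exponential-key (Efraimidis-Spirakis) draw of n distinct indices with
    probability proportional to ``weights``."""
    positive = weights > 0
    if positive.sum() < n:
        raise ValueError("not enough positive-intensity positions to draw from")
    keys = np.full(len(weights), np.inf)
    keys[positive] = rng.exponential(1.0, int(positive.sum())) / weights[positive]
    return np.argpartition(keys, n)[:n]


def simulate_library(config: SimulationConfig, genes: GeneSet | None = None,
                     essential_ids=None) -> SimulatedLibrary:
    """Generate a synthetic library with ground-truth essentiality labels.

    Steps: lay out genes (unless given); pick essential genes; reserve an
    insertion-free block of ``ceil(free_fraction * b_j)`` bp uniformly within
    each essential gene and zero its intensity; draw ``n_is`` distinct
    positions with probability proportional to the intensity; add ``n_noise``
    distinct uniform positions (reserved blocks included); attach geometric
    read counts.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    B = config.genome_length
    if genes is None:
        genes = simulate_gene_layout(config, rng)
    if essential_ids is None:
        if config.n_essential > len(genes):
            raise ValueError("n_essential exceeds the number of genes")
        essential_ids = rng.choice(genes.ids, size=config.n_essential, replace=False)
    essential_ids = set(map(str, essential_ids))

    weights, cold_spots = intensity_profile(config, rng, return_spots=True)
    reserved = {}
    for g in genes:
        if g.gene_id not in essential_ids:
            continue
        block = int(np.ceil(config.free_fraction * g.length))
        off = int(rng.integers(0, g.length - block + 1))
        s = g.start + off
        reserved[g.gene_id] = (s, s + block - 1)
        weights[s - 1 : s - 1 + block] = 0.0

    idx = _weighted_sample_without_replacement(rng, weights, config.n_is)
    positions = np.sort(idx + 1)

    if config.n_noise:
        taken = set(positions.tolist())
        noise = []
        while len(noise) < config.n_noise:
            batch = rng.integers(1, B + 1, size=2 * (config.n_noise - len(noise)) + 16)
            for pos in batch.tolist():
                if pos not in taken:
                    taken.add(pos)
                    noise.append(pos)
                    if len(noise) == config.n_noise:
                        break
        positions = np.sort(np.concatenate([positions, np.array(noise, dtype=np.int64)]))

    counts = rng.geometric(config.read_count_p, size=len(positions))
    iss = InsertionSiteSet(B, positions, counts)
    truth = pd.Series(
        ["essential" if gid in essential_ids else "non-essential" for gid in genes.ids],
        index=pd.Index(genes.ids, name="gene_id"), name="label",
    )
    return SimulatedLibrary(iss, genes, truth, reserved, cold_spots, config)
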