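# Methods

## Exact null distribution of the longest insertion-free run

The core model treats the `ĥ` insertion sites expected in a non-essential
gene of `b` bp as an unordered uniform draw of `ĥ` of the `b` positions.
The pmf of the length `L` of an insertion-free consecutive sequence is

    P(L = i) = C(b − i − 1, b − ĥ − i) / C(b − 1, b − ĥ − 1),  1 ≤ i ≤ b − ĥ.

The test statistic is the tail `P(L ≥ l) = 1 − Σ_{i<l} P(L = i)`.  Writing
`C(b − i − 1, b − ĥ − i) = C(b − i − 1, ĥ − 1)` and applying the hockey-stick
identity collapses the partial sum, giving the closed form used in the code:

    P(L ≥ l) = C(b − l, ĥ) / C(b − 1, ĥ).

This is exercised against both the literal partial sum and a brute-force
enumeration oracle (all `C(b, ĥ)` placements, all maximal runs) in the test
suite.  Binomial coefficients are evaluated in log-gamma space, so genome
lengths up to 1e7 cause no overflow; tails are clamped to [0, 1].

Conventions at the edges, chosen for reproducibility and consistency with
the empty-sum reading of the tail definition:

* `⌊·⌉` rounds to nearest with ties **up** (0.5 → 1).
* `l ≤ 1` ⇒ p = 1 (the sum over `i < l` is empty).
* `⌊ĥ·w⌉ = 0` ⇒ p = 1: with no expected insertions, no gap is remarkable.
* `⌊ĥ·w⌉ ≥ b` ⇒ p = 0 with a warning — outside the model's support.
* `l > b − ĥ` ⇒ p is exactly 0 and is reported as 0, not floored: it is an
  exact statement under the null.
* `ĥ` is computed from the **truncated** (effective) gene length, matching
  the interval on which `l` is measured; mixing full and truncated lengths
  would bias the test.

## Weighting and the competing callers

All density-based callers receive the weight only through `θ → θ·w`
(ConNIS through `ĥ → ⌊ĥ·w⌉`); observed quantities (`k`, `l`) are never
rescaled.  The Geometric tail is `(1 − θw)^(l−1)`, the exponent chosen so
that it is the large-`b` limit of the exact tail (verified numerically to
sup-distance < 0.01 at b = 1e5).  The Binomial caller uses the lower tail
`P(X ≤ k)`, `X ~ Bin(b_eff, θw)`.  Tn5Gaps approximates the longest
genome-wide insertion-free run overlapping a gene by a Gumbel law with scale
`β = 1/ln(1/(1−θw))` and location `μ = ln(n·θw)·β`, where `n` is the gene's
effective length extended by the non-overlapping part of the longest
intersecting run.  The location deliberately excludes the `γβ − 1/2` term —
that term belongs to the *expected* longest run (the Gumbel mean is
`μ + γβ`), and including it in the location shifts every p-value; the chosen
form matches Monte-Carlo longest-run tail frequencies within 0.02 in the
tested regime and the TRANSIT-style construction this caller reconstructs.

The Exp-vs-Gamma classifier fits `π·Exp(λ) + (1−π)·Gamma(s, r)` to gene-wise
insertion indices `d_j = k_j/b_j` by EM (tolerance 1e−8 on the
log-likelihood, ≤ 500 iterations; gamma M-step by weighted MLE through the
digamma equation).  Initialisation splits at the antimode of a smoothed
50-bin histogram; bimodality is accepted only if the valley dips below 60%
of the smaller of the two dominant peaks, otherwise the split falls back to
the 10th percentile with a warning.  Zero indices are displaced to half the
smallest positive index for density evaluation only.  Labels compare the
log2 ratio of the *component* densities to a symmetric threshold `t`
(essential / ambiguous / non-essential); ambiguous maps to non-essential in
all binary metrics — MCC needs binary labels and this is the conservative
direction.

## Multiple testing

Bonferroni, Holm and Benjamini-Hochberg are implemented directly (stable
sort, running max/min) and are checked element-wise against statsmodels on
random vectors as an independent reference.  `m` counts every tested gene,
including genes with p = 1.  The package default is Holm at α = 0.05.

## Instability-based tuning

`m` subsamples (default 500; the benchmark scripts use 100) of a fraction
(default 0.5) of the IS positions are drawn without replacement; read counts
travel along unchanged, since all methods consume positions.  The same `m`
subsamples are reused for every candidate tuning value, and per-subsample
work that does not depend on the tuning value (gene summaries, subsample
density, mixture fit) is computed once.  The per-subsample expected count
enters through the recomputed subsample density `θ_sub = h_sub/b`, i.e.
`ĥ_j^sub = ⌊b_j·θ_sub⌉`.  The correction applied inside subsamples is the
same one used for the final call.  Subsample `d` uses the derived RNG stream
`(seed, d)`, so results are independent of execution order.

`φ = Σ_j π̂_j(1−π̂_j)/q` with `q = #{π̂_j > 0}`; when `q = 0` we define
`φ = 0` (flagged in the profile as uninformative).  Genes with `π̂_j = 1`
stay in `q` — the formula counts every gene ever labeled.  Selection:
`w_max` = smallest candidate attaining `max φ`; candidates `< w_max` are
discarded; the selection is `argmin φ` over the rest, ties to the smallest
value (fewer expected insertions ⇒ fewer calls ⇒ conservative).  On very
clean libraries `φ` can be monotone increasing, in which case the rule
selects the largest (unweighted) value — the criterion is informative
precisely when insertion density varies across the genome.

## Synthetic libraries

The generator emulates an E. coli-scale genome: 4.6 Mb, 4,000 non-overlapping
genes with log-normal lengths (median 900 bp, σ = 0.45, minimum 120 bp),
exponential intergenic gaps rescaled to fill the genome exactly, and 300
essential genes.  Intensity profiles: uniform; sinusoidal
`1 + A·sin(2πκx/B)` with defaults A = 0.5, κ = 3 (visibly non-uniform,
never zero, clipped at 0.01); cold spots — `n_spots` non-overlapping windows
(default 25 × 10 kb) whose intensity is divided by `reduction_factor`
(default 10).  Each essential gene reserves a uniformly placed contiguous
block of `⌈c·b_j⌉` bp whose intensity is zeroed (`c` = minimum insertion-free
fraction); the rest of the gene keeps its profile intensity, so essential
genes may carry IS away from the block.  `n_is` distinct positions are drawn
without replacement with probability proportional to intensity via
exponential keys (Efraimidis–Spirakis); `n_noise` additional distinct
positions are uniform over the whole genome, reserved blocks included —
noise is label-violating contamination.  Read counts are Geometric(0.1).
Circular genomes are treated as linear (no wrap-around runs), and each run
analyses a single sequence.

What the simulator does *not* emulate: read-level artefacts (mapping,
barcodes, sequencing error), replicate structure, gene-length/essentiality
correlation, operon effects, and real biological ambiguity in "essentiality"
itself.  Passing benchmarks on these libraries therefore demonstrates
correctness and calibration of the statistics under the stated generative
assumptions, not field performance on any particular organism.

## Benchmark scale and reported quantities

The acceptance script simulates two benchmark libraries at the full E. coli
scale above — sinusoidal (400,000 IS, c = 0.80, 8,000 noise IS) and
cold-spot (200,000 IS, 25 × 10 kb spots at 1/10, c = 0.75, 4,000 noise IS) —
tunes ConNIS with m = 100 subsamples (a problem size chosen so the whole
pipeline completes in seconds while keeping Monte-Carlo error on φ small),
and reports MCCs at the instability-selected and grid-optimal weights, plus
the analytic maximum (0.25) of the instability criterion.  On the cold-spot
library the selected weight lands at an MCC of ≈ 0.76 — cold spots inflate
false positives for every caller, and the weight trades recall against that
inflation.  On the sinusoidal library the exact test at the selected weight
recovers nearly all essential genes with few false positives (MCC ≈ 0.98);
mild amplitude (A = 0.5) keeps trough densities at half the genome average,
which the weighting absorbs almost entirely.

## Known limitations

* The Tn5Gaps reconstruction follows the extreme-value form validated by
  simulation here; byte-compatibility with TRANSIT output is not a goal.
* The Exp-vs-Gamma fit uses EM; mode-split heuristics used elsewhere may
  give different parameter estimates on the same data.
* Overlapping genes are summarised independently; no merging.
* Multi-chromosome inputs must be analysed one sequence at a time.
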