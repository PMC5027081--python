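# Methods

This note documents the models, algorithms, defaults and design choices
behind `oacgh`, and what its synthetic-data benchmarks do and do not show
about real array data.

## Problem setting

Two-color oligonucleotide array CGH measures somatic DNA copy number as
the fluorescence ratio of test (red) to reference (green) DNA hybridized
to probes tiled across the genome — here a canine-like genome of 38
acrocentric autosomes plus X at ~13 kb probe spacing (~180,000 features).
The pipeline turns per-probe signal pairs into segments of constant copy
number, three-state gain/loss calls, genome-imbalance summaries, and a
subtype classification obtained by co-clustering a sample with labeled
reference tumor cohorts (leukemias, lymphomas, histiocytic malignancies).

## Normalization

Per retained probe the log ratio is `a = log2(r/g)`. The sample is then
centered and scaled genome-wide:

    ProcessedRatio = (a − mode(a)) / MAD(a)

* **Mode.** The mode of a continuous sample is not well defined; we use
  the argmax of a Gaussian KDE with Silverman's bandwidth evaluated on a
  512-point grid spanning the data range, ties to the smallest location.
  Mode centering (rather than mean or median) keeps the neutral state at
  zero even when a large fraction of the genome is aberrant, as in
  heavily rearranged tumor lines.
* **MAD.** Here MAD is the **mean** absolute deviation about the sample
  median — deliberately not the conventional median absolute deviation,
  which is offered as a `statistic="median"` switch for sensitivity
  checks. By construction the scaled output has mean absolute deviation
  exactly 1.
* **QC.** Probes with either channel at or above the saturation cap
  (default 2^16 − 1, a 16-bit scanner full scale) or at or below the
  minimum signal (default 0, excluding nonpositive values whose log is
  undefined) are dropped before any statistic is computed; the exclusion
  count is reported.

## Segmentation (CBS)

Each chromosome's probe series is segmented by circular binary
segmentation: the series is treated as a circle, and the arc `x[i:j]`
maximizing the two-sample t statistic against its complement is tested
against a permutation null (default 1000 permutations, alpha 0.01). A
significant arc contributes its endpoints as change-points and the
sub-segments are re-examined recursively; adjacent segments with equal
means are merged. Numerical notes:

* The t denominator uses the segment-wide sample SD. Since that SD is
  permutation-invariant, the permutation distribution of max|t| — and
  hence the test decision — is identical to the classical statistic's.
* The maximization is exact (every arc), not heuristic: O(n²) via
  cumulative sums, with an O(n)-memory width-sweep fallback above 700
  probes. Ties resolve to the first pair in (i, j) scan order.
* The permutation loop exits early once the exceedance count already
  guarantees p > alpha.
* Chromosomes (or sub-segments) with fewer than `min_width` probes
  (default 3) are left unsplit. Degenerate zero-variance series are
  single segments.
* Segment bp spans partition each chromosome at inter-probe midpoints,
  with the first segment starting at 0 and the last ending at the
  chromosome length. For planted intervals aligned to the probe grid
  this reproduces interval lengths exactly (shifted by half a spacing),
  which keeps percent-genome arithmetic honest on the probe grid.

This in-house CBS stands in for the proprietary segmentation used by
commercial copy-number suites; it makes no attempt to replicate any
particular product's exact boundaries.

## Calling rules

Two rules, both producing per-segment states in {−1, 0, +1}:

* **Threshold rule** — gain if the segment mean is ≥ +0.2 with ≥ 3
  probes, loss if ≤ −0.2 with ≥ 3 probes. Thresholds apply to the
  ProcessedRatio scale (the scale the pipeline's segment means live on);
  on MAD-scaled data ±0.2 is a sensitive cutoff, appropriate for cell
  lines where aberrations are clonal and far exceed it.
* **MAD dichotomization** — gain/loss if the segment mean lies more than
  3 mean-absolute-deviations from the median of the sample's probe-level
  response across all chromosomes (a `basis="segment"` switch computes
  the center and spread from segment means instead).

Both rules are antisymmetric: negating the profile swaps gains and
losses.

## Imbalance metrics

An aberration is a maximal run of adjacent same-state non-neutral
segments. The summary reports gain/loss counts, cumulative megabases,
and percent of genome changed against the total length of non-excluded
chromosomes. X is excluded by default: with a sex-mismatched pooled
reference (the common design when the reference pool is all-female), X
ratios reflect sex, not somatic change.

## Co-clustering classification

Independently segmented samples are projected onto a shared marker grid
(1 Mb bins over non-excluded chromosomes; each bin takes the
length-weighted mean of overlapping segment means, 0 where uncovered —
the projection is idempotent). Rows are scaled per sample by
median/mean-absolute-deviation (consistent with the probe normalization;
per-marker z-scores available) and clustered with Ward's minimum-variance
criterion on Euclidean distances (the Lance–Williams update on squared
distances, via scipy).

A query is classified by cutting the joint tree into k flat clusters and
taking the majority subtype among labeled members of its cluster; an
unlabeled cluster or tied vote falls back to the nearest labeled
neighbor, flagged. The default cut is **k = 2 × (number of cohort
subtypes)**: cutting at exactly the subtype count presumes the top
clades align one-to-one with subtypes, but heterogeneous subtypes split
and similar ones lump, polluting the vote; a finer cut keeps clusters
pure and measurably improves recovery (96.0% vs 89.9% aggregated over
the 20-seed benchmark below) while the fallback covers clusters left
without labels. `k` remains a parameter.

Cell-line relatedness (five-sample scale) uses the same Ward tree over
dichotomized {−1, 0, +1} vectors on the shared grid.

## FISH concordance

Per-locus cell counts over copy-number categories {0, 1, 2, 3, 4, >4}
reduce to the modal category, requiring at least 50 scored cells (the
usual cytogenetic minimum); ties break toward the category nearest 2,
then lower. The modal copy maps to {−1, 0, +1} against a baseline ploidy
of 2 — kept at 2 even for aneuploid lines, matching how side-by-side
array comparisons are conventionally read, but configurable because
hypodiploid lines arguably warrant their modal ploidy. The array state
at a locus is the state of the segment containing the locus midpoint
(BAC inserts are far smaller than segments). Multi-modal, heterogeneous
distributions are reduced by the same modal rule; that is this package's
convention, not a community standard.

## Expression companions

The expression module contracts on an already-normalized log2 matrix
(array preprocessing such as GC-RMA is upstream and out of scope):
median centering per array; a variability filter dropping rows with SD
(n−1 denominator) strictly below the threshold (default 2, boundary
retained); signed fold change against the mean of baseline columns
(2^Δ for Δ ≥ 0, −2^(−Δ) for Δ < 0, so a 3-cycle drop reads −8, matching
the "downregulated N-fold" convention; the >5-fold gene lists use the
signed magnitude); Ward clustering of sample columns; and the
comparative-Ct method 2^(−ΔΔCt) with replicate Cts averaged before ΔCt
and a designated reference gene (default RPL32). ΔΔCt is invariant to
per-sample plate shifts.

## Synthetic data: what it emulates, and what it does not

The generator produces every input with machine-readable planted truth:

* **Genome** — 38 autosomes + X with CanFam2-like lengths (~122 Mb down
  to ~24 Mb, ~2.4 Gb total), plus a toy preset (3 autosomes + X, 1000
  probes at 13 kb) for fast tests.
* **Signals** — green channel lognormal around a baseline intensity
  (default 1000 units, log-SD 0.25), red = green · 2^(shift + noise)
  with Gaussian ratio noise (default SD 0.1 log2 units). The model is
  exactly invertible: at zero noise, log2(r/g) equals the planted shift
  bit-for-bit. Planted shifts default to +0.58 (one extra copy over two)
  and −1.0 (single-copy loss).
* **Cohorts** — subtype signatures are lists of CNA templates with
  per-tumor occurrence frequencies; each sample carries each template by
  an independent Bernoulli draw and adds marker-level Gaussian noise
  (default SD 0.15). The default seven-subtype set places lesions in the
  regions recurrently reported for canine round cell tumors (CDKN2A-
  region loss on CFA 11 plus proximal CFA 22 loss and CFA 29 gain for
  T-cell lymphoma; CFA 13 gain with CFA 14 and proximal CFA 3 loss for
  B-cell lymphoma; distal CFA 1 loss with CFA 12/25 gain and CFA 35 loss
  for ALL; broad multi-chromosome loss plus CFA 13 gain for histiocytic
  malignancy) and invents signatures for AML/T-CLL/B-CLL, which lack
  well-established lesion sets. Frequencies (0.6–0.9) are chosen so that
  a single sampled tumor is identifiable from its profile; the published
  population frequencies of individual lesions (often 10–55%) are too
  weak for that, so these defaults are illustrative study conditions,
  not population estimates.
* **FISH counts** — multinomial over the six categories: the true
  category gets the concordance probability, the remainder splits evenly
  between adjacent categories (entirely to the single neighbor at the
  ends) — the simplest symmetric miscount model.
* **Expression** — planted differential rows shifted by a fixed log2
  effect (default 5) between groups over small within-group noise.

One global seed fans out to fixed per-component substreams, so any
module's inputs can be regenerated independently; all generators are
bit-reproducible.

Not emulated: dye bias, spatial artifacts, wave/GC effects, probe-level
variance heterogeneity, subclonality, contaminating normal tissue, or
any sequence content. Passing benchmarks therefore demonstrate the
correctness of the algorithms under their stated noise models — not
performance on production scanner data, where the QC and normalization
steps carry much more weight.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` use: the 1000-probe toy
genome for normalization and end-to-end recovery; 100 random
single-change-point profiles of 50–200 probes (step = 3 × noise SD)
checked against an exhaustive maximal circular-t oracle; 20 replicate
cohorts of 7 subtypes × 20 reference + 10 query samples each (1400
queries) on the full-genome 1 Mb grid for subtype recovery; 50 random
matrices of ≤ 12 rows against a brute-force Ward agglomeration oracle;
1000 simulated FISH loci at per-cell concordance 0.9 and 50 cells; and a
5000-row expression matrix with 1200 planted high-variance rows. These
sizes make the whole suite run in well under a minute apiece while
leaving the statistical assertions (binomial/CLT bounds, ≥90% recovery,
≥99% concordance) sharp.

## Known limitations

* CBS here tests one split at a time and accepts both endpoints of a
  significant arc; it does not implement the undo/prune refinements of
  mature implementations, and boundary placement on shallow aberrations
  will differ from them.
* The threshold calling rule operates on the ProcessedRatio scale;
  applying ±0.2 to raw log2 ratios instead is a one-line configuration
  but changes sensitivity materially.
* Co-clustering classification inherits Ward's sensitivity to scaling;
  per-sample robust scaling is the default, and per-marker z-scoring can
  reverse rankings when marker variances differ wildly.
* The FISH modal rule collapses genuinely heterogeneous cell populations
  (frequent in chaotic, near-random karyotypes) to one state.
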