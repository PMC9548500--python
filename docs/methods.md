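# Methods

This note documents the models and procedures implemented in `sclonal`, the
parameters that matter, what the synthetic generator does and does not
emulate, and the design choices made where conventions were genuinely open.

## Synthetic data model

The generator emulates multi-tumor droplet scRNA-seq at the level needed to
exercise CNA inference, clonality testing, QC, rank-based DE and editing
calls:

- **Genome.** Autosomes labelled "1".."N" with evenly spaced genes (100 kb
  apart), plus a mitochondrial pseudo-chromosome "MT". Housekeeping genes are
  a flagged subset of autosomal genes.
- **Counts.** Per-gene relative baselines are drawn once from a
  Gamma(shape = 0.5) across genes — the heavy right skew typical of UMI data
  — and shared by every sample. A cell of clone *k* has expected expression
  `baseline(g) × copy_multiplier(k, g) × library_size`, with library sizes
  log-normal per sample (default median 2,000 UMIs, log-sd 0.35). Observed
  counts are negative binomial via the gamma–Poisson mixture with one global
  dispersion (default 2, i.e. variance μ + μ²/2). CNAs act multiplicatively
  on expected expression — the assumption under which expression-smoothing
  CNA inference is well-posed.
- **Categories.** Housekeeping baselines are inflated (30× the mean gene,
  ±20%) so typical singlets clear the housekeeping QC floor; mitochondrial
  baselines are rescaled so MT genes take a controllable share of each
  cell's counts (default 5%).
- **Doublets.** `round(doublet_fraction × planned singlets)` extra cells per
  sample, each the sum of the raw counts of two independently drawn parent
  cells from two distinct classes (uniformly chosen). Purely additive — the
  regime in which a simulated-doublet kNN detector is well-posed.
- **Editing reads.** Each cell receives Poisson(coverage) UMIs with one read
  each; reads from edited (sample, class) strata carry the alternate base
  with probability `edit_rate`, all others with the sequencing-error rate.
  Per-cell alternate-UMI counts are retained as truth.

Not emulated: splicing, batch effects, cell-cycle structure, ambient RNA and
empty droplets, class-specific marker programs (immune classes differ from
malignant cells only through the clone multipliers), PCR duplication within
UMIs. Consequently, passing tests demonstrate correctness of the algorithms
under a clean generative model, not robustness to those real-data artifacts.

## QC

Normalization is `log(count / cell_total × 10,000 + 1)`; natural log by
default, base 2 by flag. "log" is read as natural log, the convention of the
expression-program literature this normalization descends from. Cell filters
(literal boundary semantics): detected genes ≥ 300 and ≤ 3,000, UMIs ≥ 500,
mitochondrial fraction < 0.2, mean normalized housekeeping expression > 0.8,
doublet score < 0.5. The housekeeping mean is computed on the normalized
scale. Genes detected in fewer than 10 *kept* cells are dropped after cell
filtering (cell-level metrics precede the gene-level metric; the order is
fixed here as a convention). Housekeeping genes come from the annotation's
category flag or a user list — no authoritative list is shipped.

The doublet score synthesizes `round(2n)` artificial doublets by summing
random observed cell pairs, embeds observed + simulated cells in 20 PCs of
the top 1,000 variable genes (PCA fitted on observed cells only), and scores
each cell by the fraction *f* of its `k = round(0.5·√n)` nearest neighbours
that are simulated, rescaled by the simulation prior ρ = n_sim/(n_sim+n) to
`f(1−ρ) / (f(1−ρ) + (1−f)ρ)`, so 0.5 means "as doublet-like as a simulated
doublet". The 0.5 threshold is exactly that indifference point. Note the
score separates *heterotypic* doublets; homotypic doublets are invisible to
any expression-profile detector after per-cell normalization.

## CNA inference

Six deterministic steps on normalized expression with immune cells as the
copy-neutral reference: (1) drop genes with mean normalized expression
< 0.1 over all cells; (2) center each gene on its reference mean; (3) clip
to ±3; (4) sort genes by (chromosome, start, gene id) and smooth each cell
within each chromosome by a 101-gene pyramidal (triangular) moving window,
truncated and renormalized at chromosome edges — windows never cross
chromosome boundaries because CNAs are intra-chromosomal; (5) subtract each
cell's median across genes; (6) subtract the post-smoothing per-gene
reference mean, making the reference average exactly zero everywhere. The
defaults (0.1 / ±3 / 101, pyramidal) are the established defaults of the
moving-average CNA-inference method family; all are configurable and logged.
The mitochondrial pseudo-chromosome is excluded from profiles by default
(CNA profiles are autosomal). No HMM denoising or subclustering is applied:
the downstream statistic is a correlation of mean profiles, which smoothed
residuals already support, and the plain chain is fully specified and
oracle-checkable.

Chromosomes are ordered numerically when their labels parse as integers,
lexicographically otherwise; ordering ties within a chromosome are broken by
gene id, which makes the output invariant to input gene/cell order.

## Clonality test

Mean CNA profiles per tumor (arithmetic mean over its malignant cells) are
compared by Pearson r. The null sample is all off-diagonal correlations of
pairs whose *both* members are outside the tested set and which are not
designated related (e.g. known primary/metastasis pairs). Two one-sided
p-value recipes:

- `empirical`: `(1 + #{null ≥ r_obs}) / (1 + N)` — assumption-free, but its
  granularity is limited to 1/(N+1);
- `gaussian` (default): fit a normal to the Fisher-z transformed null and
  take its upper tail. Fisher's z makes a normal tail defensible for a
  statistic bounded in [−1, 1].

The gaussian default reflects that meaningful sub-percent p-values cannot
come from an empirical fraction over a handful of unrelated pairs. Both
methods are label-monotone (p non-increasing in r) and are property-tested
for calibration under the null and power under a shared clone.

## Differential expression and ORA

Group means are taken on the linear normalized scale (`expm1` of the log
values); `log2FC = log2((mean_A + 1)/(mean_B + 1))`. The pseudocount-1
convention of mainstream single-cell toolkits means fold changes of lowly
expressed genes shrink toward 1 — a 2× shift on a gene with near-zero
normalized mean is not recoverable by design, which is why the DE power
experiment simulates its shifted genes on a moderately expressed panel
(gamma shape 2, median library 5,000 UMIs). Genes are tested only when
max(pct_A, pct_B) ≥ 0.1 and |log2FC| ≥ 0.25 (configurable); Bonferroni m is
the number of genes actually tested, which is logged.

The exact Wilcoxon branch computes the full permutation distribution of the
rank sum (midranks for ties) by dynamic programming over the doubled-rank
lattice and doubles the smaller tail; it is used when both groups have ≤ 10
cells. Larger comparisons use scipy's tie- and continuity-corrected normal
approximation, which agrees with exact to < 0.01 at sizes (10, 10).

ORA: for each GMT set, upper-tail hypergeometric p with population =
tested genes, successes = set ∩ universe, draws = thresholded DE genes;
Benjamini–Hochberg q over sets with nonzero overlap with the universe. The
DE thresholds (|FC| > 1.8, adjusted p < 0.05) and the volcano threshold
(1.5) are parameters, not constants.

## Editing detection

Reads below Phred 20 or with base N are discarded; each UMI's base is the
majority among its surviving reads, ties discard the UMI; a cell is edited
with ≥ 1 alternate UMI (configurable), unobserved with no surviving UMI.
Denominators of edited fractions use covered cells only, so sparse coverage
does not deflate fractions. One caveat is documented deliberately: edited
calls are monotone non-increasing in `min_alt_umis` unconditionally, and in
`min_base_quality` whenever quality is constant within a UMI (filtering then
removes whole UMIs); when a single UMI mixes bases across quality strata,
removing a low-quality reference read can flip the majority, so strict
monotonicity in base quality is not a theorem under majority consensus. An
adapter extracts the same read table from SAM/BAM at a 1-based position
using CB/UB tags.

## Pipeline

Stages run in the fixed order simulate → qc → cna → clonality → de → ora →
editing, each only when configured, each writing TSV/MTX outputs and a
report entry with parameters, counts and SHA-256 checksums. Validation
collects every schema problem before any compute (exit code 2); runtime
failures exit 1. One seed drives every random draw, so a rerun with the same
config reproduces every output byte-for-byte — the determinism check in the
acceptance script asserts exactly this.

## Problem sizes used in validation

The clonality recovery study uses 10 tumors of 400 malignant + 200 immune
cells over 2,000 genes (10 chromosomes), 50 replicates; sign recovery uses
20 single-tumor simulations of 800 cells × 500 genes with three random gain/
loss segments each; DE power uses 1,050 genes × 400 cells; doublet detection
uses ~1,100 cells with 10% heterotypic doublets between two clone-separated
classes; editing uses 1,800 cells at coverage 5. These sizes were chosen as
the smallest at which the stochastic properties under test are stable across
seeds.

## Known limitations

- The clonality null requires enough unrelated tumors; with ≤ 3 profiles and
  one tested pair the null is empty and the test refuses to run.
- Reference immune cells share the malignant baseline in simulation, so QC's
  doublet score hovers near the indifference point for homotypic
  neighbourhoods; on data without well-separated classes, the 0.5 threshold
  is conservative (drops borderline cells).
- Expression-inferred CNA levels are relative smoothed residuals, not
  integer copy numbers; no ploidy estimation is attempted.
- ORA tests a thresholded gene list; no ranked-list enrichment with
  permutation normalization is provided.
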