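# Methods

This note documents the statistical model behind each stage of
`camtraits`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions that
matter for reproducibility.

## Study layout and comparisons

The pipeline targets grouped factorial microcosm designs: soil compartment
(bulk vs rhizosphere) crossed with a stress gradient (Cd dose at 0, 20,
100 mg kg⁻¹; dose values are labels, never used numerically). Every
analysis is a pairwise comparison of one treatment cell against the
uncontaminated bulk-soil baseline cell. This reference-community design is
a known limitation: scores are only interpretable relative to the chosen
baseline, and cross-study comparison requires a shared reference.

## KO differential enrichment

Counts for KO *j* in sample *i* are modelled as negative binomial with
mean s_i·μ_g (s_i a sample size factor, μ_g the group mean) and
dispersion α, Var = μ + αμ².

* **Normalization.** Median-of-ratios size factors: per KO, the geometric
  mean across samples (KOs with any zero excluded); per sample, the median
  of count/geometric-mean ratios. Factors are reported unscaled; all
  estimands downstream depend only on factor ratios, so the overall scale
  is immaterial. Tables in which no KO is observed in every sample refuse
  this estimator and direct the caller to an explicit `pseudocount=True`
  (+1) fallback rather than silently changing the data.
* **Dispersion.** Per-KO pooled method of moments on normalized counts:
  within each group the Poisson part μ·mean(1/s) is subtracted from the
  sample variance and the remainder scaled by μ²; group estimates are
  pooled by degrees of freedom and floored at 1e-8. No empirical-Bayes
  shrinkage is applied — the test is deliberately self-contained and
  "DESeq2-like" only in model and normalization, not numerics.
* **Fold change and test.** log2FC = log2(μ̂_t/μ̂_b) of normalized group
  means, with a pseudo-count of ½ entering a group mean only when that
  mean is exactly zero. The delta-method standard error is
  Var(log2 μ̂) = Var(μ̂)/(μ̂² ln²2) with
  Var(μ̂) = n⁻²Σ(μ/s_i + αμ²). The Wald statistic log2FC/SE is referred
  two-sided to Student t with n_t+n_b−2 degrees of freedom. With the
  five-replicate groups this package targets, the moment dispersion is
  noisy and a plain normal reference is measurably anticonservative
  (empirical type-I error ≈ 0.10 at nominal 0.05); the t reference
  restores the nominal rate (≈ 0.05, recomputed by
  `scripts/acceptance.py`) and converges to the normal as replication
  grows.
* **Multiplicity.** Benjamini–Hochberg step-up over all tested KOs
  (delegated to `statsmodels.stats.multitest`). KOs all-zero in both
  groups are untestable and reported separately. Default significance is
  adjusted p < 0.05 with direction given by the fold-change sign; the
  threshold is a declared default, not an estimate.

## Bootstrap pathway enrichment

For a directional enriched-KO set of size *n* within a KO universe of
size *N* (the "collective predicted functional genome": KOs observed in at
least one sample of the comparison), and a pathway with *K* universe KOs:

* **Statistic.** observed hits = |enriched ∩ pathway|; expected hits are
  the pathway hits of random n-subsets of the universe drawn without
  replacement, 1,000 replicates; the statistic is the median of
  (observed − expected) differences. Since observed is constant,
  median(observed − draws) = observed − median(draws); the midpoint
  convention applies to even replicate counts.
* **Null.** Both KO lists drawn at random, 1,000 replicate differences
  sorted ascending; the 5% and 95% limits are the order statistics at
  1-based ranks 50 and 950 (generalized to ⌈0.05R⌉ and ⌊0.95R⌋ for other
  replicate counts). Calls use strict inequalities: a median difference
  equal to a limit is not significant. The null is tabulated per pathway
  and per direction from single differences, not medians of differences —
  the wider, more conservative reading.
* **Sampling.** A single n-subset's hit count is exactly hypergeometric
  (N, K, n), so replicates are drawn from `numpy`'s hypergeometric
  generator rather than materializing subsets; unit tests verify the
  equivalence against enumerated pmfs (χ² GOF) and the null against
  exhaustive subset-pair enumeration (KS distance ≈ 0.002 at 20,000
  replicates).
* **Reproducibility.** Each (comparison, direction) gets an independent
  RNG substream keyed by the master seed, the comparison label (crc32, not
  Python's randomized hash) and the direction index; pathways are
  processed in sorted-id order. Adding comparisons never perturbs earlier
  results. Single-KO pathways are allowed and flagged in output.
* **Empty directions.** An empty enriched set yields all-not_significant
  calls with zero statistics and a logged warning, not an error.

## Under-representation screen

Pathways can accumulate apparent hits purely because their KOs are shared
with other pathways. Before any enrichment call, the same bootstrap runs
with the study's predicted metagenome (KOs nonzero in any sample,
intersected with the reference map) as the observed list and random lists
of the same size from the *full reference map universe* as expected;
pathways whose median difference falls below the 5% limit are excluded
from the final analysis. The screen runs once per pipeline (whole-study
metagenome), while enrichment calls use per-comparison universes.

## CSR classification and scores

The packaged registry freezes curated trait assignments of KEGG pathway
names to Grime classes; curation criteria are: Competitive — investment
in monopolizing local resources (siderophores, antimicrobial
biosynthesis); Stress-tolerant — maintenance of cell integrity in
underproductive or toxic conditions (DNA repair, antioxidant and cofactor
metabolism, proteasome); Ruderal — re-establishment capacity (central
metabolic flux, ribosome, nucleotide and amino-acid biosynthesis).

Registry conventions, asserted at load:

* tallies are 9 C, 6 S, 9 R distinct traits plus six foraging pathways;
* the ABC-transporters trait is conditionally C or S depending on the
  nature of the enriched transporters. It is counted in both the C and S
  tallies and resolves to one class per call via `conditional_as`
  (default S);
* "Carbon metabolism" and "TCA cycle" (the KEGG overview pathway and its
  component) share one central-carbon trait name, so the ruderal tally is
  nine traits over ten pathway names;
* the six foraging pathway names (chemotaxis, motility, sensing) are
  representative synthetic stand-ins — foraging investment does not fit a
  single CSR corner — and sit outside all three axes, as do unregistered
  pathways (reported as unclassified, never dropped);
* cell-wall and membrane-modification pathways are deliberately absent
  from the S class: taxa with non-canonical envelopes (sphingolipid
  membranes, proteinaceous walls) confound their interpretation;
* name matching is case-insensitive and whitespace/punctuation-tolerant.

Per treatment, pathways called enriched in the treatment direction give
class-wise enriched trait sets; pathways called enriched in the baseline
direction give depleted sets; both are de-duplicated at the trait level. A
trait called in both directions is contradictory and raises. The score per
axis is Δ_X = (|enriched_X| − |depleted_X|)/N_X × 100 with N_X the
per-class tally (9/6/9) by default, or the global tally (24) as an option;
per-class scaling follows the convention that each axis is scaled by the
number of traits detected for its class, and bounds every axis to
[−100, 100]. The baseline scored against itself is the origin, and
swapping enriched with depleted negates every axis.

## Synthetic data

The generator emulates the downstream-visible features of a predicted
functional profile:

* **Pathway maps** with uniform sizes in a configurable range (pathways
  with a single KO are legitimate), KO redundancy via an overlap
  probability (a pathway slot reuses an already-assigned KO with that
  probability), and pathway-free KOs in the universe.
* **Counts** negative-binomial in the same mean/dispersion
  parameterization the test assumes, with log-normal library-size factors
  renormalized to geometric mean 1. Defaults: base mean 500 counts per KO,
  dispersion 0.1, library-size CV 0.3, five replicates per cell — the CV
  is a realistic free choice for predicted profiles, whose depth
  distribution is not otherwise constrained. Planted effects multiply the
  means of a fixed random subset of a pathway's KOs by 2^±log2FC in one
  design cell only, and the exact affected subsets are returned as ground
  truth.
* **Draw order** is fixed (library factors, then affected subsets in
  effect order, then the count matrix row-major), so fixtures are stable;
  with CV = 0 no library draw is consumed.

What it does **not** emulate: 16S sequencing, OTU inference, copy-number
correction, or PICRUSt's prediction error; KO counts are conditionally
independent given the design, with no correlation structure beyond
library size. Passing recovery tests therefore demonstrates that the
statistical chain is correct and calibrated under its own model, not that
predicted profiles from real surveys are unbiased.

## Problem sizes and validation summary

The shipped tests and `scripts/acceptance.py` use desk-scale problems
chosen to make Monte-Carlo bounds sharp: oracle comparisons at N ≤ 12
(exact enumeration), calibration at 200 pathways × 1,000-KO universe ×
20 seeds (enrichment-call rate ≈ 0.02 under uniform-random KO sets,
within the [0.01, 0.10] band implied by the rank-950 limit plus
discreteness), and recovery at 40 pathways × 600 KOs with log2FC = 2 on
75% of a ~20-KO pathway (recovered in 100% of 20 seeds; ≤ ~3% of
unplanted pathways called, those mostly via genuinely shared KOs).
Determinism is verified by byte-comparing complete artifact sets of
repeated runs.

## Known limitations

* The NB test is shrinkage-free; at very low counts or extreme dispersion
  its power profile differs from empirical-Bayes tools.
* Enrichment calls inherit the discreteness of order-statistic limits:
  for small universes the attainable significance levels are coarse.
* The registry is a frozen curation; applying it to communities whose
  trait-environment relationships differ from soil systems is
  extrapolation, and no automated de-novo CSR classification is
  attempted.
* Pairwise design: all scores are relative to the configured baseline
  cell.
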