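# Methods

This note documents the statistical model behind `svadist`, the default
parameter values and why they were chosen, what the synthetic-annotation
generator does and does not emulate, and the numerical conventions used
throughout the package.

## 1. Windowed density model

All distribution analyses operate on non-overlapping fixed-width windows
tiling each chromosome (default width 1 Mb). One megabase is the
conventional scale for retrotransposon density profiling: it is large enough
that per-window counts are informative for a family with thousands of
reference copies genome-wide, yet small enough to resolve individual
zinc-finger (ZNF) gene clusters, which span one to a few megabases. The last
window of a chromosome may be shorter than the nominal width and is marked
`is_partial`; correlations can optionally exclude partial windows, and an
assembly-gap mask can flag windows fully covered by gaps.

An interval is assigned to the window containing its **start coordinate**
(`floor(start / window_size)`), so every element is counted exactly once and
the per-window tallies sum to the input size. A midpoint rule is available as
an option. The start rule is preferred for its exact-partition property; at
1 Mb windows and ~2 kb elements the two rules differ for at most the handful
of elements straddling a window boundary.

Counts are tabulated per subfamily (A, B, C, D, E, F, F1), per age class
(old = {A, B, C}, young = {D, E, F, F1}), and for transcripts and RIPs
(retrotransposon insertion polymorphisms).

## 2. Density–transcript correlation

The association between element density and transcript density is summarised
by the Pearson correlation (Spearman optional) of the per-window counts,
computed per chromosome and genome-wide across all chromosomes. Windows on
chromosomes absent from the window grid are tallied and excluded. A
correlation over fewer than three windows, or where either series is
constant, is reported as NaN rather than an arbitrary number.

## 3. Dense-cluster calling

A window is flagged **old-dense** when it carries at least `old_threshold`
old-subfamily elements (default 4) and **young-dense** at
`young_threshold` young elements (default 6). The defaults correspond, at
1 Mb windows, to roughly an order of magnitude over the genome-average
per-window density of each age class in the hg19 reference SVA set, and are
the thresholds under which the bundled dense-locus intervals were called.
Flagged windows are merged into maximal runs of consecutive windows per
chromosome; a run containing both old-dense and young-dense windows is
classed `both`, otherwise it inherits the single class. Raising either
threshold can only shrink the flagged set (monotonicity, enforced by tests).

## 4. Locus characterisation and composition

For a called locus (or any user-supplied interval) the package reports
distinct gene count, transcript count, ZNF gene count and percentage
(gene-symbol patterns `ZNF\d`, `ZKSCAN\d`, `ZSCAN\d`, `ZIK\d`, `ZFP\d` by
default, with user-extensible include/exclude lists), optional KRAB-domain
subsetting against a user gene list, and transcripts/genes per SVA element.
Membership uses the same start-coordinate rule as windowing; user loci given
as 1-based inclusive strings are snapped to window boundaries.

Subfamily composition is compared as percentage shares:
`fold_change(s) = locus_share(s) / genome_share(s)`, rounded to two decimals
(half away from zero). A subfamily absent from the locus has fold 0.00; a
subfamily absent from the genome reference has undefined fold (NaN).
Aggregate folds for the old and young classes are computed from the summed
shares. The bundled genome-wide hg19 shares are A 7.82, B 16.45, C 10.17,
D 44.39, E 4.94, F 13.43, F1 2.80 (percent); the E and F1 shares are the
residual split of the reported combined young-minor share, consistent with
the published per-subfamily fold changes at the ZNF loci.

Element-to-gene proximity annotates each element as within a gene
(any-overlap with a transcript span), upstream or downstream of the nearest
transcript (orientation taken from that transcript's strand) within a
configurable distance (default 10 kb), or intergenic. The genic fraction
(within-gene plus upstream-within-window) is non-decreasing in the upstream
window size.

## 5. KRAB-ZFP enrichment cross-reference

The ChIP-exo binding-enrichment table lists one p-value per protein and SVA
subfamily (A–F; F1 is not separated in the source screen). P-values are
parsed **textually into log10 space** — `log10(p) = log10(mantissa) +
exponent` — because values such as 1.14 × 10⁻³²⁰ underflow an IEEE double to
0.0 if evaluated naively. A protein–subfamily pair is significant when
`log10(p) ≤ log10_alpha` (default −20, i.e. p ≤ 1e-20, an extreme cutoff
relative to the screen's 159 × 6 tests; no further multiple-testing
correction is applied). A protein is retained when significant for at least
one subfamily. Retained proteins are intersected with the dense-locus
intervals under half-open any-overlap semantics, and the containment check
verifies that every old-subfamily (A/B/C) binder lies inside a dense locus.

The bundled dense-locus set extends the chromosome 7 locus to 63–65 Mb: the
ZNF gene cluster there spills into the megabase adjacent to the dense window,
and the published dense-locus membership of ZNF736 (chr7:63.77–63.81 Mb)
requires the extended span.

## 6. Synthetic-annotation generator

The generator draws, per 1 Mb window:

* a gamma multiplier `g ~ Gamma(k, 1/k)` with dispersion `k = 1.5`,
  making transcript counts negative-binomial — transcript density is
  overdispersed relative to Poisson in real genomes;
* transcript count `T ~ Poisson(λ_t · g)` with `λ_t = 26` per Mb, matching
  the order of magnitude of GENCODE transcript density per megabase;
* SVA element count `N ~ Poisson(a + b·T)` with coupling
  `(a, b) = (0.48, 0.015)`. With the transcript model above this yields a
  genome-wide element–transcript Pearson r of ≈ 0.33 at 500 windows and a
  mean density of ≈ 0.87 elements/Mb, the reference-set order of magnitude;
* RIP count with coupling `(0.135, 0.009)` (r ≈ 0.30) drawn from a
  young-only subfamily mixture (D 0.55, E 0.25, F 0.15, F1 0.05) — only
  young subfamilies are retrotranspositionally active;
* subfamily labels from the hg19 composition mixture (§4) unless a planted
  cluster overrides it.

Planted clusters add `extra_rate` elements/window (Poisson) over a set of
windows with their own subfamily mixture, and are recorded in a ground-truth
object whose `true_class` derives from the expected old/young counts versus
the calling thresholds. Elements are canonical 2 kb spans; transcripts are
1–100 kb with about two transcripts per gene; a small fraction of genes
(2%) receive ZNF-style symbols.

Determinism: all draws derive from a single integer seed through
`numpy.random.SeedSequence` with one spawned child stream per chromosome
(sorted order), so outputs are bit-identical for a given configuration and
independent of dict ordering. Replicate and derived seeds are reduced
modulo 2³¹ − 1.

The **cluster-recovery experiment** regenerates the configuration across
replicate seeds, runs the full counting-and-calling chain, and reports
sensitivity (planted windows recovered with the correct class) and
false-positive rate (background windows flagged). At the study condition —
background 0.5 elements/window, plants adding 12/window — sensitivity
exceeds 0.95 with a false-positive rate below 0.001 over 200 replicates.

What the generator does **not** emulate: chromatin state, GC/isochore
structure, assembly gaps, segmental duplications, element truncation and
fragmentation (no split records), strand bias, insertion-site sequence
preferences, and linkage between neighbouring windows beyond the shared
coupling to transcripts. It is a calibration and validation harness, not a
genome simulator.

## 7. Numerical conventions

* Coordinates are 0-based half-open internally (BED convention); locus
  strings for display and user input are 1-based inclusive, with thousands
  separators and Unicode dashes accepted on input.
* Interval overlap is any-overlap under half-open semantics; abutting
  intervals do not overlap.
* Percentages and fold changes are rounded to two decimals, half away from
  zero (`Decimal ROUND_HALF_UP`), to make table values reproducible across
  platforms.
* Undefined quantities (correlation on constant series, fold change with a
  zero genome share, sensitivity with no recoverable plants) are NaN, never
  silently 0.
* Split RepeatMasker records sharing a non-empty ID are merged
  unconditionally; anonymous same-subfamily neighbours merge when
  overlapping or within `merge_max_gap` (default 5000 bp — larger than
  typical L1-mediated interruptions, smaller than the distance between
  independent insertions at reference densities).
* Output tables carry a header with the package version and a 12-hex-digit
  SHA-256 hash of the analysis-relevant configuration (output location and
  timestamping excluded), so identical analyses produce byte-identical
  files.

## 8. Limitations

* The dense-cluster caller is a fixed-threshold scan, not a model-based
  segmentation; thresholds are in elements per window and do not adapt to
  local background.
* The ZFP analysis consumes a pre-computed enrichment table; the package
  does not recompute binding enrichment from reads.
* Genome-wide correlations pool heterogeneous chromosomes; per-chromosome
  values are reported alongside for that reason.
* The bundled reference tables are hg19-based; analyses of other assemblies
  must supply their own annotations and, for composition fold changes, their
  own genome shares.
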