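# Methods

This note documents the models, rules and numerical choices behind each
stage of the pipeline, what the synthetic generators do and do not emulate,
and where the design was genuinely open.

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED convention); 1-based inputs are
converted on read. Interval merging treats touching half-open intervals as
mergeable at `min_gap = 0`, which matches base-level union semantics.
Consensus across sample sets is computed by base-level occupancy: each set
contributes depth 1 over its merged coverage and the consensus keeps bases
with depth ≥ k, merged. Whole-region voting would differ at partial
overlaps; base-level counting was chosen because it is the unique rule
consistent with the union/intersection limits (k = 1 and k = n) and is
directly checkable against a per-base boolean oracle.

Signal tracks are piecewise-constant (bedGraph semantics). Bases without
coverage carry *missing* signal, not zero: anchored aggregation excludes
missing bins from cross-anchor means so unmappable stretches cannot deflate
the flank normalization. Profiles around oriented anchors place the feature
interior on the right half after orientation alignment; `flank_outside`
normalization divides by the mean over the outside-flank bins. Distances to
features are measured to interval midpoints (summits are unavailable in
BED-only input; this is flagged as a choice, not a fact about the data).

## PMD calling

A partially methylated domain is called from one sample's methylome by a
windowed scan: windows of 10 kb placed every 1 kb, a window qualifying iff
it contains at least one CpG and its (equally weighted) mean β is < 0.65.
Qualifying windows are merged and merged regions **over** 100 kb are
reported; regions overlapping assembly-gap annotation by ≥ 1 bp are
discarded. Windows with zero CpGs never qualify — absence of data is not
evidence of hypomethylation. The scan stride is exposed because a denser
stride approximates a running mean at linear cost; 1 kb is the default.
Consensus PMDs keep bases covered in ≥ ⌈f·n⌉ samples (f = 0.5: six of
eleven). Note the strict `<` at 0.65 and strict `>` at 100 kb; the length
cutoff matters at the boundary because qualifying windows extend a called
region up to one window beyond the underlying hypomethylated block.

## DMR calling and the maturation filter

Per-CpG statistics come from Welch's t-test on per-sample β-values at
positions covered in ≥ 2 samples of each group (effect = mean β difference,
group1 − group2). This is a deliberate methodological substitution for
smoothed dispersion-based callers: the contribution here is the threshold
chain and the maturation filter, not the site-level test, and a location
test keeps the chain self-contained. Zero-variance sites get p = 1 when the
groups agree and p = 0 when they differ.

Runs of consecutive CpGs with p < 0.05, same-sign delta and inter-CpG gaps
≤ 500 bp (the gap default is a module choice) form candidate regions;
a region is reported iff its span is ≥ 200 bp and |mean delta| ≥ 0.3
(significance strict, length and effect inclusive).

Because malignant B cells derive from normal B cells at different
maturation stages, a region that also shifts during normal naive → memory
maturation is not disease-specific. The filter keeps a DMR iff
|Δβ_disease − Δβ_maturation| ≥ 0.2, with the maturation delta evaluated at
region level (region-level vs CpG-level averaging was unspecified;
region-level is simpler and the planted scenarios cannot distinguish them).

## Promoter H3K4me3 broadening and nucleosome gain

Peak widths are matched to promoters per sample (widest overlapping peak
wins; promoters lacking a peak in any sample are excluded — only "common"
promoters are tested). A promoter is broadened iff a one-sided exact
Mann-Whitney test on per-sample widths gives p < 0.05 **and** the median
width difference is ≥ 400 bp (inclusive, per-promoter — not a global
median). The rank test replaces an unpublished per-region P-value
procedure; with 11 vs 4 samples the exact null has 1365 arrangements, so
p-values are exact. Nucleosome gain uses the mean H3 signal in a 1,000-bp
window centered on the TSS, library-size normalized per sample, with a
one-sided rank test (disease > control) at p < 0.05; the rank test makes
the call invariant to any common rescaling of the tracks. Note the group
sizes bound the attainable p: with 3 vs 3 the smallest one-sided exact p is
0.05, which cannot clear the strict threshold — at least 4 samples per
group are needed.

## Mixture-based fold-change thresholds

The log2 fold-change distribution is modelled as a three-component Gaussian
mixture: down-regulated, null, up-regulated. The fit is plain 1-D EM on the
raw values (a least-squares fit to histogram counts is available behind a
flag; EM was chosen because it needs no binning decision). Initialization
is deterministic — means at the 10th/50th/90th percentiles, equal weights,
a common sd — so the common path needs no seed; the seed only perturbs the
restarts taken when a component collapses below the sd floor (1e-3), with
an error after five failed restarts. Convergence is declared when the mean
per-observation log-likelihood improves by < 1e-8 in one iteration, and the
log-likelihood is non-decreasing across iterations by construction.

Thresholds are the crossover points of adjacent *weighted* component
densities, w_i·φ_i(x) = w_j·φ_j(x), solved by bracketed root search on the
log-density difference between the component means (|f| driven to machine
precision; an unweighted variant is exposed since the weighting convention
is a choice). Crossovers are exactly equivariant under shift and scale of
the data. If one weighted density dominates the whole bracket there is no
crossover and the degenerate pair is named in the error.

The FDR rule builds N(t) = #{q ≤ t} on a 200-point grid, smooths with an
edge-corrected moving average (width 5 % of the grid), and returns the grid
point of maximum absolute second difference — where the curve bends from
the steep signal regime into the flat noise regime. A bend is accepted only
if the peak curvature exceeds 10× the mean curvature; otherwise (near-linear
curve, i.e. uniform q-values) the upper boundary is returned with a
warning. A single distinct q-value is returned as its own threshold; 2 to
20 distinct values raise an error advising a direct choice, since no
200-point curve can be estimated from them.

## Bidirectional (eRNA) locus detection

Windows of 1 kb slide every 100 bp over the covered extent. A window passes
iff (i) the major strand carries ≥ 10 reads (a floor against ratio tests on
noise; not a published value), (ii) the minor strand carries ≥ 20 % of the
major strand's reads, (iii) the geometry is divergent — the minus-strand
read centroid lies ≥ 100 bp 5′ of the plus-strand centroid and each strand
holds ≥ 60 % of its reads on its own half of the window — and (iv) the
region overlaps no TSS and is not exonic on both strands. "Bimodal shape"
has no published definition; the centroid-separation + half-concentration
operationalization is this module's rule and both parameters are exposed.
Passing windows are merged; the merged locus is extended to whole
overlapping coverage segments and must itself satisfy the minor-ratio rule,
which removes the boundary artifact where a window clipping the major-strand
peak inflates the apparent minor ratio. Annotation exclusion is applied to
the merged loci rather than per window so a TSS-straddling locus cannot
survive through its flanking windows.

## Active-enhancer annotation

Replicate-consistent loci are those of replicate 1 overlapping (≥ 1 bp) a
replicate-2 locus, reported with replicate-1 coordinates. The ±1 kb region
around each locus center (interval midpoint) is kept iff it overlaps a
segment in chromatin state 1 or 9 (the two active-enhancer states of the
12-state segmentation, both carrying H3K4me1 with strong H3K27ac); regions
overlapping a TSS ± 1 kb are dropped, and survivors merged. Consensus uses
base-level occupancy with ≥ 3 disease lists and ≥ 1 (ATAC) or ≥ 2 (eRNA)
control lists; evidence kinds are never mixed in one consensus. The control
minimum is interpreted as the control-side consensus threshold (the
alternative cross-condition reading would make the "NBC set" depend on
disease samples, which contradicts its use as a condition-specific list).

## Single-cell co-accessibility

Cell QC removes cells with integration counts < 0.2× the mean or more than
3 population standard deviations above it; both bounds are computed once on
the original input (carried on the QC'd matrix), never iterated, so
re-application is the identity. Candidate pairs are all same-chromosome
promoter–enhancer pairs with midpoint distance ≤ 100 kb (TAD-sized;
promoter–promoter and enhancer–enhancer pairs excluded). Pair association
is the phi coefficient — Pearson correlation of the two binary columns —
computed across all QC-passed cells; pairs touching a constant column are
skipped and counted.

The calling threshold is derived from the data's own null: each of 100
permutations shuffles every locus column independently across cells,
preserving per-locus open frequencies while destroying all dependence, and
the threshold is the 0.999 quantile of the pooled permuted pair
correlations. The original study reports the resulting value on its cohort
(0.22) but not the rule; the rule — not the value — is the contract here,
and the column-shuffle scheme (vs a marginal-preserving swap scheme) was
chosen for determinism and speed. On the synthetic 400–500-cell panels the
threshold lands near 0.14–0.17.

Pairs called in both conditions (same promoter gene, enhancers overlapping
≥ 1 bp) are class CH; disease-only pairs C; control-only pairs H; each pair
is emitted once. A promoter is *rewired* iff it has ≥ 1 C pair and ≥ 1 H
pair and no CH pair.

## GREN assembly

Enhancer intervals from classified pairs are merged across conditions; a
merged region is CH if it subsumes called pairs from both conditions (or
any CH pair), else it keeps its single class — the class of a merged region
spanning a C and an H pair to *different* genes is undefined in the source
procedure, and the both-conditions rule is this module's documented choice.
Promoters resolve to gene symbols (a promoter→gene map backs pairs without
a gene id; unmappable pairs are dropped and counted), collapsing multiple
TSSs of one gene onto the gene node. Within each class, enhancers are
numbered in (chrom, start) order from 1 (C1, C2, …), independent of input
order. Differential regulators are those with Benjamini-Hochberg adjusted
P < 0.05 (two-sided t-test on activity); deregulated genes need P < 0.01
and |LFC| > 1.7 (both strict; the source notation "−1.7 < LFC > 1.7" is
read as |LFC| > 1.7, the only coherent reading). The graph is a networkx
DiGraph: regulator→gene edges (`regulates`), enhancer→gene edges
(`enhances`), node attributes for kind, selections, chromatin-modifier flag
and enhancer position; serialization is GraphML plus flat node/edge TSVs,
and the round trip is exact. The disease subnetwork keeps the core TFs,
their deregulated targets and selected modifiers, and enhancers linked to
retained genes; dangling enhancers are removed and isolated core TFs are
retained (configurable) for completeness of the picture.

## Synthetic data: what it emulates, what it does not

All generators are pure functions of their parameters and a seed, and every
planted structure is returned as machine-readable truth so recall/precision
of each caller is computable without reaching into generator internals.

- **Methylomes** (defaults: 11 samples, 20-Mb genome, CpG every 100 bp, 15
  PMDs of 150 kb–2 Mb, β means 0.45 inside / 0.85 outside, Beta-distributed
  with concentration 10, 60 % of PMDs shared by all samples, ~30× Poisson
  coverage). PMD lengths are log-uniform — domain sizes span an order of
  magnitude and a uniform draw over the range would exceed the genome in
  expectation — and placement splits the leftover genome into gaps by a
  Dirichlet draw, so placement is deterministic-in-seed and always succeeds
  when capacity allows. Not emulated: CpG density variation (islands,
  deserts), coverage-dependent β noise, intermediate-methylation blocks.
- **DMR scenario** (6 per group, 30 DMRs of 400–800 bp with CpGs every
  25 bp inside vs 200 bp outside, background β 0.75, disease loses
  Δβ = 0.4, 30 % of DMRs carry an equal maturation delta making them
  filterable). Not emulated: coverage dropout, sex/age covariates.
- **Fold-change mixture**: exact draws from the stated 3-component mixture;
  truth includes the analytic crossovers of the true parameters.
- **Stranded coverage**: divergent loci place minus-strand mass 5′ of
  plus-strand mass with minor/major = 0.6; unidirectional loci carry 5 %
  co-located minor mass; extra divergent loci overlapping both-strand exons
  or a TSS are planted as must-exclude truth. Not emulated: read-level
  noise, ragged coverage, overlapping transcription units.
- **scATAC**: loci sit in isolated neighborhoods (one promoter + two
  enhancers within 80 kb; neighborhoods 300 kb apart so pairing never
  crosses them). Unlinked loci open as independent Bernoulli(0.1); a linked
  pair shares a per-cell latent factor (rate 0.5) raising both open
  probabilities by 0.6 when it fires — giving an analytic pair phi of
  0.375 — because the downstream analysis only assumes correlated openness,
  whatever its physical source (contact or co-regulation). Shared links
  appear in both conditions; rewired promoters switch enhancer between
  conditions; 2 low-count and 2 high-count cells per condition exercise QC.
  Not emulated: per-cell depth effects on openness, batch structure,
  transposase sequence bias, copy number.
- **GRN**: 40 regulators × 50 targets from a shared pool (regulon sizes on
  the tens-of-genes scale typical of B-cell networks); 8 regulators get a
  1.5-unit activity shift and 5 of each of their targets a ±2.0 log2
  expression shift at 10 samples per group, so the planted signals clear
  the adj-P < 0.05 and P < 0.01 / |LFC| > 1.7 gates with high margin. DE
  and activity tables are computed from the simulated matrices by t-tests,
  mirroring how such tables arrive as inputs in practice.

Passing tests on these generators show that each caller implements its rule
correctly and recovers structure under the stated noise model; they do not
show robustness to the real-data pathologies listed as not emulated.

## Numerical choices and degenerate inputs

Betas outside [0, 1] by more than 1e-9 are data errors; smaller excursions
are clamped. Zero-coverage windows/bins are missing, not zero, throughout.
The phi of a constant accessibility column is undefined and the pair is
skipped with a count rather than silently set to 0. Root searches use
Brent's method with xtol 1e-12 on the log-density difference. Enhancer-id
assignment breaks ties by (chrom, start, end) lexicographic order. Genomic
scans place windows on multiples of the step anchored at coordinate 0, so
mirror-symmetry properties hold exactly only when the mirrored genome
length is a multiple of the step.

## Problem sizes

The self-validation suite and the acceptance script run the generators at
the default scales above (20-Mb methylomes, 2-Mb DMR genomes, 50,000
mixture draws, 400–500 cells × ~200 loci with 100 permutations), which a
single core completes in well under a minute per stage.

## Known limitations

The per-CpG test ignores coverage (a β observed at 5× counts as much as one
at 60×); the maturation filter assumes a single reference delta per region;
the bidirectionality criterion is a geometric proxy, not a transcription
model; the permutation scheme preserves locus marginals but only
approximately preserves per-cell totals; and the GREN inherits whatever
biases the upstream regulator→target edge list carries.
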