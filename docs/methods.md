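# Methods

## Input model

The pipeline starts from per-sample edit-site tables as produced by an
RNA-editing caller: one row per called site carrying genomic location, edit
type (two nucleotides, e.g. A→G on +, T→C on −), strand, and edited/total
read counts. The on-disk dialect is fixed as six tab-separated columns —
chrom, start (0-based), end (start+1), edit type, strand, `edits:reads` —
chosen to match the shape of caller output while remaining parseable
without the caller installed. All interval files (Alu repeats, gene
features) use BED conventions on disk (0-based, half-open) and 1-based
inclusive coordinates in memory; the conversion is bijective and tested as
its own inverse. Chromosome names are compared as exact strings; an
opt-in flag prefixes bare names with `chr`, because silent renaming hides
input errors.

## Site inclusion and editing indices

A site is admitted per sample when `reads > 5` **and** `edits/reads >
0.05`, both strict, to exclude sequencing-error-level signals; presence of
a site in a sample is defined only after this filter, so a detected but
sub-threshold site counts as absent everywhere downstream. Indices
additionally require detection in ≥ 2 samples of one cohort.

- per-site index: `I_s = mean(r) × n`, the mean edit/read ratio over the
  `n ≥ 2` samples containing the site. The mean runs only over samples
  containing the site — absence is not a ratio of zero. The infimum of
  `I_s` under the defaults is `0.05 × 2 = 0.1`, approached but never
  attained (strict ratio inequality); this analytic floor is what
  `scripts/acceptance.py` recomputes and verifies empirically.
- genome-wide index: `Σ_s I_s` within one cohort; rankings are
  deterministic (descending index, site-key tiebreak).
- per-gene index: `Σ I_s` over sites annotated to the gene. The
  alternative reading — raw edit counts per gene — is also computable from
  the site records, but the index-sum is the default because the
  per-lineage display plots "the editing index". Genes qualify for the
  case/control contrast when they hold **more than 5** sites in either
  cohort; `log2(I_case/I_control)` is reported when both indices are
  positive, otherwise a sentinel (`case_only`, `control_only`,
  `both_zero`) plus the nonzero index — no pseudo-counts, so zero-editing
  genes are visible as categorical extremes rather than being smoothed.

Common-site sets between cohorts A and B: a site is "common" to a cohort
when present (post-filter) in every one of its samples; "not all" of the
other cohort means any presence count strictly below its size, including
zero. The three sets (A-only, B-only, shared) are disjoint by
construction, mean ratios are reported per cohort (never pooled), and the
set sizes are compared with a two-cell χ² goodness-of-fit test against an
equal split — the minimal test of "do the cohorts yield the same number of
qualifying sites", with df = 1.

## Annotation

Point-in-interval classification assigns each site a feature class and Alu
membership. When intervals overlap, precedence is 3′UTR > 5′UTR > ncRNA >
intron (UTR editing being the biological focus); within one class the gene
whose feature start is nearest wins, with gene id as the final
deterministic tiebreak. A site covered by no gene feature is intergenic
(and only those sites have no gene). Strand is ignored for membership by
default — repeat databases and editing callers do not always agree on
strand conventions — with a strict-strand switch available. `in_alu` is
true iff any covering repeat belongs to family `Alu`.

Edited Alu DNA templates are built by substituting G for A at declared
1-based positions (every declared position must hold an A; violations
raise with the position named) and prepending a promoter — the canonical
18-nt SP6 sequence by default, overridable — to both the unedited and
edited constructs for synthesis export as FASTA.

## Lineage comparison

Lineage-defining genes are selected from single-cell marker statistics:
pct1 (fraction of cells in the cluster expressing the gene) over pct2
(fraction in all other clusters) strictly above 10; pct2 = 0 with pct1 > 0
counts as an infinite ratio and selects. Per lineage, the unit of
observation is the **gene**: the vectors of per-gene editing indices in
control and case are compared with Welch's unpaired t-test. This reading
is forced by the degrees of freedom such comparisons report (e.g. df ≈ 129
for 83 genes, consistent only with per-gene observations under
Welch–Satterthwaite). Two deliberate choices: (i) per-gene indices for
this analysis are summed over all qualifying sites with *no*
minimum-sites-per-gene filter (that filter belongs to the gene-contrast
figure, not the lineage screen), and (ii) genes with no qualifying sites
contribute index 0 rather than being dropped — excluding them would delete
genes asymmetrically under uniform loss and bias the comparison. Lineages
with fewer than 3 genes, or zero variance in both cohorts, are flagged
untestable rather than given a p-value.

## Expression screens

The per-sample ratio screen divides each sample's expression of a gene by
the control-cohort mean and categorises with strict cutoffs (under < 0.5,
over > 2.0). It operates on raw counts by default — cohorts with matched
library sizes need no further normalisation and the published readout was
count-based — with FPKM (`count × 1e9 / (length × library size)`) as a
switch. Genes whose control mean is zero are flagged unevaluable, never
silently dropped.

Panel fold changes are transparent normalized ratios rather than a
shrinkage-based differential-expression fit: per gene,
`log2(mean FPKM_case / mean FPKM_control)` with a delta-method standard
error. Significance comes from label permutations (10,000 by default,
seeded): the permutation statistic is the difference in cohort means of
`log2(x + 1)`, which stays finite when a permuted group mean is zero; the
reported effect size remains the log-ratio of means. Benjamini–Hochberg
adjustment runs across all panel genes screened in one call, and the FDR
flag marks adjusted p > 0.05. Each panel is also tested with a two-way
fixed-effects ANOVA (factors gene and cohort) on `log2(x + 1)`.

## Statistical procedures

Welch's t (with Welch–Satterthwaite df), χ² goodness of fit, BH step-up,
and one-/two-way ANOVA are implemented from their closed forms; SciPy
supplies only distribution tails. All p-values are two-sided. The two-way
ANOVA covers balanced designs with ≥ 2 replicates per cell (the classical
sum-of-squares decomposition); unbalanced input raises, since all designs
this pipeline produces (equal cohort sizes crossed with genes) are
balanced. Kruskal–Wallis is a thin wrapper over SciPy with a hand-written
Dunn post hoc (rank z-tests with tie correction); neither is attached to a
pipeline stage. The test suite cross-checks every statistic against
scipy/statsmodels to 1e-8 on random instances — those libraries act as
independent oracles only, never as the implementation.

## Synthetic-data generator

`simulate_truth` draws, per gene, a Poisson number of editing sites
(mean 10; a negative-binomial dispersion is available), places them with
~400-base spacing on a synthetic genome, samples each site's feature class
(intron 0.60, 3′UTR 0.25, 5′UTR 0.05, ncRNA 0.10), puts 90% inside
300-base Alu intervals, and adds ~5% intergenic sites — matching the
empirical composition of editing catalogues (> 90% Alu, predominantly
intronic/UTR). True per-site edit ratios are Beta(2, 5) (mean ≈ 0.29), so
the bulk of sites sit well clear of the 0.05 inclusion threshold; the case
cohort's ratios are the control ratios times a single **retention** factor
in (0, 1] — uniform loss across lineages — with per-lineage overrides to
simulate the alternative, localized-loss scenario. `simulate_cohorts`
then draws, per sample and site, negative-binomial read depth (mean 60,
size 8; floored at one read) and binomial edited reads, emitting a site
only when at least one edited read is sampled, as a caller would. Cohort
sizes default to 7 + 7.

`simulate_expression` produces negative-binomial counts (size 100, i.e.
~10% biological CV, the regime of deeply sequenced matched tissue) over
8 named RBP genes, 25-gene ISG and NF-κB panels, and 2,000 background
genes. The background is deliberately large so the panels are a small
fraction of the library: per-million normalisation against a small
transcriptome would otherwise absorb part of any injected panel fold
change (a compositional artefact, not a property of real data). Panel
folds apply to all case samples; the RBP knockdown factor applies to a
designated subset of case samples only.

All randomness flows from one integer seed through independent
`SeedSequence` child streams (truth / cohorts / expression), so outputs
are byte-reproducible and the three generators can be called in any order.

What the generator does **not** emulate: nucleotide sequence content and
double-stranded RNA structure, correlated editing across neighbouring
sites, sample-level covariates (age, sex, RNA quality), cell-composition
shifts, and library-size imbalance. Passing tests therefore demonstrate
the correctness and calibration of the *analysis* under the stated
stochastic model, not robustness to those real-data complications.

A structural consequence worth knowing: because case truth is defined as a
deterministic transform of control truth (same sites, same Beta draws),
the per-gene index vectors of the two cohorts share all between-gene
variance. Welch's unpaired test on such gene-paired data is conservative
— at retention 1.0 the suite measures a per-lineage rejection rate of
essentially zero at α = 0.05, far below nominal. The same pairing (same
genes in both cohorts) exists in real studies of this design, so the
lineage p-values should be read as conservative bounds; a paired test on
per-gene differences would be the calibrated alternative and is left to
future work.

## Problem sizes and numerical choices

The test suite exercises the pipeline at 40–700 genes (up to ~7,000 sites
× 14 samples), 200-replicate null calibrations, and 200 random brute-force
instances for set logic — sizes chosen so the whole suite runs in well
under a minute while keeping Monte-Carlo error small relative to the
asserted margins. Round-trip I/O is exact for integers and 1e-9 for
reals; the gene + intergenic partition of the genome-wide index is
asserted to 1e-9; rank orderings break ties by site key so every output
is deterministic. Degenerate inputs (empty cohorts, both-zero χ² cells,
zero-variance Welch, zero control means, empty annotation sets) raise or
flag explicitly rather than propagating NaNs.

## Known limitations

- Edit-site calling, alignment and pileup are out of scope; the pipeline
  trusts the caller's tables.
- The per-gene index sums site indices; an edit-count-based variant is
  computable but not the default (see above).
- Fold-change p-values are permutation-based on 14-sample designs, so the
  attainable p floor is ~1/(n_permutations+1) and discreteness matters at
  small cohort sizes.
- The two-way ANOVA requires balance; unbalanced cohort designs must be
  subsampled or analysed externally.
- The lineage Welch test is conservative under the null for the reason
  described above.
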