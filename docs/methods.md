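# Methods

## The problem and the model

A lung adenocarcinoma that contains both lepidic (LEP) and micropapillary
(MIP) growth patterns can be micro-dissected so that each component is
exome-sequenced on its own. If the two components descend from one
initiating clone, mutations of that clone appear in both components at
cancer cell fraction (CCF) ≈ 1, while later mutations are private to one
component or subclonal within it. The package quantifies that structure:
filter the somatic calls, estimate per-mutation CCF with uncertainty,
label clonality, summarise ITH at the mutation and copy-number level,
assemble a two-leaf trunk/branch phylogeny per patient, and compare the
two groups.

## CCF estimation

For a mutation with variant allele frequency `VAF = alt/(alt+ref)` in a
sample of purity `p`, lying on a segment of total copy number `CN_t`, with
mutation multiplicity `m` (copies of the mutant allele per tumor cell):

    CCF = VAF · (p·CN_t + 2(1−p)) / (p·m)

This is a deliberate simplification of joint purity/ploidy optimisation:
purity and allele-specific copy number are taken as given (from metadata
and the segment table), and `m` is estimated per mutation by rounding
`VAF·(p·CN_t + 2(1−p))/p` and clamping to `[1, major_cn]`. In diploid
regions `m = 1` and the formula reduces to `CCF = 2·VAF/p · (…)`
correctly hitting the two sanity anchors: VAF 0.25 at purity 0.5 and VAF
0.5 at purity 1 both give CCF 1.

**Uncertainty.** The 95% CI is the exact (Clopper–Pearson) binomial CI on
the VAF pushed through the same linear map. It is *not* truncated at 1:
the clonality rule below needs the upper bound to be able to exceed 1.
The clonal probability is the posterior mass of CCF ≥ 0.9 under a flat
Beta(alt+1, ref+1) prior on the VAF. The CCF threshold 0.9, the CI level
(α = 0.05) and the probability cutoff 0.5 are all exposed parameters.

**Clonality rule.** `clonal ⇔ P(CCF ≥ 0.9) > 0.5 AND CI_high ≥ 1`; the
boundary `CI_high = 1` counts as clonal by default (a `strict_ci` flag
demands strict excess). Everything else is subclonal.

## Mutation-level ITH

- MATH = `100 · 1.4826 · median(|VAF − median(VAF)|) / median(VAF)`,
  computed on each sample's filtered mutations (a flag switches to
  unfiltered input if callers prefer).
- Clonal TMB = clonal mutation count per Mb of capture; the default
  capture size is 53 Mb (a custom whole-exon capture design).
- Subclonal mutation proportion = subclonal count / total calls.

## Variant filter

Four rules in fixed order, each recorded in the report: population
frequency ≤ 0.01 (a missing annotation means "never observed" and
passes); alt-supporting reads strictly greater than 3 ("supporting reads"
means alt-allele reads, the standard somatic-QC usage, not total depth);
VAF ≥ 0.01; drop synonymous and noncoding classes. The chain is
idempotent and order-insensitive. Cancer-gene subsetting is exact,
case-sensitive symbol matching (plus records already flagged upstream).

## SCNA handling

Copy-neutral LOH (`total_cn = 2`, `minor_cn = 0`) is flagged first and
excluded from all clonality-based metrics — CNLOH is invisible to total
copy number yet is not a "neutral" state, so leaving it in would dilute
the subclonal fractions. A segment is *altered* when its total copy
number differs from the rounded sample ploidy, and *subclonal* when its
segment-level CCF falls below 0.9 (configurable; the synthetic truth
supplies segment CCFs, real data would take them from an allele-specific
caller). The subclonal-SCNA *proportion* is on a segment-count basis and
the subclonal *genome fraction* is length-weighted over the total
segmented length — both are computed because the two conventions answer
slightly different questions; an undefined proportion (no altered
segments) is reported as missing, never as 0. Arm and chromosome burdens
are altered length over arm/chromosome length (over segmented length when
true lengths are unavailable), reported as continuous fractions rather
than a 50%-of-arm binarization.

Focal calls test each gene's log2 ratio against a normal-panel baseline:
`z = (log2 − mean)/sd`, two-sided normal p, BH across the genes of one
sample, and a call additionally requires `|log2| ≥ 0.2` so statistically
significant but biologically trivial wobbles are never labelled. Gene
copy number is the copy number of the segment covering the gene midpoint
— deterministic and robust for genes straddling a breakpoint.

Note what FDR control does and does not promise here: with 10 strong
planted effects among 100 genes, BH at q = 0.05 admits ≈ 0.5 false
discoveries per sample *by design* (5% of ~10.5 discoveries). Recovery of
all planted genes is near-certain (≥ 95% of replicates at |log2| = 0.8,
sd = 0.15); a replicate with zero false calls is *not* near-certain, and
the tests assert the former plus an FDR-consistent false-call count. Under
a global null the chance of any call stays below q (+ Monte-Carlo slack).

## Pair phylogeny

Mutation identity is the genomic key (chrom, pos, ref, alt) — two
different mutations in one gene stay distinct. The trunk is the set of
mutations shared by both components **and** clonal in both; private
mutations form the branches; shared-but-not-bi-clonal mutations are kept
as a separate annotated class rather than silently forced onto the trunk
or a branch. Focal SCNAs identical in gene and direction in both
components decorate the trunk. Each shared mutation also gets a
clonality-transition label (stable-clonal, stable-subclonal, and the two
LEP→MIP switches). Newick output is `(LEP:b1,MIP:b2):t;` with branch
lengths = private counts and root length = trunk count.

**A coverage fact worth knowing.** Because trunk membership demands the
95% CCF CI reach 1 in *both* components, a truly clonal mutation fails in
one component with probability up to α/2 — independent of depth. Expected
bi-clonal trunk recall is therefore ≈ (1 − α/2)² ≈ 0.95, never 1, and the
probability that a 30-mutation trunk is recovered *exactly* is only
≈ 0.975⁶⁰ ≈ 0.2 per pair. The *shared* set, by contrast, is exact at high
depth (private mutations cannot leak across components, and every truncal
site is observed). Both counts are reported per tree; recovery
experiments assert exactness on the shared set and the ≈ 0.95 recall on
the bi-clonal trunk.

## Cohort statistics

Fisher's exact test is two-sided by the minimum-likelihood convention
(sum of hypergeometric probabilities ≤ the observed table's); an all-zero
table returns p = 1 by convention. BH adjustment is the standard step-up.
The Mann–Whitney test is exact by full enumeration of group assignments
whenever the pooled size is ≤ 12 — the 5-vs-6 component cohorts this
package targets make the normal approximation dubious — with ties counted
half in U and "at least as extreme" measured as distance from the null
mean n₁n₂/2; larger samples use the tie-corrected normal approximation.
Spearman is Pearson on mid-ranks and returns missing (not 0) for a
constant vector. The one-sided t-test is Welch's; two zero-variance equal
groups return p = 0.5 by symmetry. Every statistic is checked in the test
suite against an independent brute-force oracle (full hypergeometric
enumeration, an independent step-up, permutation enumeration, rank-then-
Pearson, the textbook Welch formula).

BH families: adjustment is applied within one analysis table at a time
(the genes of one sample's focal calls; the steps of one immune
comparison; the rows of one alteration-frequency table).

## ssGSEA step activities

Per sample, genes are ranked by expression descending with ties broken by
gene name (determinism); the score is the integrated difference between
the weighted in-set ECDF (weights `|rank value|^α`, α = 0.25 by default)
and the uniform out-of-set ECDF, summed over all list positions. The raw
score depends only on within-sample ranks — strictly monotone transforms
of a sample's expression leave it unchanged — and an optional per-step
min-max normalization across samples (on by default, switchable off) puts
steps on a common scale without affecting rank-based group tests.

One systemic property to keep in mind: a strong planted shift on one gene
set displaces other sets' genes down the ranked list in the shifted
group, so unshifted steps can drift slightly in the *opposite* direction.
This is inherent to rank-based single-sample scoring, not an artifact of
this implementation; the group comparison therefore asks whether the
planted step is the top BH hit with the right direction, which it is in
every seeded power replicate.

## The synthetic cohort

`SimulationConfig` defaults are the study conditions: 5 patient pairs;
per-site depth ~ Poisson(500) floored at 30 (deep FFPE-like exome
coverage with a floor so no site has a degenerate CI); purity uniform in
(0.2, 0.9); 30 truncal, 10 private-clonal and 20 private-subclonal
mutations per component with subclonal CCF uniform in (0.1, 0.4); 40
copy segments per genome of which half are altered, 20% (LEP) vs 60%
(MIP) of altered segments subclonal, and 10% CNLOH; a 400-gene synthetic
exome laid out deterministically over 22 chromosomes with one reserved
EGFR-like truncal driver locus on chromosome 7. Observed alt counts are
Binomial(depth, E[VAF]) with
`E[VAF] = p·m·CCF / (p·CN_t + 2(1−p))`; multiplicity is 1 in diploid
regions and uniform on {1..major_cn} in gains. Everything is
deterministic given (seed, pair index), and the truth file records the
planted sets, per-sample purity and per-segment clonal/CNLOH flags.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: sequencing error and strand bias, FFPE artifact
chemistry (OxoG/deamination), mapping ambiguity, purity/ploidy estimation
error (purity is given, not inferred), clone trees deeper than one
subclone per branch, and germline contamination. Expression matrices are
log-scale Gaussian with planted mean shifts; real bulk RNA-seq dispersion
and compositional effects are not modelled.

## Numerical and design choices

- Coordinates 1-based inclusive (SEG convention); `chr` prefixes
  stripped on input.
- Readers are strict: missing columns name the column, bad values name
  the 1-based line, overlapping segments name both rows; no row is ever
  silently dropped.
- Exact-MWU cutoff at pooled n = 12 (enumeration ≤ C(12,6) = 924
  assignments).
- Fisher two-sided comparisons use a 1e−7 relative tolerance on pmf
  equality, matching the minimum-likelihood convention's usual guard.
- The clonality boundary `CI_high = 1` counts as clonal (the untruncated
  CI can land exactly on 1); a strictness flag is exposed.
- Pipeline outputs are written in sorted, rounded form so a rerun under
  the same config and seed is byte-identical.
- The bundled example tables (per-gene alteration summary of a 5 LEP / 6
  MIP paired cohort; 286-patient histological composition) are inputs for
  the tally and comparison machinery; the per-sample expansion of the
  summary assigns carriers deterministically and gives every altered
  sample at least one mutation record (one printed mutation tally is
  internally inconsistent with its own carrier count and is reconciled
  that way). The bundled immune-cycle gene sets are synthetic stand-ins
  sized for testing, not curated signatures.

## Problem sizes

The recovery and calibration studies run at: clonality recovery on 5
pairs × 120 mutations at depth 1000 and purity 0.8; trunk recovery at
depth 2000; subclonal-SCNA power over 100 replicates of 10-pair cohorts;
immune-shift power and null calibration over 100 replicates of 20-vs-20
samples × 200 genes; focal null calibration over 500 replicates of 100
genes; Mann–Whitney type-I calibration over 2000 replicates of 30-vs-30.
These sizes give Monte-Carlo standard errors comfortably inside the
asserted margins while keeping a full run in the tens of seconds.

## Known limitations

CCF estimation trusts the supplied purity and segment calls; errors there
propagate linearly. Multiplicity rounding can mis-assign `m` for low-VAF
mutations in high-amplitude gains. The focal caller assumes an adequate
normal panel (per-gene Gaussian baseline) and does not model GC or
length biases. The two-leaf phylogeny is deliberately minimal — it is a
bookkeeping of shared/private clonality, not clone-tree inference from
CCF clusters, and supports exactly two components per patient.
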