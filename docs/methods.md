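# Methods

This note documents the statistical models, numerical choices and known
limitations of dmrkit, in the order the pipeline applies them.

## Coordinates and tags

All coordinates are 0-based half-open (BED convention); conversion to
other dialects happens only at I/O boundaries. A sequenced tag is reduced
to its 5′ position, strand and sample label — every downstream operation
uses the shifted 5′ position, so read length (typically 36 bp) is
metadata only. Duplicate tags (same sample, chromosome, position, strand)
are removed once, before peak calling and counting, on the PCR-duplicate
rationale.

## Candidate region discovery

The caller is a deliberate single-scale simplification of the MACS 1.4
family. Tag 5′ positions are shifted a fixed 75 bp toward the fragment
centre (no fragment-model building). A window of width 2 × shift slides
at a step of shift/2; for an ordered (treatment, control) sample pair a
window is significant when the upper-tail Poisson p value of the
treatment count is below 10⁻⁵ against

λ = max(genome-wide control rate, control rate in a centred 10 kb window)
    × window width × (treatment library / control library).

The local rate uses a single 10 kb scale rather than a 1 k/5 k/10 k
ensemble; at the genome sizes this package targets the extra scales add
essentially nothing. Both directions of every sample pair are scanned so
gains and losses are both discoverable, and overlapping significant
windows are fused keeping the minimum p. Pair-level regions are merged
across all comparisons with bedtools-merge semantics (overlapping *or
book-ended* intervals fuse), giving a disjoint candidate catalogue.

Degenerate inputs: an empty control sample is an error (no background
estimable); a shift of 0 falls back to a 100 bp window; shifted positions
are clamped to chromosome bounds.

## Differential testing

**Counting and filtering.** Tags are counted into a region when their
shifted position lies in [start, end). Rows whose count sum falls below
the matrix's empirical centile (linear-interpolation definition; ties at
the threshold retained) are removed — the 50th centile for capture
regions and the 30th for gene expression counts.

**Normalization.** TMM: the reference sample is the column whose upper
quartile of relative counts is closest to the mean upper quartile; for
each other sample the factor is 2^(precision-weighted doubly-trimmed mean
of per-row log2 ratios against the reference) with 30% log-ratio and 5%
absolute-intensity trimming, rescaled so factors multiply to 1. Library
sizes default to matrix column sums but should be the genome-wide tag
totals when the analyzed matrix covers only candidate regions (the
pipeline does this); TMM's trimming assumes most rows are not
differential, so the candidate catalogue must be dominated by
non-differential rows — true of real cohorts, and of the synthetic data
once inter-individual effects are simulated (below).

**Library equalization.** The exact test conditions on row totals at
equal library sizes, so counts are rescaled to a common effective library
(library size × TMM factor) and rounded. The common size is the *median*
effective library: rescaling any sample that stays on the same side of
the median is then absorbed exactly. Exact invariance to library
rescaling through re-estimated TMM factors is not attainable — the
precision weights (N−y)/(Ny) depend on absolute depth — and the tests
assert it at the level it actually holds (|Δlog10 p| ≤ 0.05 at the 99th
percentile, call concordance > 99%).

**Dispersion.** The NB dispersion φ is estimated by conditional maximum
likelihood at equalized libraries: for one group with counts y₁…yₙ and
sum z the conditional log-likelihood is Σᵢ lnΓ(yᵢ+1/φ) − n lnΓ(1/φ) +
lnΓ(n/φ) − lnΓ(z+n/φ); the common φ maximizes the sum over rows and
groups (bounded scalar optimization on log10 φ ∈ [−8, 2]), and tagwise
dispersions maximize each row's likelihood plus prior_df × the per-row
average likelihood on an 81-point geometric grid spanning ±10 doublings
around the common value. prior_df defaults to 10 and is exposed in the
model; prior_df → ∞ collapses tagwise to common. Groups with a single
sample contribute no information; if no group has ≥ 2 samples the
estimator refuses and asks for a fixed dispersion.

**Exact test.** Conditional on a row's total t, the case-group sum is
compared to its null distribution: group sums are NB with means nₐμ, n_bμ
(μ = t/(nₐ+n_b)) and sizes nₐ/φ, n_b/φ; the two-sided p sums the
probabilities of all splits no more probable than the observed one
(double-tail convention; at φ = 0 this reduces exactly to a binomial
split, which the tests verify by enumeration). log2 fold change is the
ratio of group means of equalized counts with a proportional prior count
of 0.125 per sample; the sign convention is case minus control. BH
adjustment is the standard step-up (statsmodels backend, checked against
a direct implementation).

**Clustering.** Significant rows (p < 0.01) are library-normalized,
row-standardized to mean 0 / sd 1, and clustered on Euclidean distance
with complete linkage in both dimensions; columns are ordered
lexicographically first so the tree is invariant to input column order,
and constant rows are dropped with a warning.

## Feature enrichment

The feature catalogue derives from gene models and CGI intervals:
promoter = strand-aware 3 kb upstream of the TSS; TSS = 1 bp interval
(on the minus strand, the last covered base); intron = gene body minus
exons; non-genic = complement of gene bodies ∪ promoters (the
promoter-exclusive definition is switchable, since "non-genic" admits
both readings). Overlap means ≥ 1 bp of shared sequence; book-ended
intervals do not overlap.

For hyper- versus hypomethylated regions the 2×2 table per feature is
summarized by the log2 *conditional maximum-likelihood* odds ratio with
the exact conditional 95% CI (scipy's implementation) — chosen because
published CIs of this kind are asymmetric about the estimate, which a
Woolf interval cannot produce; Woolf is available as an option. When a
cell is zero the point estimate applies the Haldane–Anscombe 0.5
correction to all cells; a zero margin is an error (undefined OR) and
Fisher's p is 1 by convention on a zero margin. The background variant
compares one direction of change against the non-differential regions
(−log10 p < 0.25 from the differential stage).

## Preranked GSEA

Rank score = −log10(p) × sign(logFC), descending, ties broken by gene id;
p = 0 is capped at −log10 p = 320 with a warning. Methylation gene sets:
for each of gene body, TSS, promoter, exon, intron × increased/decreased,
a gene joins when that feature instance overlaps (≥ 1 bp) a DMR with
p < 0.01 of that direction. TF sets intersect ChIP intervals with
promoters, map ids through an ortholog table when given, and are bounded
to sizes [15, 500] before testing (both bounds configurable).

The enrichment score is the weighted KS running sum (hits add
|score|^w / Σ_hits |score|^w, misses subtract 1/(N−N_h); w defaults to
1); ES is the signed maximum deviation. Null distributions come from
*gene-set permutation*: size-matched uniform draws from the ranked
universe. NES divides ES by the mean same-sign null |ES|; the nominal p
is the same-sign null tail with a +1 continuity correction; FDR q
compares each NES against the pooled sign-matched null NES distribution,
as in the standard preranked procedure. All randomness flows from one
seed. With a single permutation the p degenerates to {0.5, 1} — the
implementation allows it but it is meaningless.

## Validation statistics

Clone matrices are binary clones × CpG; a minimum of six clones per
subject is a QC gate (warning, not a hard stop). Group comparison uses
the Mann–Whitney U test on per-clone methylation proportions pooled
within group — the unit of analysis is a design choice; a per-subject-
mean alternative is available by passing subject means instead. The test
is exact (full enumeration) for combined n ≤ 20 without ties, otherwise
normal approximation with tie correction. Per-CpG comparisons use the
two-sided Fisher exact test with optional BH correction across sites.

ΔΔCt: per sample, ΔCt = mean target Ct − arithmetic mean of the two
reference-gene Cts (equivalent to the geometric mean of reference
expression); ΔΔCt subtracts the control-group mean ΔCt; RQ = 2^(−ΔΔCt).
Adding any constant to all Cts cancels. Group-level tests are the
unpaired two-tailed t test (two groups) or one-way ANOVA with Bonferroni
pairwise post hoc (p × number of pairs, capped at 1).

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not sequencing physics. A toy genome carries non-overlapping genes
(1–8 exons, random strand) and CGIs placed uniformly; one chromosome may
be flagged spared (no planted group effects), mimicking the X-chromosome
sparing seen in the motivating data. Capture density is
piecewise-constant: a positive baseline multiplied inside each effect
interval by its fold change for the affected label. Effect intervals are
planted preferentially (weight 0.7) on CGIs and gene bodies. Per-sample
tag totals are Poisson(depth); positions are drawn from the density,
strands uniformly; duplicates are injected by resampling existing tags so
they collide exactly.

Two effect tiers matter: *group* effects (the signal) and
*inter-individual* effects attached to single samples. Real capture
cohorts discover most of their candidate regions from individual
variability, and the TMM/centile machinery relies on that composition;
simulations that plant only group effects produce a degenerate
all-differential candidate matrix in which normalization absorbs the
signal. Defaults: depth 10⁵ tags/sample, group sizes 5 controls vs 4
cases, NB expression dispersion 0.1, expression coupling 1 (genes whose
bodies carry hypermethylation lose one log2 unit of expression in the
affected group), expression depth 10⁶.

What the generator does **not** model — and hence what passing tests do
not demonstrate about real data: fragment-size distributions, capture
efficiency and saturation chemistry, sequence composition and mappability,
bisulfite conversion inefficiency, batch effects, and correlated
(non-independent) CpG calls within clones. The capture-density model is
an assumption; no published capture-efficiency profile informs it.

## Problem sizes in the shipped checks

The test suite and the reproduction script run at reduced scale chosen as
the smallest sizes at which each property is statistically identifiable:
null calibration on 2000 regions at 4-vs-5 samples; planted-recovery at
depth 10⁶ over a 10 Mb genome with 200 two-fold regions and 10 samples
per group (the planted effect extends one tag-shift beyond each counted
window so the shifted pileup sees fully enriched density); the GSEA and
clustering contracts over 10 simulation seeds with 400-gene universes and
1000 permutations. The published contingency counts for the seven genomic
features are carried as literal inputs to the enrichment statistics.

## Known limitations

- The caller is single-scale and summit-free; it is not a MACS
  replacement on real genomes.
- Testing regions discovered from the same samples is circular
  (selection bias); the type-I calibration holds for pre-specified
  regions, and discovered-region p values should be read as ranking
  scores, as in the original workflow.
- The conditional-likelihood dispersion assumes equalized libraries;
  equalization is by scaling and rounding, not quantile adjustment, which
  is slightly conservative at very unequal depths.
- GSEA FDR q uses the pooled sign-matched null; with very few sets it is
  noisy (the tests use medians over seeds).
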