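# Methods

This note documents the models, rules and numerical choices behind
`dmrmem`, and what the synthetic-data experiments do and do not show.

## Data model and coordinates

All coordinates are 0-based, half-open (BED convention). The
`cytosine_report` dialect is 1-based on disk (Bismark convention) and
converted at the I/O boundary. A methylome sample is a table of
per-cytosine calls (chrom, pos, strand, context ∈ {CpG, CHH, CHG},
methylated reads, total reads) with the invariants meth ≤ total and no
duplicate keys (duplicates are a hard error, never a silent merge).

Symmetric CpG calls — a `+` call at *p* and a `-` call at *p*+1 — are
summed into one strand-combined unit at the `+` position, the standard
WGBS practice; unpaired calls pass through unchanged so read counts are
conserved. Pretreatment before DMR calling retains calls with ≥ 10 reads
on autosomes and is idempotent. The region-level rule (≥ 5 reads and ≥ 5
covered cytosines per region, otherwise missing) is a *different* filter
used for feature averages, window vectors and DMR heatmap matrices; both
thresholds are explicit parameters.

All levels are read-weighted (Σ meth / Σ total), so the level of a
concatenation equals the read-weighted mean of its parts; a site-averaged
alternative would weight shallow sites equally and was rejected.

## Window summaries and correlation

Windows are 1 kb every 500 bp, anchored at 0 per chromosome; the last
window is truncated at the chromosome end and generation stops with it, so
a chromosome shorter than one window yields a single `[0, length)` window.
Pairwise Pearson correlation uses complete-pairs deletion over windows
non-missing in both samples and needs ≥ 3 shared windows (imputing missing
windows as 0 would bias R and was rejected).

## DMR caller

Input: per-CpG pooled group levels. Replicates are pooled per group per
site (sum of counts) before testing — at 2–3 replicates per group a
replicate-level test has essentially no power and the pooled level is the
natural effect scale. Sites need ≥ 10 pooled reads in *both* groups and an
autosomal location.

**Pre-segmentation.** Consecutive sites with inter-CpG gap ≤ 300 bp share
a block; blocks with < 10 sites are dropped (the defaults of the published
segmentation tool this caller reimplements).

**Segmentation.** Recursive binary segmentation of each block on the
per-site signed differences d_i = levelA_i − levelB_i. Every breakpoint
leaving ≥ 10 sites on each side is scored by
|mean(d_left) − mean(d_right)|; the best breakpoint (leftmost on exact
ties, giving deterministic output) is accepted only while at least one
sub-segment is *more significant* than its parent (strictly smaller
Mann–Whitney p, tolerance 10⁻¹²). The significance-improvement stop is the
essential design choice: a stop based on the sub-segment mean difference
alone splits whenever noise nudges a sub-mean above the parent mean, which
fragments genuinely homogeneous regions into sub-threshold pieces; with
the significance stop, a homogeneous effect region is emitted whole
because its children, with fewer sites, test less significant.

**Testing.** Each emitted segment is tested by a two-sided Mann–Whitney U
comparing the two groups' per-site pooled levels across the segment's
sites (exact null when scipy selects it at small n without ties, normal
approximation with tie correction otherwise). Degenerate candidates
(< 2 sites, or all values identical) get p = 1. Using a rank test here
instead of the 2D Kolmogorov–Smirnov statistic of the published tool is a
deliberate simplification: it is closed-form checkable, and the retention
filter dominates behaviour. Benjamini–Hochberg correction is applied over
all candidates of one comparison genome-wide; the three pairwise
comparisons are corrected independently, as the study design treats each
pair separately.

**Retention.** A candidate becomes a DMR iff it has ≥ 20 CpGs, q < 0.05
and |mean difference| > 10 % (strict inequalities on q and Δ). DMR
boundaries run from the first to the last CpG of the segment, end
exclusive at last position + 1. Direction is `hyper` when the focal group
(argument A) is the more methylated.

## Annotation and memory classification

Position classes use the DMR midpoint with precedence
promoter > exon > intron > intergenic; the promoter window is
[−2000, +500] bp around the TSS in gene orientation (inclusive bounds).
The source study never defines its two concentric class systems, so one
documented system with a CGI-overlap overlay is implemented. CGI overlap
is any shared base of the full DMR interval. TSS distances are signed in
gene orientation (negative = upstream), measured midpoint-to-TSS, nearest
gene by absolute distance with lexicographic gene-id tie-break; gene
association uses |distance| ≤ 10 kb.

A focal DMR (reprogrammed vs target) is classified **mDNA** iff it
overlaps a reference DMR (source vs target) by ≥ 1 bp — the most
permissive deterministic reading of "based on the overlap", exposed as a
parameter — else **sDNA**. The partition is exhaustive and exclusive by
construction.

## Expression integration

Signals are assumed normalized and log₂-scaled, so fold changes are group
mean differences. Dunnett's many-to-one test uses pooled within-group
variance and the multivariate-t distribution of the Dunnett statistic
(scipy's implementation; its quasi-Monte-Carlo integration receives a
generator seeded per probe, making p-values reproducible to well below
the 0.05 decision threshold). Probes with zero within-group variance in
every group raise an error rather than returning NaN.

DEG derivation is an assumption of this package (the source study imported
DEG lists from earlier work without restating thresholds): a probe is
differential when its Dunnett-adjusted p vs the target group is < 0.05
and |log₂FC| ≥ 1; a gene is a DEG when any of its probes passes, with
direction from the passing probe of largest |log₂FC|. A user-supplied DEG
list can replace the derivation. Intersections report counts and
fractions relative to the DMR-associated gene set, counting each gene
once regardless of probe multiplicity.

## Synthetic data generator

The generator defines the study conditions for every experiment in the
test suite and acceptance script.

- **Design**: groups MEF (source), ISC (target), iISC (reprogrammed) with
  3/2/3 replicates; 3 chromosomes of 2 Mb, 2 autosomal (the non-autosome
  exercises the pretreatment filter); CpG sites at geometric spacing with
  100 bp mean; sparse CHH/CHG sites likewise.
- **Counts**: depth ~ Poisson(30); methylated reads ~ beta-binomial with
  the site's true level as mean and dispersion ρ = 0.02 — the simplest
  noise model with replicate-level overdispersion. The study reports no
  replicate variance; ρ is an assumption and a config field.
- **Regional baseline**: per-2-kb-tile levels drawn once from a Beta
  distribution and shared across groups through a common quantile
  (CpG: mean 0.7, concentration 8 → s.d. ≈ 0.15; non-CpG: mean 0.08,
  concentration 2 → mostly unmethylated with occasional methylated
  tiles). Shared regional structure is what makes windowed methylomes of
  any two samples correlate highly, and its absence of group dependence
  for CHH/CHG makes those correlation matrices ≈ 1 everywhere — the
  qualitative pattern of the real design. Setting the concentrations very
  large recovers a flat baseline, used by the marginal-calibration test.
- **Planted regions**: four classes with per-group true levels — `shared`
  (MEF differs; ISC = iISC), `memory` (MEF = iISC; ISC differs),
  `specific_hyper` / `specific_hypo` (MEF = ISC; iISC higher/lower), all
  with effect 0.4 by default. Regions are anchored on runs of real CpG
  sites (≥ 20 sites, internal gaps ≤ 300 bp so pre-segmentation cannot cut
  them — planted regions emulate CpG-dense loci), non-overlapping with a
  5 kb margin so distinct loci remain distinct in the output. The default
  plan (40 shared / 8 memory / 16 specific-hyper / 8 specific-hypo)
  mirrors the study's qualitative findings: fewer reprogrammed-vs-target
  DMRs than source-vs-target, memory a minority of aberrations, hyper
  aberrations ≈ 3× hypo.
- **Expression**: one probe per gene, Gaussian log₂ signals (gene means
  ~ N(8, 1.5), replicate s.d. 0.25). A configurable fraction (default 0.1)
  of TSS-proximal focal aberrations is coupled to a DEG (±2 log₂ shift in
  iISC, hyper → down / hypo → up), plus a few uncoupled background DEGs —
  so only a small minority of DMR-proximal genes are differential, the
  low-overlap regime of the real data.
- **Determinism**: one master seed; each stage (annotation, site layout,
  truth, tiles, per-replicate sampling, expression) draws from a
  deterministically derived child seed, so identical configs give
  byte-identical outputs at every stage.

What passing tests on this generator show: the caller recovers contiguous,
CpG-dense, well-separated effect regions of the planted magnitude with the
stated error control, and the classification/integration logic is exact.
What they do not show: performance on real methylomes with
partially-methylated domains, coverage biases, conversion errors, or DMRs
below ~20 CpGs/10 % — and the published real-data values (global levels,
DMR counts, the 39 % memory fraction) depend on the deposited sequencing
data and are not desk-reproducible; the synthetic design reproduces their
qualitative patterns only.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script each
run in minutes on one core: 6 Mb genome (~60 k CpG sites, ~40 k shared
covered sites per comparison), 12 k windows, 72 planted regions, 300
genes; the type-I experiment uses one 500 kb chromosome (~5 000 CpGs) and
100 label permutations; Dunnett calibration uses 2 000 null simulations.

## Known limitations

- The caller is CpG-only (as in the source analysis); CHH/CHG enter only
  summaries and correlations.
- Boundary precision degrades when an effect region sits closer than the
  minimum sub-segment size (10 sites) to a block edge, and two effect
  regions separated by less than the pre-segmentation gap can merge if the
  intervening sites are few.
- The Mann–Whitney p under selection (segments chosen for extremity) is
  anti-conservative as a pure p-value; error control in practice comes
  from the joint retention filter, which the type-I experiment verifies
  directly.
- `fc_scatter_table` labels genes associated with both an mDNA and an
  sDNA DMR as `both` rather than duplicating the record.
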