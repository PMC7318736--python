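# Methods

`csslkit` analyses chromosome segment substitution line (CSSL) populations:
lines carrying one or a few donor-genome segments (e.g. *Gossypium
barbadense*) in an otherwise recurrent-parent background (e.g. *G.
hirsutum*). This note records the models, the numerical choices, and what
the synthetic-data generator does and does not emulate.

## Segment reconstruction from SSR graphical genotypes (MM-map)

Each line is scored at sparse SSR markers as DD (homozygous donor), DR
(heterozygous) or RR (homozygous recipient). A maximal run of non-RR calls
is one candidate segment; missing calls never break a run (they are spanned
and counted, so sparse genotyping failures do not fragment segments).

The length estimator weights marker intervals by their expected donor
content: the span between the outermost DD markers counts at 100%, and each
flank — from the outermost DD marker to the nearest bounding RR marker,
whether or not DR markers lie inside it — counts at 50%. A run with no DD
marker (het-only) is estimated as half the span between its bounding RR
markers and flagged heterozygous; a run containing any DD marker is flagged
donor-homozygous. At a chromosome end with no bounding RR marker, a
DD-anchored flank extends to the end at full weight (the crossover, if any,
is beyond the last marker, so the symmetric 50% argument does not apply);
a het-only terminal flank keeps the 50% weight as the conservative choice.

With markers spaced Δ apart and error-free calls, the estimate of an
interior segment is within one marker interval of the true length: each
boundary contributes at most Δ/2 of error (the estimator effectively places
boundaries at flank midpoints).

## Sliding-window bin map from re-sequencing SNPs (GR-map)

Biallelic SNPs that distinguish the parents are reduced per line to
donor / recipient / het / missing. A call matching neither parental allele
is treated as missing; sites monomorphic between the parents are dropped
(they carry no ancestry information), and identical parent columns
genome-wide abort the run.

Windows of `window_size` = 50 kb anchored every `step` = 5 kb are genotyped
by a majority rule: if more than `majority_threshold` = 80% of the window's
genotyped SNPs carry one parent's allele, the window is homozygous for that
parent; otherwise heterozygous. The denominator is all genotyped SNPs in
the window (donor + recipient + het); heterozygous calls count toward
neither parent's numerator, so a window dominated by het calls is called
het. (Restricting the denominator to homozygous calls would make genuinely
heterozygous regions undecidable — 0/0 — rather than het.) Windows with
fewer than `min_snps_per_window` = 5 genotyped SNPs are NA rather than
inheriting a neighbour's genotype: an explicit NA keeps the downstream
length filter well defined in SNP deserts.

Maximal runs of equal window genotype become recombination bins. The
breakpoint between two runs is the midpoint of the overlap between the last
window of the left run and the first window of the right run (equivalently
the midpoint between the two window centers) — the symmetric choice, with
no information favouring either side within the overlap. Bins always tile
the chromosome: the first starts at 0 and the last ends at the chromosome
length.

Merging and filtering, iterated to a fixed point (hence idempotent):

1. two bins of the same genotype separated by less than `merge_gap` =
   100 kb are fused, absorbing whatever lies between (including short
   opposite-genotype bins — distance is measured in coordinates, so any
   intervening feature ≥ 100 kb blocks the merge automatically);
2. bins shorter than `min_bin` = 100 kb become NA;
3. adjacent same-genotype bins re-fuse.

Donor-homozygous and heterozygous bins become introgression segments. At a
true ancestry breakpoint the overlapping windows produce a short run of
mixed (het) calls ~0.6 × window wide; it is removed by the 100 kb filter
and the adjacent segment boundary lands within about half a window of the
truth, which is why the recovery tests demand ≤ 50 kb (one window) boundary
accuracy under 1% genotyping error and 5% missingness.

Coordinates are 0-based half-open internally and in BED-like exports.

## Coverage statistics

Union coverage is the per-chromosome interval union over all lines' donor
segments; rates are union / map length, aggregated by summing unions and
lengths before dividing (so an aggregate rate always lies between its
members'). Fold coverage counts overlaps multiply: Σ segment lengths / Σ
chromosome lengths. Heterozygous segments count at full length in the
SNP-based map; in the marker-based map the DR flanks already enter at half
weight through the estimator, so no extra discount is applied. Reported
percentages round half-up to 2 decimals, spacing/density to 1, matching the
conventions of published map-comparison tables.

## Block partition and QTL scan

Cutting the genome at every segment boundary yields atomic intervals within
which every line's donor dosage x ∈ {0, 0.5, 1} is constant; empty
intervals are dropped and contiguous intervals with identical dosage
vectors merge into blocks, numbered in genome order. Block lengths
therefore sum exactly to the union coverage length.

The scan regresses line BLUPs on block dosages. Forward–backward stepwise
selection (entry p ≤ `p_in` = 0.05, removal p ≥ `p_out` = 0.10; both
config-exposed since the published analyses delegate them to mapping
software defaults) picks background cofactors; blocks with constant dosage
are skipped and blocks collinear with earlier ones are dropped from the
cofactor pool. Each block b is then tested by the likelihood ratio of the
cofactor model without b against the one including b:

    LOD_b = (n/2) · log10(RSS_reduced / RSS_full)

which for a 1-df contrast equals (n/2)·log10(1 + F/dfe); the test suite
asserts this identity against an independent regression fit. PVE_b =
100·(RSS_reduced − RSS_full)/TSS. The additive effect a_b is half the
fitted donor-homozygous minus recipient difference, i.e. the dosage
coefficient / 2; heterozygous dosage 0.5 enters linearly (additive-only
model). The default report threshold is LOD ≥ 2.5. A numerically separable
fit (RSS_full ≈ 0) caps LOD at 50 rather than overflowing. Because either
parent's allele may raise a trait, a `donor_positive` flag flips the sign
convention; the default reports positive a when the donor allele increases
the trait.

## Phenotype statistics

Per trait, the model is y_ij = μ + env_j (fixed) + g_i (random) + e_ij.
Replicates within a line × environment cell are averaged first (pooled into
the residual; the replicate structure of multi-year trials is rarely
uniform across traits). Balanced tables use the closed-form two-way ANOVA
method-of-moments estimator, which equals REML in the balanced case;
unbalanced tables fall back to REML via `statsmodels` MixedLM. Negative
genetic-variance estimates truncate at zero.

BLUP_i = μ̂ + k_i (ȳ_i − μ̂) with k_i = σ̂²_g / (σ̂²_g + σ̂²_e / n_i),
where ȳ_i is the environment-adjusted line mean — so BLUPs always shrink
toward the grand mean relative to raw line means. Broad-sense heritability
is reported on a line-mean basis, H² = σ²_g / (σ²_g + σ²_e / n_env),
matching across-environment repeatability; a `plot` basis (σ²_e
undivided) is config-switchable. A trait observed in a single environment
(e.g. a seed-index trait scored in two of five trials would be the
borderline case) gets H² = NA with a warning rather than a misleading
number.

Pearson correlations are computed over line BLUPs with two-tailed p-values
and the conventional * (0.05) / ** (0.01) flags.

WAF — the weighted mean of per-trait additive effects per block — is

    WAF_b = Σ_t Add_bt · r_t · H²_t / Σ_t r_t · H²_t

with r_t the positive correlation of trait t with the anchor trait (the
first trait by default; both the anchor and the trait list are config
options). Traits negatively correlated with the anchor are excluded rather
than sign-flipped — exclusion is the conservative reading of "positive
correlation coefficient" weights and avoids inventing an orientation for
traits whose improvement direction is ambiguous. Weights must be strictly
positive; blocks with no additive estimate yield NA. The statistic is exact
weighted-mean arithmetic: bounded by the min and max of its inputs,
scale-equivariant in the effects, invariant to rescaling all weights.

## The synthetic generator

`simulate_population` plants donor segments directly: per line, a number of
segments drawn uniformly from `segments_per_line`, placed on chromosomes
with probability proportional to length, with lengths uniform on
`segment_length` (published populations report a wide right-skewed range;
uniform on a configurable interval keeps every regime testable without
privileging one shape). Placement resamples on overlap (100 tries, then an
error) and enforces a `min_segment_gap` (default 300 kb) between segments
of one line so the planted truth stays identifiable under the pipeline's
100 kb merge rule. A segment is heterozygous with probability
`het_fraction`.

SNP positions are uniform per chromosome at `snp_density` (default 5/kb,
the density of interspecific cotton parents); parent alleles always differ.
SSR markers sit on a jittered grid anchored at both chromosome ends
(genetic maps of established populations have terminal markers), with
genetic positions from a constant `cm_per_mb` = 2.0, the genome-wide
cM/Mb ratio of interspecific cotton maps. Genotyping error replaces a call
with a uniform draw from the two other states — so the realized
mismatch-to-truth rate equals the configured rate exactly, which is what
the binomial-oracle tests check — and missingness blanks calls
independently. Defaults (1% error, 5% missing, 26 chromosomes at 1/10
scale, 100 lines, five environments) mirror the resequenced CSSL study
design at reduced genome size.

Phenotypes follow y_ij = μ + env_j + Σ_b 2 a_b x_ib + g_i + e_ij with
dosage coding x ∈ {0, 0.5, 1} and genotypic value 2a·x, so the reported a
is half the homozygote difference — the convention of published QTL effect
tables. Environment effects are drawn N(0, σ²_env); g and e are the usual
normal components.

What the generator does **not** emulate: meiotic recombination through the
actual backcross generations (segments are planted, not inherited), linkage
disequilibrium between segments of different lines, reference-alignment
artefacts (paralogy between the A and D subgenomes, mapping bias near
structural variants), clustered SSR positions, non-normal residuals, and
genotype × environment interaction. Passing tests therefore demonstrate
the pipeline's correctness under its stated model, not robustness to those
real-data pathologies.

## Problem sizes

The test and acceptance runs use populations of 50–100 lines on 2-chromosome
20–40 Mb genomes (≈ 200k SNPs each), 20 recovery seeds, 500 null QTL
replicates at n = 300 lines, 100 power seeds, and 50 heritability seeds —
sizes at which every Monte-Carlo criterion is stable to well inside its
tolerance while the whole suite runs in well under a minute of simulation
time per module.

## Known limitations

* The stepwise cofactor criterion is a plain partial-F rule; mapping
  software may use information criteria or permutation thresholds, so
  cofactor sets (not per-block LODs given a cofactor set) may differ.
* `fit_blup` fits one trait at a time; no multi-trait or spatial models.
* The window caller assumes SNP density high enough that 50 kb windows
  hold ≥ 5 informative SNPs; sparse panels should raise `window_size`.
* WAF inherits any sign-orientation choice made in the QTL scan; compare
  orientations with the `donor_positive` flag before interpreting signs.
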