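# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical conventions, and the design choices that were genuinely open.

## Presence calling (1%-of-mean rule)

Each dataset (one species/organ/timepoint) is reduced to a per-gene
profile by arithmetic averaging over its replicate columns. The expressed
threshold is `fraction x grand_mean`, where `grand_mean` is the mean over
genes of the per-gene averages and `fraction` defaults to 0.01. Because
the threshold is proportional to the profile's own mean, the
expressed/not-expressed partition is invariant to global rescaling
(sequencing depth, array gain), and raising a single gene's value can
never silence it (the threshold rises by at most `fraction/n` of the
bump).

Conventions the rule alone does not determine:

* the grand mean is **per dataset**, not pooled across datasets — each
  count table is processed on its own scale;
* a value exactly at the threshold counts as expressed (exclusion applies
  to values strictly below);
* an all-zero profile calls every gene not expressed, with a warning —
  `0 >= 0` would otherwise declare universal expression on no evidence;
* cell fractions (basal + luminal mammary) are combined by the per-gene
  **mean** rather than the sum, keeping the combined profile on a
  single-fraction scale. Scale invariance of the caller makes the two
  choices equivalent downstream; the mean is logged as the convention.

## Differential expression (`method=nb_wald_simple`)

Counts for gene *g*, sample *j* are modelled NB with mean `mu_gj` and
gene dispersion `alpha_g` (variance `mu + alpha mu^2`).

1. **Size factors** — median over all-positive genes of
   `count(g,j) / geomean_g(counts)`, rescaled to geometric mean 1. If no
   gene is positive in every sample this is a hard error (no
   pseudo-reference fallback); ties in the median use the midpoint.
2. **Dispersion** — method-of-moments on size-factor-normalised counts,
   `(s^2 - m)/m^2` per group, df-weighted across the two groups, clipped
   below at 0. Each group needs >= 2 samples; pooling replicates across
   nuisance factors (timepoints for the compartment contrast, compartments
   for the stage contrast) happens upstream by design. Inside the GLM the
   dispersion is floored at 1e-8 to keep the variance function
   non-degenerate.
3. **Wald test** — per-gene NB GLM `log mu = log s_j + b0 + b1 x_j`
   (x = 1 for group A), fitted for all genes simultaneously by vectorised
   IRLS (shared design, per-gene 2x2 normal equations; linear predictor
   clipped to ±30; 50 iterations, tolerance 1e-10). The statistic is
   `b1 / SE(b1)` against N(0,1), two-sided; `log2FC = b1 / ln 2`, positive
   meaning up in group A. All-zero genes are reported with p = 1, log2FC =
   0 and an `all_zero` flag.
4. **BH adjustment** — the classical step-up with monotonicity
   enforcement, order-preserving with the input, capped at 1.

Deliberate simplifications relative to full DESeq2: no dispersion-trend
shrinkage, no Cook's-distance outlier handling, no independent filtering,
no fold-change shrinkage. The comparative analyses consume only the
significant-gene partition, for which this plainer estimator is calibrated
(measured in the acceptance checks: BH discovery fraction under a complete
null at n = 5+5, alpha = 0.2 stays well under 0.05's nominal budget; sign
agreement under planted 4-fold changes is ~100%). The raw Wald p-values
are mildly anticonservative at very small n, as expected for a plug-in
dispersion; BH over many genes absorbs this at the decision level.

## Stage mapping

The common gene universe is the set of ortholog pairs expressed in
*every* dataset entering the grid (query placenta; reference series;
control organ), computed **once** for the whole matrix — per-cell
universes would make correlations incomparable across cells. Profiles are
ranked from highest to lowest expression with average ranks on ties
(guaranteed with tag counts), and each cell is the Pearson correlation of
the two rank vectors — the tie-safe Spearman; the `6 Σd²` shortcut is
biased under ties and is used only as a test oracle on tie-free data.
Microarray intensities enter as-is: no log transform, because ranks make
any strictly monotone rescaling irrelevant (this invariance is asserted
bit-for-bit in the tests).

The best-matching stage is the argmax over non-control columns; ties break
to the earliest stage and are flagged. The control contrast requires
`min(reference rho) - max(control rho) > 0` strictly — an exact tie fails.

## Stage-partition enrichment and screens

The early/late placenta-specific programs (reference namespace) are
crossed with the ortholog-mapped query expressed set into a 2x2 table; the
test is a Pearson chi-square with 1 df on marginal-derived expected
counts, Yates correction behind a flag (default off — both variants are
always reported). On the published program counts — 90 of 340 early and
10 of 70 late genes expressed — the statistic is 4.67 uncorrected (p =
0.031) and 4.04 with Yates (p = 0.045).

Screen formulas, in query-species (A) namespace:

* co-option screen: `(placenta_A ∩ placenta_B ∩ organ_A) \ organ_B`;
* reference-only screen: `(placenta_B ∩ organ_A) \ (placenta_A ∪ organ_B)`.

Genes without an ortholog cannot be evaluated against the other species'
sets; they are excluded and tallied (`unmappable`) rather than treated as
absent — a missing mapping is not evidence about expression. Control
screens substitute liver/testis expressed sets into the organ slots of the
identical formula. The ORA is a one-sided hypergeometric tail per
annotation set with BH across sets; its default universe is the union of
the expressed sets entering the screen (configurable).

## Synthetic-data model

Per gene the log relative expression in dataset (species s, organ o) is

    lambda = b_g + org_(g,o) + sp_(g,s,o) [+ w_g(stage)] [+ DE effects]

* `b_g ~ N(0, 0.5)` — gene baseline, shared everywhere;
* `org ~ N(0, 0.45)` — organ modulation **shared between species**: this
  is the conserved organ identity the control contrast must detect;
* `sp ~ N(0, 0.2)` — species-by-organ residual;
* `w_g` — a per-gene random walk across the reference stages (step sd
  0.3, zero at the first stage), applied to placental datasets; query
  placenta timepoints reuse `w` at the planted stage (default `e10.5`),
  which is exactly what stage mapping must recover. Adjacent stages are
  thereby more rank-correlated than distant ones.
* DE effects: ±half the configured log fold change (default 4x) on the
  planted compartment/stage genes within the query placenta design
  (4 BOM + 6 TOM samples over days d21/d23/d25).

Membership: housekeeping and DE-truth genes are active everywhere; organ
programs only in their organ (both species); early/late programs are
placenta-specific and switch at the e12.5 boundary of the series (the
bulk reference placenta is a term sample, so it expresses the late
program); the co-opted set is active in both placentas and the query
mammary gland but silenced in the reference mammary gland; the
reference-only set is active in the reference placenta and query mammary
gland but silenced in the query placenta and reference mammary gland.
Planted subsets of the early/late programs (fractions 90/340 and 10/70)
are active in the query placenta, so the stage-partition table is
early-enriched by construction.

Silenced genes keep an NB mean of 0.1% of their active mean — not a
structural zero — so the caller's threshold boundary stays exercised.
This coupling constrains the effect-size scale: with a 10^3 silencing
depth and a 1%-of-mean threshold, a gene whose active mean exceeds ~10x
the genome average would leak past the threshold even when "silenced",
contradicting its planted status. The defaults above keep that tail below
~0.3% of genes per dataset, which is what makes the planted sets
recoverable (screen precision/recall ~0.92–0.99 across seeds) while
leaving a realistic trickle of chance hits for the control screens to
quantify.

Counts are NB with gene dispersions uniform on [0.05, 0.5] and per-sample
library sizes lognormal around 4x10^5 (sd 0.2 on the log scale). The
reference series is emitted as intensities
`20 x (log2(mean + 1) + N(0, 0.1))`, clipped at zero — an affine-log,
strictly monotone distortion that forces the rank-based pipeline to prove
platform invariance rather than assume it. Every sample column draws from
a child RNG keyed by (seed, dataset labels, replicate), so generation is
fully deterministic given the config and any column is individually
reproducible.

What the generator does **not** emulate: read-level artifacts (mapping
bias, positional coverage), correlated gene programs beyond the planted
block structure, batch effects, and compositional distortion between
samples. Passing tests therefore demonstrate that the pipeline's logic and
calibration are correct under the stated noise model, not that the
biological conclusions of any particular real dataset would replicate.

## Problem sizes

Defaults are 5000 genes with planted sets of 300 per organ program,
340/70 early/late, 77 co-opted, 108 reference-only, 2x200 DE genes, and 3
replicates per dataset; recovery properties are measured over 20
generator seeds. These sizes keep every planted structure at the scale of
the real screens while the full test suite and the acceptance script each
run in seconds on one CPU.

## Known limitations

* The Wald test's normal reference is a large-sample approximation; at
  n = 4–6 per group the raw type-I rate at 0.05 runs near 0.07–0.10.
  Decisions are made on BH-adjusted q-values, which the null calibration
  check shows to be conservative at the defaults.
* The one-to-one ortholog map is a modelling choice; many-to-many
  orthology is out of scope and multi-mapping genes must be resolved
  upstream.
* The chi-square test assumes the early/late programs are fixed gene
  lists, not estimated from the same data being tested.
* `best_matching_stage` returns a point assignment; no uncertainty is
  attached to the argmax (bootstrap over genes would be the natural
  extension).
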