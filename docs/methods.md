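# Methods

`sphereproteo` re-implements, as a tested library, the quantitative
proteomics analyses used to characterize neurosphere-to-oligosphere (neural
stem cell to oligodendrocyte precursor) differentiation: a TMT-labelled
whole-proteome time course, a dimethyl-labelled phosphoproteome time
course, a SILAC proximity-biotinylation (BioID) interactome screen for
Dclk1 isoforms, and the inference of proteolytic processing sites from
semi-tryptic peptide evidence. Because the original raw mass-spectrometry
data are not required (or desirable) for testing the statistics, every arm
is exercised on synthetic data with known ground truth; this note records
the models behind both the analyses and the generators, the defaults and
why they were chosen, and what the tests do and do not demonstrate.

## Statistical core

All quantities are log2 intensities or log2 ratios.

**Cyclic LOESS normalization.** For each ordered sample pair, the
difference M is regressed on the average A with locally weighted
regression over features present in both samples, and half the fitted
trend is moved from one member to the other; the pair loop runs for 3
cycles with span 0.7 (common practice for M-A normalization; the upstream
description fixes neither). Missing values are never created or destroyed.

**Robust linear regression (RLR) normalization.** Each sample is regressed
on the feature-wise median profile by iteratively reweighted least squares
with Huber weights, and the fitted linear distortion is inverted:
`x_norm = (x - intercept) / slope`. A sample that is an exact affine
transform of the reference is restored to slope 1 / intercept 0.

**Batch-effect regression.** Per feature, log2 intensity is modelled on
time-point one-hot columns plus sum-to-zero batch (plex) contrasts; the
fitted batch contribution is subtracted. Sum-to-zero coding leaves group
means untouched and makes the refitted batch coefficients exactly zero on
corrected data. A design in which batch cannot be separated from group is
rejected with an error naming the confounding. Features with too few valid
values for a full-rank fit pass through unchanged.

**Paired and moderated t-tests.** The TMT arm uses an ordinary paired t on
complete plex pairs. The BioID arm uses an empirical-Bayes moderated t:
per-feature OLS residual variances are shrunk toward a scaled
inverse-chi-square prior whose hyperparameters are obtained by moment
matching on log variances — with `e = log(s²) − ψ(d/2) + log(d/2)`, the
prior df solves `ψ′(d₀/2) = var(e) − mean(ψ′(d/2))` (trigamma inverse by
Newton iteration) and the prior variance is
`exp(mean(e) + ψ(d₀/2) − log(d₀/2))`. With the intensity trend enabled,
`mean(e)` is replaced by a LOESS fit of `e` on the feature's average
intensity. The posterior variance is the df-weighted mix of prior and
observed variance and the statistic has `d + d₀` degrees of freedom. When
the moment estimate of the prior df is infinite (variances consistent with
a single scale), the prior variance is the pooled mean variance. Tests
verify agreement with an independently coded closed-form oracle (1e-6) and
with the Bioconductor limma implementation (1e-8); forcing the prior df to
0 reproduces ordinary t-tests to 1e-9.

**Multiple testing, enrichment, clustering, imputation.** BH adjustment is
the standard step-up with cumulative minima, NaNs propagated. Term
enrichment uses the Fisher exact test on the 2×2 membership table
(two-sided by default, one-sided for over-representation-only analyses)
with fold enrichment `(k/set)/(K/background)`; callers collapse sites to
proteins first so a protein counts once. Profile clustering uses complete
linkage on `1 − Spearman ρ`; constant profiles, whose rank correlation is
undefined, become singleton clusters with a warning. `impute_min` replaces
missing values by the global observed minimum (feeds only the
biotinylation-ratio calls); `impute_minprop` replaces them by the global
minimum scaled by a proportion (default 1.0 — the source pipelines do not
define the "MinProp" semantics, so the proportion is an explicit
parameter rather than a guess).

## TMT whole-proteome arm

Pipeline order: flag filtering (contaminant/reverse), cyclic LOESS within
each plex, per-protein batch regression across plexes, paired t-tests of
each day against day 0 using only plexes where both values are present
(≥ 3 complete pairs, no imputation), BH within each comparison, and calls
at q < 0.05 with |log2 FC| ≥ 1 (fold-change cut-off 2). BH is applied per
comparison, matching the description of the tests as day-0-vs-day-d
analyses. Features significant in ≥ 1 comparison get per-day mean
profiles, z-scored per feature (sd with n−1), and are cut into k = 7
complete-linkage clusters; a silhouette scan over k = 2..12 is available
for users who prefer data-driven k, but 7 is the default. Cluster
enrichment uses the full filtered dataset as background.

## Dimethyl phosphoproteomics arm

Class-I filtering keeps sites with localization probability ≥ 0.75. The
boundary is inclusive because the source descriptions state both "> 0.75"
retained and "< 0.75 removed"; the inclusive reading reconciles them and
matches field convention. Multiplicity splitting emits one row per (site,
multiplicity) with ≥ 1 ratio, purely reshaping values. Regulation calls
require both replicate log2 ratios beyond ±1 with the same sign, per
comparison (day 7/0, day 14/0, day 14/7) — no averaging. Keyword
enrichment tests proteins bearing ≥ 1 regulated site (per direction and
comparison) against all dataset proteins at BH FDR 0.02. Motif analysis
compares position-wise residue frequencies between foreground and
background windows with two-proportion z-tests; the default background is
the dataset's own class-I windows (an external background file can be
supplied). The z-test's p-values are only approximately uniform under the
null — counts are discrete and residues at one position are multinomially
dependent — so calibration checks use ≥ 500 windows per set, where the
normal approximation is accurate.

## SILAC BioID arm

Features need ≥ 2 observed light values in some construct to enter at all.
Two strictly ordered imputation paths mirror the published pipeline:
(1) for biotinylation calls, missing light values are min-imputed, ratios
are light − heavy where the heavy (control) value exists, and a feature is
biotinylated for a construct iff ≥ 2 replicate ratios exceed 1;
(2) for construct-vs-construct tests, the *non-imputed* light intensities
are normalized across all constructs (cyclic LOESS at protein level, RLR
at phosphosite level), then MinProp-imputed, then compared with the
trended moderated t-test; significance requires BH q < 0.05 and
|log2 FC| > 0.58. The pairwise test additionally applies the ≥ 2-valid
rule to the two compared constructs: a feature observed only in other
constructs carries no information about the pair, and its fully or mostly
imputed row otherwise contaminates the variance-prior estimate (in
simulations this occasionally collapsed the prior df below 1 and halved
sensitivity). Over-representation analysis takes an explicit background —
global for classifying biotinylated proteins, all biotinylated proteins
for construct comparisons — filtered at BH FDR < 0.2 and p < 0.05, and
redundant terms are removed greedily in ascending adjusted-p order when
the Jaccard similarity of their feature sets exceeds 0.7 (the
minimum-adjusted-p member of each redundant group survives).

## Cleavage-site mapper

Semi-tryptic peptides shorter than 7 residues are ignored (below the
minimum detectable peptide length). Peptides sharing a protein and a
tryptic anchor terminus whose non-tryptic break positions are consecutive
form a ladder candidate; singletons are width-1 candidates. Breaks with
proline on either side are excluded as gas-phase fragmentation artifacts
(both sides, since the directionality is not knowable from the evidence).
A candidate whose members' intensity-weighted retention times all lie
within 1 minute of the fully tryptic parent peptide spanning the same
region is classified as in-source fragmentation; otherwise it is
proteolytic (candidates without an observed parent are proteolytic with a
low-confidence flag). Raising the tolerance can only reclassify
proteolytic → in-source, never the reverse. Proteolytic candidates are
matched against an externally predicted protease (calpain) site list
within ±2 residues of the candidate region; the nearest site wins, ties to
the higher score. Predicted sites that coincide with a tryptic cut or fall
into a sub-minimum-length tryptic peptide are reported as unmatchable
context rather than misses. Trypsin/P digestion (cleavage after K/R,
including before proline, ≤ 2 missed cleavages) is delegated to pyteomics.

## Synthetic data

All noise is Normal on the log2 scale, matching the
log2-transform-then-test structure of every arm.

**TMT generator.** Defaults are the study design: 6 time points (0–15 d,
every third day), 5 plexes (one plex = one biological replicate; the
source reports both n = 5 and n = 7 for this design, so the plex count is
an explicit parameter), 500 features, 20% regulated at |log2 FC| = 1.5,
noise sd 0.3, batch sd 0.5, 5% missingness. Regulated features follow one
of seven temporal archetypes — sustained monotone rise/fall, early
peak/dip with gradual decay, mid-course peak/dip, and a fall-then-rise
profile — evaluated by interpolation of anchor values and scaled to the
effect size. Two properties of the archetype set are deliberate:
profiles are smooth and sustained, because differentiation is a continuous
process sampled every three days (a protein elevated at day 3 is still
partly elevated at day 6), and all seven have distinct day-mean rank
orders, because rank-identical shapes (e.g. a monotone rise and a late
plateau) are indistinguishable under Spearman correlation distance by
construction. Batch offsets are drawn per plex and shared by its channels
— exactly the structure the batch regression removes. Missingness is
completely at random at the (feature, plex) level: isobaric reporter
quantification yields all channels of a plex from one identification, so
a feature drops out of whole plexes, not single channels.

**Phospho generator.** 1000 sites on ~333 proteins (unique positions per
protein), residues S/T/Y at 75/20/5%, a configurable fraction (default
10%) below the class-I localization boundary, one or two quantified
multiplicities per site, 2 replicates over the three comparisons.
Regulated sites (10%) shift both replicates of the day 7/0 and day 14/0
ratios by ±1.5; their ±15-residue windows carry a planted S-P motif
(proline at +1, basic residue at −3) at a 60-point excess over the 20%
background rate.

**BioID generator.** 4 constructs × 3 replicates; interactors (15% at
default) are assigned to a single construct and gain +2 log2 in that
construct's light channel over the shared heavy control; noise sd 0.4.
Missingness is left-censored through a logistic curve on intensity (50%
missing at log2 intensity 19, scale 0.7, against a baseline of 22 ± 1.5)
— the not-at-random pattern that justifies minimum-based imputation.

**Cleavage fixture.** A deterministic synthetic 420-residue protein (not
the real Dclk1 sequence) whose tryptic architecture reproduces the
evidence classes of interest: true proteolytic ladders at breaks 320–323
and 356–359 with retention times far from their parents, a co-eluting
in-source ladder at 313–316, a proline-adjacent artifact break, a
predicted site coinciding with a tryptic cut (R342), and a predicted site
inside a 6-residue tryptic peptide (Q384) that is too short to detect.
The predicted-site list {323, 342, 357, 384} is consumed as an external
input, as in practice.

What the generators do *not* emulate: spectrum-level effects (co-isolation,
isotope interference, identification FDR), protein inference, correlated
biological variation between features, and intensity-dependent noise.
Passing recovery tests therefore demonstrates that the statistical rules
behave as specified under their own assumptions, not that the pipelines
are robust to every artifact of real data.

## Problem sizes and numerical choices

Recovery measurements use 500-feature TMT runs (10–20 seeds), a
1000-site phospho table, 400-feature BioID runs (10 seeds) and the fixed
cleavage fixture — sizes at which every recovery statistic stabilizes to
well within the asserted margins while the whole suite stays fast.
Deterministic tie-breaks: complete-linkage input order is feature order;
term simplification orders by (adjusted p, term id); predicted-site
matching breaks distance ties by score. Degenerate inputs: zero-variance
paired differences report p = 1 (zero mean) or the smallest positive
float with a warning (nonzero mean); all-missing matrices are rejected;
constant profiles become singleton clusters.

## Known limitations

- TMT truth recovery at the default design (5 plexes, effect 1.5, noise
  0.3 per value) has feature-level sensitivity ≈ 0.84–0.87, not higher:
  the day-vs-day-0 paired difference carries √2× the per-value noise, its
  variance is estimated on ≤ 4 df, and BH across 500 features leaves an
  effective per-test threshold near 0.004. This is a property of the
  published design, not of the implementation.
- Min-based imputation with 3 replicates inflates within-group variance
  for features with mixed observed/imputed values; the trended prior
  absorbs most but not all of this, so BioID differential sensitivity
  varies noticeably between seeds.
- The motif analysis is a position-frequency comparison; kinase-motif
  catalogue annotation is out of scope.
- Phosphosite-to-protein-level normalization of ratios is out of scope
  (performed upstream in the source tables).
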