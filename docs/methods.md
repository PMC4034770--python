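# Methods

## The measurement model

A 2D-gel experiment yields, per channel (silver densitometry, autoradiogram
greyness), a spots × gels table of strictly positive intensities. Gels are
loaded with a fixed amount of material (equal protein mass, equal cpm of
incorporated label), so only *relative* spot quantities are comparable
between gels. The pipeline therefore treats every gel as a composition:
`normalize_total` divides each column by its total over detected spots.

Two consequences of compositional closure are modelled explicitly and
verified by tests:

* **Scale invariance** — multiplying a raw gel column by any k > 0 changes
  nothing downstream.
* **Dominant-spot distortion** — a spot holding a share *s* of one
  condition's gels depresses every other spot's share there by the factor
  (1 − s), shifting their apparent log2 fold change in contrasts against
  that condition by exactly log2(1 − s). RubisCO's large subunit plays this
  role in N/N→H autoradiograms.

Fold changes are ratios of replicate means, `F_POI = log2(mean_num /
mean_den)` (ratio-of-means rather than mean-of-ratios: robust to
per-replicate dropouts and matching gel-averaging practice). A spot missing
in any required replicate is flagged ND for that contrast; zero condition
means make the ratio undefined and the feature is excluded with a logged
count — the arithmetic never imputes.

## Significance filter and archetypes

Differential spots are found with a classical one-way fixed-effects ANOVA
across the four treatments on the normalized intensities (df₁ = 3, df₂ = 8
at three replicates). The threshold is a *raw* p ≤ 0.01; no multiple-testing
correction is applied by default (a Benjamini–Hochberg option exists). Spots
with missing gels are tested on available data while df₂ ≥ 1; a spot with
zero between- and within-group variance is defined as no evidence (F = 0,
p = 1).

Significant profiles are z-scored per spot (sample SD, ddof = 1; population
SD available via `ddof=0`; zero-variance profiles are excluded with a log
entry) and clustered agglomeratively with euclidean distance and complete
linkage, cutting the tree at k = 4 (a configurable default, not a
hard-coded constant). Cluster labels 1..k follow first appearance along the
dendrogram leaves; tie-breaking is scipy's deterministic pair ordering, so
results are reproducible given the input order.

## Deviation sets and Venn regions

After z-scoring, the all-treatment average of every profile is zero, so
"above/below average in condition c" reduces to a threshold on the mean
z-score over c's replicates: |mean z| ≥ θ, direction by sign. θ defaults to
1.0 standardized unit — an explicit pipeline choice, not an inherited
criterion. One geometric caveat, found while validating the stage: a profile
regulated in exactly 6 of 12 gels (a clean both-H archetype) has condition
means of at most √(11/12) ≈ 0.957 after ddof = 1 standardization, so θ = 1.0
can only be exceeded with the help of noise or asymmetric patterns; analyses
targeting clean two-level archetypes should use θ < 0.95. Region counts are
an exact inclusion–exclusion decomposition; each condition total equals its
specific count plus its overlap regions (property-tested), and percentages
are counts over the significant-spot universe, rounded half away from zero
(the rounding convention used for every percentage in the package). The
4-set diagram is rendered as an UpSet-style exclusive-region bar chart.

## Response factor and concordance

For method m and shift contrast c, v = F_POI / |F_Ext(sign(F_POI), c, m)|,
where F_Ext is the extreme fold change of the matching sign over the
analysed feature set; v preserves sign and lies in [−1, 1], F_POI = 0 maps
to v = 0 (assigned to the positive-sign rule by convention). R_m sums v over
the two shift contrasts, so R ∈ [−2, 2]; the feature attaining both positive
extremes has R = +2 exactly, both negative extremes −2. The extremes are
computed over whatever feature set is supplied — the analysis universe is an
explicit input, never inferred from a larger table.

Deviation from the diagonal of the (R_transcript, R_de_novo) plane is the
coordinate difference d = |R_de_novo − R_transcript| (a band of half-width
0.5 around the diagonal; the boundary d = 0.5 counts as concordant). The
perpendicular distance d/√2 is available via `perpendicular=True`. The
discordant fraction estimates the extent of translational control.

## The synthetic-data generator

`SimulationConfig` defaults are the study conditions: 129 spots, 4 × 3
gels, archetype proportions 8:8:10:8:14 (clusters 1–4 plus the no-pattern
remainder, mirroring the identified-protein catalog), effect size 2 log2
units, replicate noise SD 0.25 log2 units (multiplicative lognormal noise on
positive intensities, so noise is additive on the log2 scale), dominant-spot
share 0.30 of the detected N/N→H gel intensity, ND dropout 8/49, discordance
fraction 0.65. Baseline abundances are lognormal (log2 mean 10, SD 1.5,
arbitrary densitometry units). Where the original study states no value
(noise SD, baseline spread, dominant share), the defaults are realistic
stand-ins exposed in the config, not asserted facts.

Ground-truth effects are recorded on the **relative scale the pipeline
measures**: planting effects changes gel totals, so each true fold change
carries the common per-contrast closure shift δ = log2(ratio of noise-free
non-dominant totals). With noise = 0 the normalize → fold-change stages
reproduce the recorded truth to < 1e-9 once the dominant spot is removed
(verified); with it present, contrasts against N-conditions shift by
log2(1 − s) as derived above. Transcript truths share the same closure
shift (arrays are themselves total-intensity normalized), so coupled
features have identical truths on both levels. Emitted transcript tables add
noise of SD noise_sd/√n_replicates (the standard error of a replicate mean).

Discordant features re-draw the *de novo* side: both H-shift effects are
sign-flipped (or zeroed, per `discordance_mode`); when the flip would leave
the summed response unchanged (patterns with R_t = 0), a fresh same-sign
±effect pair is drawn instead, so every planted-discordant feature has a
true deviation d ≥ 2 ≫ 0.5. The ground-truth `concordant` flag is computed
by running the response-factor statistic on the true effects, which makes it
consistent with the pipeline's own cutoff at zero noise by construction.
The ND dropout is applied before the dominant boost so the dominant share is
exact over the *detected* total. The dominant spot is forced to the
no-pattern class and excluded from dropout and discordance; its truth row
describes its pre-boost behaviour (`dominant` flag set).

What the generator does **not** emulate: spot-boundary/warping errors of
gel image analysis, intensity-dependent noise (CVs are constant on the log
scale), partial (per-gel rather than per-spot) dropout, correlated
replicate effects, and any real biological covariance between archetypes.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not performance on raw gel images.

## Calibration studies (analysis/07)

Each property runs on a purpose-built configuration chosen a priori to
isolate the question:

* **Type-I error** — a pure null (all no-pattern archetypes, no dominant
  spot, no dropout, no discordance), 2,000 spots: a dominant spot boosted
  in N-gels is itself a condition effect and has no place in a null. The
  significant fraction at p ≤ 0.01 must lie within 3 binomial SDs of 0.01
  (observed 0.0090).
* **Archetype recovery** — four balanced archetypes, 400 spots, effect 2,
  noise 0.25, nuisance processes off (discordance would redraw the de novo
  patterns the clusters are defined on). Adjusted Rand index vs planted
  labels ≥ 0.9 (observed 1.0).
* **Discordance recovery** — planted fraction 0.65 over 200 features at
  low noise (SD 0.1): estimate within ±0.07 (observed 0.650).

Problem sizes (2,000 / 400 / 200 spots) are chosen so each study finishes
in seconds while keeping binomial bands tight enough to be informative.

## Numerical choices

* Percent rounding: half away from zero, everywhere.
* ANOVA zero-variance ties: exact SSW = 0 with SSB = 0 → p = 1; SSW = 0
  with SSB > 0 → F = ∞, p = 0.
* Standardization default ddof = 1 (documented, switchable).
* Missing-value sentinel in all TSV dialects: `NA` (configurable).
* All stochastic stages consume a single `numpy.random.default_rng(seed)`
  stream in a fixed draw order; identical config + seed ⇒ byte-identical
  written tables.

## Known limitations

* The ANOVA operates on normalized intensities (shares), which are mildly
  non-Gaussian; at the default noise level the F-test holds its level
  (verified on the null), but heavier-tailed noise would call for a log
  transform or a rank test.
* Whether autoradiograms should be re-normalized on total label beyond
  equal-cpm loading is experiment-specific; both behaviours are supported
  (normalization is a separate, skippable stage).
* The concordance statistic depends on the feature universe through the
  extremes; results are only comparable between runs using the same
  universe.
* Four-set Venn "overlap" counts are exclusive-region counts; the classic
  printed two-set overlaps of small studies correspond to sums of exclusive
  regions containing both conditions.
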