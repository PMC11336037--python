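# Methods

## The model

The package analyzes cross-sectional aging of regional cortical gray-matter
(GM) volumes over the 148 structures of the Destrieux parcelation (74 gyral
and sulcal structures per hemisphere). Inputs are subject-level tables: one
row per subject with population, sex, age `a_i` (years), intracranial
volume `ICV_i` (mm³), and 148 regional volumes `v_ir` (mm³).

**Double normalization.** Head size is removed first, `v'_ir = v_ir /
ICV_i`. Then, within each population × sex group and for each region, an
OLS line `v' = β_r·age + c_r` is fit and every value is expressed as a
percent of the predicted value at the anchor age `a0` (by default the
group's youngest observed age):

    v''_ir = 100 · v'_ir / (β_r·a0 + c_r)

A subsequent slope of `v''` on age therefore reads directly as percent of
anchor-age volume per year, and the group regression of `v''` on age
predicts exactly 100 at `a0` by construction (this is asserted to 1e−6 in
the tests). Regions whose predicted anchor volume is not positive cannot
be expressed on this scale; they are excluded with a logged warning.
Anchoring within population × sex (rather than pooled) matches the
within-group standardization used for effect sizes; the pooled variant is
available (`anchor_grouping="pooled"`).

**Trends and effect sizes.** Per region, OLS of `v''` on age gives the
rate β (%/year), its standard error, and a two-sided p-value from the t
distribution with n−2 degrees of freedom. The standardized coefficient
`β_s` is the slope after z-scoring both variables within the group — in
simple regression it equals the Pearson correlation (asserted to 1e−10).
Effect classes use |β_s| with left-closed boundaries: negligible < 0.10 ≤
small < 0.30 ≤ medium < 0.50 ≤ large. Per-region significance is
Bonferroni-corrected at α = 0.05/148. Tissue-level (e.g. total cortical
GM) trends run the same machinery on a summed volume column.

**Matched-subsample bootstrap.** Confidence intervals for β come from
B = 1000 realizations. Each realization draws `m_sub = 100` study subjects
*without replacement* (the study groups are several times larger than the
subsample, so this is a subsample rather than a classical resample; a
with-replacement mode exists for the calibration regime below) and a
reference subsample of the same size and sex matched on *integer age*:
for each sampled study subject, one not-yet-used reference subject with
the same integer age, with a nearest-age fallback (ties split at random)
that is counted and logged, never silent. With an ample reference pool the
reference subsample reproduces the study subsample's integer-age histogram
exactly. Per-region slopes of both subsamples are recorded at every
realization; `μ(β)`, `σ(β)` and percentile intervals summarize the draws.
`H0: β = 0` is rejected when the percentile interval excludes zero.
Seeding: realization k uses the k-th spawn of `SeedSequence(seed)`, so
realizations are order-independent.

**Between-population comparison.** Per region, the study and reference
draw sets are compared with Welch's unequal-variance t-test, with the
number of realizations B as the per-side sample size and
Welch–Satterthwaite degrees of freedom. This reading reproduces the
published worked examples: e.g. means (0.41, −0.37) with SDs (0.29, 0.18)
at n = 1000 per side give t = 72.3, printing as 72. A ternary indicator
summarizes each region at the Bonferroni threshold α = 0.05/148:

    m(r) = +1  study slope significantly more negative (study declines faster)
           −1  significantly less negative
            0  no significant difference

and the cortical summary is κ = 100·Σ_r m(r)·w_r, where `w_r` is region
r's fraction of total cortical GM volume (group-mean region volume over
group-mean total; fractions sum to 1). κ ∈ [−100, 100] and satisfies
κ = 100·(f₊ − f₋) for the directional weight fractions exactly. Whose
volumes define `w_r` is not uniquely determined by the published
description; the default uses the study group (keeping κ interpretable for
that population), with `reference` and `pooled` as configuration options.
Per-hemisphere κ is reported in two variants — weights renormalized within
the hemisphere, and the raw hemisphere contribution — because the
published description does not fix this either.

**CT/MRI agreement.** Per region, the average CT−MRI difference `Δv_r` is
computed over the paired validation sample, in mm³ or in percent of the
MRI volume. The scalar summary ϖ defaults to the weighted mean absolute
percent difference, `ϖ = Σ_r w_r·|Δv_r^%|` with fractional weights, which
reads as "CT differs from MRI by ϖ percent of the MRI volume on average";
the alternative `(1/R)·Σ_r w_r·|Δv_r|` convention (weights in percent,
deltas in mm³) is computed alongside. The two cannot agree numerically —
the second is brain-size dependent — and only the first supports the
percent-of-MRI interpretation, which is why it is the default.

**Mediation.** Whether a mediator (visuospatial "stick design" score, or
minutes of moderate daily activity) transmits part of the age effect on a
volume of interest is assessed by the product of coefficients on one
complete-case sample of within-group z-scores: `volume ~ age` (total β_a),
`volume ~ age + mediator` (direct β′_a, mediator path β′_t),
`mediator ~ age` (β_b). The indirect effect is β_b·β′_t, and

    β_a = β′_a + β_b·β′_t

holds exactly (to 1e−10) on any complete-case sample — the module's
primary correctness oracle. Inference bootstraps rows with replacement
(1000 iterations): percentile CI, sign-flip percentile p, and a
product-over-bootstrap-SE z statistic (one- and two-sided p both reported,
since published mediation p-values are sometimes one-sided). Rows with a
missing mediator are dropped (complete-case), with a logged warning above
50% missingness. The pipeline's volume of interest is the summed volume of
structures with positive trends and |β_s| > 0.10 within the group.

## The synthetic cohort generator

Real subject-level data for such studies are access-restricted, so a
generator emulates exactly the structure the analysis relies on. For
subject i in group g:

    v_ir = ICV_i · 0.35 · share_r · (1 + slope_gr·(a_i − 46)/100 + ε_ir)

with `ICV` lognormal (median ≈ 1.45×10⁶ mm³, log-SD 0.08, females ≈ 10%
smaller), `share_r` deterministic left/right-symmetric cortical shares
spanning about a fourfold size range and summing to 1, the factor 0.35
placing total cortical GM at a realistic fraction of ICV, and
ε ~ N(0, 5%) homoscedastic per-region noise on the percent scale. Because
volumes are exactly proportional to ICV, `v'` is linear in age and the
fitted `v''` slope recovers `slope_gr` (%/year of anchor-age volume).
Ages are uniform on 46–83 by default (maximizing regression information
for recovery tests); a truncated-normal option reproduces study-like
moments (mean ≈ 60, SD ≈ 9). Default cell sizes are 700 per study
population × sex and 2000 per reference sex — the study-scale conditions
used throughout the calibration experiments — and default slopes give the
study groups faster overall decline with a small posterior
occipital/parietal set of positive-trend structures, reference males
−0.35 %/yr and reference females −0.15 %/yr everywhere, so female
study-vs-reference comparisons come out strongly positive on κ and male
ones mixed.

Mediators: a latent `m = 0.5·z(age) + N(0,1)` drives a bounded 0–12 stick
score (affine transform, rarely clipped) and a dedicated `mediated_volume`
channel `0.2·z(age) + 0.3·m + N(0,1)`, so the generative indirect effect
is 0.15. The *regional* volumes deliberately carry no mediator pathway:
pipeline mediation on the regional volume of interest behaves as a null,
and recovery tests use the explicit channel. `moderate_minutes` is
age-correlated activity noise with no volume pathway. Validation pairs
apply a per-region multiplicative CT-vs-MRI offset δ_r ~ N(2.5%, 1%)
shared across subjects (a systematic per-structure segmentation bias); a
uniform offset of exactly 2.5% forces ϖ (weighted-percent) = 2.5 by
construction, which anchors the agreement metric's scale.

What the generator does **not** emulate: spatial covariance between
neighboring regions, heteroscedastic or age-dependent noise, non-linear
trajectories, demographic confounding, missingness mechanisms, or any
image-level artifact. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated model, not robustness to real
acquisition and segmentation noise.

Seeding: one master seed; the cohort, validation pairs and stand-alone
mediation datasets use fixed child sequences (`SeedSequence([seed, k])`,
k = 0, 1, 2), so each table regenerates independently and byte-identically.

## Numerical and design choices

- Slopes are computed by the closed-form centered formula (equivalent to
  `scipy.stats.linregress`, cross-checked in tests); all 148 regions are
  fit in one vectorized pass per bootstrap realization.
- Percentile CIs (assumption-light) are the default; normal-approximation
  μ ± z·σ is not used for inference.
- The Welch test runs on draw summaries (mean, SD, B); a draws-level
  variant (`scipy.stats.ttest_ind`) must agree to 1e−9 and is tested.
- Degenerate inputs: constant ages are a hard error; zero-variance regions
  get `β_s = NaN` and an `undefined` effect class; non-positive ICV and
  anchor predictions error/exclude with the offending subject or region
  named.
- Calibration experiments run at the study-scale conditions (n = 700,
  B = 1000, subsamples of 100). The type-I calibration of the percentile
  slope test uses the classical with-replacement regime at n = 700: the
  percentile interval is mildly anti-conservative at much smaller n
  (empirically ~7% rejection at n = 100, a known finite-sample property of
  the pairs bootstrap), so the calibration check is meaningful only where
  its asymptotics apply. The matched-subsample CI, whose draws have the
  dispersion of size-100 subsamples, is *conservative* for the full-group
  slope; its coverage of the generative slope across regions is
  correspondingly high.
- Bonferroni-corrected percentile tests at α = 0.05/148 need extreme
  quantiles of the draw distribution; with B = 1000 these are coarse, which
  is inherent to the percentile approach at this B.

## Known limitations

- Cross-sectional slopes are not atrophy measurements; the package
  estimates age associations, not within-subject change.
- κ inherits every thresholding artifact of `m(r)`: a region just missing
  the Bonferroni cut contributes 0 regardless of its effect size.
- The verbatim ϖ convention is reported but has no percent interpretation;
  consumers should prefer the weighted-percent value.
- With the generator's modest 5% noise, Welch t magnitudes on synthetic
  draws are larger than those typical of real cohorts; comparisons of
  magnitude across data sources are not meaningful.
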