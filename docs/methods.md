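# Methods

## The question and the design

Siblings growing up with less-educated parents might face more variable
household environments (nutrition, illness), which the bioecological
hypothesis predicts should *mask* genetic differences — lower heritability
and more shared-environmental variance of height at low parental education,
the reverse in enriched environments.  The classical twin design can test
this: monozygotic (MZ) co-twins share their full genome, dizygotic (DZ)
co-twins on average half of the segregating alleles, and both share the
family environment, so the pattern of MZ vs DZ cross-twin covariances
identifies the additive-genetic (A), shared-environmental (C) and
unique-environmental (E) variance components.  `twinmod` stratifies this
decomposition by a family-level moderator (parental education category) and
asks, by meta-regression over strata, whether the components differ.

## Stage by stage

### Synthetic cohorts

The generator emulates a pooled multinational twin database: several
cohorts with distinct regions, birth-year ranges, mean-height offsets, and
education offsets; measurements at configurable single-year age groups with
exact ages jittered within the band; and a zygosity mix of 38% MZ, 34%
same-sex DZ, 28% opposite-sex DZ (split evenly by sex within MZ and SSDZ).
Latent pair deviations are built so the cross-twin correlations hold
exactly: the additive part of a DZ pair is √r·z_shared + √(1−r)·z_own with
r = 0.5 (same-sex) or r = r_os (opposite-sex); the shared environment uses
one draw per family; E is independent per twin.  DZ twins receive a small
mean advantage (`dz_mean_delta`, default 0.3 cm), consistent with DZ twins
running slightly taller than MZ twins, which is why the model later allows
separate MZ/DZ means.

Parental education is generated at the family level: each parent's years
are a cohort- and birth-year-dependent mean plus a bivariate-normal family
deviation (SD 2.5 years per parent, couple correlation 0.45 — educational
homogamy), clipped to 0–30 years.  The education *stratum* of a family is
assigned by the same ±0.5 SD cut of the summed deviations that the
preprocessing later applies to its estimated residuals, so the generating
label is recoverable downstream up to estimation noise at the cut
boundaries (a small, n-dependent misclassification fraction concentrated
near ±0.5 SD).  The distribution of education within cohorts in real
registries is unknown to us; the linear-trend-plus-homogamous-deviation
model is a design choice recorded in the config, and a gene–education
correlation is deliberately absent (the generator's education draw is
independent of the latent genetic values).

Default per-stratum variances (A=33, C=6, E=9 cm² male; 28/6/8 female,
r_os = 0.45) give total SD ≈ 6–7 cm and heritability ≈ 0.7, typical of
adolescent/adult height; variances are constant over age by default, a
simplification (real height variance grows with age).

What the generator does *not* emulate: longitudinal correlation of the
latent deviations across ages (each measured age redraws them), secular
height trends, assortative mating, measurement error of self-reported
height, dominance variance (available only through the model's ADE variant,
not the generator), and real cohorts' unequal sizes.  Passing tests
therefore demonstrate correctness of the estimators under the stated model,
not robustness to those real-data features.

### Preprocessing

Age bands are half-open: group k covers [k−0.5, k+0.5) years for k = 1..19,
[19.5, 70) is the adult band (labelled 20), ages < 0.5 or ≥ 70 are excluded
(the 19/adult boundary at 19.5 is a convention; any choice in [19.5, 20)
affects only which band a sliver of ages joins).  Within each person × age
group the youngest measurement is kept, ties broken by input order.
Manual outlier inspection is not reproducible, so the package uses a
one-pass symmetric z-score filter within age × sex groups (default
z = 4, removing ≈ 2·Φ(−4) ≈ 0.006% of normal data; groups with < 3 records
pass through with a warning).

Height is residualized on exact age and cohort indicators within each
age × sex group by OLS; rank-deficient designs (e.g. a cohort with one
observation) fall back to the minimum-norm solution, which leaves the
residuals well defined.  Each parent's education is residualized, one row
per family, on cohort indicators and the twins' birth year; the two
residuals are summed, standardized by the sample SD of the sum, and cut at
±0.5.  Boundary values (exactly ±0.5) belong to the middle category.  The
SD is computed over the whole analysis dataset by default and per region
when `sd_scope="region"` (for regional analyses).  Standardize-then-cut and
cut-at-±0.5·SD-of-the-raw-sum are the same operation; the standardized
score is also what the association stage uses, so its slope is per SD of
combined parental education.  Families missing either parent's education
are excluded from categorized analyses (counted, logged) — a conservative
choice over imputation.

Pairs are complete-case per age group, ordered male-first for opposite-sex
pairs and by person id otherwise, making every downstream statistic
invariant to input row order.

### Mean association

Within each age × sex (× region) group, the height residual is regressed on
the standardized combined education score plus zygosity indicators
(MZ/SSDZ/OSDZ — DZ twins are slightly taller and slightly differently
educated, so zygosity is a confounder of the mean association).  Because
co-twins' errors are correlated, the coefficient covariance is the cluster
sandwich (XᵀX)⁻¹[Σ_g Xᵀ_g e_g eᵀ_g X_g](XᵀX)⁻¹ with clusters = pairs.  The
default small-sample factor G/(G−1)·(N−1)/(N−k) follows the convention of
the major survey-regression packages; `cr0` and `g-only` are selectable
since conventions differ across software.  With every observation its own
cluster the default reduces exactly to HC1.  95% intervals use the normal
quantile by default (the intended datasets have thousands of pairs per
group); t with G−1 degrees of freedom is a flag.

### Sex-limitation ACE model

Five groups (MZM, MZF, DZM, DZF, OSDZ) are fitted jointly per stratum.
Expected covariances are as in the README; the opposite-sex genetic
correlation r_os is bounded to [0, 0.5] — the same-sex DZ value is the
natural upper bound and sex-limitation can only reduce it — and the
cross-sex shared-environment correlation is fixed at 1 (only the genetic
correlation is freed).  The ADE variant swaps the C slot for dominance
(cross-twin coefficient 1.0 MZ / 0.25 DZ); C and D are not jointly
identifiable in a twins-only design.

**Parameterization.**  Variances are optimized directly under nonnegativity
bounds rather than through Cholesky/path coefficients: the boundary Ĉ = 0
is then representable exactly, estimates are never sign-flipped, and the
reported numbers are the raw variances the meta-regression consumes.

**Likelihood and optimization.**  The per-pair bivariate-normal likelihood
is evaluated through per-group sufficient statistics (count, mean, scatter),
making each evaluation O(1) in the number of pairs; the public
`neg_loglik` sums per pair and equals the fast path to ~1e-11.  Singular
implied covariances yield +inf, never an exception.  L-BFGS-B runs from
moment-based starts (A₀ = 2(r_MZ − r_DZ)·V̂, C₀ = (2r_DZ − r_MZ)·V̂ clipped
at 0, E₀ the remainder) plus jittered restarts (default 3 for single fits,
2 inside `fit_by_stratum`, where the moment starts are reliable and many
cells are fitted).  Ties between restarts resolve to the lowest objective.

**Uncertainty.**  Parameter covariance comes from the inverse observed
information, computed by bound-aware central finite differences (one-sided
at active bounds, where the constrained-side curvature is still defined).
If the information matrix is not positive definite — typical at boundary
estimates — the fit falls back to a parametric bootstrap (default 100
refits, seed recorded in `bootstrap_seed_`).  Standardized components
a² = A/(A+C+E) get delta-method variances; profile-likelihood intervals
are available per parameter for headline per-stratum reporting, while the
meta-regression consumes the information/bootstrap variances.

Cells below `min_pairs` (default 50) are skipped and logged.  If the OSDZ
group is absent, r_os is fixed (unidentified) and flagged.  Each pair
enters exactly one analysis per age group; no longitudinal model links age
groups.

### Meta-regression

Each stratum contributes, per sex, its raw A, C, E (or standardized a², c²,
e²) with sampling variance.  τ² is estimated by the method of moments
(generalized DerSimonian–Laird: τ̂² = max(0, (Q_res − (k − p))/tr(P)),
deterministic and exactly zero for zero residuals) with REML by flag;
coefficients by WLS with weights 1/(vᵢ + τ²); Wald normal intervals by
default, Knapp–Hartung (truncated at 1) by flag.  Moderators are education
category (reference low), age-group and region indicators, and — in the
pooled "both sexes" run — male and female rows entered separately with a
sex indicator (rather than a single sex-averaged effect; both per-sex runs
are always available).  A cluster-robust coefficient covariance
(``fit(..., clusters=...)``) is exposed for effect rows known to share an
underlying fit, though in simulation the cross-sex sampling correlation of
the components within one joint fit proved negligible at the cell sizes the
pipeline produces.  When the same pairs contribute to multiple
age-group strata the tool warns that the meta-regression SEs ignore that
dependence and the CIs are somewhat too narrow; age-specific results do not
have this problem.

## Numerical choices and degeneracies

- OLS residualization uses `lstsq`; collinear columns are pruned (pivoted
  QR) in the association design with a warning.
- Cut boundaries ±0.5 → middle category; zero variance of summed education
  residuals is an explicit error.
- The likelihood returns 1e12 inside the optimizer (finite, step-back
  friendly) and +inf from the public function for non-PD covariances.
- Standardized components sum to 1 by construction (same denominator).
- Empty simulation configs return an empty dataset with a warning; empty
  groups warn and reduce the model rather than crash.

## Problem sizes in the shipped checks

The test suite and acceptance script run entirely on synthetic data sized
for routine desktop compute: covariance-structure checks at 20,000 pairs
per group; parameter recovery at 5,000 pairs per group plus 50 replicates
at 2,000; the end-to-end moderation study at 20 age groups × 3 categories
× ~3,000 pairs per age block (120 meta-regression strata), 50 replicates in
the test suite and 10 in the acceptance script; cluster-CI coverage over
500 replicates.  These sizes are the package's own choices for a
reproducible demonstration; all are configurable upward.

## Known limitations

- Wald intervals for variance-component contrasts in the meta-regression
  are mildly anti-conservative at moderate stratum sizes: in the shipped
  end-to-end moderation study (~150–320 pairs per zygosity group per cell)
  the realized coverage of the 95% CIs is about 88–90% rather than 95%,
  a combined effect of the zero boundary, estimator skewness and the
  estimated sampling variances.  Coverage approaches nominal as cells grow;
  per-sex and pooled runs behave alike (the cross-sex sampling correlation
  within a joint fit is negligible at these sizes), and Knapp–Hartung
  scaling does not change it (the residual scale sits at its truncation
  point).  Treat borderline meta-regression significance accordingly.
- Sampling variances of variance components from the observed information
  can be optimistic in small strata; the bootstrap fallback mitigates only
  the singular cases.
- The moderator is categorical; continuous gene–moderator interaction
  models are out of scope.
- No dominance-plus-shared-environment model (not identifiable here), no
  assortative mating, no measurement-error model for self-report.
- Region handling is a config-level label per cohort; the package does not
  infer ancestry or population structure.
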