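# Methods

## The axial-length estimation model

Axial length is modelled as a linear function of mean corneal radius of
curvature and spherical equivalent refraction:

    AL = beta_k * K + beta_se * SE + intercept + epsilon

The bundled default carries the published fit on 650 young-adult right
eyes with post-cycloplegic refraction:

| parameter  | value   | units    | meaning                                   |
|------------|---------|----------|-------------------------------------------|
| beta_k     | 2.102   | mm/mm    | flatter corneas accompany longer eyes     |
| beta_se    | −0.4125 | mm/D     | each dioptre of myopia ≈ +0.41 mm of AL   |
| intercept  | 7.268   | mm       | —                                         |
| R²         | 0.794   | —        | variance explained in the training cohort |
| residual SD| 0.486   | mm       | SD of AL_est − AL_act in validation       |

Assumptions worth knowing before trusting the estimate: the model was
trained on healthy, phakic, predominantly Caucasian eyes with normal
anterior segments; it contains no age term (population data show age adds
little once refraction is in the model), and it will mis-estimate eyes
whose refraction has been decoupled from AL — contact-lens wearers at the
time of keratometry, post-refractive-surgery and keratoconic eyes. Sites
imaging different populations or instruments can refit with
`fit_al_model` / `octamag fit` and drop the resulting JSON model into the
same pipeline.

**Units.** The regression consumes K as a radius in millimetres.
Keratometers reporting dioptric power are converted with the keratometric
index convention r = 337.5/K_D. Only the millimetre reading makes the
published cohort means (K ≈ 7.76 mm) consistent with the published
mean differences, which is why the package treats mm as canonical.

**SE convention.** SE = sphere + cylinder/2, agnostic to plus/minus
cylinder notation. Cycloplegia is metadata: the formula is identical, but
non-cycloplegic SE is biased toward myopia (accommodation), which
propagates into AL_est as a positive bias of roughly
0.4125 × (accommodation shift) mm; reports carry the flag so post- and
non-cycloplegic comparisons stay separable.

**Sanity bounds.** Estimates outside [15, 40] mm are logged as warnings
rather than raised, so one keyed-in 77.6 mm cornea does not kill a batch
run. The bounds are arguments, not constants.

## Magnification correction

The ocular magnification factor of the Bennett relation is
q = 0.01306 × (AL − 1.82), with AL in mm and 1.82 mm the corneal-apex
offset at which the relation is anchored; q is undefined at or below it
and the package raises. True linear fundus dimensions follow the Littmann
relation D_t = p·q·D_m with the instrument factor p; areas scale by
(p·q)².

Two deliberate choices:

* **Areas use (p·q)², not q² alone.** q ≈ 0.289 for a typical eye, so
  squaring q alone would shrink areas twelvefold; only the full linear
  factor p·q (≈ 1.006 for the reference eye on the bundled device) yields
  the near-unity corrections observed in practice. The sentence-level
  ambiguity in common descriptions of "multiplying by the square of the
  linear magnification factor" is resolved in favour of the Littmann
  relation.
* **p is used exactly as published (3.48)** even though p·q(23.95) =
  1.00578 rather than 1 at the device's own assumed AL. Users who want
  measured == true at the reference AL can enable `ratio_mode`, which
  scales by q(AL)/q(reference AL) instead; it is off by default to match
  the published convention.

The constants 0.01306 and 1.82 are fixed model constants, overridable
only through explicit keyword arguments intended for expert
re-parameterisation. The device registry bundles only the RTVue XR Avanti
profile (p = 3.48, reference AL 23.95 mm, 3-mm scan); other vendors'
factors are not bundled because they cannot be verified, but load from a
schema-checked JSON registry (`name`, `p_factor`, `reference_al_mm`,
optional `scan_width_mm`; unknown keys are rejected).

The package emits scale factors and corrected scalar measurements; it does
not resample image pixels (the `pixel_scale` helper gives the true
on-retina sampling pitch for image tooling to use).

## Agreement statistics

Differences are (first method − second method), the first argument being
the estimate/uncorrected series, the second the reference; every report
states the direction because sign conventions are a classic source of
silent error in method comparison.

* **Limits of agreement**: d̄ ± 1.96·SD, sample SD (n−1). The coverage
  multiplier is an argument; 1.96 is the default and is used as printed
  rather than the exact normal quantile.
* **Confidence intervals**: SE(d̄) = SD/√n and the classical Bland–Altman
  approximation SE(LoA) = SD·√(3/n), both with a 1.96 multiplier. This is
  the variant that reproduces published LoA CIs in this literature; an
  exact-t option (t quantile, SE(LoA) = SD·√(1/n + z²/2(n−1))) is
  available and is slightly wider at small n.
* **Paired t**: t = d̄/(SD/√n), df = n−1, two-sided p. Zero SD raises
  rather than returning ±inf.
* **ICC**: two-way random-effects, absolute agreement, single measures —
  ICC(A,1)/ICC(2,1) — computed from the ANOVA mean squares with McGraw &
  Wong F-distribution confidence bounds. Absolute agreement is the right
  family here because a systematic offset between AL_est- and
  AL_act-corrected FAZA is exactly what must be penalised; the variant is
  pinned and documented rather than configurable-by-accident. The test
  suite cross-checks the implementation against pingouin's independent
  one and against a hand-computed three-subject oracle.
* **CR exceedance**: percentage of pairs with |difference| strictly
  greater than the coefficient of repeatability (default 0.052 mm², the
  published replicate-scan repeatability of FAZA on this device in
  healthy eyes). Strict inequality: a difference exactly at CR is within
  tolerance. CR is an input constant; estimating it from replicate scans
  is out of scope.
* **Relative change**: per-pair 100·|reference − other|/reference, with
  the maximum relative and absolute change reported. References must be
  positive.

p-values display as three decimals floored at "< 0.005" in formatted
tables; machine-readable JSON always carries full double precision.

A caveat on reconstructing results from published summaries: because the
model is linear, a cohort's mean AL difference is recoverable from its
mean K, mean SE and mean AL — but only when all three summaries describe
exactly the same eyes in the same refraction state. Published summary
rows are not always internally consistent at that level (rounding, or a
t-statistic that does not reproduce from its own printed d̄/SD/n), so the
test suite pins its fixtures to rows whose internal arithmetic closes,
and treats the others as unusable rather than as targets.

## Synthetic cohorts

`generate_cohort` emulates a young-adult biometry cohort at the
measurement level:

| quantity              | default distribution       | units |
|-----------------------|----------------------------|-------|
| K (corneal radius)    | N(7.76, 0.26)              | mm    |
| SE (post-cycloplegic) | N(−0.15, 1.62)             | D     |
| AL residual           | N(0, 0.486)                | mm    |
| accommodation shift   | N(−0.43, 0.30), added to SE| D     |
| true FAZA             | N(0.25, 0.10), floor 0.05  | mm²   |

AL is generated *conditionally* on (K, SE) through the regression, not
jointly from an empirical covariance matrix. That is a simplification —
real AL/K/SE have richer covariance — chosen because it makes coefficient
recovery a well-posed experiment: the refit's estimand is exactly the
generating vector, and the implied refit R² (≈ 0.75 at these spreads)
lands close to the published training value. The accommodation shift's
mean is the training cohort's post-minus-non-cycloplegic SE gap; its SD is
a free parameter since no replicate data exist to pin it.

The uncorrected FAZ area is constructed as the exact inverse of the
forward correction at the eye's true AL,
FAZA_measured = FAZA_true/(p·q(AL_act))², so correcting with the true AL
recovers the truth to machine precision (the closure property the tests
assert at 1e-10) and any residual discrepancy after correcting with an
estimated AL is attributable to the estimate alone. Optional FAZ
measurement noise defaults to 0 mm² for the same reason.

What passing tests on these cohorts do **not** show: robustness to
segmentation error, to SQI-dependent noise (scans are treated as
homogeneous above the quality floor, mirroring the usual SQI ≥ 7 filter),
to non-normal refraction tails in highly myopic clinics, or to diseased
or anterior-segment-altered eyes.

All randomness flows from the single integer seed in the `CohortSpec`
through one `numpy.random.default_rng` generator; identical spec + seed
reproduce the cohort bit for bit, across platforms. The Monte-Carlo
harness `emulate_ba_summaries` spawns per-replicate seeds from a
`SeedSequence` of its own seed argument.

## Numerical and interface choices

* OLS refits go through statsmodels; residual SD uses denominator n−3;
  an exact 3-point interpolation reports residual SD 0 and R² 1.
  Rank-deficient designs (no variation in K or SE) raise instead of
  silently pseudo-inverting.
* Degenerate agreement inputs are explicit errors: < 2 pairs, zero
  difference SD for t, zero total variance for ICC, non-positive
  denominators for relative change.
* CSV ingestion is deterministic, not sniffed: fixed column names
  (`participant_id, eye, k1_mm, k2_mm, k_mean_mm, k_power_d, sphere_d,
  cylinder_d, se_d, cycloplegic, al_act_mm, faza_mm2, sqi`), a `--map`
  option for renames, empty cells for missing values, `#` comment lines
  for provenance headers. Keratometry resolves k_mean_mm, then
  (k1_mm, k2_mm), then k_power_d; SE resolves se_d, then
  sphere_d + cylinder_d/2. Bad rows are skipped with logged line numbers
  unless `--strict`.
* Outputs are written atomically (temp file + rename) with a provenance
  comment (version, config hash, seed where applicable).
* Synthetic-cohort CSVs carry `faza_true_mm2` and `se_noncyclo_d`
  columns that exist only for generated data and are clearly
  ground-truth-only.

## Problem sizes

The default test suite and the acceptance script work at the study's own
scales — 650-eye cohorts for fit/recovery (200 seeded repetitions for the
coverage check), 46-eye cohorts for the FAZA pipeline — and complete in a
few seconds on one CPU.

## Known limitations

* The estimation model and the generator describe healthy adult eyes;
  neither should be extrapolated to paediatric, highly myopic, aphakic or
  post-surgical populations without refitting.
* The Littmann–Bennett correction itself assumes an unaltered anterior
  segment; for eyes with contact lenses or refractive surgery, AL-only
  correction is known to be insufficient.
* Vessel-density correction, OCTA image resampling and FAZ segmentation
  are out of scope; the package operates on scalar measurements.
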