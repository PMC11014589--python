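# Methods

## The crowding model and the letter count λ

Crowding distance is modeled by the Bouma law: the radial threshold spacing
at eccentricity φ (deg) is s_r = b(φ + φ₀), and the tangential spacing is
s_t = s_r/a. Parameters, units and defaults:

| parameter | meaning | unit | default |
|---|---|---|---|
| b | Bouma factor (slope of spacing vs eccentricity) | – | per observer |
| φ₀ | foveal offset of the linear law | deg | 0.24 |
| a | radial/tangential elongation of crowding zones | – | 2 |
| φ_max | radius of the analyzed visual field | deg | 10 |

Packing letters at threshold spacing gives a local density 1/(s_r·s_t)
letters/deg². Integrating the density over the disk of radius φ_max in polar
coordinates (the angular integral is exactly 2π; the radial integral uses
∫ φ/(φ+φ₀)² dφ = ln(φ+φ₀) + φ₀/(φ+φ₀)) yields the closed form

λ = (2πa/b²)·[ln(1 + φ_max/φ₀) − 1/(1 + φ₀/φ_max)],

which is 34.9·b⁻² at the defaults. Because the count diverges
logarithmically as φ₀ → 0, `uncrowded_letter_count` rejects φ₀ = 0. The
closed form is re-derived here rather than transcribed, so an independent
quadrature oracle (`uncrowded_letter_count_numeric`, scipy `quad` on the
radial integral at 1e-10 relative tolerance) guards it in the test suite at
≤1e-6 relative error; with φ₀ = 0 the oracle requires an explicit positive
inner radius. λ is kept as a real number and rounded to whole letters only
for reporting.

`letter_layout` is a visualization aid: concentric rings whose radii advance
by the radial crowding distance evaluated midway between consecutive rings
(closed-form implicit midpoint step for the linear law), with the per-ring
letter count floored from arc length / tangential spacing. Its full-field
count approximates λ to within discretization (~8% at b = 0.34); it makes no
claim to optimal packing.

## From thresholds to Bouma factors

Each threshold (4 cardinal meridians × 2 eccentricities × 2 sessions per
observer) is converted to a Bouma factor by dividing by the target
eccentricity; the φ₀ offset is deliberately omitted in this conversion
(negligible at the eccentricities used) while λ is always evaluated with
φ₀ = 0.24. Spacing thresholds are multiplicative quantities, so every
aggregation is geometric: per-session factor = geometric mean over the 8
locations, per-observer factor = geometric mean over sessions. With complete
data this equals the geometric mean of all 16 values. Missing locations are
tolerated with a logged warning (the mean is taken over what is present);
the study design assumes complete data. Test–retest reliability is the
Pearson correlation of per-session λ across observers, and the session
effect is summarized as the geometric mean of per-observer session-2/
session-1 λ ratios.

## The conservation fit

Conservation of cortical crowding distance states λ = kA with k constant
across observers. `ConservationRegressor` fits k by least squares through
the origin (k = ΣAλ/ΣA²; verified in tests against brute-force grid search)
and reports c = k^(−1/2) in mm and the variance explained
R² = 1 − Σ(λ−kA)²/Σ(λ−mean λ)². R² can be negative because the origin line
is not nested in the mean-only model; a cohort with constant λ has no
defined R² and is rejected (the estimator returns NaN there, since the
slope itself is still defined). Association is also summarized
symmetrically: Pearson's r, and covariance ellipses in standardized
coordinates, where the covariance matrix becomes the correlation matrix
with eigenvalues 1 ± r; semi-axes are n_sd·√(1 ± r) on the ±45° diagonals,
so r = 0 draws a circle.

Uncertainty: percentile bootstrap over observers (rows resampled with
replacement, λ and all areas paired), 68% and 95% intervals from the
16th–84th and 2.5th–97.5th percentiles, 10 000 resamples by default, fully
determined by an integer seed. k is refit inside every resample (this also
underlies the R² and c intervals). Degenerate resamples (zero variance)
yield NaN for r/R² and are dropped with a logged count. The implementation
is vectorized and was checked against `scipy.stats.bootstrap` (percentile
method) to numerical identity of the interval endpoints.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any particular dataset:

* **Bouma factors** are lognormal, median 0.27, log-SD 0.17 — about a
  2-fold range across healthy adults.
* **Thresholds**: each of the 16 per-observer thresholds is b·φ·exp(η),
  η ~ N(0, 0.10) per location and session. 0.10 log-units puts the
  between-session reliability of λ at r ≈ 0.96. Thresholds are generated
  proportional to eccentricity (no φ₀), matching the analysis convention,
  so the pipeline is unbiased for b by construction.
* **Practice effect**: a 10% session-2 λ gain, applied symmetrically in the
  log domain (session-1 thresholds × gain^¼, session-2 ÷ gain^¼). The
  session-2/session-1 λ ratio is exactly the gain while the session-
  combined Bouma factor stays centered on the true value; applying the gain
  to one session only would bias combined λ by √gain.
* **V4 area** is tied to λ by a true cortical crowding distance
  c_true = 1.36 mm. The joint (λ, A_V4) distribution is generated
  *area-first*: A_V4 is lognormal, and λ = (A_V4/c_true²)·exp(ηc) with
  mean-one lognormal conservation scatter ηc (log-SD 0.25, the
  `v4_area_log_noise_sd` parameter); the true Bouma factor is then derived
  from λ. Log-mean shifts of ±half the scatter variance keep
  E[λ|A] = A/c_true² — so 1/c_true² is the exact population slope of the
  through-origin regression — and keep the Bouma-factor median at
  b_median. Placing the conservation scatter in the dependent variable is
  what real cohorts look like: with the scatter in A instead, errors-in-
  variables attenuation caps the origin-line R² near zero at any
  correlation, whereas empirically a λ–A correlation of ~0.65 coexists
  with R² ≈ 0.4. Closed-form lognormal moment algebra gives, at these
  defaults, r ≈ 0.65 and R² ≈ 0.43, both confirmed by Monte Carlo.
* **V1–V3 areas** are lognormal (medians 2800/2790/1980 mm², log-SD 0.15)
  and independent of crowding, so their λ–A correlations form a null band.
* **QUEST simulator** (optional measurement layer): a Bayesian staircase on
  a discrete log₁₀-spacing grid. The simulated observer responds through
  the Weibull family ψ(x) = δγ + (1−δ)(1 − (1−γ)·exp(−10^{β(x−T)})) with
  guess rate γ = 1/9 (9-letter alphabet), lapse rate δ = 0.01 and slope
  β = 2.3; each of the 35 trials is placed at the posterior mode and the
  estimate is the posterior mean. Grid (step 0.01, half-width 2 log units),
  prior SD (0.6) and slope are conventional staircase settings and are
  config-exposed rather than hard-coded, since they are not uniquely
  determined by the measurement procedure being emulated. Trial count,
  guess and lapse rates follow the emulated procedure.

What the generator does **not** emulate: meridional asymmetries of
crowding, eye movements and fixation-triggered trial repeats, letter
confusion structure, acuity limits, hemispheric asymmetries beyond a random
L/R split of bilateral area, and any fMRI measurement detail (researcher
disagreement in map delineation is not modeled; simulated areas are "true"
areas plus conservation scatter). Passing tests therefore demonstrate
correctness and calibration of the *analysis* under the assumed statistical
structure — not that real data satisfy that structure.

## Parameter recovery and coverage

`recovery_experiment` repeats, on independent seeds: generate cohort →
pipeline → per-map conservation fit → 68% bootstrap CI for c in V4, and
reports bias, SD, per-map mean r and median R², and the empirical CI
coverage of c_true. With all noise at zero, recovery is exact to machine
precision and every CI has zero width. At the defaults (49 observers), the
68% CI coverage sits near 0.67 over hundreds of replicates; the residual
1–2 point shortfall from nominal reflects the usual small-sample behavior
of percentile intervals for a ratio statistic. The shipped acceptance test
uses 400 replicates with 1000 resamples per CI; the CLI default remains
10 000 resamples for single-cohort analyses. Monte-Carlo problem sizes
throughout the test suite (200-seed null bands, 1000 staircase runs,
400-replicate coverage runs) were chosen to keep Monte-Carlo error several
times smaller than the asserted tolerances.

## Numerical and design choices

* Quadrature: angular integration is exact (factor 2π); only the radial
  integral is numeric, with failure to converge reported rather than
  silently accepted.
* Sensitivity analysis (`lambda_sensitivity`): changing a multiplies λ by
  a′/a; changing φ₀ or φ_max multiplies λ by the ratio of the bracketed
  log terms; the implied c multiplier (areas held fixed) is the inverse
  square root of the λ multiplier.
* File formats are plain CSV (UTF-8, comma, header mandatory) with units
  embedded in column names; meridian vocabulary is fixed to
  {upper, lower, left, right}; areas are summed L+R on read, with single-
  hemisphere and missing-map records flagged. Reports are JSON with the
  effective configuration echoed, and identical config + inputs produce
  byte-identical reports.
* Reported precisions follow field convention: k and c to 2 decimals, R²
  to 2 decimals, λ to whole letters.

## Known limitations

* The conservation fit treats A as error-free regressor; if real area
  measurements carry substantial independent noise, k is attenuated and c
  correspondingly inflated — the package estimates the regression slope,
  not a latent structural slope.
* Through-origin R² is sensitive to heteroscedastic multiplicative scatter
  and is not comparable across cohorts with different λ ranges.
* The QUEST simulator assumes the observer's psychometric slope matches
  the staircase's model slope; slope mismatch biases threshold estimates,
  which can be explored via the config but is not calibrated here.
* Percentile bootstrap intervals slightly undercover at n ≈ 50 for ratio
  statistics (see above); BCa or studentized intervals are not provided.
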