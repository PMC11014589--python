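# corticalcrowding

Visual **crowding** — the failure to recognize a peripheral object when its
neighbors are too close — is the main spacing limit on reading and visual
search. The minimum center-to-center spacing for recognition, the *crowding
distance*, grows linearly with eccentricity φ (the Bouma law):

    s_r(φ) = b · (φ + φ₀),      s_t(φ) = s_r(φ) / a,

where `b` is the observer's unitless **Bouma factor**, `φ₀ ≈ 0.24°` a small
foveal offset, and `a ≈ 2` the radial-to-tangential elongation of crowding
zones. Packing letters at exactly threshold spacing everywhere, the number of
letters that fit into a visual field of radius φ_max is

    λ = (2πa / b²) · [ ln(1 + φ_max/φ₀) − 1/(1 + φ₀/φ_max) ],

which at the default constants reduces to λ = 34.9·b⁻². λ is an intuitive
per-observer summary of crowding: more tolerant observers fit more letters.

This package tests whether λ is explained by the surface area `A` (mm²) of a
retinotopic cortical map (V1–V4), i.e. whether the **cortical crowding
distance is conserved** across observers:

    λ = k · A        ⇔        A = λ · c²,   with   c = k^(−1/2)  (mm).

`c` is the threshold letter spacing on the cortical surface. The fit is least
squares through the origin of λ on A; association is summarized by Pearson's
r and standardized covariance ellipses; all uncertainty is percentile
bootstrap over observers (n = 10 000 resamples, 68% and 95% intervals). A
synthetic-cohort generator — including a trial-level QUEST staircase
simulator of the threshold measurements — makes the whole pipeline testable
end to end and supports parameter-recovery experiments.

It is intended for psychophysicists and visual neuroscientists analyzing
paired crowding/retinotopy datasets, and for anyone who wants a tested
reference implementation of the Bouma-law letter count and the conservation
fit.

## Worked example

Simulate a 49-observer cohort (4 meridians × 2 eccentricities × 2 sessions of
spacing thresholds, plus V1–V4 bilateral map areas), push it through the
pipeline, and print the per-map conservation summary:

```bash
corticalcrowding simulate --out demo --seed 7
corticalcrowding bouma --thresholds demo/thresholds.csv --out demo/bouma.csv
corticalcrowding fit --bouma demo/bouma.csv --areas demo/areas.csv \
    --out demo/report.json --seed 7
corticalcrowding report --json demo/report.json
```

```
n = 49 observers
test-retest: r = 0.95, session ratio = 1.11
 map       k  c (mm)      r    R^2
  V1    0.17    2.44  -0.12  -0.38
  V2    0.17    2.43   0.19  -0.02
  V3    0.24    2.05   0.12  -0.15
  V4    0.55    1.35   0.64   0.41
best map by R^2: V4
```

Reading the output: λ is highly reliable between sessions (r = 0.95) with a
~11% session-2 practice improvement. Only V4 shows a strong λ–A association
(r = 0.64); its origin fit k = 0.55 letters/mm² explains 41% of the λ
variance and implies a cortical crowding distance c = 1.35 mm (68% CI
1.33–1.37 from the JSON report) — matching the generator's true value of
1.36 mm. For V1–V3, generated independent of crowding, the conservation line
explains none of the variance (R² ≤ 0; through-origin R² is negative when
the origin line predicts worse than the mean).

The same analyses are available as a library: `uncrowded_letter_count`,
`bouma_table`, `ConservationRegressor` (a scikit-learn estimator with
fitted attributes `k_`, `c_`, `r_squared_`), `bootstrap_ci`,
`map_comparison_report`, `recovery_experiment`, and more — see the module
docstrings and `docs/methods.md`.

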