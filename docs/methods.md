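# Methods

This note documents the models implemented in `mesolim`, the defaults and
their rationale, the numerical choices, and what the synthetic-data tests do
and do not demonstrate.

## Standardisation

**Units and pressure.** Mesophyll conductance is accepted in mol m⁻² s⁻¹,
mol m⁻² s⁻¹ bar⁻¹ or μmol m⁻² s⁻¹ Pa⁻¹. Liquid-phase-equivalent
(pressure-normalised) values are converted via
1 μmol m⁻² s⁻¹ Pa⁻¹ = 0.1 mol m⁻² s⁻¹ bar⁻¹ and multiplied by the ambient
pressure in bar, standardising to 100 kPa (= 1 bar). When pressure is
unreported it is derived from elevation with the international barometric
formula P = 101.325·(1 − 2.25577×10⁻⁵ z)^5.25588 kPa, and failing that
100 kPa is assumed. Stomatal conductance reported on a water-vapour basis is
divided by 1.6 (the H₂O:CO₂ diffusivity ratio in air) to obtain g_s,c.

**Temperature.** g_m,25 = g_m / f(T). Two response shapes are shipped in
`src/mesolim/data/tresponse.yaml`, transcribed from the primary measurement
literature rather than fitted here:

- `tobacco` (default): peaked Arrhenius,
  f ∝ exp(c − H_a/RT) / (1 + exp((ΔS·T − H_d)/RT)) with c = 20.01,
  H_a = 49.6 kJ mol⁻¹, H_d = 437.4 kJ mol⁻¹, ΔS = 1.4 kJ mol⁻¹ K⁻¹
  (optimum ≈ 36 °C, so f rises through 25 °C).
- `arabidopsis`: simple Arrhenius with E_a = 20.2 kJ mol⁻¹, a deliberately
  weaker response used to bracket the uncertainty in the temperature
  correction.

Both are renormalised in code so f(25) = 1 exactly; any transcription-scale
error therefore cannot move the reference point, and only the curve shape
matters. Records flagged `already_standardised` bypass scaling; the value at
the original measurement temperature is retained alongside g_m,25. Analyses
can be rerun with either response; on synthetic cohorts the g_m,25 values
change but the signs of the anatomical GLM coefficients do not (tested).

**Fick's law.** C_c = C_i − A_n/g_m and drawdown = A_n/g_m, with the
convention that A_n ≤ 0 yields C_c ≥ C_i (physically admissible under net
respiration) rather than an error; g_m = 0 is an error (undefined drawdown).

## Quality control

The five exclusion criteria (defaults in `FilterThresholds`, all
overridable): temperature outside 15–35 °C **or missing**; irradiance
< 300 μmol m⁻² s⁻¹; CO₂ outside 300–500 μmol mol⁻¹; drawdown outside
10–300 μmol mol⁻¹; and statistical outliers. Missing irradiance or CO₂ does
**not** exclude a row — only temperature carries an explicit
"or not reported" rule — but such rows are counted in the filter report so
the choice is auditable per run.

Outlier detection is strictly two-step: (1) extreme values above
2 mol m⁻² s⁻¹ (herbaceous) or 1 mol m⁻² s⁻¹ (woody); ferns are assigned the
woody threshold since their g_m range is the lowest of all groups;
(2) per PFT, the step-1 survivors are natural-log-transformed and flagged
outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR]. Quartiles use linear interpolation
(type 7, the common default; the convention is otherwise arbitrary and is
exposed in config only through the multiplier). Fences are never
back-transformed — flags are set membership on the log scale — which makes
the flags invariant under uniform positive rescaling of a group. Groups
smaller than 4 skip step 2 (quartile fences on 2–3 points are meaningless)
and the skip is logged.

Method reconciliation: curve-fitting + one other method → the other method
(curve-fitting estimates are the least independent); two non-curve-fitting
methods → arithmetic mean; combinations beyond these take the mean of
non-curve-fitting values and are labelled as beyond the rule set.

## Limitation analysis

L_m = (A_np − A_n)/A_np × 100, where A_np is photosynthesis at C_c = C_i.
The cross-species decline of L_m with g_m is summarised by
L_m = a·exp(−b·g_m), fitted by **plain** (not robust) nonlinear least
squares — the limitation curve is a summary of a derived quantity, and
point exclusions are deliberately manual (an explicit id list), never
automatic. Start values come from a log-linear fit over L_m > 0 pairs, with
a perturbed-restart grid as a fallback; b is stored positive. The 95%
confidence band is a seeded nonparametric percentile bootstrap (default
1000 resamples); a closed-form band was not used because the intended CI
construction for this curve is not uniquely determined, and the bootstrap
makes the choice explicit and reproducible.

Per-PFT "typical limitation" ranges combine the band with the PFT's
interquartile g_m,25 range in the widest defensible way: lower bound of the
band at Q3 (high-g_m, least-limited edge) to upper bound at Q1, rounded to
integer percent. The combination rule (band-at-quantile) is a design choice
and is localised in `pft_limitation_ranges`.

## Trait statistics

**Gamma GLM.** log E[g_m,25] = β₀ + β₁·S_c + β₂·T_cw with gamma errors,
dispersion by the Pearson-χ² estimate, Wald 95% intervals exponentiated to
the reporting scale (one unit of S_c multiplies expected g_m,25 by exp β₁).
Profile-likelihood intervals were not used; Wald is the convention the
exp-scale reporting implies. McFadden's pseudo-R² = 1 − lnL(full)/lnL(null)
is computed against an intercept-only gamma GLM refitted on the same rows.
*Caveat:* for continuous responses the log-likelihood is scale-dependent and
can be positive (densities above one), in which case the ratio can leave
[0, 1) — on narrow synthetic g_m scales it is routinely negative. The
statistic is therefore meaningful for comparing fits on a given response
scale, and near-zero-dispersion data drive it to 1 (statsmodels' likelihood
degenerates to 0 from above); tests assert coefficient recovery, not
pseudo-R² magnitudes, on synthetic cohorts.

**Robust regressions.** Tukey-bisquare M-estimation, tuning constant 4.685
(95% Gaussian efficiency), IRLS to 1e-8 relative tolerance or 50
iterations. The linear case uses statsmodels RLM. The power law y = a·x^b
is fitted by iteratively reweighted *nonlinear* least squares on the
original scale (weights from bisquare ψ with MAD scale; inner step by
Levenberg–Marquardt), started from a robust linear fit on logs — fitting on
the original scale keeps the downweighting meaningful in the units of y.
The reported R² is the robust weighted variant
1 − Σw·r² / Σw·(y − ȳ_w)², stated here because there is no unique "robust
R²"; p-values come from the robust standard error of the slope (linear) or
the weighted Gauss–Newton covariance of the exponent (power). Exact numeric
agreement with other robust-regression implementations is not a goal; the
estimator, tuning constant and convergence rule are specified instead, and
tests check recovery, contamination resistance and agreement with OLS on
clean data. Regression significance is reported only when n ≥ 12
(configurable); smaller samples carry `reported=False` rather than being
hidden.

**Dunn's test** is implemented directly (pooled ranks, tie-corrected
pairwise z, two-sided normal p, Holm adjustment by default) and is verified
against a brute-force rank oracle and the two-group Mann–Whitney normal
approximation.

## Leaf simulator

The generator's leaf model couples the Rubisco-limited demand curve
A = V_cmax(C_c − Γ*)/(C_c + K_m) − R_d with the linear supply chain
C_c = C_a − A·(1/g_s + 1/g_m). Substitution gives a quadratic in A whose
smaller root (the one with C_c ∈ (0, C_a]) is taken; A_np repeats the solve
with 1/g_m = 0. Defaults Γ* = 42.75 and K_m = 717 μmol mol⁻¹ are standard
25 °C constants; no identity or recovery test depends on them. Only the
Rubisco-limited demand is modelled — adequate for the light-saturated
measurements a g_m compilation represents, and a documented limitation
(no electron-transport or TPU limitation, no energy balance, no boundary
layer).

## Cohort generator

Six PFT strata with uniform trait ranges chosen so that expected g_m,25
(from the log-linear anatomical model with exp β = (0.128, 1.050, 0.096)
and gamma multiplicative noise, shape 5) reproduces the observed ordering
of PFT medians — annual herbs highest, ferns lowest — and a right-skewed
marginal. Measurement temperatures are drawn in 20–30 °C and g_m is
back-transformed through the inverse temperature response, so the
standardisation stage can be tested closed-loop (recovering the generated
g_m,25 to 1e-9). Stomatal conductance is drawn proportional to g_m
(ratio 1.2–2.5, clipped to 0.05–1.5 mol m⁻² s⁻¹), V_cmax per stratum, and
leaf N and K are generated with a positive linear link to g_m,25 so the
pairwise-regression machinery has realistic targets. Violations are planted
by modifying selected rows to break exactly one criterion each, with ground
truth labels retained.

What the synthetic data do **not** emulate: method-specific biases between
isotope/fluorescence/curve-fitting estimates, study-level random effects,
correlated trait measurement error, missingness patterns of real
compilations, and any electron-transport-limited records. Passing recovery
tests therefore demonstrates correctness of the estimators under the
model's own assumptions, not robustness to every failure mode of literature
data.

## Problem sizes and determinism

Default test and acceptance runs use desk-scale sizes chosen to exercise
the statistics meaningfully: cohorts of 40–80 leaves per PFT, 100 replicate
GLM recoveries at n = 295, 20 bootstrap-coverage replicates at 200
resamples, and 1000 random groups for the outlier-fence cross-check. All
randomness flows through `numpy.random.default_rng` seeds carried in
configs; pipeline bundles embed the seed and a config hash so identical
configurations produce byte-identical outputs.

## Known limitations

- The temperature-response parameter values are transcriptions; alternative
  parameterisations can be supplied via YAML without code changes.
- Bootstrap confidence bands are percentile-based and do not correct for
  fit bias at small n.
- The per-PFT limitation ranges depend on the band/IQR combination rule
  (documented above); other defensible readings give slightly narrower
  ranges.
- No mixed-effects structure: studies contribute rows, not random effects.
- The deterministic PFT mapping requires lineage/habit/longevity metadata;
  records lacking it must be classified upstream (the mapping table is
  config-exposed).
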