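# Methods

## Problem and models

`zebratk` analyses the toxicokinetics of waterborne drug exposure in
zebrafish (*Danio rerio*) larvae: how fast a dissolved compound is taken
up, where it distributes, and how fast it is eliminated once the animals
are transferred to clean water. The worked example throughout is mCPP
(meta-chlorophenylpiperazine), a basic piperazine psychoactive drug
(MW 196.68 g/mol, logP 2.06, pKa 8.87) whose dominant storage site in the
larva is the melanin-rich eye.

### One-compartment model

The whole larva is a single well-mixed compartment exchanging with the
water:

    dC_int/dt = k_in · C_w(t) − k_out · C_int(t)

with `C_int` in mg/kg wet weight, `C_w` in mg/L, `k_in` in L kg⁻¹ h⁻¹ and
`k_out` in h⁻¹. The forcing is constant-then-zero: `C_w(t) = c_w` for
`t ≤ t_uptake` (daily-renewal exposure approximated as constant; the bath
volume is assumed large enough that larval uptake does not deplete it) and
0 afterwards. Under this forcing the model has the closed form

    C(t) = (k_in/k_out)·c_w·(1 − e^(−k_out·t))              t ≤ t_uptake
    C(t) = C(t_uptake)·e^(−k_out·(t − t_uptake))            t > t_uptake

used both for simulation and inside the fitter. An independent numerical
path (piecewise `solve_ivp`, LSODA, rtol 1e-10) exists purely as a
cross-check; tests require agreement within 1e-6 relative error, with an
absolute floor of 1e-12 of the curve maximum for terminal values that
decay below machine resolution.

The kinetic bioconcentration factor is `BCF = k_in/k_out` (L/kg), the
steady-state ratio of internal to water concentration.

### Eye / rest-of-body model

Because basic drugs bind melanin, the eye behaves as a high-affinity,
slowly releasing reservoir. It is modelled as a second compartment in
parallel with the rest of the body, each with its own `k_in`/`k_out` and
each exchanging only with the water — there is no eye↔body flux term.
The whole-larva concentration is the wet-weight-weighted mean

    C_whole = (C_eyes·W_eyes + C_rest·W_rest) / (W_eyes + W_rest)

which conserves total chemical mass exactly. With a slow eye compartment
(`k_out_eyes ≪ k_out_rest`) the combined curve is biphasic in
depuration: the fast rest-of-body phase dominates early, the slowly
emptying eye dominates late.

### Passive-partitioning baseline

To ask whether the measured uptake can be explained by passive diffusion
alone, predicted rates are computed from physico-chemical properties via
the Arnot–Gobas gill-uptake kinetic framework:

    E_W  = 1 / (1.85 + 155/Kow)              gill uptake efficiency
    G_V  = 1400 · W^0.65 / C_OX              ventilation rate, L/day
    k_in = E_W · G_V / W                     L kg⁻¹ day⁻¹ (→ per hour)
    k_out = k_in / (L_B · Kow)

so the implied steady-state BCF is exactly `L_B · Kow` (lipid fraction
times partition coefficient). Dissolved oxygen defaults to
`(−0.24·T + 14.04) × 0.9` mg/L at the water temperature `T`. All
coefficients live in a versioned JSON file
(`src/zebratk/data/passive_coefficients.json`) and can be replaced. The
allometric ventilation term is calibrated on much larger fish; at larval
weights the predicted `k_in` is only an order-of-magnitude statement, but
the predicted *steady state* — which is what an 8-h exposure reaches under
the very fast predicted `k_out` — depends only on `L_B · Kow` and is
robust. The quantitative claim carried by this module is therefore the
gap: measured whole-body levels exceed the passive prediction >20-fold
(eyes >250-fold), the argument for active transport; no attempt is made to
reproduce any particular published predicted curve bit-exactly.

For an ionizable base the partition input can be switched from logP to
logD(pH) via the monoprotic Henderson–Hasselbalch correction
`logD = logP − log10(1 + 10^(pKa−pH))`. The medium pH is always an
explicit argument: the quoted logD of 0.91 for mCPP back-solves to a
medium pH of about 7.75, which is plausible for reconstituted embryo
medium but not stated anywhere, so the package never assumes it silently.

## Fitting

Rate constants are estimated by unweighted least squares on the
concentration scale (lmfit/MINPACK; standard errors from the Jacobian at
the optimum). A log-scale residual option exists for data spanning
several decades. Uptake and depuration observations are fitted jointly.
Starting values are data-driven: `k_out` from the terminal log-linear
depuration slope, `k_in` from the earliest uptake point divided by
`c_w·t`; the multi-compartment fit seeds the eye compartment from a
one-compartment fit of the eye series and the rest compartment from the
whole-body fit corrected for the eye contribution. The joint
multi-compartment objective stacks eye and combined-whole-body residuals
with equal weight. Underdetermined data (<3 distinct non-zero time
points, or no eye data for the multi-compartment model) raise `FitError`
rather than returning garbage; the one- and multi-compartment fits are
deliberately independent (no parameter sharing), since a whole-body
one-compartment fit to biphasic data is a deliberate simplification whose
rates need not equal any weighted mean of the compartment rates.

The 4PL dose–response fit uses the variable-slope logistic
`f(c) = bottom + (top − bottom)/(1 + 10^((logEC50 − log c)·hill))` on
response proportions, unweighted (the common practice of standard 4PL
software), with a binomial-likelihood option. Constant responses (all 0%
or all 100%) are flagged non-estimable; an EC50 standard error above 0.5
log units triggers a warning instead of a hard failure, because
monotone-violating toy data should still converge somewhere inspectable.

## Model-free depuration analysis

`biphasic_half_lives` performs a two-segment log-linear regression on
pooled per-time means of the depuration series (a per-replicate option
exists). Every interior observed time point with ≥2 points on each side
is tried as a breakpoint (the breakpoint sample belongs to both
segments); the split minimizing total SSE on ln(C) wins, ties going to
the earlier breakpoint (conservative initial phase). Per-segment
half-lives are `ln 2/|slope|`. Segment slopes within 5% of each other
set a `degenerate` flag — the data are effectively single-exponential and
the two reported half-lives coincide. Zero/negative concentrations are
dropped from the log regression with a warning rather than imputed.

Published compartment half-lives of 13 h (eyes) and 48 min (rest) differ
slightly from `ln 2/k_out` at the printed rates (13.9 h, 52 min); the
package reports the `ln 2/k` values and makes no attempt to force
agreement, since the provenance of the printed figures is unknown.

## Tissue statistics

Panels of pooled-tissue measurements (one value per pool of larvae; pools
are the statistical unit) are compared by one-way ANOVA with all-pairs
Tukey HSD (scipy), on the raw concentration scale by default with a
log-scale option. Unadjusted pairwise p-values use the pooled
within-group mean square (Fisher LSD), so the Tukey-adjusted p-value is
never smaller by construction. The pigmentation report gives, per
tissue, each line's mean, SD, n, fold reduction versus the reference line
(wild type by default) and the Tukey-adjusted p of that contrast;
significance thresholds are reported, never baked into logic.

## Synthetic data

Generators are pure functions of (parameters, seed) and define the
package's study conditions:

* **Time courses** — the compartment models evaluated on the default
  grid (uptake samples at 0.25, 1, 3, 6 and 8 h; depuration samples 1, 3,
  6, 18, 24, 27 and 48 h after transfer, on one absolute axis), 16
  replicates, multiplicative lognormal noise with unit mean and CV 0.06.
  The CV matches the ~5–6% relative SDs of pooled-larvae LC-MS/MS
  measurements; an additive-normal option (sd = cv·value, truncated at 0)
  exists for robustness testing. The experimental design also sampled a
  10-h uptake point in a separate uptake-only experiment; the default
  grid stops at 8 h because the modelled scenario switches to clean water
  there.
* **Tissue panels** — group mean = tissue mean ÷ line fold-factor, same
  noise model, default 3 pools/group.
* **Embryo outcomes** — binomial draws at 4PL-evaluated response
  probabilities, default 10 embryos per concentration on the standard
  0.01–100 µM series.
* **Piecewise-exponential depuration** — a model-free biexponential-phase
  series (half-life h₁ to a breakpoint, h₂ after) used to validate the
  biphasic estimator against known phase half-lives. This generator is
  the natural oracle for the estimator: with the published rates and a
  10% eye mass fraction the mechanistic two-compartment whole-body curve
  has an initial phase near 1.9 h, so the printed 4.5 h/28.5 h phase pair
  is reproduced from its own phase definition, not from that parameter
  set.

What the synthetic data do *not* emulate: inter-larva weight variation
(one fixed 360 µg weight), biotransformation losses (~1–2% oxidation and
glucuronidation are ignored), bath depletion, time-varying exposure
beyond constant-then-zero, and any correlation between tissues within a
larva. Passing round-trip tests therefore demonstrates estimator
correctness under the stated noise model, not robustness to every feature
of real measurements.

## Internal-dose conversion

External effect concentrations are converted to internal body burdens as
`mmol/kg = (µM/1000) × BCF(L/kg)`. This is a documented approximation for
internal lethal/effect/no-effect metrics (ILC50/IEC50/INTC analogues)
whose published computational conventions vary; outputs based on it should
be labelled approximate. Only *ratios* between compounds computed from
published values are used in validation, which are insensitive to the
convention's common factors.

## Defaults and parameters

| Parameter | Default | Unit | Why |
|---|---|---|---|
| exposure concentration | 5 | µM | highest phenotype-neutral screen concentration |
| uptake / depuration duration | 8 / 48 | h | standard design emulated throughout |
| larva wet weight | 360 | µg | 5–7 dpf average |
| eye mass fraction | 0.10 | – | dissected-weight tables are not republished; 10% of a 360 µg larva places the weighted whole-body level (≈368 mg/kg at the published rates) consistently between eye (≈2100) and rest (≈175) levels, matching the measured ~308 mg/kg ordering; overridable in config |
| lipid fraction | 0.05 | kg/kg | typical larval lipid content |
| water temperature | 28 | °C | standard rearing temperature |
| noise CV | 0.06 | – | matches reported measurement SDs |
| replicates per time point | 16 | larvae | matches the uptake design |

## Numerical choices and limitations

* All internal arithmetic at full precision; rounding to printed
  precision happens only at the reporting/CLI layer.
* Optimizer: MINPACK `leastsq` with default tolerances (~1.5e-8), which
  recovers noise-free generating parameters to ≤1e-6 relative error.
* Random seeds are explicit everywhere; no global RNG state.
* Problem sizes in the validation scripts (16 replicates × 12-13 time
  points per dataset, 100 stochastic fit replicates, 50 embryos per
  concentration in the dose–response round trip) were chosen as the
  smallest designs at which the recovery criteria are comfortably
  identifiable.
* Out of scope by design: biotransformation kinetics, saturable
  melanin-binding terms, a third (brain) compartment, dietary uptake and
  growth dilution in the passive baseline, regression-based BCF
  estimates from external programs, and behavioural endpoint statistics.
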