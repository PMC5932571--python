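# zebratk

Toxicokinetic modelling of waterborne drug exposure in zebrafish
(*Danio rerio*) larvae.

Zebrafish larvae are screened for drug toxicity and behavioural effects by
dissolving the compound in the water — so interpreting any effect requires
knowing how much drug actually gets inside the animal, where it goes, and
how fast it leaves. `zebratk` provides the modelling toolkit for that
question, built around mCPP (meta-chlorophenylpiperazine, MW 196.68 g/mol,
logP 2.06, pKa 8.87), a basic piperazine drug that accumulates strongly in
the melanin-rich larval eye:

* **One-compartment model** — `dC_int/dt = k_in·C_w(t) − k_out·C_int(t)`:
  closed-form simulation and least-squares estimation of the uptake rate
  constant `k_in` (L kg⁻¹ h⁻¹) and elimination rate constant `k_out`
  (h⁻¹) from whole-body time courses, with the kinetic bioconcentration
  factor `BCF = k_in/k_out`.
* **Eye / rest-of-body model** — the eye as a separate melanin-binding
  compartment in parallel with the rest of the body, combined into the
  whole-larva concentration by wet-weight weighting
  `C_whole = (C_eyes·W_eyes + C_rest·W_rest)/(W_eyes + W_rest)`; jointly
  fitted, it reproduces the biphasic depuration a single compartment
  cannot.
* **Passive-partitioning baseline** — predicted (not fitted) rates from
  logP/logD, lipid content and body weight via the Arnot–Gobas
  gill-uptake framework; the >20-fold gap between prediction and
  measurement quantifies the case for active uptake.
* **Model-free depuration analysis** — two-segment log-linear regression
  with exhaustive breakpoint scan for biphasic half-lives, percent
  remaining, fold differences, linear dose scaling.
* **Tissue statistics** — one-way ANOVA + Tukey HSD on pooled-tissue
  panels; wild-type vs hypo-pigmented (albino, PTU-treated) fold tables.
* **Dose–response** — four-parameter logistic (variable-slope) fits of
  embryo toxicity outcomes, and conversion of external effect
  concentrations to internal body burdens (mmol/kg) via the BCF.
* **Synthetic data** — seeded generators for all of the above, so every
  estimator is validated by parameter-recovery round trips.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Generate a synthetic eye + whole-body time course at the study conditions
(5 µM exposure for 8 h, 48 h depuration, 16 replicate larvae, 6%
measurement CV), then fit both models and compare with the passive
baseline:

```python
import numpy as np
from zebratk import *

sc = ExposureScenario(c_w=micromolar_to_mg_per_l(5.0, MCPP),
                      t_uptake=8.0, t_depuration=48.0)
true = MultiCompartmentParams(k_in_eyes=325.0, k_out_eyes=0.05,
                              k_in_rest=143.2, k_out_rest=0.8)
body = BodyComposition.from_fraction(3.6e-7, 0.10)  # 360 ug larva, 10% eyes

data = gen_timecourse(true, sc, n_replicates=16,
                      noise=NoiseModel(cv=0.06, seed=1), body=body)

fit = fit_multi_compartment(data, data, body, sc)
print(f"k_in_eyes = {fit.k_in_eyes:.1f} +/- {fit.k_in_eyes_se:.1f} L/kg/h")
print(f"k_in_rest = {fit.k_in_rest:.1f} +/- {fit.k_in_rest_se:.1f} L/kg/h")
hl = compartment_half_lives(fit)
print(f"eye half-life  = {hl['eyes']:.1f} h, rest = {hl['rest']*60:.0f} min")

one = fit_one_compartment(data, sc)
bcf = compute_bcf(one.k_in, one.k_out)
print(f"whole-body logBCF = {bcf.log_bcf:.2f}")

pred = predict_passive_timecourse(MCPP, PassiveModelParams(), sc, [8.0])[0]
t, mean = data.pooled_means()
meas = mean[t == 8.0][0]
print(f"passive prediction at 8 h = {pred:.1f} mg/kg vs measured "
      f"{meas:.0f} mg/kg ({meas/pred:.0f}-fold gap)")
```

Output:

```
k_in_eyes = 324.3 +/- 1.3 L/kg/h
k_in_rest = 135.4 +/- 16.7 L/kg/h
eye half-life  = 13.8 h, rest = 54 min
whole-body logBCF = 2.71
passive prediction at 8 h = 5.6 mg/kg vs measured 370 mg/kg (66-fold gap)
```

The fit recovers the generating rates within their standard errors. The
eye empties with a ~14 h half-life while the rest of the body clears in
under an hour — the slow melanin reservoir that makes whole-body
depuration biphasic. The whole-body one-compartment fit of the same data
gives a kinetic logBCF near 2.7, roughly 80-fold above the passive
steady-state prediction of `lipid_fraction × Kow ≈ 5.7 L/kg`: passive
partitioning cannot explain the measured accumulation.

A command-line interface mirrors the library
(`zebratk simulate|fit|predict-passive|halflife|tissue-report|zfet|synth|run`);
`zebratk run --outdir out/` executes the whole pipeline on synthetic data
and writes all fit JSONs and report CSVs.

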