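# cmlkinetics

Quantitative modelling of long-term molecular response in chronic myeloid
leukemia (CML) under tyrosine-kinase-inhibitor (TKI) therapy.

Peripheral-blood BCR-ABL transcript levels under first-line TKI therapy
typically decline in two phases: a steep initial drop as cycling leukemic
cells are cleared, then a slow decline attributed to the gradual depletion
of quiescent leukemic stem cells (LSC) in the bone marrow.  This package
is for modellers and biostatisticians who want to (i) describe individual
time courses statistically, (ii) map them onto a mechanistic stem-cell
model, and (iii) quantify what reduced follow-up and the hidden stem-cell
compartment do to long-term predictions — all of it exercisable on
synthetic cohorts that emulate a five-year two-arm trial monitoring design.

The pieces, in the field's notation (`LRATIO = log10(BCR-ABL/ABL in %)`):

* **Bi-exponential response model** — `LRATIO(t) = log10(A e^(-αt) +
  B e^(-βt))` with `A > B ≥ 0`, `α > 0`, `β` free; per-patient fits
  maximise a censored-Gaussian likelihood (values below the quantification
  limit are left-censored), and point-wise 95 % confidence bands come from
  a parametric bootstrap.  Tumor-load halving time is `ln 2 / α`.
* **Mechanistic model** — a single-cell clonal-competition model of normal
  vs leukemic stem cells switching between quiescence and cycle, with TKI
  effects: cytotoxic kill of cycling leukemic cells (`r_deg`), gradual
  onset (`r_trans`), and altered activation/deactivation
  (`f_ω^CML`, `f_α^CML`); the blood readout is `n1/(n1+2n2)·100 %`.
* **Look-up-table calibration** — a five-parameter screen (the full grid
  has 10·16·13·10·13 = 270,400 configurations) summarised by bi-exponential
  fits; every configuration whose curve lies inside a patient's confidence
  band is a *suitable* explanation (Θ̂ᵢᵗ), ranked by curve distance.
* **Prediction framework** — envelopes over suitable configurations give
  five-year intervals for blood levels and for residual LSC counts
  (`Δlsc = log10(lsc_max) − log10(lsc_min)`); cross-validation against
  truncated follow-up classifies configuration-level predictions as
  TP/TN/FP/FN.
* **Cohort statistics** — two-stage Wald comparison of arm-level slopes,
  α-β correlation, binned mean response curves.

See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

```python
from cmlkinetics import (GridSpec, MechConfig, fit_individual,
                         bootstrap_band, halving_time, run_screen)
from cmlkinetics.matching import (find_suitable, lsc_prediction_interval,
                                  pb_prediction_interval)
from cmlkinetics.synthetic import generate_from_mechanistic

# one virtual patient whose (hidden) truth is a stem-cell scenario:
# moderate kill rate, strongly TKI-deepened quiescence
true_config = MechConfig(f_omega_cml=0.1, f_alpha_cml=2.0, r_deg=0.05,
                         lratio_init=1.8, r_trans=0.005)
patient = generate_from_mechanistic(true_config, seed=7)

fit = fit_individual(patient)
print(f"alpha={fit.params.alpha:.3f}/mo  beta={fit.params.beta:.4f}/mo  "
      f"halving time={halving_time(fit):.1f} d  sigma2={fit.sigma2:.3f}")

band = bootstrap_band(fit, patient, n_boot=300, seed=1)

# coarse mechanistic screen (3^5 configurations), then match the patient
table = run_screen(GridSpec.from_defaults("coarse_grid"), seed=1)
suitable = find_suitable(table, band, tau=60.0, fit=fit)
pb = pb_prediction_interval(suitable, table, 60.0)
lsc = lsc_prediction_interval(suitable, table, 60.0)
print(f"suitable configurations: {len(suitable)}")
print(f"5y blood-level interval (LRATIO): [{pb.pb_lower:.2f}, {pb.pb_upper:.2f}]")
print(f"residual LSC at 5y: [{lsc.lsc_min:.0f}, {lsc.lsc_max:.0f}]  "
      f"delta_lsc={lsc.delta_lsc:.2f}")
```

Output (the screen takes about a minute):

```
alpha=0.953/mo  beta=0.0330/mo  halving time=22.1 d  sigma2=0.595
suitable configurations: 11
5y blood-level interval (LRATIO): [-2.40, -0.85]
residual LSC at 5y: [23, 400]  delta_lsc=1.24
```

Read: this virtual patient halves its tumor load every ~22 days and then
declines at 0.033 log10/month.  Eleven screened stem-cell scenarios
reproduce the observed kinetic within its confidence band; they agree the
five-year blood level lies between MR2 and MR3-and-a-half but disagree by
more than a decade (`delta_lsc = 1.24`) about the residual stem-cell
burden — the uncertainty that peripheral-blood monitoring alone cannot
resolve.  Patients whose band contains no screened configuration are
reported as unmatched rather than forced onto the nearest entry.

The same pipeline runs from the shell:

```bash
cmlkinetics run-all --seed 1 --out results/
cmlkinetics report results/
```

producing stage CSVs (cohort, fits, bands, predictions, accuracy), a
manifest, and a five-panel summary report.

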