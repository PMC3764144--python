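# neuralinertia

Tools for quantifying **neural inertia** — the hysteresis barrier that
separates wakefulness from anesthetic-induced unresponsiveness — from
*Drosophila* activity-monitor data.

Flies exposed to a stepwise ascending-then-descending anesthetic titration
stop moving (induction) at a higher drug concentration than the one at which
they start moving again (emergence). This hysteresis is not a
pharmacokinetic artifact: it reflects a bistable arousal switch whose
stability can be widened or collapsed genetically and by sleep pressure.
This package implements the full analysis chain for that phenomenon, for
researchers working with locomotor (beam-break) data from stepwise
anesthetic titrations:

- **`io_monitor`** — read/write a documented tab-separated activity-monitor
  dialect, describe titration protocols (YAML-configurable), and align
  binned counts to protocol steps.
- **`endpoints`** — binarize activity, call per-fly induction and emergence
  concentrations, apply the standard exclusion filters, and score sleep
  (inactivity bouts of at least 5 minutes).
- **`dose_response`** — aggregate calls into population concentration-response
  tables and fit constrained Hill curves; EC_p arithmetic; a single-compartment
  chamber washin calculator.
- **`inertia`** — the neural-inertia area statistic with fly-level bootstrap
  standard errors and standard group comparisons (one-way ANOVA with
  Bonferroni correction, t, Mann-Whitney).
- **`synthetic`** — a generative model of fly cohorts (latent log-normal
  induction/emergence thresholds, sleep/wake Markov activity, never-emerging
  subpopulation) with genotype scenario presets.
- **`circuit`** — a 3-cell firing-rate flip-flop model of the arousal switch
  whose concentration sweeps produce hysteretic induction/emergence
  transitions and genotype-like perturbations.

## The statistic

Per-fly endpoints: induction is the lowest ascending-limb concentration at
which movement ceased for ≥ 5 min (persisting, by default, for the remainder
of the ascending limb); emergence is the highest descending-limb
concentration at which movement resumed. Population fractions are fit to the
Hill equation with the bottom constrained to zero and top, EC₅₀ and Hill
coefficient *n* free:

    F(c) = top · cⁿ / (cⁿ + EC₅₀ⁿ)

The descending limb is fit in the fraction-*emerged* parameterization, so
flies that never resume movement surface as a top constant below one.

Neural inertia is the area between the curves on the fraction-anesthetized
scale,

    NI = ∫ [F_emergence(c) − F_induction(c)] dc,

integrated from the induction curve's EC₁ to the emergence curve's EC₉₉
(EC_p is taken relative to each curve's top plateau). When the bounds invert
— as in collapse mutants whose emergence occurs at or above induction doses —
the value is reported as 0 with the raw signed area kept as a diagnostic.
The standard error comes from a fly-level nonparametric bootstrap.

## Worked example

```python
from neuralinertia import NeuralInertiaModel, default_protocol
from neuralinertia.synthetic import generate_traces, sample_population, scenario

protocol = default_protocol()          # 0.25..2.00 vol% up, 1.75..0.00 down
params = scenario("control", n_flies=150, seed=42)
traces = generate_traces(sample_population(params), protocol, params)

model = NeuralInertiaModel.from_traces(traces, protocol, group="iso31 control")
results = model.fit(n_boot=200, seed=7)
print(results.summary())
```

prints

```
Neural inertia analysis: iso31 control
======================================================
flies                150 (33 excluded: {'inactive_first_dose': 22, 'no_24h_recovery': 11})
induction EC50         0.9168 vol%  (Hill n 4.67, top 1.000)
emergence EC50         0.5806 vol%  (Hill n 4.85, top 0.920)
integration bounds   [0.3425, 1.4962] vol%
neural inertia         0.3496 vol% x prob  (se 0.0253, signed 0.3496)
```

Reading the output: this simulated control cohort needs ~0.92 vol% to
anesthetize half the population on the way up but only ~0.58 vol% to keep
half of it anesthetized on the way down; the 0.35 vol%·probability area
between the two curves is the inertial barrier. The emergence top of 0.92
means 8% of the usable cohort never resumed movement during the descending
titration; 22 flies were excluded for inactivity at the first dose and 11
for failing to move during the 24-h recovery window (the latter still count
as never-emergers for the emergence top). `results.plot()` draws both
curves with the integrated area shaded, and `results.to_row()` yields a
results-table row (log EC₅₀s, tops, inertia ± SE, n).

Scenario presets (`scenario("sss_like")`, `"na_like"`, `"Sh_like"`,
`"sleep_deprived"`) reproduce the qualitative genetics of the barrier:
Sh/sss-like loss of function resists induction yet collapses inertia,
na/unc79-like sensitizes induction and also collapses inertia, and sleep
deprivation widens inertia without moving induction. The circuit model
(`CircuitParams`, `sweep`, `apply_mutation`, `population_curves`) produces
the same phenomenology from two wake-promoting cells and one
wake-suppressing cell coupled by mutual inhibition.

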