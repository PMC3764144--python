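# Methods

This note documents the models, conventions and numerical choices behind the
package. Everything quantitative stated here is computed by the test suite or
by `scripts/acceptance.py`; nothing is asserted from memory.

## Data model and endpoint definitions

Locomotor data are beam-break counts per fly per 5-minute bin. Bins are
half-open intervals labeled by their start time; zeitgeber time 0 is
lights-on. A bin is *active* iff its count is positive. Dropped monitor
readings are tracked as an explicit missing mask and are scored as "no
movement" only behind an opt-in flag (`missing_as_inactive`), because a
dropped reading is not evidence of immobility.

The titration protocol is a pre-window (≥ 15 min, drug-free), an ascending
limb of non-decreasing concentration steps, a descending limb of
non-increasing steps, and a 24-h drug-free post-window. Every dwell must be a
whole number of bins. The shipped default — ascending 0.25–2.00 vol% in
0.25 vol% increments, descending 1.75–0.00, 10-min dwells — is a package
default chosen to bracket the cohort threshold distributions the generator
produces; real protocols are supplied as YAML.

**Induction** is the concentration of the earliest ascending step containing
a ≥ 5-min run of inactivity. Binned data cannot distinguish a fly that went
under from one that fell asleep, so by default the run must *persist* for the
remainder of the ascending limb (`persistence=True`); a transient 5-min rest
at a low dose followed by renewed activity is not induction. The literal
first-run reading is available with `persistence=False`. All timing is
bin-quantized; sub-bin latencies are not resolvable.

**Emergence** is the concentration of the earliest descending step (the
highest descending concentration) containing an active bin. A fly with no
descending-limb activity is a never-emerger.

**Exclusions**, in precedence order: inactive throughout the final 15 min of
the pre-window; inactive during the first 5-min bin of the lowest dose; and,
for never-emergers only, no activity anywhere in the 24-h post-window.
Excluded flies carry no endpoint concentrations. A fly excluded for 24-h
non-recovery is nonetheless a genuine never-emerger, so the descending-limb
aggregation retains it in its denominator; this is how the never-emerging
subpopulation reaches the emergence curve's top constant without
contaminating the ascending curve.

**Sleep** is any maximal run of inactive bins (hence ≥ 5 min); wake bouts are
maximal runs of active bins. Scoring can be restricted to a zeitgeber window,
and totals are invariant to activity outside that window.

## Dose-response aggregation and Hill fits

Aggregation is cumulative: on the ascending limb the fraction anesthetized at
step *c* is the fraction of usable flies with induction ≤ *c*; on the
descending limb it is the fraction with emergence strictly below *c* plus all
never-emergers. Both limbs are monotone in *c* by construction.

Curves are fit to the three-parameter Hill equation with the bottom fixed at
zero (top, EC₅₀, Hill coefficient free). The ascending limb is fit directly
as fraction anesthetized. The descending limb is fit as fraction *emerged*
(a decreasing Hill curve): its bottom is genuinely zero at high
concentration, and its top estimates the fraction of the cohort that ever
emerges. `anesthetized_fraction()` maps either fit onto the common scale
(1 − emerged for descending fits). Fits are unweighted least squares by
default, with optional binomial weighting.

Optimization is bounded multistart `scipy.optimize.least_squares` (trust
region reflective): EC₅₀ log-spaced over the observed concentration range
(20 starts), Hill coefficient starts {1, 2, 4, 8}, top starting at the
maximum observed response; bounds EC₅₀ ∈ [10⁻⁹, 10⁶], n ∈ [10⁻³, 60],
top ∈ (0, 1]. Hill fits are multimodal in the slope, hence the multistart.
Convergence is declared when a start terminates cleanly at the best cost
basin, when several independent starts agree on the same minimum (steep
transitions leave the slope weakly identified, so the optimizer may hit its
iteration cap while sitting at the minimum), or when the best residual sum of
squares is below 10⁻¹⁰ (a near-interpolating fit). Degenerate tables — fewer
than four distinct concentrations, or responses flat at 0/1 — raise rather
than returning a fit. Parameter covariance is the standard Gauss-Newton
approximation s²(JᵀJ)⁻¹.

EC_p is defined *relative to the fitted top plateau*:
EC_p = EC₅₀·(p/(100−p))^(1/n) for increasing fits, reciprocal exponent for
decreasing fits. This keeps EC₉₉ finite when the top is below one, which is
essential for emergence curves with never-emergers. The absolute-response
convention is computable from the same parameters but is not the default.

## The inertia statistic

Neural inertia is ∫ (F_emergence − F_induction) dc on the
fraction-anesthetized scale, from the induction curve's EC₁ to the emergence
curve's EC₉₉ (both in the anesthetized orientation), evaluated by adaptive
quadrature (`scipy.integrate.quad`, absolute tolerance 10⁻¹⁰, verified
against a 10⁶-point trapezoid and, for unit-slope curves, against the
closed-form antiderivative c − a·ln(c + a)).

Degenerate-hysteresis conventions: the reported value is floored at zero
whenever the signed area is negative (emergence at or right of induction) or
the integration bounds invert; the raw signed area is always reported
alongside, because its sign distinguishes genuine inversion from mere
collapse. Note that the EC₁/EC₉₉ window can also invert for *steep,
well-separated* curves — the window convention presumes curves of moderate
slope that overlap, which holds for the cohorts this package generates
(fitted n ≈ 4–6).

The standard error is a fly-level nonparametric bootstrap (default 1000
replicates; cohort-scale analyses here use 100–200): flies are resampled with
replacement, both limbs re-aggregated and re-fit (with a reduced multistart
for speed), and the area recomputed. Replicates whose fits fail are dropped
and counted; more than 20% failures aborts with advice to enlarge the cohort.
Group comparisons use one-way ANOVA followed by Bonferroni-corrected pairwise
t-tests, plain t-tests, or Mann-Whitney U; Bonferroni is the only
multiplicity correction offered.

## The synthetic cohort generator

The generator is a latent-threshold forward model of the assay. Each fly
draws log T_induction ~ Normal(log m, σ²) and
log T_emergence = log m − Δ + σ(ρ z_ind + √(1−ρ²) z′), i.e. identical
marginal spread, correlation ρ with induction, and median log-ratio equal to
the hysteresis gap Δ. Thresholds are log-normal because concentrations are
positive and the population curves are sigmoidal on a log axis. A Bernoulli
fraction never emerges.

Awake flies alternate wake/sleep through a two-state Markov chain and emit
counts in wake bins with probability `p_active_bin`; anesthetized flies emit
exactly zero counts (optional `twitch_prob` adds artifacts). Immobility
begins at the first ascending bin whose concentration reaches T_induction;
movement resumes at the first descending bin below T_emergence. Flies start
the pre-window awake, as in an assay run at the evening activity peak.

Defaults (chosen once, as plausible for isoflurane-titration cohorts of this
kind): n = 100 flies, induction median 1.0 vol%, σ = 0.4 (giving fitted Hill
slopes ≈ 4–6; a much smaller σ produces near-step curves whose EC₁/EC₉₉
window degenerates), Δ = 0.5 (emergence median ≈ 0.61 vol%), ρ = 0.6,
5% never-emergers in collapse scenarios and 10% otherwise,
p_active_bin = 0.9, wake→sleep 0.03 and sleep→wake 0.4 per bin (≈ 7%
stationary sleep at the activity peak). `PopulationParams.noiseless()`
(p_active_bin = 1, no naps) defines the conditions under which the endpoint
caller provably recovers every threshold step exactly; with activity noise,
rests adjacent to induction merge into the immobility run and bias induction
calls slightly downward — a property of the assay itself, visible in the
worked example (fitted EC₅₀ ≈ 0.92 for a generative median of 1.0).

Scenario presets encode effect *directions*, not any measured effect sizes:
`Sh_like`/`sss_like` raise the induction median (×1.45/×1.4) and collapse the
gap (Δ = 0.05); `na_like` lowers the induction median (×0.5), inverts the gap
(Δ = −0.1) and fragments the sleep/wake chain (0.2/0.6); `sleep_deprived`
keeps induction untouched and widens the gap (Δ = 0.8). Sleep deprivation is
modeled purely as an emergence-threshold shift; the mechanical stimulus is
not simulated. Paired comparisons (sleep-deprived vs control with a shared
population seed) isolate the emergence effect exactly.

What the generator does *not* emulate: circadian modulation of thresholds,
graded (non-binary) anesthetic depth, pharmacokinetic lag between chamber and
brain concentration (beyond the washin helper), sub-bin behavior, and
between-monitor technical variation. Tests passing on synthetic cohorts
therefore validate the statistical machinery under the stated generative
assumptions, not the biology of any real genotype.

## Chamber washin

A single well-mixed compartment with volume V and flow Q follows
c(t) = c_in(1 − e^(−Qt/V)); the time to come within a tolerance fraction f of
the inflow is (V/Q)·ln(1/f). For the standard 0.75-ml tube at 15 ml/min,
99.75% equilibration takes 17.97 s — fast relative to the 10-min dwells, so
the quasi-static treatment of steps is justified.

## The 3-cell circuit model

Two wake-promoting cells (W1, W2) mutually excite each other and inhibit a
wake-suppressing cell A; A inhibits both W cells. Activities relax as
τ dxᵢ/dt = −xᵢ + σ(g(Σⱼ wⱼᵢxⱼ + bᵢ + dᵢc)) with logistic σ, inhibitory
weights entering negatively, and drug concentration c entering through signed
couplings dᵢ. The behavioral readout is mobility: mean W activity above a
threshold (0.5). Sweeps are adiabatic — the steady state at one concentration
seeds the next — matching the stepwise assay; `relax` integrates to a fixed
point (residual norm < 10⁻¹⁰) by damped Euler steps and raises on
non-convergence.

The model's published content is its topology and sign structure; all rate
constants are invented and tuned so the shipped defaults satisfy the
phenomenology the topology implies: a bistable window inside the titration
range (hysteresis: ascending flip 1.47, descending 0.94 vol% on a 0.01
grid), collapse of the window when cross-inhibition is removed (flips 1.66
vs 1.65), and the four mutation direction checks below.

Drug couplings are asymmetric by design: d = (−1.0, −0.3, 0) for (W1, W2,
A). W1 — the cell that expresses both anesthetic-sensitivity genes — is the
primary drug sensor; W2 is only weakly coupled, so during anesthesia it
retains residual, bias-sensitive activity whose inhibition of A controls how
easily the anesthetized state destabilizes; A is drug-free. This asymmetry
is load-bearing: if the drug couples equally to both W cells and not to A,
the fixed-point equations depend on the W biases and c only through their
difference, so any uniform W-bias perturbation translates both flip points
rigidly and can never change the hysteresis gap — and coupling the drug to A
instead forces the two mutation obligations into opposite saturation regimes
of A's sigmoid. With the asymmetric couplings, excitation of W1+W2 (the
*sss*/*Sh* loss-of-function operator, +0.25 bias) raises the induction flip
and shrinks the gap via the W2→A channel, while suppression of W1+A (the
*na*/*unc79* operator, −0.25 bias) lowers the induction flip and shrinks the
gap by weakening A. *Sh* and *unc79* are implemented as aliases of *sss* and
*na* respectively, as pathway partners.

`population_curves` adds a shared Normal(0, 0.15²) jitter to both W biases
per simulated fly and sweeps each fly over the protocol's concentration
steps, yielding endpoint calls consumable by the statistical pipeline; the
default-parameter pipeline gives positive inertia (≈ 0.38 with 120 flies)
and the feedback-removed circuit gives ≈ 0 (|signed| < 0.02).

## Problem sizes and reproducibility

Cohort analyses in the tests and the acceptance script use 150–500 flies
with 100–200 bootstrap replicates, sizes at which every scenario contrast is
significant at z > 1.96 while a full run stays fast on one core. All
randomness flows through explicit integer seeds (`numpy.random.default_rng`);
identical seeds and parameters reproduce traces, fits and bootstrap SEs
bit-for-bit.

## Known limitations

- The persistence rule makes induction calls robust to naps but cannot
  rescue a fly that falls asleep and crosses its threshold without waking;
  with realistic activity noise this biases induction EC₅₀ a few percent low.
- The EC₁/EC₉₉ integration window truncates area in the curve tails; with
  very steep or widely separated curves it can even invert. The raw signed
  area over the same window is reported, but no alternative window convention
  is offered.
- The bootstrap resamples flies only; it does not model uncertainty in the
  protocol itself (step placement, dwell length).
- The circuit model is a minimal rate model: no spiking, no conductances, no
  parameter fitting to data, and its numeric constants are illustrative.
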