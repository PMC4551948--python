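# Methods

## Kinetic model

The single-turnover pseudouridylation cycle is modeled as

    S + E  ⇌(k_on,S / k_off,S)  ES  →(k_cat)  EP  ⇌(k_off,P / k_on,P)  E + P

with S the unmodified substrate RNA, P the pseudouridylated product, and E
the RNP enzyme.  ES and EP are treated as the most stable complexes before
release; multi-step release pathways are deliberately collapsed to single
exponentials, which is what the control dissociation experiments support.
All rates are in s⁻¹ (bimolecular constants in M⁻¹ s⁻¹), temperatures in
kelvin internally with Celsius accepted at interfaces (K = °C + 273.15).

**Dissociation after dilution.**  After an ~4000-fold dilution the free
enzyme concentration (~1.5 nM) makes the rebinding flux k_on·[E] ≈ 10⁻⁵ s⁻¹,
two orders of magnitude below the off-rates, so the closed forms neglect
rebinding:

    [ES](t) = es₀·e^(−k₂t),  k₂ = k_cat + k_off,S
    [EP](t) = ep₀·e^(−k₁t) + es₀·k_cat/(k₁−k₂)·(e^(−k₂t) − e^(−k₁t)),  k₁ = k_off,P

The bound fraction is a double exponential with amplitudes
A₂ = es₀(1 + k_cat/(k₁−k₂)), A₁ = ep₀ − es₀·k_cat/(k₁−k₂), and
A₁ + A₂ = es₀ + ep₀.  When |k₁−k₂|/max(k₁,k₂,1) < 10⁻⁶ the singular
quotient is replaced by the degenerate limit (a + b·t)e^(−kt), flagged on
the result.  A brute-force linear-ODE integrator (`ode_oracle`,
scipy `solve_ivp`/LSODA at rtol 10⁻¹², conservation checked to 10⁻¹⁰)
retains the rebinding terms and is used to validate both the closed forms
and the dilution approximation.

**Incubation.**  During preincubation at micromolar enzyme (3-fold over
substrate) binding is much faster than catalysis (association half-time tens
of seconds versus catalytic half-times of minutes to hours), so all
substrate is treated as bound and conversion is first-order:
p(t_inc) = 1 − e^(−k_cat·t_inc).  The bound-species split at dilution is
(es₀, ep₀) = (1−p, p), which makes both decay amplitudes single-exponential
functions of incubation time with rate k_cat — the basis of the
incubation-amplitude method.  The ODE oracle with 6 μM free enzyme bounds
the error of the all-bound approximation; the product that pre-dissociates
during incubation (equilibrium bound fraction ≈ 0.86 for EP at 6 μM) is not
modeled, consistent with the amplitude method's use of relative amplitudes.

**Association.**  With enzyme in ≥10-fold excess over 10 nM labeled RNA the
binding curve is pseudo-first-order, f(t) = f_eq(1 − e^(−k_obs t)) with
k_obs = k_on[E] + k_off.

## Synthetic data generator

The generator emulates a dual-channel confocal photon-counting instrument.
Per 0.1 s acquisition bin the bound fraction sets the anisotropy
r = f_b·r_bound + (1−f_b)·r_free (equal molecular brightness of bound and
free dye — the assumption implicit in fitting r(t) directly to
exponentials); the mean total count rate splits into channels as
I_p : I_s = (1+2r) : (1−r), the s-channel divided by the sensitivity factor
G, and counts are Poisson-sampled.  Defaults, configurable throughout:

| parameter | default | rationale |
|---|---|---|
| r_free / r_bound | 0.05 / 0.25 | plausible free-dye vs ~100 kD-complex plateaus; absolute values are not reported for the instrument emulated |
| total_rate | 10⁵ counts/s | makes 1 s analysis bins shot-noise limited at roughly the scatter seen in published curves |
| g_factor | 1.0 | the anisotropy definition used carries no correction factor; ≠1 supported |
| raw_bin | 0.1 s | acquisition bin of the photon counter card |
| background | 0 | Poisson shot noise only; no afterpulsing or detector dead-time model |
| dead_time | 30 s (association), 0 (dilution) | hand-mixing dead time; flagged bins are simulated, excluded from fits |

Study conditions baked into the default protocols: association panels at
0.10–0.75 μM enzyme with 10 nM substrate; dissociation after 4000-fold
dilution to 0.5 nM; reactive dissociation after 0.5 min (fast catalysis) or
0–5 h (slow catalysis) incubation; trace durations of 1200–3000 s chosen to
reach the decay plateau (≥8 half-lives of the slowest observed rate).
What passing recovery tests on these synthetics shows is that the
*extraction machinery* is unbiased and correctly calibrated under
shot-noise-limited conditions; they do not validate instrument-specific
effects (bleaching, background drift, detector nonlinearity) that real
traces may carry and the generator does not emulate.

## Trace reduction

Counts are rebinned by summation (0.1 s → 1 s default) and *then* converted
to anisotropy: the ratio-of-sums is less biased than a mean of ratios at low
counts.  Per-point errors come from first-order (delta-method) propagation
of independent Poisson counting noise,
Var(r) = 9G²·I_p·I_s·(I_p+I_s)/(I_p+2G·I_s)⁴, with a one-photon sensitivity
floor so usable points never carry infinite weight.  Zero-count bins are
masked.  Because the rebinned ratio corresponds to the discrete mean of the
constituent-bin anisotropies, exponential *rates* are unbiased by rebinning
while amplitudes acquire a factor e^(kΔ/2−…) of order 10⁻⁴ at the default
bins; amplitude-based inference always refits amplitudes, so this is
immaterial.

## Fitting

All decay models are sums of exponentials plus a constant baseline r_∞ (the
printed two-exponential model is extended by this offset because the
free-RNA anisotropy is nonzero).  Every nonlinear fit uses variable
projection: amplitudes and baselines are profiled out by weighted linear
least squares on a log-spaced grid of rates (5×5 and finer), the best starts
are refined by Nelder–Mead on the 2-D profiled surface — which avoids a
spurious k₁ ≈ k₂ collapse basin that full-parameter descent can enter — and
a damped least-squares polish (lmfit/TRF, ftol = xtol = gtol = 10⁻¹⁵)
delivers machine-precision convergence on noiseless data and the covariance
on noisy data.  Weighted fits use the propagated Poisson errors and report
unscaled (known-sigma) covariances; unweighted fits (available as a switch,
since published fits do not state their weighting) scale the covariance by
the reduced chi-square.  Dead-time-flagged points are excluded by default.

Conventions and safeguards: k₁ ≥ k₂ is enforced by fitting (k₂, Δk ≥ 0);
amplitudes are unconstrained in sign (A₁ < 0 is physical at short
incubation); rate pairs with ratio < 2 and overlapping intervals raise an
`identifiability` flag; a flat amplitude series returns k_cat = 0 with an
`inactive` flag (the dead-mutant phenotype); k_cat pinned at the zero bound
in the fixed-off-rate fit is flagged `boundary`.  The global
double-exponential fit shares the baseline across incubation times by
default (per-curve baselines are a switch; sharing is the stiffer, safer
default when curves come from the same sample and instrument).

## Temperature analysis

Arrhenius fits are weighted linear regressions of ln k on 1/T
(σ_lnk = σ_k/k), with Ea = −slope·R and A = e^intercept;
R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹, k_B and h in SI.  Transition-state
decomposition at a stated T gives ΔH_a = Ea − RT and ΔS_a from
A = (k_B T/h)(e/c°)e^(ΔS_a/R); the standard-concentration factor c° (1 M) is
applied only to bimolecular rate constants — for first-order rates it is
dropped by dimensional necessity.  ΔG_a = ΔH_a − T·ΔS_a is enforced as an
identity to 10⁻¹⁰.  Two-regime (non-Arrhenius) dissociation behavior is fit
as a piecewise-linear ln k vs 1/T model *continuous* at the breakpoint (a
rate constant cannot jump with temperature); a free breakpoint is located by
grid search over interior temperatures minimizing the total weighted
residual sum of squares, requiring ≥2 points per segment and ≥5
temperatures.  Extrapolation along the fitted law reports two significant
figures by default, the convention for quoted extrapolated rates.

## Replication studies and problem sizes

`anisokin.studies` packages the recovery experiments run by
`scripts/acceptance.py` and the end-to-end tests: 20-replicate ensembles per
dissociation/reactive protocol (traces of 1200–3000 s at 0.1 s bins,
analyzed at 1 s), 6 incubation times over 0–5 h for the amplitude method,
and 100 replicates of the four-temperature Arrhenius refit with 10 %
log-normal noise.  These sizes give medians stable to ~1 % while keeping a
full replication run around a minute on one CPU.  Confidence-interval
calibration is checked at the curve level (Gaussian noise of known sigma,
500 seeded fits) where the nominal 95 % interval must cover in 93–97 % of
runs.

## Known limitations

* Release of reactant and product is single-exponential by construction;
  multi-step release would bias off-rates toward their slowest resolvable
  component.
* The generator does not model product pre-dissociation during incubation,
  detector artifacts, photobleaching, or diffusion/FCS effects.
* High-temperature extrapolations far outside the fitted range (e.g. to
  60 °C) depend on per-rate fit parameters not reproducible from summary
  values alone and are out of scope for the replication studies.
* The WT product and reactant off-rates used to generate and to fix the
  fixed-off-rate fits are those measured in catalytically dead backgrounds
  (V149G, D85A/V149G), the standard practice when the active enzyme converts
  too quickly for a clean single-channel measurement.
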