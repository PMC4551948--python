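# anisokin

Kinetic analysis of RNA-guided pseudouridylation by fluorescence anisotropy.

H/ACA ribonucleoprotein particles (RNPs) — the guide-RNA-directed
pseudouridine synthases of archaea and eukaryotes — convert a target uridine
in substrate RNA to pseudouridine while the substrate is bound.  Binding,
on-enzyme conversion, and release of reactant and product can all be timed
by polarized fluorescence: a dye-labeled substrate tumbles fast when free
and slowly when bound to the ~100 kD enzyme, so the anisotropy

    r(t) = (I_p(t) − I_s(t)) / (I_p(t) + 2 I_s(t))

of the two polarized detection channels reports the bound fraction in real
time.  `anisokin` provides, for researchers doing quantitative enzyme
biophysics of this kind:

* **photon-level simulation** of the three bench protocols (association with
  excess enzyme, dissociation after large dilution, reactive-complex
  dissociation after variable incubation), with Poisson shot noise on 100 ms
  acquisition bins;
* **closed-form and numerical kinetics** of the single-turnover scheme
  S + E ⇌ ES → EP ⇌ E + P, whose post-dilution bound fraction is a double
  exponential with fast rate k₁ = k_off,P and slow rate k₂ = k_cat + k_off,S;
* **rate extraction**: single-exponential fits (k_obs, k_off), global
  shared-rate double-exponential fits, the two k_cat strategies
  (fixed-off-rate and incubation-amplitude), and the k_obs = k_on[E] + k_off
  regression;
* **temperature analysis**: weighted Arrhenius fits (k = A·e^(−Ea/RT)),
  transition-state decomposition (Ea = ΔH_a + RT,
  A = (k_B T/h)(e/c°)·e^(ΔS_a/R)), two-regime fits with a continuous
  breakpoint, and extrapolation of rates along the fitted law.

## Worked example

Extracting the catalytic rate of the full *Pyrococcus furiosus* RNP at
22 °C by the fixed-off-rate method (`examples/02_catalytic_rate_fixed_offrates.py`):

```bash
$ python examples/02_catalytic_rate_fixed_offrates.py
true k_cat   : 1.86 x1e-3 1/s
fitted k_cat : 1.89 +/- 0.02
flags        : none
```

A reactive enzyme–substrate complex is incubated 0.5 min, diluted
4000-fold, and its anisotropy decay simulated at the literature parameter
set (k_cat = 1.86×10⁻³ s⁻¹, k_off,S = 1.80×10⁻³ s⁻¹,
k_off,P = 8.6×10⁻³ s⁻¹).  With both off-rates fixed, the slow decay rate is
k_cat + k_off,S, and the fit returns the on-enzyme modification rate with
its standard error — here within one error bar of the generating value.
The other examples cover dissociation rates, the incubation-amplitude
method for slow catalysis (`0.169 ± 0.001 ×10⁻³ s⁻¹` recovered against a
true 0.170), association panels, and the Arrhenius/entropy analysis that
shows an accessory-protein effect that is purely entropic
(ΔΔS_a = R·ln 10.94 ≈ 4.75×10⁻³ kcal mol⁻¹ K⁻¹).

A thin CLI mirrors the stages (`anisokin simulate | anisotropy | fit-dissoc
| fit-kcat | arrhenius | run-all`); `run-all` executes a YAML/JSON study
config end to end and writes a machine-readable report.

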