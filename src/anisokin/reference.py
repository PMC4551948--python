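"""Literature kinetic parameters for *Pyrococcus furiosus* H/ACA RNP at the
bench temperatures used throughout the package.

These are measured rate constants reported for the guide-RNA-directed
pseudouridine synthase and its Gar1-free and point-mutant variants.  They are
inputs to the synthetic-data generator and the worked examples; nothing in the
fitting code depends on them.

Notes on provenance of individual values:

* Catalytic (single-turnover modification) rates at 22 degC:
  full RNP 1.86e-3 1/s, Gar1-free RNP 0.17e-3 1/s.
* Product (Sub-Psi) off-rate 8.6e-3 1/s and reactant (Sub-U) off-rate
  1.80e-3 1/s, both measured in catalytically dead backgrounds (V149G and
  D85A/V149G respectively); the dead backgrounds are used precisely because
  the off-rates there are not confounded by on-enzyme conversion, and the
  same values are the ones fixed when extracting k_cat from reactive decays.
* V149G Gar1-free complexes show a single mean off-rate of 1.13e-3 1/s at all
  incubation times — the signature of a catalytically dead mutant.
* Apparent activation energies of the modification step: 40.4 kcal/mol (full
  RNP, fitted over 15-22 degC) and 40.7 kcal/mol (Gar1-free, 22-37 degC).
* Association rate constants are reported on a 1e3-1e4 1/(M s) scale
  (e.g. 8.8e3 1/(M s) for the full RNP loading Sub-U at 22 degC, extrapolating
  to ~4.5e4 1/(M s) at 30 degC).  The printed mutant-panel table carries the
  mantissas; ``ASSOC_KON_PRINTED`` stores them as printed since only their
  ratios are used.
"""

from __future__ import annotations

from .kinetics import RateSet, celsius_to_kelvin

__all__ = [
    "WT_22C",
    "DGAR1_22C",
    "V149G_DGAR1_22C",
    "D85A_V149G_DGAR1_22C",
    "EA_KCAT_WT_KCAL",
    "EA_KCAT_DGAR1_KCAL",
    "ASSOC_KON_PRINTED",
    "wt_rates_at",
]

#: full RNP at 22 degC (k_cat measured directly; off-rates from dead backgrounds)
WT_22C = RateSet(
    k_on_S=8.8e3,
    k_off_S=1.80e-3,
    k_cat=1.86e-3,
    k_off_P=8.6e-3,
    k_on_P=8.0e3,
    temperature=celsius_to_kelvin(22.0),
)

#: Gar1-free RNP at 22 degC — ~11-fold slower catalysis, similar binding
DGAR1_22C = WT_22C.with_(k_cat=0.17e-3)

#: V149G thumb-loop mutant without Gar1: catalytically dead, slow release
V149G_DGAR1_22C = WT_22C.with_(k_cat=0.0, k_off_S=1.13e-3)

#: doubly dead background used to measure the pure Sub-U off-rate
D85A_V149G_DGAR1_22C = WT_22C.with_(k_cat=0.0, k_off_S=1.80e-3)

#: apparent Arrhenius activation energies of the modification step, kcal/mol
EA_KCAT_WT_KCAL = 40.4
EA_KCAT_DGAR1_KCAL = 40.7

#: association rate constants as printed in the mutant-panel table
#: (mantissa, standard error); only ratios of these are meaningful here
ASSOC_KON_PRINTED = {
    "WT/Sub-U": (8.8, 1.6),
    "V149L/Sub-U": (3.9, 0.2),
}


def wt_rates_at(temperature_c: float) -> RateSet:
    """Full-RNP rate set with k_cat moved to ``temperature_c`` along the
    Arrhenius law (anchor: 1.86e-3 1/s at 22 degC, Ea = 40.4 kcal/mol).

    Off-rates and association rates are kept at their 22 degC values; use this
    only where the catalytic step is the quantity of interest.
    """
    from .thermo import extrapolate_rate

    T = celsius_to_kelvin(temperature_c)
    k = extrapolate_rate(
        EA_KCAT_WT_KCAL, WT_22C.k_cat, WT_22C.temperature, T, round_sig=None
    )
    return WT_22C.with_(k_cat=k, temperature=T)
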