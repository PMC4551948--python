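"""Parameter-recovery studies: simulate an ensemble under known rates, run
the standard reduction and fit, and report the recovered values.

These are the package's replication experiments: each function regenerates a
bench protocol at the literature parameter set and measures how well the
corresponding extraction method recovers the generating rate.  They are used
by the acceptance script and the test suite; problem sizes default to the
study conditions (>= 20 seeds per ensemble, 0.1 s raw bins rebinned to 1 s).
"""

from __future__ import annotations

import numpy as np

from . import reference as ref
from .fitting import fit_single_exponential, kcat_fixed_offrates
from .kinetics import RateSet, celsius_to_kelvin
from .pipeline import analyze_incubation_series, trace_to_curve
from .simulate import OpticalParams, Protocol, simulate_incubation_series, \
    simulate_polarized_trace
from .thermo import extrapolate_rate, fit_arrhenius

__all__ = [
    "child_seeds",
    "recover_kcat_fixed_offrate",
    "recover_kcat_amplitude_series",
    "recover_koff_single_exponential",
    "recover_activation_energy",
]

#: incubation times spanning 0-5 h for the slow-catalysis amplitude method
DEFAULT_INCUBATION_TIMES = (0.0, 1800.0, 3600.0, 7200.0, 12600.0, 18000.0)


def child_seeds(master_seed: int, n: int) -> list[int]:
    """n reproducible per-replicate seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def recover_kcat_fixed_offrate(
    master_seed: int,
    n_seeds: int = 20,
    rates: RateSet = ref.WT_22C,
    incubation_time: float = 30.0,
    duration: float = 3000.0,
    optics: OpticalParams | None = None,
) -> np.ndarray:
    """Fixed-off-rate k_cat recovery on reactive-dissociation ensembles.

    Simulates ``n_seeds`` reactive decays after a short incubation (default
    0.5 min, the fast-catalysis protocol), fits each with both off-rates
    fixed at their generating values, and returns the fitted k_cat values.
    """
    optics = optics or OpticalParams()
    proto = Protocol.reactive(incubation_time, duration=duration,
                              temperature=rates.temperature)
    out = []
    for s in child_seeds(master_seed, n_seeds):
        trace = simulate_polarized_trace(proto, rates, optics, s)
        res = kcat_fixed_offrates(trace_to_curve(trace, g_factor=optics.g_factor),
                                  rates.k_off_S, rates.k_off_P)
        out.append(res["k_cat"])
    return np.asarray(out)


def recover_kcat_amplitude_series(
    master_seed: int,
    n_seeds: int = 20,
    rates: RateSet = ref.DGAR1_22C,
    incubation_times=DEFAULT_INCUBATION_TIMES,
    duration: float = 3000.0,
    optics: OpticalParams | None = None,
) -> np.ndarray:
    """Incubation-amplitude k_cat recovery (the slow-catalysis protocol).

    For each replicate: simulate one decay per incubation time, globally fit
    all curves to a shared-rate double exponential, fit both amplitude series
    to a shared single exponential of incubation time, and return the fitted
    rates.
    """
    optics = optics or OpticalParams()
    base = Protocol.reactive(0.0, duration=duration, temperature=rates.temperature)
    out = []
    for s in child_seeds(master_seed, n_seeds):
        traces = simulate_incubation_series(base, rates, optics,
                                            incubation_times, s)
        curves = {t: trace_to_curve(tr, g_factor=optics.g_factor)
                  for t, tr in zip(incubation_times, traces)}
        out.append(analyze_incubation_series(curves)["k_cat"])
    return np.asarray(out)


def recover_koff_single_exponential(
    master_seed: int,
    rates: RateSet,
    n_seeds: int = 20,
    species: str = "product",
    duration: float | None = None,
    optics: OpticalParams | None = None,
) -> np.ndarray:
    """Single-exponential off-rate recovery from dilution-protocol ensembles.

    ``species`` chooses which complex starts fully bound: 'product' decays at
    k_off_P, 'substrate' (with k_cat = 0) at k_off_S.
    """
    optics = optics or OpticalParams()
    if species == "product":
        es0, ep0, k_true = 0.0, 1.0, rates.k_off_P
    elif species == "substrate":
        es0, ep0, k_true = 1.0, 0.0, rates.k_cat + rates.k_off_S
    else:
        raise ValueError("species must be 'product' or 'substrate'")
    if duration is None:
        duration = 8.0 / k_true  # through the plateau
    proto = Protocol.dissociation(duration=duration, initial_es=es0,
                                  initial_ep=ep0, temperature=rates.temperature)
    out = []
    for s in child_seeds(master_seed, n_seeds):
        trace = simulate_polarized_trace(proto, rates, optics, s)
        res = fit_single_exponential(trace_to_curve(trace, g_factor=optics.g_factor))
        out.append(res["k"])
    return np.asarray(out)


def recover_activation_energy(
    master_seed: int,
    n_seeds: int = 100,
    Ea_true: float = ref.EA_KCAT_WT_KCAL,
    k_ref: float = ref.WT_22C.k_cat,
    T_ref_c: float = 22.0,
    temperatures_c=(15.0, 17.5, 20.0, 22.0),
    noise_frac: float = 0.10,
) -> np.ndarray:
    """Arrhenius-slope recovery from noisy synthetic rate tables.

    Rates at the given temperatures are generated from the Arrhenius law
    anchored at (T_ref, k_ref) with multiplicative log-normal noise of
    relative width ``noise_frac``, then refit; returns the fitted Ea values
    in kcal/mol.
    """
    T_ref = celsius_to_kelvin(T_ref_c)
    out = []
    for s in child_seeds(master_seed, n_seeds):
        rng = np.random.default_rng(s)
        table = {}
        for tc in temperatures_c:
            T = celsius_to_kelvin(tc)
            k = extrapolate_rate(Ea_true, k_ref, T_ref, T, round_sig=None)
            kn = k * rng.lognormal(0.0, noise_frac)
            table[T] = (kn, noise_frac * kn)
        out.append(fit_arrhenius(table).Ea)
    return np.asarray(out)
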