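"""Photon-level simulation of polarized-fluorescence kinetics experiments.

Emulates the three bench protocols used to characterise RNA-guided
pseudouridylation kinetics:

``association``
    Dye-labeled substrate (nM) is mixed with excess enzyme (0.1-0.75 uM) and
    binding is followed as an anisotropy rise with pseudo-first-order rate
    k_obs = k_on [E] + k_off.
``dissociation``
    A preincubated complex (uM concentrations) is diluted ~4000-fold so that
    rebinding is negligible and the bound fraction decays.
``reactive_dissociation``
    Same dilution applied to an *active* enzyme-substrate complex after a
    chosen incubation time; the decay is double-exponential because bound
    substrate, bound product and on-enzyme conversion all contribute.

Per raw acquisition bin (100 ms by default) the bound fraction sets the
anisotropy, r = f_b * r_bound + (1 - f_b) * r_free (equal molecular brightness
of bound and free dye), the total intensity splits into channels as
I_p : I_s = (1 + 2r) : (1 - r), and counts are Poisson-sampled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .kinetics import (
    RateSet,
    association_bound_fraction,
    dissociation_bound_fraction,
    incubation_conversion,
)
from .traces import PolarizedTrace

__all__ = [
    "OpticalParams",
    "Protocol",
    "simulate_polarized_trace",
    "simulate_incubation_series",
    "simulate_association_panel",
    "make_fixture_dataset",
]


@dataclass(frozen=True)
class OpticalParams:
    """Detection parameters of the dual-channel confocal setup.

    r_free / r_bound are the anisotropies of free and RNP-bound labeled RNA
    (the ~20-fold molecular-weight change gives a large contrast);
    ``total_rate`` is the mean detected count rate summed over channels, in
    counts/s; ``g_factor`` multiplies the s-channel sensitivity; ``raw_bin``
    is the acquisition bin in seconds.  ``shot_noise=False`` switches Poisson
    sampling off and returns expected counts (the infinite-intensity limit).
    """

    r_free: float = 0.05
    r_bound: float = 0.25
    total_rate: float = 100_000.0
    g_factor: float = 1.0
    raw_bin: float = 0.1
    background_rate: float = 0.0
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if not (-0.2 <= self.r_free < self.r_bound <= 0.4):
            raise ValueError("require -0.2 <= r_free < r_bound <= 0.4")
        if self.total_rate <= 0 or self.raw_bin <= 0:
            raise ValueError("total_rate and raw_bin must be > 0")
        if self.g_factor <= 0 or self.background_rate < 0:
            raise ValueError("g_factor must be > 0 and background_rate >= 0")


@dataclass(frozen=True)
class Protocol:
    """One experiment definition.

    ``initial_es`` / ``initial_ep`` are the bound fractions of reactant and
    product complex at the moment of dilution (dissociation protocols); for
    ``reactive_dissociation`` they are derived from ``incubation_time`` and
    the catalytic rate at simulation time and need not be set.
    """

    kind: str
    enzyme_conc: float = 6e-6
    substrate_conc: float = 10e-9
    incubation_time: float = 0.0
    dilution_factor: float = 4000.0
    duration: float = 3000.0
    dead_time: float = 0.0
    temperature: float = 295.15
    initial_es: float = 1.0
    initial_ep: float = 0.0

    _KINDS = ("association", "dissociation", "reactive_dissociation")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}, got {self.kind!r}")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if not self.duration > self.dead_time >= 0:
            raise ValueError("require duration > dead_time >= 0")
        if self.enzyme_conc < 0 or self.substrate_conc < 0:
            raise ValueError("concentrations must be >= 0")
        if self.incubation_time < 0:
            raise ValueError("incubation_time must be >= 0")

    # -- convenience constructors ------------------------------------------
    @classmethod
    def association(cls, enzyme_conc: float, duration: float = 600.0,
                    dead_time: float = 30.0, substrate_conc: float = 10e-9,
                    temperature: float = 295.15) -> "Protocol":
        return cls(kind="association", enzyme_conc=enzyme_conc,
                   substrate_conc=substrate_conc, duration=duration,
                   dead_time=dead_time, temperature=temperature)

    @classmethod
    def dissociation(cls, duration: float = 3000.0, initial_es: float = 1.0,
                     initial_ep: float = 0.0, temperature: float = 295.15,
                     dead_time: float = 0.0) -> "Protocol":
        return cls(kind="dissociation", duration=duration, dead_time=dead_time,
                   initial_es=initial_es, initial_ep=initial_ep,
                   temperature=temperature, substrate_conc=0.5e-9,
                   enzyme_conc=6e-6)

    @classmethod
    def reactive(cls, incubation_time: float, duration: float = 3000.0,
                 temperature: float = 295.15, dead_time: float = 0.0) -> "Protocol":
        return cls(kind="reactive_dissociation", incubation_time=incubation_time,
                   duration=duration, dead_time=dead_time,
                   temperature=temperature, substrate_conc=0.5e-9,
                   enzyme_conc=6e-6)

    def with_(self, **kwargs) -> "Protocol":
        return replace(self, **kwargs)


def _bound_fraction(protocol: Protocol, rates: RateSet, t: np.ndarray) -> np.ndarray:
    if protocol.kind == "association":
        return association_bound_fraction(
            rates.k_on_S, rates.k_off_S, protocol.enzyme_conc, t
        )
    if protocol.kind == "dissociation":
        return dissociation_bound_fraction(
            rates, protocol.initial_es, protocol.initial_ep, t
        )
    # reactive dissociation: all-bound incubation sets the split at dilution
    p = incubation_conversion(rates.k_cat, protocol.incubation_time)
    return dissociation_bound_fraction(rates, 1.0 - p, p, t)


def simulate_polarized_trace(
    protocol: Protocol, rates: RateSet, optics: OpticalParams, seed: int
) -> PolarizedTrace:
    """Simulate one dual-channel photon trace for a protocol.

    The time origin is the mixing/dilution event; bins earlier than
    ``protocol.dead_time`` are simulated but flagged.  ``seed`` is required
    even in noiseless mode so that call sites stay reproducible by
    construction.
    """
    if seed is None:
        raise ValueError("seed is required")
    t = np.arange(0.0, protocol.duration, optics.raw_bin)
    fb = _bound_fraction(protocol, rates, t)
    r = optics.r_free + (optics.r_bound - optics.r_free) * fb
    per_bin = optics.total_rate * optics.raw_bin
    lam_p = per_bin * (1.0 + 2.0 * r) / 3.0 + optics.background_rate * optics.raw_bin
    lam_s = per_bin * (1.0 - r) / 3.0 / optics.g_factor \
        + optics.background_rate * optics.raw_bin
    if np.any(lam_p + lam_s <= 0):
        raise ValueError("protocol yields zero expected counts in some bins")
    if optics.shot_noise:
        rng = np.random.default_rng(seed)
        Ip = rng.poisson(lam_p).astype(float)
        Is = rng.poisson(lam_s).astype(float)
    else:
        Ip, Is = lam_p, lam_s
    return PolarizedTrace(
        time_s=t,
        Ip=Ip,
        Is=Is,
        raw_bin=optics.raw_bin,
        dead=t < protocol.dead_time,
        meta={
            "kind": protocol.kind,
            "enzyme_conc_M": protocol.enzyme_conc,
            "incubation_time_s": protocol.incubation_time,
            "temperature_K": protocol.temperature,
            "seed": int(seed),
            "g_factor": optics.g_factor,
        },
    )


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n reproducible sub-seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def simulate_incubation_series(
    base_protocol: Protocol,
    rates: RateSet,
    optics: OpticalParams,
    incubation_times,
    seed: int,
) -> list[PolarizedTrace]:
    """One reactive-dissociation trace per incubation time.

    The bound-species split at dilution follows the first-order conversion
    p = 1 - exp(-k_cat * t_inc), so the downstream decay amplitudes are
    single-exponential functions of incubation time with rate k_cat.
    """
    incubation_times = list(incubation_times)
    if len(incubation_times) < 3:
        raise ValueError("need at least 3 incubation times")
    if any(t < 0 for t in incubation_times):
        raise ValueError("incubation times must be >= 0")
    seeds = _child_seeds(seed, len(incubation_times))
    return [
        simulate_polarized_trace(
            base_protocol.with_(kind="reactive_dissociation", incubation_time=t_inc),
            rates,
            optics,
            s,
        )
        for t_inc, s in zip(incubation_times, seeds)
    ]


def simulate_association_panel(
    rates: RateSet, optics: OpticalParams, enzyme_concs, seed: int,
    duration: float = 600.0, dead_time: float = 30.0,
) -> list[PolarizedTrace]:
    """One association trace per enzyme concentration (k_obs = k_on E + k_off)."""
    enzyme_concs = list(enzyme_concs)
    if len(enzyme_concs) < 2:
        raise ValueError("need at least 2 enzyme concentrations")
    seeds = _child_seeds(seed, len(enzyme_concs))
    return [
        simulate_polarized_trace(
            Protocol.association(E, duration=duration, dead_time=dead_time,
                                 temperature=rates.temperature),
            rates, optics, s,
        )
        for E, s in zip(enzyme_concs, seeds)
    ]


# ---------------------------------------------------------------------------
# full synthetic study
# ---------------------------------------------------------------------------

def _default_conditions() -> list[dict]:
    """The default synthetic study: association panel, dissociation curves for
    reactant and product with and without Gar1, a reactive temperature series,
    and the catalytically dead mutant panel."""
    from . import reference as ref
    from .kinetics import celsius_to_kelvin
    from .thermo import extrapolate_rate

    conds: list[dict] = []
    for E in (0.10e-6, 0.25e-6, 0.50e-6, 0.75e-6):
        conds.append({
            "name": f"assoc_WT_{E * 1e6:.2f}uM",
            "protocol": Protocol.association(E, temperature=ref.WT_22C.temperature),
            "rates": ref.WT_22C,
        })
    for label, rates in (("WT", ref.WT_22C), ("dGar1", ref.DGAR1_22C)):
        dead = rates.with_(k_cat=0.0)
        conds.append({"name": f"dissoc_SubU_{label}",
                      "protocol": Protocol.dissociation(initial_es=1.0, initial_ep=0.0,
                                                        temperature=rates.temperature),
                      "rates": dead})
        conds.append({"name": f"dissoc_SubPsi_{label}",
                      "protocol": Protocol.dissociation(initial_es=0.0, initial_ep=1.0,
                                                        temperature=rates.temperature),
                      "rates": dead})
    # reactive series: full RNP 15-22 degC, Gar1-free 22-37 degC
    for temp_c in (15.0, 17.5, 20.0, 22.0):
        conds.append({"name": f"reactive_WT_{temp_c:g}C",
                      "protocol": Protocol.reactive(30.0,
                                                    temperature=celsius_to_kelvin(temp_c)),
                      "rates": ref.wt_rates_at(temp_c)})
    for temp_c in (22.0, 27.0, 32.0, 37.0):
        T = celsius_to_kelvin(temp_c)
        kcat = extrapolate_rate(ref.EA_KCAT_DGAR1_KCAL, ref.DGAR1_22C.k_cat,
                                ref.DGAR1_22C.temperature, T, round_sig=None)
        conds.append({"name": f"reactive_dGar1_{temp_c:g}C",
                      "protocol": Protocol.reactive(3600.0, temperature=T),
                      "rates": ref.DGAR1_22C.with_(k_cat=kcat, temperature=T)})
    # dead-mutant panel
    conds.append({"name": "dissoc_SubU_V149G_dGar1",
                  "protocol": Protocol.dissociation(),
                  "rates": ref.V149G_DGAR1_22C})
    conds.append({"name": "dissoc_SubU_D85A_V149G_dGar1",
                  "protocol": Protocol.dissociation(),
                  "rates": ref.D85A_V149G_DGAR1_22C})
    return conds


def make_fixture_dataset(
    output_dir,
    master_seed: int,
    conditions: list[dict] | None = None,
    optics: OpticalParams | None = None,
    overwrite: bool = False,
) -> dict:
    """Write a synthetic study (trace CSVs + manifest of true parameters).

    Each condition dict has keys ``name``, ``protocol``, ``rates``.  Per-file
    seeds are derived deterministically from ``master_seed``, so the same seed
    writes byte-identical files.  Refuses to overwrite an existing manifest
    unless ``overwrite=True``.
    """
    from .io import write_trace_csv

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace")
    optics = optics or OpticalParams()
    conditions = conditions if conditions is not None else _default_conditions()
    seeds = _child_seeds(master_seed, len(conditions))
    manifest: dict = {"master_seed": int(master_seed), "conditions": {}}
    for cond, s in zip(conditions, seeds):
        name, protocol, rates = cond["name"], cond["protocol"], cond["rates"]
        trace = simulate_polarized_trace(protocol, rates, optics, s)
        fname = f"{name}.csv"
        write_trace_csv(trace, out / fname)
        manifest["conditions"][name] = {
            "file": fname,
            "seed": s,
            "protocol": {
                "kind": protocol.kind,
                "enzyme_conc_M": protocol.enzyme_conc,
                "incubation_time_s": protocol.incubation_time,
                "duration_s": protocol.duration,
                "dead_time_s": protocol.dead_time,
                "temperature_K": protocol.temperature,
                "initial_es": protocol.initial_es,
                "initial_ep": protocol.initial_ep,
            },
            "true_rates": {
                "k_on_S": rates.k_on_S, "k_off_S": rates.k_off_S,
                "k_cat": rates.k_cat, "k_off_P": rates.k_off_P,
                "k_on_P": rates.k_on_P, "temperature_K": rates.temperature,
            },
            "optics": {
                "r_free": optics.r_free, "r_bound": optics.r_bound,
                "total_rate": optics.total_rate, "g_factor": optics.g_factor,
                "raw_bin": optics.raw_bin,
            },
        }
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
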