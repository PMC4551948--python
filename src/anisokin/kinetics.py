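"""Three-state single-turnover kinetics of RNA-guided pseudouridylation.

The reaction scheme is

    S + E  <=>  ES  -->  EP  <=>  E + P

with bimolecular loading of substrate (``k_on_S``) and product (``k_on_P``),
first-order release of the reactant complex (``k_off_S``) and product complex
(``k_off_P``), and an irreversible on-enzyme isomerisation step ``k_cat``
(uridine -> pseudouridine while bound).

After a large dilution the free-enzyme concentration is negligible and the
bound species decay without rebinding; the bound fraction ES + EP is then a
double exponential whose fast rate equals the product off-rate and whose slow
rate equals ``k_cat + k_off_S``.  Those closed forms, plus a brute-force ODE
integrator that keeps the rebinding terms, live here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "RateSet",
    "SpeciesState",
    "BiexpDecay",
    "dissociation_bound_fraction",
    "biexp_parameters",
    "incubation_conversion",
    "association_bound_fraction",
    "ode_oracle",
    "celsius_to_kelvin",
]

#: relative rate separation below which the biexponential is treated as degenerate
DEGENERATE_REL_TOL = 1e-6


def celsius_to_kelvin(t_celsius: float) -> float:
    """Convert a Celsius temperature to kelvin (K = degC + 273.15)."""
    return float(t_celsius) + 273.15


@dataclass(frozen=True)
class RateSet:
    """The five rate constants of the single-turnover scheme at one temperature.

    Parameters
    ----------
    k_on_S, k_on_P : float
        Bimolecular association rate constants of substrate and product,
        in 1/(M s).
    k_off_S, k_off_P : float
        Dissociation rate constants of the reactant (ES) and product (EP)
        complexes, in 1/s.
    k_cat : float
        On-enzyme modification rate (single-turnover), in 1/s.
    temperature : float
        Thermodynamic temperature in kelvin.
    """

    k_on_S: float
    k_off_S: float
    k_cat: float
    k_off_P: float
    k_on_P: float
    temperature: float = 295.15

    def __post_init__(self) -> None:
        for name in ("k_on_S", "k_off_S", "k_cat", "k_off_P", "k_on_P"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if not math.isfinite(self.temperature) or self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature!r}")

    def with_(self, **kwargs) -> "RateSet":
        """Return a copy with the given rates replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SpeciesState:
    """Fractions of labeled RNA in each species: free S, bound ES, bound EP, free P."""

    S: float
    ES: float
    EP: float
    P: float

    def __post_init__(self) -> None:
        vals = (self.S, self.ES, self.EP, self.P)
        if any((not math.isfinite(v)) or v < -1e-12 or v > 1 + 1e-12 for v in vals):
            raise ValueError(f"species fractions must lie in [0, 1], got {vals}")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"species fractions must sum to 1, got {sum(vals)!r}")

    @property
    def bound(self) -> float:
        return self.ES + self.EP

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.ES, self.EP, self.P], dtype=float)


@dataclass(frozen=True)
class BiexpDecay:
    """Parameters of r(t) = A1 exp(-k1 t) + A2 exp(-k2 t) + offset, k1 >= k2.

    ``degenerate`` marks the limiting form (a + b t) exp(-k t) used when the
    two rates coincide; then ``A1`` holds the linear-in-t prefactor b.
    """

    k1: float
    k2: float
    A1: float
    A2: float
    offset: float = 0.0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("decay rates must be >= 0")
        if not self.degenerate and self.k1 < self.k2:
            raise ValueError("convention requires k1 >= k2")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.degenerate:
            return (self.A2 + self.A1 * t) * np.exp(-self.k2 * t) + self.offset
        return (
            self.A1 * np.exp(-self.k1 * t)
            + self.A2 * np.exp(-self.k2 * t)
            + self.offset
        )


def _check_initial_fractions(es0: float, ep0: float) -> None:
    if not (math.isfinite(es0) and math.isfinite(ep0)):
        raise ValueError("initial fractions must be finite")
    if es0 < 0 or ep0 < 0:
        raise ValueError("initial fractions must be >= 0")
    if es0 + ep0 > 1 + 1e-12:
        raise ValueError("es0 + ep0 must be <= 1")


def dissociation_bound_fraction(rates: RateSet, es0: float, ep0: float, t) -> np.ndarray:
    """Bound fraction ES(t) + EP(t) after dilution, neglecting rebinding.

    Closed-form solution of the linear decay system

        dES/dt = -(k_cat + k_off_S) ES
        dEP/dt =  k_cat ES - k_off_P EP

    When ``k_off_P`` coincides with ``k_cat + k_off_S`` (relative separation
    below ``DEGENERATE_REL_TOL``) the limiting form with a linear-in-t
    prefactor is used instead of the singular quotient.

    Parameters
    ----------
    rates : RateSet
    es0, ep0 : float
        Bound fractions of reactant and product complex at the moment of
        dilution; es0 + ep0 <= 1.
    t : array_like
        Times since dilution, seconds.  Must be >= 0 and finite.
    """
    _check_initial_fractions(es0, ep0)
    t = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise ValueError("times must be finite and >= 0")
    k2 = rates.k_cat + rates.k_off_S
    k1 = rates.k_off_P
    es = es0 * np.exp(-k2 * t)
    scale = max(k1, k2, 1.0)
    if abs(k1 - k2) / scale < DEGENERATE_REL_TOL:
        # degenerate limit: EP picks up a t * exp(-k t) term
        ep = ep0 * np.exp(-k1 * t) + es0 * rates.k_cat * t * np.exp(-k2 * t)
    else:
        ep = ep0 * np.exp(-k1 * t) + es0 * rates.k_cat / (k1 - k2) * (
            np.exp(-k2 * t) - np.exp(-k1 * t)
        )
    return es + ep


def biexp_parameters(rates: RateSet, es0: float, ep0: float) -> BiexpDecay:
    """Amplitudes and rates of the double-exponential bound-fraction decay.

    The fast rate is the product off-rate, ``k1 = k_off_P``; the slow rate is
    the depletion rate of the reactant complex, ``k2 = k_cat + k_off_S``.  The
    amplitudes follow from the closed form:

        A2 = es0 (1 + k_cat / (k_off_P - k2)),   A1 = ep0 - es0 k_cat / (k_off_P - k2)

    so that A1 + A2 = es0 + ep0.  A1 may be negative (product grows before it
    decays at short incubation).  Degenerate rates return the limiting form
    flagged via ``BiexpDecay.degenerate``.
    """
    _check_initial_fractions(es0, ep0)
    k2 = rates.k_cat + rates.k_off_S
    k1 = rates.k_off_P
    scale = max(k1, k2, 1.0)
    if abs(k1 - k2) / scale < DEGENERATE_REL_TOL:
        # (A2 + A1 * t) exp(-k t): constant term es0 + ep0, slope es0 * k_cat
        return BiexpDecay(
            k1=k1, k2=k2, A1=es0 * rates.k_cat, A2=es0 + ep0, degenerate=True
        )
    cross = es0 * rates.k_cat / (k1 - k2)
    decay = BiexpDecay(k1=max(k1, k2), k2=min(k1, k2),
                       A1=(ep0 - cross) if k1 >= k2 else es0 + cross,
                       A2=(es0 + cross) if k1 >= k2 else ep0 - cross)
    return decay


def incubation_conversion(k_cat: float, t_inc: float) -> float:
    """Fraction of substrate converted to product after incubating ``t_inc`` s.

    Assumes saturating enzyme (all substrate bound throughout the incubation),
    so conversion is a simple first-order process: p = 1 - exp(-k_cat t_inc).
    """
    if k_cat < 0:
        raise ValueError("k_cat must be >= 0")
    if t_inc < 0:
        raise ValueError("incubation time must be >= 0")
    return -math.expm1(-k_cat * t_inc)


def association_bound_fraction(k_on: float, k_off: float, E: float, t) -> np.ndarray:
    """Pseudo-first-order binding curve f(t) = f_eq (1 - exp(-k_obs t)).

    Valid when the enzyme is in large excess over labeled RNA, so the free
    enzyme concentration ``E`` is constant; then k_obs = k_on E + k_off and the
    equilibrium bound fraction is f_eq = k_on E / k_obs.
    """
    if E < 0:
        raise ValueError("enzyme concentration must be >= 0")
    if k_on < 0 or k_off < 0:
        raise ValueError("rates must be >= 0")
    t = np.asarray(t, dtype=float)
    k_obs = k_on * E + k_off
    if k_obs == 0:
        return np.zeros_like(t)
    f_eq = k_on * E / k_obs
    return f_eq * -np.expm1(-k_obs * t)


def ode_oracle(
    rates: RateSet,
    initial: SpeciesState,
    E_free: float,
    times,
    rtol: float = 1e-12,
    atol: float = 1e-14,
) -> list[SpeciesState]:
    """Numerically integrate the full scheme, including rebinding.

    Brute-force check of the closed forms: integrates

        dS/dt  = -k_on_S E S + k_off_S ES
        dES/dt =  k_on_S E S - (k_off_S + k_cat) ES
        dEP/dt =  k_cat ES + k_on_P E P - k_off_P EP
        dP/dt  =  k_off_P EP - k_on_P E P

    at fixed free-enzyme concentration ``E_free`` (molar), which is exact in
    the pseudo-first-order regime.  Total labeled RNA is conserved to 1e-10.
    """
    if E_free < 0:
        raise ValueError("free enzyme concentration must be >= 0")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be non-decreasing")

    konS, koffS, kcat = rates.k_on_S * E_free, rates.k_off_S, rates.k_cat
    koffP, konP = rates.k_off_P, rates.k_on_P * E_free
    gen = np.array(
        [
            [-konS, koffS, 0.0, 0.0],
            [konS, -(koffS + kcat), 0.0, 0.0],
            [0.0, kcat, -koffP, konP],
            [0.0, 0.0, koffP, -konP],
        ]
    )

    t0 = float(times[0])
    sol = solve_ivp(
        lambda _t, y: gen @ y,
        (t0, float(times[-1]) if times[-1] > t0 else t0 + 1.0),
        initial.as_array(),
        t_eval=times if times[-1] > t0 else None,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    ys = sol.y.T if times[-1] > t0 else np.tile(initial.as_array(), (times.size, 1))
    out = []
    for row in ys:
        total = row.sum()
        if abs(total - 1.0) > 1e-10:
            raise RuntimeError(f"labeled-RNA conservation violated: total={total!r}")
        out.append(SpeciesState(*np.clip(row, 0.0, 1.0)))
    return out
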