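"""Temperature dependence of rate constants: Arrhenius fits, transition-state
decomposition, two-regime (non-Arrhenius) fits, and extrapolation.

Arrhenius:  k(T) = A exp(-Ea / R T), fitted as a weighted linear regression of
ln k on 1/T.

Transition-state theory:  k = (kB T / h) exp(dS_a / R) exp(-dH_a / R T), so

    Ea   = dH_a + R T
    A    = (kB T / h) (e / c0) exp(dS_a / R)

with the standard-concentration factor c0 appearing only for bimolecular rate
constants (dimensional necessity; c0 = 1 M by convention).  Energies are in
kcal/mol throughout, with R = 1.987e-3 kcal/(mol K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "R_KCAL",
    "K_B",
    "PLANCK_H",
    "ArrheniusFit",
    "EyringParams",
    "fit_arrhenius",
    "eyring_decompose",
    "extrapolate_rate",
    "fit_piecewise_arrhenius",
    "round_sig",
]

#: gas constant, kcal mol^-1 K^-1
R_KCAL = 1.987e-3
#: Boltzmann constant, J/K
K_B = 1.380649e-23
#: Planck constant, J s
PLANCK_H = 6.62607015e-34


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting convention for
    extrapolated rates)."""
    return _round_sig(x, sig)


@dataclass(frozen=True)
class ArrheniusFit:
    """Result of fitting ln k = ln A - Ea / (R T).

    ``cov`` is the 2x2 covariance of (ln A, Ea).  Two-regime fits carry a
    ``breakpoint`` (kelvin) and per-regime values in ``segments`` as
    (A, Ea, Ea_err) tuples ordered low-T, high-T.
    """

    A: float
    Ea: float
    Ea_err: float
    cov: np.ndarray
    T_range: tuple[float, float]
    breakpoint: float | None = None
    segments: tuple | None = None
    #: full covariance of (intercept, slope_lowT, slope_highT) in ln k / (1/T)
    #: space, for joint inference on two-regime fits
    seg_cov: np.ndarray | None = None
    rss: float = 0.0
    n: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.Ea):
            raise ValueError("Ea must be finite")
        if not self.T_range[0] < self.T_range[1]:
            raise ValueError("fitted temperature range must be non-empty")
        if self.breakpoint is not None and not (
            self.T_range[0] < self.breakpoint < self.T_range[1]
        ):
            raise ValueError("breakpoint must lie strictly inside the fitted range")

    def predict(self, T) -> np.ndarray:
        """k(T) from the fitted law (single-regime parameters)."""
        T = np.asarray(T, dtype=float)
        return self.A * np.exp(-self.Ea / (R_KCAL * T))


@dataclass(frozen=True)
class EyringParams:
    """Transition-state decomposition at one stated temperature.

    dH_a, dG_a in kcal/mol; dS_a in kcal/(mol K); ``c0`` in molar (only
    meaningful for bimolecular rates); ``molecularity`` is 'uni' or 'bi'.
    """

    dH_a: float
    dS_a: float
    dG_a: float
    T: float
    molecularity: str
    c0: float = 1.0

    def __post_init__(self) -> None:
        if self.molecularity not in ("uni", "bi"):
            raise ValueError("molecularity must be 'uni' or 'bi'")
        if abs(self.dG_a - (self.dH_a - self.T * self.dS_a)) > 1e-10:
            raise ValueError("dG_a must equal dH_a - T dS_a")

    def reconstruct(self) -> tuple[float, float]:
        """Return (A, Ea) implied by these activation parameters at self.T."""
        Ea = self.dH_a + R_KCAL * self.T
        conc = math.e / self.c0 if self.molecularity == "bi" else math.e
        A = (K_B * self.T / PLANCK_H) * conc * math.exp(self.dS_a / R_KCAL)
        return A, Ea


def _as_rate_table(rates: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalize {T: k} or {T: (k, err)} into arrays sorted by T."""
    Ts, ks, errs = [], [], []
    for T, v in rates.items():
        if np.ndim(v) == 0:
            k, e = float(v), 0.0
        else:
            k, e = float(v[0]), float(v[1])
        Ts.append(float(T))
        ks.append(k)
        errs.append(e)
    order = np.argsort(Ts)
    return np.asarray(Ts)[order], np.asarray(ks)[order], np.asarray(errs)[order]


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares y ~ a + b x; returns (a, b), covariance, rss."""
    X = np.column_stack([np.ones_like(x), x])
    W = np.diag(w)
    XtW = X.T @ W
    cov = np.linalg.inv(XtW @ X)
    beta = cov @ (XtW @ y)
    resid = y - X @ beta
    rss = float(resid @ (w * resid))
    return beta, cov, rss


def _lnk_weights(ks: np.ndarray, errs: np.ndarray, weighted: bool) -> np.ndarray:
    if weighted and np.all(errs > 0):
        return (ks / errs) ** 2  # Var(ln k) ~ (err/k)^2
    return np.ones_like(ks)


def fit_arrhenius(rates: dict, weighted: bool = True) -> ArrheniusFit:
    """Weighted linear regression of ln k on 1/T.

    ``rates`` maps temperature (K) to either k or (k, err) in any consistent
    rate unit.  Ea = -slope * R (kcal/mol); A = exp(intercept).  Errors
    propagate from the regression covariance; with fewer than 3 points the
    slope is not identified and a precondition error is raised.  When point
    errors are absent or ``weighted=False`` the fit is unweighted and the
    covariance is scaled by the reduced chi-square (if dof > 0).
    """
    Ts, ks, errs = _as_rate_table(rates)
    if Ts.size < 3:
        raise ValueError("need at least 3 temperatures for an Arrhenius fit")
    if np.any(ks <= 0):
        raise ValueError("all rates must be > 0")
    x = 1.0 / Ts
    y = np.log(ks)
    w = _lnk_weights(ks, errs, weighted)
    beta, cov, rss = _wls(x, y, w)
    dof = Ts.size - 2
    if not (weighted and np.all(errs > 0)) and dof > 0:
        cov = cov * max(rss / dof, np.finfo(float).tiny)
    # (intercept, slope) -> (ln A, Ea): Ea = -slope * R
    J = np.array([[1.0, 0.0], [0.0, -R_KCAL]])
    cov_ea = J @ cov @ J.T
    Ea = -beta[1] * R_KCAL
    return ArrheniusFit(
        A=float(np.exp(beta[0])),
        Ea=float(Ea),
        Ea_err=float(np.sqrt(max(cov_ea[1, 1], 0.0))),
        cov=cov_ea,
        T_range=(float(Ts.min()), float(Ts.max())),
        rss=rss,
        n=int(Ts.size),
    )


def eyring_decompose(
    fit: ArrheniusFit, T: float, molecularity: str = "uni", c0: float = 1.0
) -> EyringParams:
    """Decompose an Arrhenius fit into activation enthalpy and entropy at T.

    dH_a = Ea - R T; dS_a solves A = (kB T / h)(e / c0) exp(dS_a / R), with
    the c0 factor applied only for bimolecular rates (``molecularity='bi'``).
    """
    if molecularity not in ("uni", "bi"):
        raise ValueError("molecularity must be 'uni' or 'bi'")
    if T <= 0:
        raise ValueError("temperature must be > 0")
    if c0 <= 0:
        raise ValueError("standard concentration must be > 0")
    dH = fit.Ea - R_KCAL * T
    conc = math.e / c0 if molecularity == "bi" else math.e
    dS = R_KCAL * math.log(fit.A * PLANCK_H / (K_B * T) / conc)
    dG = dH - T * dS
    return EyringParams(dH_a=dH, dS_a=dS, dG_a=dG, T=T,
                        molecularity=molecularity, c0=c0)


def extrapolate_rate(
    Ea: float, k_ref: float, T_ref: float, T_target: float, round_sig: int | None = 2
) -> float:
    """Move a rate along the Arrhenius law from T_ref to T_target.

    k(T) = k_ref * exp(-(Ea / R)(1/T - 1/T_ref)); Ea in kcal/mol, T in
    kelvin.  By default the result is rounded to 2 significant figures, the
    convention used when quoting extrapolated rates; pass ``round_sig=None``
    for full precision.
    """
    if T_target <= 0 or T_ref <= 0:
        raise ValueError("temperatures must be > 0 K")
    if k_ref <= 0:
        raise ValueError("reference rate must be > 0")
    k = k_ref * math.exp(-(Ea / R_KCAL) * (1.0 / T_target - 1.0 / T_ref))
    if round_sig is not None:
        k = _round_sig(k, round_sig)
    return k


def fit_piecewise_arrhenius(
    rates: dict, breakpoint: float | None = None, weighted: bool = True
) -> ArrheniusFit:
    """Two-regime Arrhenius fit, continuous at the breakpoint.

    Model: ln k is piecewise linear in x = 1/T with a shared value at the
    break (a rate constant cannot jump with temperature).  With
    ``breakpoint=None`` the break is located by grid search over interior
    temperatures, minimizing the total (weighted) residual sum of squares;
    each segment must contain at least 2 points.  Reports the low-temperature
    segment as the headline (A, Ea) and both segments in ``segments``.
    """
    Ts, ks, errs = _as_rate_table(rates)
    if np.any(ks <= 0):
        raise ValueError("all rates must be > 0")
    if breakpoint is None and Ts.size < 5:
        raise ValueError("need at least 5 temperatures to locate a free breakpoint")
    if breakpoint is not None and not (Ts.min() < breakpoint < Ts.max()):
        raise ValueError("breakpoint must lie strictly inside the temperature range")
    x = 1.0 / Ts
    y = np.log(ks)
    w = _lnk_weights(ks, errs, weighted)

    def fit_at(Tb: float):
        xb = 1.0 / Tb
        # continuous hinge basis: y = c + b_lo * max(x - xb, 0) + b_hi * min(x - xb, 0)
        # (x decreases with T, so x > xb is the low-temperature side)
        lo = np.maximum(x - xb, 0.0)
        hi = np.minimum(x - xb, 0.0)
        if np.count_nonzero(lo) < 2 or np.count_nonzero(hi) < 2:
            return None
        X = np.column_stack([np.ones_like(x), lo, hi])
        W = np.diag(w)
        cov = np.linalg.inv(X.T @ W @ X)
        beta = cov @ (X.T @ W @ y)
        resid = y - X @ beta
        return beta, cov, float(resid @ (w * resid))

    if breakpoint is not None:
        candidates = [breakpoint]
    else:
        candidates = [0.5 * (Ts[i] + Ts[i + 1]) for i in range(1, Ts.size - 2)]
        candidates += list(Ts[2:-2])
    best = None
    for Tb in candidates:
        res = fit_at(Tb)
        if res is None:
            continue
        if best is None or res[2] < best[1][2]:
            best = (Tb, res)
    if best is None:
        raise ValueError("no admissible breakpoint leaves >= 2 points per segment")
    Tb, (beta, cov, rss) = best
    dof = Ts.size - 3
    scale = 1.0
    if not (weighted and np.all(errs > 0)) and dof > 0:
        scale = max(rss / dof, np.finfo(float).tiny)
    c, b_lo, b_hi = beta
    xb = 1.0 / Tb
    seg = []
    for b, idx in ((b_lo, 1), (b_hi, 2)):
        Ea = -b * R_KCAL
        Ea_err = R_KCAL * math.sqrt(max(cov[idx, idx] * scale, 0.0))
        A = math.exp(c - b * xb)
        seg.append((A, float(Ea), float(Ea_err)))
    lo_seg, hi_seg = seg
    cov_lo = np.array([[cov[0, 0], -R_KCAL * cov[0, 1]],
                       [-R_KCAL * cov[1, 0], R_KCAL**2 * cov[1, 1]]]) * scale
    return ArrheniusFit(
        A=lo_seg[0], Ea=lo_seg[1], Ea_err=lo_seg[2], cov=cov_lo,
        T_range=(float(Ts.min()), float(Ts.max())),
        breakpoint=float(Tb), segments=(lo_seg, hi_seg),
        seg_cov=cov * scale, rss=rss, n=int(Ts.size),
    )
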