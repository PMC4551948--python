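"""Curve fitting for anisotropy kinetics.

All decays are sums of exponentials, so every nonlinear fit here uses
variable projection for robustness: amplitudes and baselines enter linearly
and are profiled out by weighted linear least squares on a grid of rate
constants (log-spaced multi-start), and the best grid point seeds a damped
least-squares polish (lmfit).  This makes the fits deterministic and exact to
optimizer tolerance on noiseless data.

Two strategies extract the on-enzyme modification rate k_cat from reactive
dissociation decays:

* ``kcat_fixed_offrates`` — fix the independently measured off-rates
  k_off_P (fast) and k_off_S in a double-exponential fit and free only
  k_cat (the slow rate is k_off_S + k_cat).  Suited to fast catalysis,
  where varying the incubation time is impractical.
* ``kcat_from_amplitude_series`` — globally fit decays at several incubation
  times with shared rates, then fit both amplitudes as shared
  single-exponential functions of incubation time; the shared rate is k_cat.
  Suited to slow catalysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize

from .traces import AnisotropyCurve

__all__ = [
    "FitResult",
    "fit_single_exponential",
    "fit_double_exponential_global",
    "kcat_from_amplitude_series",
    "kcat_fixed_offrates",
    "fit_kobs_linear",
    "rate_ratio",
]

_TIGHT = dict(ftol=1e-15, xtol=1e-15, gtol=1e-15)


@dataclass
class FitResult:
    """Fitted parameters with uncertainties and diagnostics.

    ``flags`` may contain 'degenerate', 'inactive', 'boundary',
    'identifiability', 'negative_intercept' or 'not_converged'; a fit that did
    not converge is marked non-reportable via ``reportable``.
    """

    model: str
    params: dict
    stderr: dict
    rss: float
    n: int
    converged: bool
    cov: np.ndarray | None = None
    param_names: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)
    per_curve: list[dict] = field(default_factory=list)

    @property
    def reportable(self) -> bool:
        return self.converged

    def __getitem__(self, key: str) -> float:
        return self.params[key]

    def ci95(self, key: str) -> tuple[float, float]:
        """Normal-approximation 95% confidence interval for one parameter."""
        v, e = self.params[key], self.stderr.get(key, float("nan"))
        return (v - 1.959963984540054 * e, v + 1.959963984540054 * e)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _curve_data(curve: AnisotropyCurve, weighted: bool):
    t, r, err = curve.usable()
    if weighted:
        w = 1.0 / err**2
    else:
        w = np.ones_like(r)
    return t, r, w


def _wlin(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted linear LSQ; returns (beta, cov_unscaled, rss)."""
    Xw = X * w[:, None]
    cov = np.linalg.pinv(X.T @ Xw)
    beta = cov @ (Xw.T @ y)
    resid = y - X @ beta
    return beta, cov, float(resid @ (w * resid))


def _finish(result, model: str, weighted: bool, n: int,
            per_curve=None, flags=None) -> FitResult:
    """Package an lmfit MinimizerResult."""
    names = [p for p in result.params if result.params[p].vary]
    params = {p: float(result.params[p].value) for p in result.params}
    stderr = {}
    for p in result.params:
        se = result.params[p].stderr
        stderr[p] = float(se) if se is not None else float("nan")
    converged = bool(result.success)
    flags = list(flags or [])
    if not converged:
        flags.append("not_converged")
    return FitResult(
        model=model,
        params=params,
        stderr=stderr,
        rss=float(np.sum(np.asarray(result.residual) ** 2)),
        n=n,
        converged=converged,
        cov=getattr(result, "covar", None),
        param_names=names,
        flags=flags,
        per_curve=per_curve or [],
    )


def _rate_grid(t_span: float, n: int = 12) -> np.ndarray:
    return np.geomspace(0.05 / t_span, 100.0 / t_span, n)


# ---------------------------------------------------------------------------
# single exponential
# ---------------------------------------------------------------------------

def fit_single_exponential(curve: AnisotropyCurve, weighted: bool = True) -> FitResult:
    """Fit r(t) = A exp(-k t) + r_inf.

    Requires >= 10 usable points.  Multi-start over a log-spaced rate grid
    with amplitudes profiled out, then a damped least-squares polish.  A fit
    whose decay is indistinguishable from a constant (less than one half-life
    inside the observation window, or k consistent with 0) is flagged
    'degenerate'.
    """
    t, y, w = _curve_data(curve, weighted)
    if t.size < 10:
        raise ValueError("need at least 10 usable points")
    span = t[-1] - t[0]

    best = None
    for k in _rate_grid(span):
        X = np.column_stack([np.exp(-k * (t - t[0])), np.ones_like(t)])
        beta, _, rss = _wlin(X, y, w)
        if best is None or rss < best[0]:
            best = (rss, k, beta)
    _, k0, (A0, c0) = best
    A0 = A0 * math.exp(k0 * t[0])  # undo the t-shift used for conditioning

    pars = Parameters()
    pars.add("k", value=k0, min=0.0)
    pars.add("A", value=A0)
    pars.add("r_inf", value=c0)
    sw = np.sqrt(w)

    def resid(p):
        return (p["A"] * np.exp(-p["k"] * t) + p["r_inf"] - y) * sw

    out = minimize(resid, pars, method="least_squares",
                   scale_covar=not weighted, **_TIGHT)
    res = _finish(out, "single_exponential", weighted, t.size)
    k, ke = res.params["k"], res.stderr["k"]
    A, Ae = res.params["A"], res.stderr["A"]
    scale = max(np.max(np.abs(y)), 1e-30)
    amp_null = abs(A) < 1e-10 * scale or (np.isfinite(Ae) and abs(A) <= 2 * Ae)
    if k * span < math.log(2) or (np.isfinite(ke) and ke >= k) or amp_null:
        res.flags.append("degenerate")
    return res


# ---------------------------------------------------------------------------
# double exponential (global over curves)
# ---------------------------------------------------------------------------

def _stack(curves: list[AnisotropyCurve], weighted: bool):
    data = [_curve_data(c, weighted) for c in curves]
    if any(d[0].size < 4 for d in data):
        raise ValueError("every curve needs at least 4 usable points")
    return data


def _global_linear_amplitudes(data, k1: float, k2: float, share_baseline: bool):
    """Profile out all amplitudes (and baselines) at fixed rates."""
    ncur = len(data)
    rows = sum(d[0].size for d in data)
    ncols = 2 * ncur + (1 if share_baseline else ncur)
    X = np.zeros((rows, ncols))
    y = np.empty(rows)
    w = np.empty(rows)
    pos = 0
    for i, (t, r, wi) in enumerate(data):
        sl = slice(pos, pos + t.size)
        X[sl, 2 * i] = np.exp(-k1 * t)
        X[sl, 2 * i + 1] = np.exp(-k2 * t)
        X[sl, 2 * ncur + (0 if share_baseline else i)] = 1.0
        y[sl] = r
        w[sl] = wi
        pos += t.size
    return (*_wlin(X, y, w), y, w)


def fit_double_exponential_global(
    curves: list[AnisotropyCurve] | AnisotropyCurve,
    fixed: dict | None = None,
    weighted: bool = True,
    share_baseline: bool = True,
) -> FitResult:
    """Globally fit r_i(t) = A1_i exp(-k1 t) + A2_i exp(-k2 t) + r_inf.

    Rates k1 >= k2 are shared across curves; amplitudes are per-curve and
    unconstrained in sign; the baseline is shared by default (per-curve with
    ``share_baseline=False``).  With ``fixed={'k1': .., 'k2': ..}`` only the
    linear parameters are fitted (exact weighted linear algebra).  Poorly
    separated rates (ratio < 2 with overlapping confidence intervals) are
    flagged 'identifiability'.
    """
    if isinstance(curves, AnisotropyCurve):
        curves = [curves]
    if not curves:
        raise ValueError("need at least one curve")
    data = _stack(curves, weighted)
    ncur = len(data)
    n_tot = sum(d[0].size for d in data)

    if fixed is not None:
        k1, k2 = float(fixed["k1"]), float(fixed["k2"])
        if k1 <= 0 or k2 <= 0 or k1 == k2:
            raise ValueError("fixed rates must be positive and distinct")
        if k1 < k2:
            k1, k2 = k2, k1
        beta, cov, rss, y, w = _global_linear_amplitudes(data, k1, k2, share_baseline)
        dof = n_tot - beta.size
        scale = 1.0 if weighted else (rss / dof if dof > 0 else 1.0)
        se = np.sqrt(np.clip(np.diag(cov) * scale, 0.0, None))
        params = {"k1": k1, "k2": k2}
        stderr = {"k1": 0.0, "k2": 0.0}
        per_curve = []
        for i in range(ncur):
            a1, a2 = beta[2 * i], beta[2 * i + 1]
            ib = 2 * ncur + (0 if share_baseline else i)
            per_curve.append({"A1": float(a1), "A2": float(a2),
                              "A1_err": float(se[2 * i]), "A2_err": float(se[2 * i + 1]),
                              "r_inf": float(beta[ib])})
            params[f"A1_{i}"], params[f"A2_{i}"] = float(a1), float(a2)
            stderr[f"A1_{i}"], stderr[f"A2_{i}"] = float(se[2 * i]), float(se[2 * i + 1])
        params["r_inf"] = float(beta[2 * ncur])
        stderr["r_inf"] = float(se[2 * ncur])
        return FitResult(model="double_exponential_global_fixed", params=params,
                         stderr=stderr, rss=rss, n=n_tot, converged=True,
                         param_names=list(params), per_curve=per_curve)

    # log-spaced multi-start on (k1, k2) with profiled amplitudes: the coarse
    # grid is cheap (amplitudes are linear), so sample it finely enough that
    # the best pair lands in the right basin, then refine on the profiled
    # surface before the full polish — full-parameter descent from a poor
    # start can collapse into a spurious k1 ~ k2 minimum
    from scipy.optimize import minimize as sp_minimize

    span = max(d[0][-1] - d[0][0] for d in data)
    grid = _rate_grid(span, 10)
    starts = []
    for k1 in grid:
        for k2 in grid:
            if k1 <= k2:
                continue
            _, _, rss, _, _ = _global_linear_amplitudes(data, k1, k2, share_baseline)
            starts.append((rss, k1, k2))
    starts.sort(key=lambda s: s[0])

    def profiled_rss(logs):
        k2 = math.exp(logs[0])
        k1 = k2 + math.exp(logs[1])
        return _global_linear_amplitudes(data, k1, k2, share_baseline)[2]

    # refine from several diverse starts (distinct fast rates): the lowest
    # coarse-grid point is not always in the global basin
    nm_starts, seen_k1 = [], set()
    for rss0, k1_s, k2_s in starts:
        if k1_s in seen_k1:
            continue
        seen_k1.add(k1_s)
        nm_starts.append((k1_s, k2_s))
        if len(nm_starts) == 4:
            break
    refined = []
    for k1_s, k2_s in nm_starts:
        nm = sp_minimize(profiled_rss,
                         [math.log(k2_s), math.log(max(k1_s - k2_s, 1e-12))],
                         method="Nelder-Mead",
                         options={"xatol": 1e-10, "fatol": 1e-14,
                                  "maxiter": 300})
        k2_r = math.exp(nm.x[0])
        refined.append((float(nm.fun), k2_r + math.exp(nm.x[1]), k2_r))
    refined.sort(key=lambda s: s[0])
    starts = refined + starts

    def resid(p):
        out_ = []
        for i, (t, r, wi) in enumerate(data):
            base = p["r_inf"] if share_baseline else p[f"r_inf_{i}"]
            model = (p[f"A1_{i}"] * np.exp(-p["k1"] * t)
                     + p[f"A2_{i}"] * np.exp(-p["k2"] * t) + base)
            out_.append((model - r) * np.sqrt(wi))
        return np.concatenate(out_)

    # polish the best few starts; the profiled surface can hold local minima
    out = None
    for _, k1_0, k2_0 in starts[:3]:
        beta0, _, _, _, _ = _global_linear_amplitudes(data, k1_0, k2_0,
                                                      share_baseline)
        pars = Parameters()
        pars.add("k2", value=k2_0, min=0.0)
        pars.add("dk", value=k1_0 - k2_0, min=0.0)  # k1 = k2 + dk >= k2
        pars.add("k1", expr="k2 + dk")
        for i in range(ncur):
            pars.add(f"A1_{i}", value=beta0[2 * i])
            pars.add(f"A2_{i}", value=beta0[2 * i + 1])
        if share_baseline:
            pars.add("r_inf", value=beta0[2 * ncur])
        else:
            for i in range(ncur):
                pars.add(f"r_inf_{i}", value=beta0[2 * ncur + i])
        cand = minimize(resid, pars, method="least_squares",
                        scale_covar=not weighted, **_TIGHT)
        if out is None or cand.chisqr < out.chisqr:
            out = cand
    per_curve = []
    for i in range(ncur):
        base_key = "r_inf" if share_baseline else f"r_inf_{i}"
        per_curve.append({
            "A1": float(out.params[f"A1_{i}"].value),
            "A2": float(out.params[f"A2_{i}"].value),
            "A1_err": float(out.params[f"A1_{i}"].stderr or "nan"),
            "A2_err": float(out.params[f"A2_{i}"].stderr or "nan"),
            "r_inf": float(out.params[base_key].value),
        })
    flags = []
    k1v, k2v = float(out.params["k1"].value), float(out.params["k2"].value)
    k1e = out.params["dk"].stderr or float("nan")
    k2e = out.params["k2"].stderr or float("nan")
    if k2v > 0 and k1v / k2v < 2.0:
        if not np.isfinite(k1e) or not np.isfinite(k2e) or (k1v - k2v) < 2 * math.hypot(k1e, k2e):
            flags.append("identifiability")
    return _finish(out, "double_exponential_global", weighted, n_tot,
                   per_curve=per_curve, flags=flags)


# ---------------------------------------------------------------------------
# k_cat extraction
# ---------------------------------------------------------------------------

def kcat_from_amplitude_series(
    amplitudes: dict, errors: dict | None = None
) -> FitResult:
    """Shared single-exponential fit of both decay amplitudes vs incubation time.

    ``amplitudes`` maps incubation time (s) to (A1, A2); both series are fit
    jointly to A_i(t_inc) = a_i + b_i exp(-k_cat t_inc) with a shared rate.
    Flat series (the signature of a catalytically dead enzyme) return
    k_cat = 0 with an 'inactive' flag.
    """
    if len(amplitudes) < 3:
        raise ValueError("need at least 3 incubation times")
    t = np.array(sorted(amplitudes), dtype=float)
    A1 = np.array([amplitudes[ti][0] for ti in t])
    A2 = np.array([amplitudes[ti][1] for ti in t])
    if errors is not None:
        e1 = np.array([errors[ti][0] for ti in t])
        e2 = np.array([errors[ti][1] for ti in t])
        w1, w2 = 1.0 / e1**2, 1.0 / e2**2
    else:
        w1 = np.ones_like(A1)
        w2 = np.ones_like(A2)

    scatter = max(np.ptp(A1), np.ptp(A2))
    scale = max(np.max(np.abs(A1)), np.max(np.abs(A2)), 1e-30)
    if scatter <= 1e-12 * scale:
        return FitResult(
            model="amplitude_series", n=2 * t.size, rss=0.0, converged=True,
            params={"k_cat": 0.0, "a1": float(A1[0]), "b1": 0.0,
                    "a2": float(A2[0]), "b2": 0.0},
            stderr={"k_cat": 0.0}, param_names=["k_cat"], flags=["inactive"],
        )

    span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    y = np.concatenate([A1, A2])
    w = np.concatenate([w1, w2])
    best = None
    for k in _rate_grid(span):
        e = np.exp(-k * t)
        z = np.zeros_like(t)
        X = np.block([[np.column_stack([np.ones_like(t), e]), np.column_stack([z, z])],
                      [np.column_stack([z, z]), np.column_stack([np.ones_like(t), e])]])
        beta, _, rss = _wlin(X, y, w)
        if best is None or rss < best[0]:
            best = (rss, k, beta)
    _, k0, (a1, b1, a2, b2) = best

    pars = Parameters()
    pars.add("k_cat", value=k0, min=0.0)
    for name, v in (("a1", a1), ("b1", b1), ("a2", a2), ("b2", b2)):
        pars.add(name, value=v)
    sw1, sw2 = np.sqrt(w1), np.sqrt(w2)

    def resid(p):
        e = np.exp(-p["k_cat"] * t)
        return np.concatenate([
            (p["a1"] + p["b1"] * e - A1) * sw1,
            (p["a2"] + p["b2"] * e - A2) * sw2,
        ])

    out = minimize(resid, pars, method="least_squares",
                   scale_covar=errors is None, **_TIGHT)
    res = _finish(out, "amplitude_series", errors is not None, 2 * t.size)
    k, ke = res.params["k_cat"], res.stderr["k_cat"]
    if k <= 0 or (np.isfinite(ke) and ke >= k and k * span < math.log(2)):
        res.flags.append("inactive")
    return res


def kcat_fixed_offrates(
    curve: AnisotropyCurve, k_off_S: float, k_off_P: float, weighted: bool = True
) -> FitResult:
    """Extract k_cat from one reactive decay with both off-rates fixed.

    Fits r(t) = A1 exp(-k_off_P t) + A2 exp(-(k_off_S + k_cat) t) + r_inf with
    k_cat >= 0 the only free rate.  A k_cat pinned at the zero boundary is
    flagged 'boundary'.
    """
    if not (k_off_P > k_off_S >= 0):
        raise ValueError("require k_off_P > k_off_S >= 0")
    t, y, w = _curve_data(curve, weighted)
    if t.size < 10:
        raise ValueError("need at least 10 usable points")

    def profile(kcat):
        X = np.column_stack([
            np.exp(-k_off_P * t),
            np.exp(-(k_off_S + kcat) * t),
            np.ones_like(t),
        ])
        return _wlin(X, y, w)

    span = t[-1] - t[0]
    kgrid = np.concatenate([[0.0], _rate_grid(span)])
    kgrid = kgrid[k_off_S + kgrid < k_off_P]  # slow rate stays the slow one
    best = None
    for kc in kgrid:
        beta, _, rss = profile(kc)
        if best is None or rss < best[0]:
            best = (rss, kc, beta)
    _, k0, (A1_0, A2_0, c0) = best

    pars = Parameters()
    pars.add("k_cat", value=max(k0, 1e-3 * (k_off_P - k_off_S)),
             min=0.0, max=k_off_P - k_off_S)
    pars.add("A1", value=A1_0)
    pars.add("A2", value=A2_0)
    pars.add("r_inf", value=c0)
    sw = np.sqrt(w)

    def resid(p):
        model = (p["A1"] * np.exp(-k_off_P * t)
                 + p["A2"] * np.exp(-(k_off_S + p["k_cat"]) * t) + p["r_inf"])
        return (model - y) * sw

    out = minimize(resid, pars, method="least_squares",
                   scale_covar=not weighted, **_TIGHT)
    res = _finish(out, "kcat_fixed_offrates", weighted, t.size)
    res.params["k_off_S"], res.params["k_off_P"] = k_off_S, k_off_P
    if res.params["k_cat"] <= 1e-12 * (k_off_P - k_off_S):
        res.flags.append("boundary")
    return res


# ---------------------------------------------------------------------------
# linear k_obs analysis and ratios
# ---------------------------------------------------------------------------

def fit_kobs_linear(kobs: dict) -> FitResult:
    """Weighted linear regression k_obs = k_on [E] + k_off.

    ``kobs`` maps enzyme concentration (M) to k_obs or (k_obs, err).  Slope is
    the association rate constant, intercept the dissociation rate.  A
    negative intercept is reported with a 'negative_intercept' flag, never
    clamped.
    """
    Es = np.array(sorted(kobs), dtype=float)
    if np.unique(Es).size < 2:
        raise ValueError("need at least 2 distinct enzyme concentrations")
    ks, errs = [], []
    for E in Es:
        v = kobs[E]
        if np.ndim(v) == 0:
            ks.append(float(v))
            errs.append(0.0)
        else:
            ks.append(float(v[0]))
            errs.append(float(v[1]))
    ks, errs = np.asarray(ks), np.asarray(errs)
    weighted = bool(np.all(errs > 0))
    w = 1.0 / errs**2 if weighted else np.ones_like(ks)
    X = np.column_stack([np.ones_like(Es), Es])
    beta, cov, rss = _wlin(X, ks, w)
    dof = Es.size - 2
    scale = 1.0 if weighted else (rss / dof if dof > 0 else 1.0)
    se = np.sqrt(np.clip(np.diag(cov) * scale, 0.0, None))
    flags = ["negative_intercept"] if beta[0] < 0 else []
    return FitResult(
        model="kobs_linear",
        params={"k_on": float(beta[1]), "k_off": float(beta[0])},
        stderr={"k_on": float(se[1]), "k_off": float(se[0])},
        rss=rss, n=int(Es.size), converged=True,
        cov=cov * scale, param_names=["k_off", "k_on"], flags=flags,
    )


def rate_ratio(a: tuple, b: tuple) -> tuple[float, float]:
    """Ratio a/b of two rates with first-order error propagation.

    ``a`` and ``b`` are (value, err) pairs; returns (ratio, ratio_err).
    """
    av, ae = float(a[0]), float(a[1])
    bv, be = float(b[0]), float(b[1])
    if bv <= 0:
        raise ZeroDivisionError("denominator rate must be > 0")
    ratio = av / bv
    err = abs(ratio) * math.hypot(ae / av if av != 0 else 0.0, be / bv)
    return ratio, err
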