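"""Study orchestration: config-driven simulate -> anisotropy -> fit -> thermo.

A study config (YAML/JSON, see ``examples/`` and the README) lists
experiments.  Each experiment either references trace CSV files or asks for
simulation from a true rate set; the pipeline rebins to the analysis bin
(1 s by default), converts to anisotropy, runs the fit matching the
experiment kind, and finally feeds any temperature series to the Arrhenius
stage.  Every random step logs its seed; a stage failure aborts with the
failing stage named, preserving partial output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import fitting, io, thermo
from .kinetics import RateSet, celsius_to_kelvin
from .simulate import (
    OpticalParams,
    Protocol,
    simulate_association_panel,
    simulate_incubation_series,
    simulate_polarized_trace,
)
from .traces import AnisotropyCurve, compute_anisotropy, rebin

__all__ = ["StudyConfig", "run_pipeline", "trace_to_curve",
           "analyze_association_panel", "analyze_incubation_series"]

log = logging.getLogger("anisokin")


@dataclass
class StudyConfig:
    """Validated study configuration.

    ``experiments`` entries carry: name, kind (association | dissociation |
    reactive_fixed_offrates | incubation_series), and either ``traces``
    (file paths) or ``rates`` (simulate).  Temperatures are given in Celsius
    in configs, as bench records do, and converted internally.
    """

    experiments: list[dict]
    optics: OpticalParams = field(default_factory=OpticalParams)
    seed: int = 0
    analysis_bin: float = 1.0
    weighted: bool = True
    share_baseline: bool = True
    arrhenius: dict | None = None
    output_dir: str | None = None
    base_dir: Path = field(default_factory=Path)

    _KINDS = ("association", "dissociation", "reactive_fixed_offrates",
              "incubation_series")

    @classmethod
    def from_dict(cls, cfg: dict, base_dir=".") -> "StudyConfig":
        base = Path(base_dir)
        optics = OpticalParams(**cfg.get("optics", {}))
        exps = cfg.get("experiments", [])
        if not exps:
            raise ValueError("config defines no experiments")
        for exp in exps:
            if "name" not in exp or "kind" not in exp:
                raise ValueError("every experiment needs 'name' and 'kind'")
            if exp["kind"] not in cls._KINDS:
                raise ValueError(
                    f"experiment {exp['name']!r}: unknown kind {exp['kind']!r}"
                )
            if "traces" in exp:
                for f in np.atleast_1d(exp["traces"]):
                    if not (base / str(f)).exists():
                        raise FileNotFoundError(
                            f"experiment {exp['name']!r}: trace file {f} not found"
                        )
            elif "rates" not in exp:
                raise ValueError(
                    f"experiment {exp['name']!r}: needs 'traces' or 'rates'"
                )
            tc = exp.get("temperature_c", 22.0)
            if celsius_to_kelvin(tc) <= 0:
                raise ValueError(f"experiment {exp['name']!r}: temperature below 0 K")
        return cls(
            experiments=exps,
            optics=optics,
            seed=int(cfg.get("seed", 0)),
            analysis_bin=float(cfg.get("analysis_bin", 1.0)),
            weighted=bool(cfg.get("weighted", True)),
            share_baseline=bool(cfg.get("share_baseline", True)),
            arrhenius=cfg.get("arrhenius"),
            output_dir=cfg.get("output_dir"),
            base_dir=base,
        )

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        return cls.from_dict(io.load_config(path), base_dir=Path(path).parent)


def trace_to_curve(trace, analysis_bin: float = 1.0,
                   g_factor: float = 1.0) -> AnisotropyCurve:
    """Rebin a raw trace and convert to anisotropy (the standard reduction)."""
    return compute_anisotropy(rebin(trace, analysis_bin), g_factor=g_factor)


def analyze_association_panel(curves: dict, weighted: bool = True) -> fitting.FitResult:
    """Fit each association curve to a single exponential and regress
    k_obs on enzyme concentration.  ``curves`` maps [E] (M) -> curve."""
    kobs = {}
    for E, curve in curves.items():
        res = fitting.fit_single_exponential(curve, weighted=weighted)
        kobs[E] = (res["k"], res.stderr["k"])
    return fitting.fit_kobs_linear(kobs)


def analyze_incubation_series(curves: dict, weighted: bool = True,
                              share_baseline: bool = True,
                              fixed: dict | None = None) -> fitting.FitResult:
    """Global shared-rate double-exponential fit over incubation times, then
    the shared single-exponential amplitude fit that yields k_cat.

    ``curves`` maps incubation time (s) -> curve.  The fast-decay amplitude
    (A1) and slow-decay amplitude (A2) per curve are taken from the global
    fit; their dependence on incubation time is single-exponential with rate
    k_cat.
    """
    t_incs = sorted(curves)
    glob = fitting.fit_double_exponential_global(
        [curves[t] for t in t_incs], weighted=weighted,
        share_baseline=share_baseline, fixed=fixed,
    )
    amplitudes = {t: (pc["A1"], pc["A2"]) for t, pc in zip(t_incs, glob.per_curve)}
    errors = None
    if all(np.isfinite(pc.get("A1_err", np.nan)) and pc.get("A1_err", 0) > 0
           and pc.get("A2_err", 0) > 0 for pc in glob.per_curve):
        errors = {t: (pc["A1_err"], pc["A2_err"])
                  for t, pc in zip(t_incs, glob.per_curve)}
    res = fitting.kcat_from_amplitude_series(amplitudes, errors=errors)
    res.params["k1"], res.params["k2"] = glob.params["k1"], glob.params["k2"]
    return res


def _simulate_experiment(exp: dict, cfg: StudyConfig, seed: int):
    """Return {key: trace} for one simulated experiment."""
    rates = RateSet(temperature=celsius_to_kelvin(exp.get("temperature_c", 22.0)),
                    **exp["rates"])
    kind = exp["kind"]
    log.info("simulating %r (kind=%s, seed=%d)", exp["name"], kind, seed)
    if kind == "association":
        concs = [float(E) for E in exp["enzyme_concs"]]
        traces = simulate_association_panel(
            rates, cfg.optics, concs, seed,
            duration=float(exp.get("duration", 600.0)),
            dead_time=float(exp.get("dead_time", 30.0)))
        return dict(zip(concs, traces))
    if kind == "incubation_series":
        t_incs = [float(t) for t in exp["incubation_times"]]
        base = Protocol.reactive(0.0, duration=float(exp.get("duration", 3000.0)),
                                 temperature=rates.temperature)
        return dict(zip(t_incs, simulate_incubation_series(
            base, rates, cfg.optics, t_incs, seed)))
    if kind == "reactive_fixed_offrates":
        proto = Protocol.reactive(float(exp.get("incubation_time", 30.0)),
                                  duration=float(exp.get("duration", 3000.0)),
                                  temperature=rates.temperature)
    else:  # dissociation
        proto = Protocol.dissociation(
            duration=float(exp.get("duration", 3000.0)),
            initial_es=float(exp.get("initial_es", 1.0)),
            initial_ep=float(exp.get("initial_ep", 0.0)),
            temperature=rates.temperature)
    return {0: simulate_polarized_trace(proto, rates, cfg.optics, seed)}


def _load_experiment(exp: dict, cfg: StudyConfig):
    files = [str(f) for f in np.atleast_1d(exp["traces"])]
    keys = exp.get("trace_keys")
    if keys is None:
        keys = (exp.get("enzyme_concs") or exp.get("incubation_times")
                or list(range(len(files))))
    return {float(k): io.read_trace_csv(cfg.base_dir / f)
            for k, f in zip(keys, files)}


def _fit_experiment(exp: dict, curves: dict, cfg: StudyConfig) -> fitting.FitResult:
    kind = exp["kind"]
    if kind == "association":
        return analyze_association_panel(curves, weighted=cfg.weighted)
    if kind == "incubation_series":
        return analyze_incubation_series(curves, weighted=cfg.weighted,
                                         share_baseline=cfg.share_baseline)
    curve = next(iter(curves.values()))
    if kind == "reactive_fixed_offrates":
        return fitting.kcat_fixed_offrates(
            curve, float(exp["k_off_S"]), float(exp["k_off_P"]),
            weighted=cfg.weighted)
    return fitting.fit_single_exponential(curve, weighted=cfg.weighted)


_REPORT_KEY = {"association": "k_on", "dissociation": "k",
               "reactive_fixed_offrates": "k_cat", "incubation_series": "k_cat"}


def run_pipeline(config: StudyConfig | dict) -> dict:
    """Execute the full study and return (and optionally write) the report.

    Report structure: one entry per experiment with the fitted rates, their
    standard errors and flags, plus an ``arrhenius`` entry when the config
    requests temperature analysis over named experiments.
    """
    if isinstance(config, dict):
        config = StudyConfig.from_dict(config)
    report: dict = {"seed": config.seed, "experiments": {}}
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def _abort(stage: str, exc: Exception):
        if out_dir:
            (out_dir / "report.json").write_text(json.dumps(report, indent=1))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    seeds = np.random.SeedSequence(config.seed).spawn(len(config.experiments))
    for exp, ss in zip(config.experiments, seeds):
        name = exp["name"]
        seed = int(ss.generate_state(1)[0] % (2**31))
        try:
            if "traces" in exp:
                traces = _load_experiment(exp, config)
            else:
                traces = _simulate_experiment(exp, config, seed)
        except Exception as exc:  # noqa: BLE001 - stage boundary
            _abort(f"{name}/simulate-or-load", exc)
        try:
            curves = {k: trace_to_curve(v, config.analysis_bin,
                                        config.optics.g_factor)
                      for k, v in traces.items()}
        except Exception as exc:  # noqa: BLE001
            _abort(f"{name}/anisotropy", exc)
        try:
            res = _fit_experiment(exp, curves, config)
        except Exception as exc:  # noqa: BLE001
            _abort(f"{name}/fit", exc)
        key = _REPORT_KEY[exp["kind"]]
        log.info("experiment %r: %s = %.4g (seed %d)", name, key,
                 res.params[key], seed)
        report["experiments"][name] = {
            "kind": exp["kind"],
            "seed": seed,
            "temperature_c": exp.get("temperature_c", 22.0),
            "rate": res.params[key],
            "rate_name": key,
            "rate_err": res.stderr.get(key),
            "params": res.params,
            "stderr": res.stderr,
            "flags": res.flags,
            "converged": res.converged,
        }
        if out_dir:
            io.write_fit_result_json(res, out_dir / f"{name}.fit.json")

    if config.arrhenius:
        try:
            names = config.arrhenius["experiments"]
            table = {}
            for n in names:
                e = report["experiments"][n]
                T = celsius_to_kelvin(e["temperature_c"])
                err = e["rate_err"] if e["rate_err"] else 0.0
                table[T] = (e["rate"], err)
            fit = thermo.fit_arrhenius(
                table, weighted=bool(config.arrhenius.get("weighted", True)))
            entry = {"Ea_kcal_mol": fit.Ea, "Ea_err": fit.Ea_err, "A": fit.A,
                     "T_range_K": list(fit.T_range)}
            if config.arrhenius.get("eyring"):
                T_eval = celsius_to_kelvin(
                    float(config.arrhenius.get("eyring_temperature_c", 22.0)))
                ey = thermo.eyring_decompose(
                    fit, T_eval,
                    molecularity=config.arrhenius.get("molecularity", "uni"))
                entry["eyring"] = {"dH_a": ey.dH_a, "dS_a": ey.dS_a,
                                   "dG_a": ey.dG_a, "T": ey.T}
            report["arrhenius"] = entry
        except Exception as exc:  # noqa: BLE001
            _abort("arrhenius", exc)

    if out_dir:
        (out_dir / "report.json").write_text(json.dumps(report, indent=1))
    return report
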