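"""Scenario orchestration: single runs, PVR x dose sweeps, registry calibration.

A scenario run is fully deterministic: resolve the configuration, apply the
resistance ratios and the dobutamine dose response to the registry, build
the topology, integrate to the limit cycle, average the beat, solve the
oxygen mixing system, and extract the PV loop and function indices.

Results are memoized by a hash of the resolved configuration, so repeated
runs of an identical scenario (including sweep cells) return identical
outputs.  A volume warm-start cache reuses the most recent converged state
for neighbouring scenarios, which shortens the beat iteration considerably
during sweeps and calibration.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, asdict, replace, field
from pathlib import Path
from typing import Any, Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize

from . import cardiac_metrics, hemodynamics, oxygen_transport, pharmacology
from .cardiac_metrics import CardiacFunctionIndices, PVLoop
from .hemodynamics import BeatSolution, MeanHemodynamics
from .oxygen_transport import FickParameters, OxygenState
from .parameters import (PatientParameters, Registry, ResolvedScenario,
                         ScenarioConfig, default_registry, resolve)
from .vascular_network import Topology, build_fontan_topology

logger = logging.getLogger("fontansim")

__all__ = [
    "ScenarioResult",
    "SweepTable",
    "CalibrationTarget",
    "CalibrationResult",
    "CalibrationError",
    "run_scenario",
    "run_sweep",
    "calibrate_registry",
    "generate_fixtures",
    "COLLATERAL_CONFIGS",
    "clear_caches",
]

#: named collateral configurations (flag overrides on a base scenario)
COLLATERAL_CONFIGS: Mapping[str, dict[str, bool]] = {
    "none": {"vvc_enabled": False, "apc_enabled": False},
    "vvc": {"vvc_enabled": True, "apc_enabled": False},
    "vvc_apc": {"vvc_enabled": True, "apc_enabled": True},
    "apc": {"vvc_enabled": False, "apc_enabled": True},  # extrapolation config
}

_result_cache: dict[str, "ScenarioResult"] = {}
_warm_start: dict[tuple[str, ...], np.ndarray] = {}


def clear_caches() -> None:
    _result_cache.clear()
    _warm_start.clear()


@dataclass
class ScenarioResult:
    """Everything one scenario produces, plus convergence diagnostics."""

    config: ScenarioConfig
    patient: PatientParameters
    registry_version: str
    config_hash: str
    mean: MeanHemodynamics
    oxygen: OxygenState
    indices: CardiacFunctionIndices
    loop: PVLoop
    solution: BeatSolution
    convergence: dict[str, float]

    def summary(self) -> pd.Series:
        data = pd.Series({
            "sao2": self.oxygen.sao2, "svo2": self.oxygen.svo2,
            "co": self.mean.co, "net_co": self.mean.net_co,
            "coi": self.oxygen.coi,
            "map": self.mean.node_pressures.get("aorta", np.nan),
            "ef": self.indices.ef, "ees_over_ea": self.indices.ees_over_ea,
            "sw_over_pva": self.indices.sw_over_pva,
            "edv": self.loop.edv, "esv": self.loop.esv,
            "beats": self.convergence["beats"],
        })
        return data


def _scenario_fingerprint(config: ScenarioConfig, patient: PatientParameters,
                          registry: Registry) -> str:
    doc = {
        "config": asdict(config),
        "patient": asdict(patient),
        "registry": registry.to_dict(),
    }
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()


def run_scenario(source: Any = None, *, registry: Optional[Registry] = None,
                 patient: Optional[PatientParameters] = None,
                 use_cache: bool = True) -> ScenarioResult:
    """Run one scenario end to end.

    ``source`` is anything :func:`fontansim.parameters.load_config` accepts
    (None for defaults, a mapping, YAML text, a path) or a
    :class:`ScenarioConfig`.  ``registry``/``patient`` override the resolved
    ones.  Deterministic: identical inputs give identical outputs.
    """
    resolved = resolve(source)
    config = resolved.config
    registry = registry if registry is not None else resolved.registry
    patient = patient if patient is not None else resolved.patient

    key = _scenario_fingerprint(config, patient, registry)
    if use_cache and key in _result_cache:
        return copy.deepcopy(_result_cache[key])

    # fold ratios and dose response into the registry, then rebuild patient
    reg = pharmacology.scale_resistances(registry, config.svr_ratio, config.pvr_ratio)
    reg = pharmacology.apply_dobutamine(reg, config.dobutamine_dose)
    patient_run = PatientParameters(
        bsa=patient.bsa, hb=patient.hb,
        heart_rate=patient.heart_rate * reg["patient.heart_rate"]
        / registry["patient.heart_rate"],
        vo2i_rest=patient.vo2i_rest * reg["patient.vo2i_rest"]
        / registry["patient.vo2i_rest"],
    )

    # ratios already folded into the aggregates above
    build_config = replace(config, svr_ratio=1.0, pvr_ratio=1.0,
                           allow_ratio_override=True)
    topology = build_fontan_topology(build_config, reg)
    sim = reg["simulation"]

    # Warm-start from the last converged state with the same node set, but
    # rescale its volumes to this topology's nominal total: total blood
    # volume is a conserved quantity of the closed loop and selects the
    # limit cycle, so it must come from the scenario itself.
    warm_key = topology.node_names
    init = _warm_start.get(warm_key)
    if init is not None:
        init = init.copy()
        n = len(topology.node_names)
        nominal = hemodynamics.nominal_total_volume(topology, patient_run)
        init[:n] *= nominal / init[:n].sum()
    try:
        solution = hemodynamics.run_to_limit_cycle(
            topology, patient_run, init=init,
            sample_dt=float(sim["sample_dt"]), rtol=float(sim["rtol"]),
            atol=float(sim["atol"]), cycle_tol=float(sim["cycle_tol"]),
            max_beats=int(sim["max_beats"]))
    except hemodynamics.ConvergenceError:
        if init is None:
            raise
        solution = hemodynamics.run_to_limit_cycle(
            topology, patient_run, init=None,
            sample_dt=float(sim["sample_dt"]), rtol=float(sim["rtol"]),
            atol=float(sim["atol"]), cycle_tol=float(sim["cycle_tol"]),
            max_beats=int(sim["max_beats"]))
    _warm_start[warm_key] = solution.states[-1].copy()

    mean = hemodynamics.beat_averages(solution)
    fick = FickParameters(
        hb=patient_run.hb, vo2i=patient_run.vo2i_rest,
        pao2=float(reg["oxygen.pao2"]), pvo2=float(reg["oxygen.pvo2"]),
        pulmonary_end_capillary_saturation=
        float(reg["oxygen.pulmonary_end_capillary_saturation"]))
    try:
        oxygen = oxygen_transport.solve_saturations(
            mean, topology, fick, patient_run,
            config.initial_sao2, config.initial_svo2)
    except oxygen_transport.InfeasibleVO2Error as exc:
        raise oxygen_transport.InfeasibleVO2Error(fick.vo2i, exc.vo2i_max) from exc

    loop = cardiac_metrics.extract_pv_loop(solution)
    indices = cardiac_metrics.compute_indices(
        loop, topology.node("ventricle").chamber)

    result = ScenarioResult(
        config=config, patient=patient_run, registry_version=registry.version,
        config_hash=key, mean=mean, oxygen=oxygen, indices=indices, loop=loop,
        solution=solution,
        convergence={"beats": solution.beats_to_convergence,
                     "residual": solution.residual,
                     "volume_drift": solution.volume_drift})
    logger.info("scenario %s: beats=%d sao2=%.1f svo2=%.1f co=%.2f net_co=%.2f",
                key[:10], solution.beats_to_convergence, oxygen.sao2, oxygen.svo2,
                mean.co, mean.net_co)
    if use_cache:
        _result_cache[key] = copy.deepcopy(result)
    return result


@dataclass
class SweepTable:
    """Scalar outputs for every (collateral configuration, pvr_ratio, dose)
    grid point; failed cells carry their error message and NaN outputs."""

    table: pd.DataFrame

    def row(self, collaterals: str, pvr_ratio: float, dose: float) -> pd.Series:
        t = self.table
        mask = ((t.collaterals == collaterals)
                & np.isclose(t.pvr_ratio, pvr_ratio)
                & np.isclose(t.dose, dose))
        return t[mask].iloc[0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_sweep(base: Any = None, pvr_ratios: Sequence[float] = (1.0,),
              doses: Sequence[float] = (0.0,),
              collateral_configs: Sequence[str] = ("none", "vvc", "vvc_apc"), *,
              registry: Optional[Registry] = None) -> SweepTable:
    """Run the full scenario grid; each cell equals its standalone run."""
    if not len(pvr_ratios) or not len(doses) or not len(collateral_configs):
        raise ValueError("sweep grids must be non-empty")
    resolved = resolve(base)
    rows = []
    for name in collateral_configs:
        flags = COLLATERAL_CONFIGS[name]
        for dose in doses:
            for ratio in sorted(pvr_ratios):
                config = replace(resolved.config, pvr_ratio=float(ratio),
                                 dobutamine_dose=float(dose), **flags)
                row: dict[str, Any] = {"collaterals": name, "pvr_ratio": float(ratio),
                                       "dose": float(dose), "error": ""}
                try:
                    res = run_scenario(ResolvedScenario(config, resolved.patient,
                                                        resolved.registry),
                                       registry=registry)
                    row.update(res.summary().to_dict())
                except Exception as exc:  # record and continue
                    row["error"] = f"{type(exc).__name__}: {exc}"
                rows.append(row)
    return SweepTable(table=pd.DataFrame(rows))


# -- calibration -------------------------------------------------------------


class CalibrationError(RuntimeError):
    """Calibration finished above the acceptance threshold; carries the report."""

    def __init__(self, message: str, result: "CalibrationResult"):
        super().__init__(message)
        self.result = result


@dataclass(frozen=True)
class CalibrationTarget:
    """One named scalar to reproduce: the scenario to run, the observable
    ('sao2', 'svo2', 'co', 'net_co', ...) and its target value/tolerance."""

    name: str
    config: ScenarioConfig
    observable: str
    value: float
    tolerance: float = 2.0


@dataclass
class CalibrationResult:
    registry: Registry
    residuals: dict[str, float]
    predictions: dict[str, float]
    n_evaluations: int
    success: bool

    def report(self) -> pd.DataFrame:
        rows = [{"target": k, "predicted": self.predictions[k],
                 "residual": v} for k, v in self.residuals.items()]
        return pd.DataFrame(rows)


def _observe(result: ScenarioResult, observable: str) -> float:
    if observable in ("sao2", "svo2", "coi"):
        return float(getattr(result.oxygen, observable))
    if observable in ("co", "net_co"):
        return float(getattr(result.mean, observable))
    return float(getattr(result.indices, observable))


def calibrate_registry(targets: Sequence[CalibrationTarget],
                       free_parameters: Mapping[str, tuple[float, float]],
                       registry: Optional[Registry] = None, *,
                       patient: Optional[PatientParameters] = None,
                       max_evaluations: int = 200,
                       residual_threshold: Optional[float] = None
                       ) -> CalibrationResult:
    """Fit registry free parameters to named scalar targets.

    ``free_parameters`` maps dotted registry paths to finite (lo, hi) bounds.
    Minimizes the sum of squared relative residuals with a bounded
    derivative-free search (Powell), starting from the current registry
    values.  If the starting registry already satisfies every target's
    tolerance the registry is returned unchanged with zero iterations.
    Raises :class:`CalibrationError` if any residual ends above its target
    tolerance (no silent acceptance).
    """
    if len(free_parameters) > len(targets):
        raise ValueError("need at least as many targets as free parameters")
    registry = registry if registry is not None else default_registry()
    paths = list(free_parameters)
    bounds = [free_parameters[p] for p in paths]
    for path, (lo, hi) in free_parameters.items():
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"{path}: bounds must be finite with lo < hi")
    x0 = np.array([float(registry[p]) for p in paths])

    n_eval = 0

    def predictions(x: np.ndarray) -> dict[str, float]:
        nonlocal n_eval
        n_eval += 1
        reg = registry.updated({p: float(v) for p, v in zip(paths, x)})
        out = {}
        for tgt in targets:
            res = run_scenario(tgt.config, registry=reg, patient=patient)
            out[tgt.name] = _observe(res, tgt.observable)
        return out

    def pack(preds: Mapping[str, float]):
        resid = {t.name: preds[t.name] - t.value for t in targets}
        ok = all(abs(resid[t.name]) <= t.tolerance for t in targets)
        return resid, ok

    preds0 = predictions(x0)
    resid0, ok0 = pack(preds0)
    if ok0:
        return CalibrationResult(registry=registry, residuals=resid0,
                                 predictions=preds0, n_evaluations=0, success=True)

    def objective(x: np.ndarray) -> float:
        preds = predictions(np.asarray(x))
        return float(sum(((preds[t.name] - t.value) / max(abs(t.value), 1e-9)) ** 2
                         for t in targets))

    opt = optimize.minimize(objective, x0, method="Powell",
                            bounds=bounds,
                            options={"maxfev": max_evaluations, "xtol": 1e-3,
                                     "ftol": 1e-6})
    x_best = np.clip(opt.x, [b[0] for b in bounds], [b[1] for b in bounds])
    preds = predictions(x_best)
    resid, ok = pack(preds)
    reg_out = registry.updated({p: float(v) for p, v in zip(paths, x_best)})
    result = CalibrationResult(registry=reg_out, residuals=resid,
                               predictions=preds, n_evaluations=n_eval, success=ok)
    if not ok:
        worst = max(resid, key=lambda k: abs(resid[k]))
        raise CalibrationError(
            f"calibration residual above threshold for {worst!r}: "
            f"{resid[worst]:+.3f}", result)
    return result


# -- fixtures ----------------------------------------------------------------


def generate_fixtures(kind: str, out_dir) -> list[Path]:
    """Write deterministic fixture inputs with analytically computed expected
    outputs.  Kinds: rc_loop, two_node_mixing, rectangle_pv,
    reference_scenarios."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if kind == "rc_loop":
        ra, rb, c1, c2 = 1.0, 2.0, 1.5, 3.0
        rate = (1.0 / ra + 1.0 / rb) * (1.0 / c1 + 1.0 / c2)
        doc = {
            "description": "two-compartment resistive loop; the pressure "
                           "difference decays as exp(-t/tau)",
            "compartments": {"c1": {"C": c1, "v0": 0.0, "p0": 20.0},
                             "c2": {"C": c2, "v0": 0.0, "p0": 5.0}},
            "edges": {"a": {"source": "c1", "target": "c2", "R": ra},
                      "b": {"source": "c2", "target": "c1", "R": rb}},
            "expected": {"decay_rate": rate, "tau": 1.0 / rate,
                         "equilibrium_pressure":
                             (c1 * 20.0 + c2 * 5.0) / (c1 + c2)},
        }
        path = out / "rc_loop.yaml"
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
        written.append(path)
    elif kind == "two_node_mixing":
        s_cap, f, drop_sat = 98.0, 0.1, 34.0
        # joint solution of the pulmonary-vein mixing and the Fick venous side
        sao2 = ((1 - f) * s_cap - f * drop_sat) / (1 - f)
        doc = {
            "description": "single VVC carrying a fraction f of pulmonary "
                           "venous inflow; closed-form two-equation solution",
            "inputs": {"pulmonary_end_capillary_saturation": s_cap,
                       "vvc_fraction": f, "arteriovenous_sat_drop": drop_sat},
            "expected": {"sao2": sao2, "svo2": sao2 - drop_sat},
        }
        path = out / "two_node_mixing.yaml"
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
        written.append(path)
    elif kind == "rectangle_pv":
        v = [50.0, 120.0, 120.0, 50.0]
        p = [90.0, 90.0, 8.0, 8.0]
        df = pd.DataFrame({"volume": v, "pressure": p})
        path = out / "rectangle_pv.csv"
        df.to_csv(path, index=False)
        meta = {"expected": {"edv": 120.0, "esv": 50.0,
                             "ef_percent": 100.0 * 70.0 / 120.0,
                             "sw": 70.0 * 82.0}}
        mpath = out / "rectangle_pv.yaml"
        mpath.write_text(yaml.safe_dump(meta, sort_keys=False))
        written += [path, mpath]
    elif kind == "reference_scenarios":
        for name, flags in COLLATERAL_CONFIGS.items():
            doc = {"scenario": dict({"pvr_ratio": 1.0, "dobutamine_dose": 0.0},
                                    **flags)}
            path = out / f"scenario_{name}.yaml"
            path.write_text(yaml.safe_dump(doc, sort_keys=False))
            written.append(path)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written
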