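"""Patient constants, the calibrated default parameter registry, and scenario configuration.

All hemodynamic quantities use the mmHg / mL / s unit system; oxygen
quantities use mL O2/dL (contents), % (saturations) and mL/min/m2
(consumption index).

The registry bundles every model constant that is not a per-scenario choice:
Windkessel compartment elements, chamber elastances, valve laws, shunt
conductances, the oxygen operating point and the dobutamine dose-response
table.  It is versioned and treated as immutable; operations that modify
parameters (dose response, resistance scaling) return updated copies.
"""

from __future__ import annotations

import copy
import io
import logging
import os
from dataclasses import dataclass, asdict
from typing import Any, Iterator, Mapping, NamedTuple

import yaml

logger = logging.getLogger("fontansim")

__all__ = [
    "ConfigError",
    "PatientParameters",
    "ScenarioConfig",
    "Registry",
    "ResolvedScenario",
    "default_registry",
    "load_config",
    "resolve",
    "serialize",
]


class ConfigError(ValueError):
    """A configuration document failed validation; the message names the key."""


def _require(cond: bool, key: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{key}: {msg}")


@dataclass(frozen=True)
class PatientParameters:
    """Patient-level constants.

    bsa: body surface area (m2); hb: hemoglobin (g/dL); heart_rate
    (beats/min); vo2i_rest: resting oxygen consumption index (mL/min/m2).
    """

    bsa: float = 1.63
    hb: float = 15.0
    heart_rate: float = 80.0
    vo2i_rest: float = 125.0

    def __post_init__(self) -> None:
        _require(self.bsa > 0, "bsa", "body surface area must be positive")
        _require(self.hb > 0, "hb", "hemoglobin must be positive")
        _require(
            30.0 <= self.heart_rate <= 220.0,
            "heart_rate",
            f"must lie in [30, 220] beats/min, got {self.heart_rate}",
        )
        _require(self.vo2i_rest > 0, "vo2i_rest", "resting VO2 index must be positive")

    @property
    def period(self) -> float:
        """Cardiac period (s)."""
        return 60.0 / self.heart_rate


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulated condition: resistances, collateral switches, drug dose.

    ``svr_baseline``/``pvr_baseline`` are the total systemic and pulmonary
    vascular resistances (mmHg.s/mL); ``svr_ratio``/``pvr_ratio`` are the
    dimensionless magnification ratios applied on top of the baselines.
    Ratios outside [0.6, 1.6] require ``allow_ratio_override``.
    ``initial_sao2``/``initial_svo2`` seed the oxygen fixed-point iteration.
    """

    svr_baseline: float = 0.9
    pvr_baseline: float = 0.05
    svr_ratio: float = 1.0
    pvr_ratio: float = 1.0
    dobutamine_dose: float = 0.0
    vvc_enabled: bool = False
    apc_enabled: bool = False
    fenestration_enabled: bool = True
    initial_sao2: float = 97.0
    initial_svo2: float = 60.0
    allow_ratio_override: bool = False

    def __post_init__(self) -> None:
        _require(self.pvr_baseline > 0, "pvr_baseline", "must be positive")
        _require(
            self.svr_baseline > self.pvr_baseline,
            "svr_baseline",
            "systemic resistance must exceed pulmonary resistance",
        )
        for key in ("svr_ratio", "pvr_ratio"):
            value = getattr(self, key)
            _require(value > 0, key, "must be positive")
            if not self.allow_ratio_override:
                _require(
                    0.6 <= value <= 1.6,
                    key,
                    f"must lie in [0.6, 1.6] unless allow_ratio_override is set, got {value}",
                )
        _require(self.dobutamine_dose >= 0, "dobutamine_dose", "dose must be non-negative")
        for key in ("initial_sao2", "initial_svo2"):
            value = getattr(self, key)
            _require(0 < value <= 100, key, f"saturation must lie in (0, 100], got {value}")


class Registry(Mapping):
    """Immutable, versioned mapping of model parameters.

    Keys are dotted paths into a nested document, e.g. ``registry["svr"]`` or
    ``registry["chambers.ventricle.e_max"]``.  ``updated`` returns a new
    registry with the given dotted paths replaced.
    """

    def __init__(self, data: Mapping[str, Any], version: str) -> None:
        self._data = copy.deepcopy(dict(data))
        self._version = str(version)

    @property
    def version(self) -> str:
        return self._version

    def __getitem__(self, path: str) -> Any:
        node: Any = self._data
        for part in str(path).split("."):
            try:
                node = node[part]
            except (KeyError, TypeError):
                raise KeyError(path) from None
        if isinstance(node, dict):
            return copy.deepcopy(node)
        return node

    def __iter__(self) -> Iterator[str]:
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Registry)
            and other._version == self._version
            and other._data == self._data
        )

    def __repr__(self) -> str:
        return f"Registry(version={self._version!r}, sections={sorted(self._data)})"

    def to_dict(self) -> dict[str, Any]:
        doc = copy.deepcopy(self._data)
        doc["version"] = self._version
        return doc

    def updated(self, changes: Mapping[str, Any]) -> "Registry":
        """Return a copy with dotted-path keys replaced by new values."""
        data = copy.deepcopy(self._data)
        for path, value in changes.items():
            node = data
            parts = str(path).split(".")
            for part in parts[:-1]:
                if part not in node or not isinstance(node[part], dict):
                    node[part] = {}
                node = node[part]
            node[parts[-1]] = value
        return Registry(data, self._version)


# Calibrated default parameter set.  Compartment R is the resistance of the
# compartment's outflow toward the next compartment; bed resistances and the
# pulmonary branch resistances are derived from the svr/pvr aggregates at
# topology-build time.  The numerical values were fixed by calibrating the
# closed-loop model against its reference operating points (see docs/methods.md).
_DEFAULT_REGISTRY_DATA: dict[str, Any] = {
    "patient": {"bsa": 1.63, "hb": 15.0, "heart_rate": 80.0, "vo2i_rest": 125.0},
    # Aggregate vascular resistances (mmHg.s/mL)
    "svr": 0.9,
    "pvr": 0.05,
    # Parallel systemic beds: fraction of total systemic conductance and the
    # venous node each one drains to.  Fractions sum to 1.
    "beds": {
        "upper_body": {"fraction": 0.30, "drains_to": "svc_veins"},
        "abdominal_organs": {"fraction": 0.27, "drains_to": "ivc_veins"},
        "kidneys": {"fraction": 0.15, "drains_to": "ivc_veins"},
        "lower_extremities": {"fraction": 0.24, "drains_to": "ivc_veins"},
        "coronary": {"fraction": 0.04, "drains_to": "atrium", "r_multiplier": 1.0},
    },
    # Windkessel compartments: R is the outflow resistance (mmHg.s/mL),
    # C compliance (mL/mmHg), L outflow inertance (mmHg.s2/mL), v0
    # unstressed volume (mL).
    "compartments": {
        "aorta": {"R": 0.0, "C": 0.9, "L": 0.0, "v0": 30.0},
        "svc_veins": {"R": 0.02, "C": 4.0, "L": 0.0, "v0": 60.0},
        "ivc_veins": {"R": 0.012, "C": 17.782, "L": 0.0, "v0": 180.0},
        "conduit": {"R": 0.01, "C": 0.4, "L": 0.0, "v0": 15.0},
        "pulmonary_arteries": {"R": 0.0, "C": 1.2, "L": 0.0, "v0": 25.0},
        "pulmonary_veins": {"R": 0.0, "C": 6.0, "L": 0.0, "v0": 60.0},
    },
    # Split of the pulmonary aggregate resistance between the two parallel
    # arterial branches and the venous segment; both scale with pvr.
    "pulmonary_split": {"arterial_fraction": 0.84, "venous_fraction": 0.16},
    # Time-varying elastance chambers (double-Hill activation).
    "chambers": {
        "ventricle": {
            "e_max": 2.2,
            "e_min": 0.1577,
            "v0": 8.0,
            "viscoelastic_coefficient": 0.001,
            "m1": 1.9,
            "m2": 21.9,
            "tau1_fraction": 0.269,
            "tau2_fraction": 0.452,
            "activation_offset_fraction": 0.0,
        },
        "atrium": {
            "e_max": 0.25,
            "e_min": 0.13,
            "v0": 3.0,
            "viscoelastic_coefficient": 0.0003,
            "m1": 1.9,
            "m2": 13.0,
            "tau1_fraction": 0.11,
            "tau2_fraction": 0.18,
            "activation_offset_fraction": 0.85,
        },
    },
    "valves": {
        "aortic": {"forward_resistance": 0.012, "leak_conductance": 0.0, "smoothing": 0.02},
        "mitral": {"forward_resistance": 0.008, "leak_conductance": 0.0, "smoothing": 0.02},
    },
    # Collateral/fenestration conductances (mL/s/mmHg); exponent 1 is a
    # linear conductance, <1 gives orifice-like flow.
    "shunts": {
        "fenestration": {
            "conductance": 0.2748,
            "exponent": 1.0,
            "source": "conduit",
            "target": "atrium",
        },
        "vvc": {
            "conductance": 1.8583,
            "exponent": 1.0,
            "source": "ivc_veins",
            "target": "pulmonary_veins",
        },
        "apc": {
            "conductance": 0.2346,
            "exponent": 1.0,
            "source": "aorta",
            "target": "pulmonary_arteries",
        },
    },
    "oxygen": {
        "pulmonary_end_capillary_saturation": 98.0,
        "pao2": 100.0,
        "pvo2": 40.0,
    },
    # Dobutamine dose-response anchors; linear interpolation in between.
    "dobutamine": {
        "doses": [0.0, 5.0, 10.0],
        "e_max": [1.0, 1.2039, 1.4077],
        "svr": [1.0, 0.995, 0.99],
        "heart_rate": [1.0, 1.0, 1.0],
        "vo2i": [1.0, 1.0, 1.0],
        "coronary_r": [1.0, 0.5965, 0.1929],
    },
    # Node-class pressure guesses (mmHg) used to distribute the initial blood
    # volume over compliances; together with the compliances these set the
    # conserved total volume of the closed loop.
    "initial_pressures": {
        "arterial": 70.0,
        "systemic_venous": 12.0,
        "fontan_pathway": 11.0,
        "pulmonary_venous": 9.5,
        "atrium": 9.0,
        "ventricle": 9.0,
    },
    "simulation": {
        "sample_dt": 0.001,
        "rtol": 1.0e-6,
        "atol": 1.0e-8,
        "cycle_tol": 1.0e-4,
        "max_beats": 200,
    },
}

REGISTRY_VERSION = "1.0.0"


def default_registry() -> Registry:
    """Return the shipped calibrated parameter registry (immutable)."""
    return Registry(_DEFAULT_REGISTRY_DATA, REGISTRY_VERSION)


class ResolvedScenario(NamedTuple):
    """A fully resolved configuration: scenario, patient, and registry."""

    config: ScenarioConfig
    patient: PatientParameters
    registry: Registry


_SCENARIO_KEYS = {f for f in ScenarioConfig.__dataclass_fields__}
_PATIENT_KEYS = {f for f in PatientParameters.__dataclass_fields__}
_REGISTRY_SECTIONS = {
    "svr",
    "pvr",
    "beds",
    "compartments",
    "pulmonary_split",
    "chambers",
    "valves",
    "shunts",
    "oxygen",
    "dobutamine",
    "initial_pressures",
    "simulation",
}


def _deep_merge(base: dict, overrides: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in overrides.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(source: Any = None) -> ResolvedScenario:
    """Parse a structured-text scenario document and resolve it against the defaults.

    ``source`` may be None (pure defaults), a mapping, a YAML string, a path,
    or an open file.  Recognised top-level sections: ``patient``,
    ``scenario`` and any registry section (``compartments``, ``chambers``,
    ``shunts``, ...).  Unknown keys raise :class:`ConfigError`.
    """
    if source is None:
        doc: dict[str, Any] = {}
    elif isinstance(source, Mapping):
        doc = dict(source)
    elif isinstance(source, io.IOBase) or hasattr(source, "read"):
        doc = yaml.safe_load(source.read()) or {}
    elif isinstance(source, (str, os.PathLike)):
        text = str(source)
        if os.path.exists(text):
            with open(text, "r") as fh:
                doc = yaml.safe_load(fh) or {}
        else:
            doc = yaml.safe_load(text) or {}
    else:
        raise ConfigError(f"source: cannot interpret {type(source).__name__} as a config document")
    if not isinstance(doc, dict):
        raise ConfigError("document: top level must be a mapping of sections")

    unknown = set(doc) - ({"patient", "scenario"} | _REGISTRY_SECTIONS)
    if unknown:
        raise ConfigError(f"{sorted(unknown)[0]}: unknown top-level section")

    registry = default_registry()
    reg_overrides = {k: v for k, v in doc.items() if k in _REGISTRY_SECTIONS}
    if reg_overrides:
        base = registry.to_dict()
        base.pop("version", None)
        registry = Registry(_deep_merge(base, reg_overrides), registry.version)

    patient_doc = dict(registry["patient"])
    for key, value in (doc.get("patient") or {}).items():
        if key not in _PATIENT_KEYS:
            raise ConfigError(f"patient.{key}: unknown patient parameter")
        patient_doc[key] = value
    try:
        patient = PatientParameters(**patient_doc)
    except ConfigError:
        raise
    except TypeError as exc:
        raise ConfigError(f"patient: {exc}") from exc

    scenario_doc = {"svr_baseline": registry["svr"], "pvr_baseline": registry["pvr"]}
    for key, value in (doc.get("scenario") or {}).items():
        if key not in _SCENARIO_KEYS:
            raise ConfigError(f"scenario.{key}: unknown scenario parameter")
        scenario_doc[key] = value
    config = ScenarioConfig(**scenario_doc)

    # Keep registry aggregates consistent with the scenario baselines.
    registry = registry.updated({"svr": config.svr_baseline, "pvr": config.pvr_baseline})

    resolved = ResolvedScenario(config=config, patient=patient, registry=registry)
    logger.info("resolved configuration:\n%s", serialize(resolved))
    return resolved


def serialize(resolved: ResolvedScenario) -> str:
    """Serialize a resolved scenario back to its structured-text form."""
    doc = {
        "scenario": asdict(resolved.config),
        "patient": asdict(resolved.patient),
    }
    reg = resolved.registry.to_dict()
    reg.pop("version", None)
    reg.pop("patient", None)
    doc.update(reg)
    return yaml.safe_dump(doc, sort_keys=True)


def resolve(source: Any = None) -> ResolvedScenario:
    """Alias for :func:`load_config`; accepts an already-resolved scenario unchanged."""
    if isinstance(source, ResolvedScenario):
        return source
    if isinstance(source, ScenarioConfig):
        registry = default_registry().updated(
            {"svr": source.svr_baseline, "pvr": source.pvr_baseline}
        )
        return ResolvedScenario(source, PatientParameters(**registry["patient"]), registry)
    return load_config(source)
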