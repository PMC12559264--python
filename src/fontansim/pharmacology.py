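"""Dobutamine dose response and SVR/PVR magnification.

Dobutamine is represented by interpolated multiplier tables anchored at
0, 5 and 10 ug/kg/min: it raises end-systolic ventricular elastance, lowers
systemic vascular resistance, and (through the increased workload) raises
the oxygen consumption index.  Resistance sweeps scale the systemic and
pulmonary aggregates with dimensionless magnification ratios; both
operations are multiplicative on the registry and therefore commute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .parameters import Registry, default_registry

__all__ = ["DobutamineResponse", "apply_dobutamine", "scale_resistances"]


@dataclass(frozen=True)
class DobutamineResponse:
    """Dose grid (ug/kg/min) and the multiplier table for each affected
    parameter: ventricular e_max, systemic resistance, heart rate, VO2I."""

    doses: tuple[float, ...]
    e_max: tuple[float, ...]
    svr: tuple[float, ...]
    heart_rate: tuple[float, ...]
    vo2i: tuple[float, ...]
    #: metabolic coronary vasodilation (resistance multiplier on the coronary
    #: bed only, on top of the systemic aggregate)
    coronary_r: tuple[float, ...] = ()

    _COLUMNS = ("e_max", "svr", "heart_rate", "vo2i", "coronary_r")

    def __post_init__(self) -> None:
        if not self.coronary_r:
            object.__setattr__(self, "coronary_r", tuple(1.0 for _ in self.doses))
        n = len(self.doses)
        for name in self._COLUMNS:
            if len(getattr(self, name)) != n:
                raise ValueError(f"dobutamine table {name!r} length mismatch")
        if list(self.doses) != sorted(self.doses) or self.doses[0] != 0.0:
            raise ValueError("dose grid must be sorted and start at 0")
        for name in self._COLUMNS:
            if abs(getattr(self, name)[0] - 1.0) > 1e-12:
                raise ValueError(f"multiplier {name!r} must equal 1 at dose 0")
        if any(np.diff(self.e_max) < 0):
            raise ValueError("e_max multiplier must be non-decreasing in dose")
        if any(np.diff(self.svr) > 0):
            raise ValueError("svr multiplier must be non-increasing in dose")
        if any(np.diff(self.coronary_r) > 0):
            raise ValueError("coronary_r multiplier must be non-increasing in dose")

    @classmethod
    def from_registry(cls, registry: Registry) -> "DobutamineResponse":
        doc = registry["dobutamine"]
        return cls(doses=tuple(doc["doses"]), e_max=tuple(doc["e_max"]),
                   svr=tuple(doc["svr"]), heart_rate=tuple(doc["heart_rate"]),
                   vo2i=tuple(doc["vo2i"]),
                   coronary_r=tuple(doc.get("coronary_r", ())))

    def multipliers(self, dose: float) -> dict[str, float]:
        """Linearly interpolated multipliers at ``dose``; error beyond the grid."""
        if dose < 0:
            raise ValueError("dobutamine dose must be non-negative")
        if dose > self.doses[-1]:
            raise ValueError(
                f"dose {dose} ug/kg/min exceeds the calibrated grid maximum "
                f"{self.doses[-1]}")
        return {name: float(np.interp(dose, self.doses, getattr(self, name)))
                for name in self._COLUMNS}


def apply_dobutamine(registry: Optional[Registry], dose: float) -> Registry:
    """Return a registry with the dose-response multipliers applied.

    Scales ventricular e_max, the systemic resistance aggregate, heart rate
    and resting VO2I; every other parameter is untouched and the input
    registry is not modified.
    """
    registry = registry if registry is not None else default_registry()
    table = DobutamineResponse.from_registry(registry)
    m = table.multipliers(dose)
    try:
        cor_mult = float(registry["beds.coronary.r_multiplier"])
    except KeyError:
        cor_mult = 1.0
    return registry.updated({
        "chambers.ventricle.e_max": registry["chambers.ventricle.e_max"] * m["e_max"],
        "svr": registry["svr"] * m["svr"],
        "patient.heart_rate": registry["patient.heart_rate"] * m["heart_rate"],
        "patient.vo2i_rest": registry["patient.vo2i_rest"] * m["vo2i"],
        "beds.coronary.r_multiplier": cor_mult * m["coronary_r"],
    })


def scale_resistances(registry: Optional[Registry], svr_ratio: float,
                      pvr_ratio: float) -> Registry:
    """Scale the systemic and pulmonary resistance aggregates.

    Every systemic-bed resistance derives from the ``svr`` aggregate and
    every pulmonary resistance from ``pvr``, so scaling the aggregates
    multiplies exactly those resistances; compliances, inertances and the
    caval/conduit pathway are untouched.
    """
    registry = registry if registry is not None else default_registry()
    if svr_ratio <= 0 or pvr_ratio <= 0:
        raise ValueError("magnification ratios must be positive")
    return registry.updated({
        "svr": registry["svr"] * svr_ratio,
        "pvr": registry["pvr"] * pvr_ratio,
    })
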