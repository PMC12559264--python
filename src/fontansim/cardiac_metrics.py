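"""Pressure-volume loop extraction and ventricular function indices.

From a converged beat the systemic ventricle's (V, P) trajectory gives:

* EF = (EDV - ESV) / EDV;
* Ea = end-systolic pressure / stroke volume (effective arterial elastance);
* Ees = the chamber's end-systolic elastance (known in simulation);
* SW = the loop area (shoelace formula);
* PVA = SW + potential energy, the triangle between the linear ESPVR
  through (V0, 0), the end-systolic point, and the volume axis
  (Suga's framework); SW/PVA is the mechanical efficiency.

The end-systolic point is the loop sample maximizing P / (V - V0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .heart_chamber import ChamberParameters
from .hemodynamics import BeatSolution

__all__ = [
    "PVLoop",
    "CardiacFunctionIndices",
    "DegenerateLoopError",
    "extract_pv_loop",
    "compute_indices",
    "estimate_ees_two_load",
]

#: minimum stroke volume (relative to EDV) below which a loop is degenerate
_MIN_RELATIVE_STROKE = 1e-3


class DegenerateLoopError(ValueError):
    """The beat produced no usable pressure-volume loop (no ejection)."""


@dataclass
class PVLoop:
    """Sampled (volume, pressure) pairs over one beat plus derived scalars."""

    volume: np.ndarray
    pressure: np.ndarray
    edv: float
    esv: float
    end_systolic_pressure: float
    end_systolic_volume: float

    @property
    def stroke_volume(self) -> float:
        return self.edv - self.esv

    def area(self) -> float:
        """Signed loop area (mmHg.mL) by the shoelace formula; positive for
        the physiologic counter-clockwise loop in the (V, P) plane."""
        v, p = self.volume, self.pressure
        return float(0.5 * np.sum(v * np.roll(p, -1) - np.roll(v, -1) * p))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"volume": self.volume, "pressure": self.pressure})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class CardiacFunctionIndices:
    """EF (%), Ea and Ees (mmHg/mL), Ees/Ea, SW and PVA (mmHg.mL), SW/PVA."""

    ef: float
    ea: float
    ees: float
    ees_over_ea: float
    sw: float
    pva: float
    sw_over_pva: float

    def __post_init__(self) -> None:
        if not (0 < self.ef < 100):
            raise DegenerateLoopError(f"ejection fraction out of range: {self.ef}")
        if not (0 < self.sw_over_pva <= 1):
            raise DegenerateLoopError(f"SW/PVA out of range: {self.sw_over_pva}")
        if self.ees_over_ea <= 0:
            raise DegenerateLoopError("Ees/Ea must be positive")

    def to_series(self) -> pd.Series:
        return pd.Series({
            "ef": self.ef, "ea": self.ea, "ees": self.ees,
            "ees_over_ea": self.ees_over_ea, "sw": self.sw, "pva": self.pva,
            "sw_over_pva": self.sw_over_pva,
        })


def extract_pv_loop(solution: BeatSolution, chamber_name: str = "ventricle",
                    v0: Optional[float] = None) -> PVLoop:
    """Extract the ventricular pressure-volume loop from a converged beat.

    EDV/ESV are the volume extrema; the end-systolic point maximizes
    P / (V - V0).  Raises :class:`DegenerateLoopError` for a non-beating
    (flat) solution.
    """
    node = solution.topology.node(chamber_name)
    if node.chamber is None:
        raise ValueError(f"{chamber_name!r} is not a chamber node")
    if v0 is None:
        v0 = node.chamber.v0
    V = solution.chamber_volume(chamber_name)
    P = solution.chamber_pressure_series(chamber_name)
    edv = float(V.max())
    esv = float(V.min())
    if edv - esv < _MIN_RELATIVE_STROKE * max(edv, 1.0):
        raise DegenerateLoopError(
            f"stroke volume {edv - esv:.3g} mL is negligible; chamber is not beating")
    # drop the duplicated wrap-around sample before ratio search / area
    V, P = V[:-1], P[:-1]
    denom = V - v0
    ratio = np.where(denom > 1e-9, P / np.where(denom > 1e-9, denom, 1.0), -np.inf)
    k = int(np.argmax(ratio))
    return PVLoop(volume=V, pressure=P, edv=edv, esv=esv,
                  end_systolic_pressure=float(P[k]), end_systolic_volume=float(V[k]))


def compute_indices(loop: PVLoop, chamber: ChamberParameters) -> CardiacFunctionIndices:
    """Cardiac function indices from a PV loop and its chamber parameters.

    Ees is reported as the chamber's configured e_max (the simulated truth);
    :func:`estimate_ees_two_load` provides the load-varying estimate used to
    verify consistency.
    """
    sv = loop.stroke_volume
    if sv <= 0:
        raise DegenerateLoopError("zero stroke volume")
    ef = 100.0 * sv / loop.edv
    ea = loop.end_systolic_pressure / sv
    sw = abs(loop.area())
    # potential energy: triangle between the ESPVR through (v0, 0) and the
    # end-systolic point
    pe = max(0.5 * loop.end_systolic_pressure * (loop.end_systolic_volume - chamber.v0),
             0.0)
    pva = sw + pe
    if pva <= 0:
        raise DegenerateLoopError("pressure-volume area is zero")
    ees = chamber.e_max
    return CardiacFunctionIndices(ef=ef, ea=ea, ees=ees, ees_over_ea=ees / ea,
                                  sw=sw, pva=pva, sw_over_pva=sw / pva)


def estimate_ees_two_load(loop_a: PVLoop, loop_b: PVLoop) -> float:
    """Slope of the line through two end-systolic points from different
    afterloads — the classic multi-load Ees estimate (mmHg/mL)."""
    dv = loop_a.end_systolic_volume - loop_b.end_systolic_volume
    if abs(dv) < 1e-9:
        raise ValueError("afterload runs produced identical end-systolic volumes")
    return (loop_a.end_systolic_pressure - loop_b.end_systolic_pressure) / dv
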