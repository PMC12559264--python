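"""Time-varying elastance heart chambers and smoothed valve laws.

The single ventricle and atrium are pressure sources P = E(t) (V - V0) plus a
linear viscoelastic (resistive) term K dV/dt.  The activation waveform is a
normalized double-Hill product, the standard shape for 0D heart models: a
rising Hill function (exponent m1, time scale tau1) times a falling one
(m2, tau2), rescaled so its maximum over the beat is exactly 1, which makes
the elastance reach e_max once per beat and e_min in diastole.

Valves are smoothed diodes: algebraic, continuous and monotone in the
pressure drop, Ohmic (slope 1/R) when wide open, and carrying only the
configured leak when reverse biased.  Smoothness keeps the circulation ODE
friendly to stiff adaptive integrators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "ChamberParameters",
    "ValveParameters",
    "elastance_at",
    "chamber_pressure",
    "valve_flow",
]


@dataclass(frozen=True)
class ChamberParameters:
    """Elastance chamber constants.

    e_max / e_min: end-systolic and diastolic elastance (mmHg/mL); v0:
    unstressed volume (mL); viscoelastic_coefficient (mmHg.s/mL); m1, m2,
    tau1_fraction, tau2_fraction: double-Hill shape constants with time
    scales as fractions of the beat period; activation_offset_fraction
    shifts the activation within the beat (used to time atrial systole).
    """

    e_max: float
    e_min: float
    v0: float = 0.0
    viscoelastic_coefficient: float = 0.0
    m1: float = 1.9
    m2: float = 21.9
    tau1_fraction: float = 0.269
    tau2_fraction: float = 0.452
    activation_offset_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (self.e_max >= self.e_min > 0):
            raise ValueError(f"chamber elastances must satisfy e_max >= e_min > 0, got "
                             f"e_max={self.e_max}, e_min={self.e_min}")
        if self.v0 < 0:
            raise ValueError("unstressed volume v0 must be non-negative")
        if self.viscoelastic_coefficient < 0:
            raise ValueError("viscoelastic coefficient must be non-negative")
        if min(self.m1, self.m2, self.tau1_fraction, self.tau2_fraction) <= 0:
            raise ValueError("activation shape constants must be positive")


@dataclass(frozen=True)
class ValveParameters:
    """Smoothed-diode valve: forward resistance (mmHg.s/mL), leak conductance
    (mL/s/mmHg) when closed, and the smoothing width (mmHg) of the
    open/close transition."""

    forward_resistance: float
    leak_conductance: float = 0.0
    smoothing: float = 0.02

    def __post_init__(self) -> None:
        if self.forward_resistance <= 0:
            raise ValueError("valve forward resistance must be positive")
        if self.leak_conductance < 0:
            raise ValueError("valve leak conductance must be non-negative")
        if self.smoothing <= 0:
            raise ValueError("valve smoothing width must be positive")


def _raw_activation(u: np.ndarray | float, m1: float, m2: float,
                    t1: float, t2: float) -> np.ndarray | float:
    """Unnormalized double-Hill activation on normalized beat time u in [0, 1)."""
    x1 = (u / t1) ** m1
    x2 = (u / t2) ** m2
    return (x1 / (1.0 + x1)) / (1.0 + x2)


@lru_cache(maxsize=128)
def _activation_peak(m1: float, m2: float, t1: float, t2: float) -> float:
    """Maximum of the raw double-Hill waveform over one beat (normalization)."""
    u = np.linspace(1e-9, 1.0, 4097)
    a = _raw_activation(u, m1, m2, t1, t2)
    k = int(np.argmax(a))
    lo, hi = u[max(k - 1, 0)], u[min(k + 1, len(u) - 1)]
    # golden-section refinement of the grid maximum
    gr = (math.sqrt(5.0) - 1.0) / 2.0
    c, d = hi - gr * (hi - lo), lo + gr * (hi - lo)
    for _ in range(60):
        if _raw_activation(c, m1, m2, t1, t2) > _raw_activation(d, m1, m2, t1, t2):
            hi = d
        else:
            lo = c
        c, d = hi - gr * (hi - lo), lo + gr * (hi - lo)
    return float(_raw_activation(0.5 * (lo + hi), m1, m2, t1, t2))


def activation(chamber: ChamberParameters, t: np.ndarray | float, period: float):
    """Normalized activation a(t) in [0, 1], periodic with the beat period."""
    u = np.mod(np.asarray(t, dtype=float) / period - chamber.activation_offset_fraction, 1.0)
    u = np.where(u < 1e-12, 1e-12, u)
    peak = _activation_peak(chamber.m1, chamber.m2,
                            chamber.tau1_fraction, chamber.tau2_fraction)
    a = _raw_activation(u, chamber.m1, chamber.m2,
                        chamber.tau1_fraction, chamber.tau2_fraction) / peak
    return a if np.ndim(t) else float(a)


def elastance_at(chamber: ChamberParameters, t: np.ndarray | float, period: float):
    """Chamber elastance E(t) (mmHg/mL) at time ``t`` within a beat of ``period`` s.

    Bounded by [e_min, e_max], periodic, and attains e_max once per beat at
    the activation peak.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    a = activation(chamber, t, period)
    return chamber.e_min + (chamber.e_max - chamber.e_min) * a


def chamber_pressure(chamber: ChamberParameters, volume: float, volume_rate: float,
                     t: float, period: float) -> float:
    """Chamber pressure P = E(t) (V - V0) + K dV/dt (mmHg).

    ``volume_rate`` is the net filling rate dV/dt (mL/s); during ejection it
    is negative, so the viscoelastic term lowers the measured pressure.
    """
    if np.ndim(volume) == 0 and volume < 0:
        raise ValueError("chamber volume must be non-negative")
    e = elastance_at(chamber, t, period)
    return e * (np.asarray(volume) - chamber.v0) + \
        chamber.viscoelastic_coefficient * np.asarray(volume_rate)


def valve_flow(delta_p: np.ndarray | float, valve: ValveParameters):
    """Flow (mL/s) through a smoothed-diode valve for a pressure drop (mmHg).

    Exactly zero at delta_p = 0, approaches delta_p / forward_resistance for
    drops well above the smoothing width, carries only the leak conductance
    when reverse biased, and is continuous and monotone throughout.
    """
    dp = np.asarray(delta_p, dtype=float)
    w = valve.smoothing
    root = np.sqrt(dp * dp + w * w)
    forward = (dp + root - w) / (2.0 * valve.forward_resistance)
    leak = valve.leak_conductance * 0.5 * (dp - root + w)
    q = forward + leak
    return q if np.ndim(delta_p) else float(q)
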