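"""Fick-principle oxygen layer: O2 content formulas and the node mixing solve.

Oxygen is transported on the beat-averaged flow field (steady-species
assumption): each network node's outgoing saturation is the flow-weighted
mean of its incoming stream saturations.  Three stream rules apply:

* a pulmonary-capillary edge delivers blood at the fixed end-capillary
  saturation, independent of its inlet saturation;
* a systemic-bed edge delivers arterial blood minus the tissue extraction;
  total consumption VO2I x BSA is distributed over beds in proportion to
  their flow, so every bed returns the same venous saturation;
* any other edge transports its source-node saturation unchanged.

Contents follow CaO2 = Hb x 1.36 x SaO2/100 + PaO2 x 0.0031 (and likewise
for the venous side), and the solved state closes the Fick balance
VO2I = COI x (CaO2 - CvO2) x 10 exactly, with COI the index of
tissue-perfusing systemic flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .hemodynamics import MeanHemodynamics
from .parameters import PatientParameters
from .vascular_network import Topology

__all__ = [
    "FickParameters",
    "OxygenState",
    "InfeasibleVO2Error",
    "o2_content",
    "fick_vo2",
    "saturation_from_content",
    "solve_saturations",
    "linear_mixing_solve",
]

HB_O2_CAPACITY = 1.36    # mL O2 per g Hb at full saturation
O2_SOLUBILITY = 0.0031   # mL O2 per dL per mmHg dissolved


class InfeasibleVO2Error(ValueError):
    """The demanded VO2I cannot be extracted at the given flows."""

    def __init__(self, vo2i: float, vo2i_max: float):
        super().__init__(
            f"oxygen consumption index {vo2i:.1f} mL/min/m2 is infeasible at these "
            f"flows; the maximum supportable VO2I is about {vo2i_max:.1f} mL/min/m2")
        self.vo2i_max = vo2i_max


@dataclass(frozen=True)
class FickParameters:
    """Oxygen operating point: hemoglobin (g/dL), consumption index
    (mL/min/m2), dissolved-O2 partial pressures (mmHg) and the pulmonary
    end-capillary saturation (%)."""

    hb: float = 15.0
    vo2i: float = 125.0
    pao2: float = 100.0
    pvo2: float = 40.0
    pulmonary_end_capillary_saturation: float = 98.0

    def __post_init__(self) -> None:
        if self.hb <= 0:
            raise ValueError("hb must be positive")
        if self.vo2i <= 0:
            raise ValueError("vo2i must be positive")
        if not (0 < self.pulmonary_end_capillary_saturation <= 100):
            raise ValueError("pulmonary end-capillary saturation must lie in (0, 100]")


@dataclass
class OxygenState:
    """Solved oxygen state: per-node saturations (%), arterial/venous
    contents (mL O2/dL), and the Fick quantities."""

    node_saturations: dict[str, float]
    sao2: float
    svo2: float
    cao2: float
    cvo2: float
    coi: float
    vo2i: float
    iterations: int = 0
    residual: float = 0.0

    def fick_residual(self) -> float:
        """|VO2I - COI x (CaO2 - CvO2) x 10| (mL/min/m2)."""
        return abs(self.vo2i - fick_vo2(self.coi, self.cao2, self.cvo2))

    def to_series(self) -> pd.Series:
        data = {f"sat_{k}": v for k, v in self.node_saturations.items()}
        data.update(sao2=self.sao2, svo2=self.svo2, cao2=self.cao2, cvo2=self.cvo2,
                    coi=self.coi, vo2i=self.vo2i)
        return pd.Series(data)


def o2_content(saturation: float, hb: float, po2: float) -> float:
    """Blood O2 content (mL O2/dL): Hb x 1.36 x S/100 + PO2 x 0.0031."""
    sat = np.asarray(saturation, dtype=float)
    if np.any(sat < 0) or np.any(sat > 100):
        raise ValueError(f"saturation must lie in [0, 100], got {saturation}")
    if hb < 0 or po2 < 0:
        raise ValueError("hb and po2 must be non-negative")
    out = hb * HB_O2_CAPACITY * sat / 100.0 + po2 * O2_SOLUBILITY
    return out if np.ndim(saturation) else float(out)


def saturation_from_content(content: float, hb: float, po2: float) -> float:
    """Invert :func:`o2_content` for the hemoglobin-bound saturation (%)."""
    return (content - po2 * O2_SOLUBILITY) * 100.0 / (hb * HB_O2_CAPACITY)


def fick_vo2(coi: float, cao2: float, cvo2: float) -> float:
    """Oxygen consumption index VO2I = COI x (CaO2 - CvO2) x 10 (mL/min/m2)."""
    if coi < 0:
        raise ValueError("cardiac output index must be non-negative")
    return coi * (cao2 - cvo2) * 10.0


# -- mixing system -----------------------------------------------------------

_ARTERIAL_CLASSES = ("systemic_arterial", "ventricle", "atrium", "pulmonary_venous")


def _mixing_instance(mean: MeanHemodynamics, topology: Topology):
    """Orient edges along their mean flow and collect the mixing streams."""
    edges = []
    q_beds = 0.0
    for e in topology.edges:
        q = mean.edge_flows[e.name]
        if abs(q) < 1e-12:
            continue
        src, dst = (e.source, e.target) if q > 0 else (e.target, e.source)
        edges.append((e.name, src, dst, abs(q), e.is_bed, e.is_pulmonary_capillary))
        if e.is_bed:
            q_beds += abs(q)
    return edges, q_beds


def _delivered_terms(fick: FickParameters, patient: PatientParameters, q_beds: float):
    """Per-stream affine terms: delivered sat = coef * s_src + const."""
    q_beds_lmin = q_beds * 0.06
    if q_beds_lmin <= 0:
        raise InfeasibleVO2Error(fick.vo2i, 0.0)
    drop_content = fick.vo2i * patient.bsa / (q_beds_lmin * 10.0)
    k = fick.hb * HB_O2_CAPACITY / 100.0
    # bed venous sat = (CaO2(s_src) - drop - dissolved_v) / k
    bed_const = ((fick.pao2 - fick.pvo2) * O2_SOLUBILITY - drop_content) / k
    return drop_content, bed_const


def _node_outputs(topology: Topology, mean: MeanHemodynamics, sats: dict[str, float],
                  fick: FickParameters, patient: PatientParameters,
                  q_beds: float, iterations: int, residual: float) -> OxygenState:
    classes = {n.name: n.node_class for n in topology.nodes}
    arterial = [n for n in topology.node_names if classes[n] == "systemic_arterial"]
    sao2 = sats[arterial[0]] if arterial else max(sats.values())

    caval_q = caval_qs = 0.0
    for e in topology.edges:
        if classes.get(e.source) == "systemic_venous" and \
                classes.get(e.target) in ("fontan_pathway", "pulmonary_arterial"):
            q = abs(mean.edge_flows[e.name])
            caval_q += q
            caval_qs += q * sats[e.source]
    if caval_q > 0:
        svo2 = caval_qs / caval_q
    else:
        venous = [n for n in topology.node_names if classes[n] == "systemic_venous"]
        svo2 = float(np.mean([sats[n] for n in venous])) if venous else min(sats.values())

    coi = q_beds * 0.06 / patient.bsa
    cao2 = o2_content(np.clip(sao2, 0, 100), fick.hb, fick.pao2)
    cvo2 = o2_content(np.clip(svo2, 0, 100), fick.hb, fick.pvo2)
    return OxygenState(node_saturations=dict(sats), sao2=sao2, svo2=svo2,
                       cao2=float(cao2), cvo2=float(cvo2), coi=coi, vo2i=fick.vo2i,
                       iterations=iterations, residual=residual)


def linear_mixing_solve(mean: MeanHemodynamics, topology: Topology,
                        fick: FickParameters,
                        patient: Optional[PatientParameters] = None,
                        init_sao2: float = 97.0, init_svo2: float = 60.0,
                        _vo2i_override: Optional[float] = None) -> OxygenState:
    """Direct linear solve of the mixing system (same fixed point as
    :func:`solve_saturations`; the saturation clip at 100% is not applied)."""
    patient = patient or PatientParameters()
    if _vo2i_override is not None:
        fick = FickParameters(hb=fick.hb, vo2i=max(_vo2i_override, 1e-9),
                              pao2=fick.pao2, pvo2=fick.pvo2,
                              pulmonary_end_capillary_saturation=
                              fick.pulmonary_end_capillary_saturation)
    edges, q_beds = _mixing_instance(mean, topology)
    drop, bed_const = _delivered_terms(fick, patient, q_beds)

    names = list(topology.node_names)
    index = {n: i for i, n in enumerate(names)}
    n = len(names)
    A = np.zeros((n, n))
    b = np.zeros(n)
    inflow = np.zeros(n)
    for _, src, dst, q, is_bed, is_cap in edges:
        j = index[dst]
        inflow[j] += q
        if is_cap:
            b[j] += q * fick.pulmonary_end_capillary_saturation
        elif is_bed:
            A[j, index[src]] -= q
            b[j] += q * bed_const
        else:
            A[j, index[src]] -= q
    classes = {nd.name: nd.node_class for nd in topology.nodes}
    for i, name in enumerate(names):
        if inflow[i] > 0:
            A[i, i] += inflow[i]
        else:
            A[i, i] = 1.0
            b[i] = init_sao2 if classes[name] in _ARTERIAL_CLASSES else init_svo2
    s = np.linalg.solve(A, b)
    sats = {name: float(s[i]) for i, name in enumerate(names)}
    return _node_outputs(topology, mean, sats, fick, patient, q_beds, 0, 0.0)


def solve_saturations(mean: MeanHemodynamics, topology: Topology,
                      fick: FickParameters,
                      patient: Optional[PatientParameters] = None,
                      init_sao2: float = 97.0, init_svo2: float = 60.0, *,
                      tol: float = 1.0e-12, max_iter: int = 10000,
                      damping: float = 0.9) -> OxygenState:
    """Solve the oxygen mixing fixed point on beat-averaged flows.

    Damped successive substitution seeded from the initial arterial/venous
    saturations; raises :class:`InfeasibleVO2Error` (reporting the maximum
    supportable VO2I) if the demanded consumption drives any saturation
    negative.
    """
    patient = patient or PatientParameters()
    edges, q_beds = _mixing_instance(mean, topology)
    drop, bed_const = _delivered_terms(fick, patient, q_beds)

    classes = {n.name: n.node_class for n in topology.nodes}
    sats = {n: (init_sao2 if classes[n] in _ARTERIAL_CLASSES else init_svo2)
            for n in topology.node_names}

    s_cap = fick.pulmonary_end_capillary_saturation
    residual = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        acc = {n: 0.0 for n in sats}
        wsum = {n: 0.0 for n in sats}
        for _, src, dst, q, is_bed, is_cap in edges:
            if is_cap:
                s_in = s_cap
            elif is_bed:
                s_in = min(sats[src] + bed_const, 100.0)
            else:
                s_in = sats[src]
            acc[dst] += q * s_in
            wsum[dst] += q
        residual = 0.0
        for n in sats:
            if wsum[n] > 0:
                new = (1.0 - damping) * sats[n] + damping * acc[n] / wsum[n]
                residual = max(residual, abs(new - sats[n]))
                sats[n] = new
        if residual < tol:
            break
    if residual >= tol:
        raise RuntimeError(
            f"oxygen mixing did not converge in {max_iter} iterations "
            f"(residual {residual:.3e})")

    if min(sats.values()) < 0.0:
        vo2i_max = _max_supportable_vo2i(mean, topology, fick, patient,
                                         init_sao2, init_svo2)
        raise InfeasibleVO2Error(fick.vo2i, vo2i_max)
    return _node_outputs(topology, mean, sats, fick, patient, q_beds,
                         iterations, residual)


def _max_supportable_vo2i(mean, topology, fick, patient, init_sao2, init_svo2) -> float:
    """Largest VO2I with all node saturations non-negative (min sat is affine
    in VO2I at fixed flows, so two linear solves suffice)."""
    s0 = linear_mixing_solve(mean, topology, fick, patient, init_sao2, init_svo2,
                             _vo2i_override=1e-9)
    s1 = linear_mixing_solve(mean, topology, fick, patient, init_sao2, init_svo2,
                             _vo2i_override=fick.vo2i)
    m0 = min(s0.node_saturations.values())
    m1 = min(s1.node_saturations.values())
    slope = (m0 - m1) / fick.vo2i
    return m0 / slope if slope > 0 else float("inf")
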