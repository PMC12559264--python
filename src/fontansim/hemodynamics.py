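"""Network ODE assembly, limit-cycle integration, and beat-averaged hemodynamics.

State vector: one volume per node (compartments and chambers) followed by
one flow per inertial edge.  Compartment pressure is (V - V0)/C; chamber
pressure is the time-varying elastance law.  All non-inertial edge flows are
algebraic in the pressures, so the right-hand side conserves total blood
volume exactly: every flow leaves one node and enters another.

The chamber viscoelastic coefficient is realised as a series resistance on
the chamber's port edges (adding K to each adjacent edge's resistance),
which keeps the right-hand side explicit; the reported chamber pressure
still follows P = E(t)(V - V0) + K dV/dt using the computed net inflow.

A scenario is integrated beat by beat with a stiff-capable adaptive solver
(LSODA) until the beat-start state reaches a periodic fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .heart_chamber import ChamberParameters, elastance_at
from .parameters import PatientParameters
from .vascular_network import Topology

__all__ = [
    "CirculationState",
    "BeatSolution",
    "MeanHemodynamics",
    "CompiledModel",
    "ConvergenceError",
    "NumericalError",
    "state_derivative",
    "run_to_limit_cycle",
    "beat_averages",
]


class ConvergenceError(RuntimeError):
    """The beat iteration failed to reach a periodic steady state."""

    def __init__(self, message: str, residual_trace: Sequence[float] = ()):
        super().__init__(message)
        self.residual_trace = list(residual_trace)


class NumericalError(RuntimeError):
    """A state variable became non-finite during integration."""


@dataclass
class CirculationState:
    """Named snapshot of the circulation: volumes (mL), inertial-edge flows
    (mL/s) and the time within the beat (s)."""

    volumes: dict[str, float]
    flows: dict[str, float] = field(default_factory=dict)
    time: float = 0.0

    @property
    def total_volume(self) -> float:
        return float(sum(self.volumes.values()))


class CompiledModel:
    """Topology compiled to flat arrays with a fast ODE right-hand side."""

    def __init__(self, topology: Topology, patient: PatientParameters):
        self.topology = topology
        self.patient = patient
        self.period = patient.period

        names = list(topology.node_names)
        self.node_names = names
        self.n_nodes = len(names)
        index = {name: i for i, name in enumerate(names)}
        self.node_index = index

        C = np.ones(self.n_nodes)
        V0 = np.zeros(self.n_nodes)
        self.chambers: list[tuple[int, ChamberParameters]] = []
        visc = np.zeros(self.n_nodes)
        for i, node in enumerate(topology.nodes):
            if node.compartment is not None:
                C[i] = node.compartment.compliance
                V0[i] = node.compartment.unstressed_volume
            else:
                assert node.chamber is not None
                self.chambers.append((i, node.chamber))
                V0[i] = node.chamber.v0
                visc[i] = node.chamber.viscoelastic_coefficient
        self.C = C
        self.V0 = V0
        self._is_chamber = np.zeros(self.n_nodes, dtype=bool)
        for i, _ in self.chambers:
            self._is_chamber[i] = True

        # group edges; series viscoelastic resistance added per adjacent chamber
        res, valves, nonlin, inert = [], [], [], []
        self.edge_group: dict[str, tuple[str, int]] = {}
        for e in topology.edges:
            k_extra = visc[index[e.source]] + visc[index[e.target]]
            if e.kind == "valve":
                self.edge_group[e.name] = ("valve", len(valves))
                valves.append((index[e.source], index[e.target],
                               e.valve.forward_resistance + k_extra,
                               e.valve.smoothing, e.valve.leak_conductance))
            elif e.kind == "shunt":
                g = e.shunt.conductance
                if g > 0 and k_extra > 0:
                    g = 1.0 / (1.0 / g + k_extra)
                if abs(e.shunt.exponent - 1.0) < 1e-12:
                    self.edge_group[e.name] = ("res", len(res))
                    res.append((index[e.source], index[e.target], g))
                else:
                    self.edge_group[e.name] = ("nonlin", len(nonlin))
                    nonlin.append((index[e.source], index[e.target], g, e.shunt.exponent))
            elif e.inertance > 0:
                self.edge_group[e.name] = ("inert", len(inert))
                inert.append((index[e.source], index[e.target],
                              e.resistance + k_extra, e.inertance))
            else:
                r_eff = e.resistance + k_extra
                if r_eff <= 0:
                    raise ValueError(f"edge {e.name!r}: zero-resistance algebraic edge")
                self.edge_group[e.name] = ("res", len(res))
                res.append((index[e.source], index[e.target], 1.0 / r_eff))

        def cols(rows, m):
            if not rows:
                return tuple(np.empty(0, dtype=float) for _ in range(m))
            arr = np.asarray(rows, dtype=float)
            return tuple(arr[:, j] for j in range(m))

        rs, rd, rg = cols(res, 3)
        self.res_src = rs.astype(int); self.res_dst = rd.astype(int); self.res_g = rg
        vs, vd, vr, vw, vl = cols(valves, 5)
        self.v_src = vs.astype(int); self.v_dst = vd.astype(int)
        self.v_R = vr; self.v_w = vw; self.v_leak = vl
        ns, nd_, ng, ne = cols(nonlin, 4)
        self.nl_src = ns.astype(int); self.nl_dst = nd_.astype(int)
        self.nl_g = ng; self.nl_exp = ne
        is_, id_, ir, il = cols(inert, 4)
        self.i_src = is_.astype(int); self.i_dst = id_.astype(int)
        self.i_R = ir; self.i_L = il
        self.n_inertial = len(self.i_src)
        self.dim = self.n_nodes + self.n_inertial
        self._nl_eps = 0.1  # mmHg regularization for orifice-law shunts

    # -- state packing -------------------------------------------------------

    def initial_state(self) -> np.ndarray:
        """Distribute volume over compliances at the registry pressure guesses."""
        P = np.array([self.topology.initial_pressures.get(n, 10.0)
                      for n in self.node_names])
        V = self.V0 + self.C * P
        for i, ch in self.chambers:
            e0 = elastance_at(ch, 0.0, self.period)
            V[i] = ch.v0 + P[i] / e0
        return np.concatenate([V, np.zeros(self.n_inertial)])

    def pack(self, state: CirculationState) -> np.ndarray:
        y = np.empty(self.dim)
        for i, name in enumerate(self.node_names):
            y[i] = state.volumes[name]
        inert_names = [n for n, (g, _) in self.edge_group.items() if g == "inert"]
        inert_names.sort(key=lambda n: self.edge_group[n][1])
        for j, name in enumerate(inert_names):
            y[self.n_nodes + j] = state.flows.get(name, 0.0)
        return y

    def unpack(self, y: np.ndarray, t: float = 0.0) -> CirculationState:
        volumes = {name: float(y[i]) for i, name in enumerate(self.node_names)}
        flows = {name: float(y[self.n_nodes + j])
                 for name, (g, j) in self.edge_group.items() if g == "inert"}
        return CirculationState(volumes=volumes, flows=flows, time=t)

    # -- physics -------------------------------------------------------------

    def pressures(self, V: np.ndarray, t) -> np.ndarray:
        """Node pressures; V may be (n,) with scalar t or (n_t, n) with t (n_t,)."""
        P = (V - self.V0) / self.C
        for i, ch in self.chambers:
            if np.ndim(V) == 1:
                e = elastance_at(ch, t, self.period)
                P[i] = e * (V[i] - ch.v0)
            else:
                e = elastance_at(ch, np.asarray(t), self.period)
                P[..., i] = e * (V[..., i] - ch.v0)
        return P

    def _valve_q(self, dp):
        root = np.sqrt(dp * dp + self.v_w * self.v_w)
        return (dp + root - self.v_w) / (2.0 * self.v_R) + \
            self.v_leak * 0.5 * (dp - root + self.v_w)

    def _nonlin_q(self, dp):
        eps = self._nl_eps
        return self.nl_g * dp * (dp * dp + eps * eps) ** ((self.nl_exp - 1.0) / 2.0)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        if not np.isfinite(y).all():
            bad = int(np.flatnonzero(~np.isfinite(y))[0])
            name = (self.node_names[bad] if bad < self.n_nodes
                    else f"inertial flow #{bad - self.n_nodes}")
            raise NumericalError(f"non-finite state variable: {name}")
        V = y[:self.n_nodes]
        P = self.pressures(V, t)
        dV = np.zeros(self.n_nodes)
        n = self.n_nodes
        if len(self.res_src):
            q = (P[self.res_src] - P[self.res_dst]) * self.res_g
            dV += np.bincount(self.res_dst, q, n) - np.bincount(self.res_src, q, n)
        if len(self.v_src):
            q = self._valve_q(P[self.v_src] - P[self.v_dst])
            dV += np.bincount(self.v_dst, q, n) - np.bincount(self.v_src, q, n)
        if len(self.nl_src):
            q = self._nonlin_q(P[self.nl_src] - P[self.nl_dst])
            dV += np.bincount(self.nl_dst, q, n) - np.bincount(self.nl_src, q, n)
        if self.n_inertial:
            Q = y[n:]
            dV += np.bincount(self.i_dst, Q, n) - np.bincount(self.i_src, Q, n)
            dQ = (P[self.i_src] - P[self.i_dst] - self.i_R * Q) / self.i_L
            return np.concatenate([dV, dQ])
        return dV

    def edge_flow_series(self, Y: np.ndarray, t: np.ndarray) -> dict[str, np.ndarray]:
        """Per-edge flow time series (mL/s) for sampled states Y (n_t, dim)."""
        V = Y[:, :self.n_nodes]
        P = self.pressures(V, t)
        out: dict[str, np.ndarray] = {}
        for name, (group, j) in self.edge_group.items():
            if group == "res":
                q = (P[:, self.res_src[j]] - P[:, self.res_dst[j]]) * self.res_g[j]
            elif group == "valve":
                dp = P[:, self.v_src[j]] - P[:, self.v_dst[j]]
                w, R, leak = self.v_w[j], self.v_R[j], self.v_leak[j]
                root = np.sqrt(dp * dp + w * w)
                q = (dp + root - w) / (2.0 * R) + leak * 0.5 * (dp - root + w)
            elif group == "nonlin":
                dp = P[:, self.nl_src[j]] - P[:, self.nl_dst[j]]
                eps = self._nl_eps
                q = self.nl_g[j] * dp * (dp * dp + eps * eps) ** ((self.nl_exp[j] - 1.0) / 2.0)
            else:
                q = Y[:, self.n_nodes + j]
            out[name] = q
        return out


@dataclass
class BeatSolution:
    """One converged beat, uniformly sampled.

    ``states`` has shape (n_t, dim) over ``time`` in [0, period];
    the first and last samples agree within the limit-cycle tolerance.
    """

    time: np.ndarray
    states: np.ndarray
    period: float
    model: CompiledModel
    beats_to_convergence: int
    residual: float
    residual_trace: list[float]
    volume_drift: float

    @property
    def topology(self) -> Topology:
        return self.model.topology

    def node_pressures(self) -> dict[str, np.ndarray]:
        P = self.model.pressures(self.states[:, :self.model.n_nodes], self.time)
        return {name: P[:, i] for i, name in enumerate(self.model.node_names)}

    def edge_flows(self) -> dict[str, np.ndarray]:
        return self.model.edge_flow_series(self.states, self.time)

    def chamber_volume(self, name: str) -> np.ndarray:
        return self.states[:, self.model.node_index[name]]

    def chamber_net_inflow(self, name: str) -> np.ndarray:
        """Net dV/dt (mL/s) of a chamber from its port edge flows."""
        flows = self.edge_flows()
        net = np.zeros_like(self.time)
        for e in self.topology.edges:
            if e.target == name:
                net += flows[e.name]
            if e.source == name:
                net -= flows[e.name]
        return net

    def chamber_pressure_series(self, name: str) -> np.ndarray:
        """Chamber pressure including the viscoelastic term (mmHg)."""
        node = self.topology.node(name)
        assert node.chamber is not None
        V = self.chamber_volume(name)
        e = elastance_at(node.chamber, self.time, self.period)
        return e * (V - node.chamber.v0) + \
            node.chamber.viscoelastic_coefficient * self.chamber_net_inflow(name)

    def to_dataframe(self) -> pd.DataFrame:
        data = {"time": self.time}
        for name, p in self.node_pressures().items():
            data[f"p_{name}"] = p
        for name, q in self.edge_flows().items():
            data[f"q_{name}"] = q
        for i, name in enumerate(self.model.node_names):
            data[f"v_{name}"] = self.states[:, i]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class MeanHemodynamics:
    """Beat-averaged pressures, flows, and the two cardiac outputs (L/min)."""

    node_pressures: dict[str, float]
    edge_flows: dict[str, float]
    co: float
    net_co: float
    heart_rate: float

    def junction_imbalance(self, topology: Topology) -> dict[str, float]:
        """Mean inflow minus outflow per node (mL/s); ~0 on a converged beat."""
        out = {name: 0.0 for name in topology.node_names}
        for e in topology.edges:
            q = self.edge_flows[e.name]
            out[e.target] += q
            out[e.source] -= q
        return out

    def to_series(self) -> pd.Series:
        data = {f"p_{k}": v for k, v in self.node_pressures.items()}
        data.update({f"q_{k}": v for k, v in self.edge_flows.items()})
        data["co"] = self.co
        data["net_co"] = self.net_co
        return pd.Series(data)


def nominal_total_volume(topology: Topology,
                         patient: Optional[PatientParameters] = None) -> float:
    """Total blood volume (mL) implied by the registry initial pressures.

    The closed loop conserves total volume exactly, so this quantity selects
    the operating point of every scenario built from the topology."""
    patient = patient or PatientParameters()
    model = CompiledModel(topology, patient)
    return float(model.initial_state()[:model.n_nodes].sum())


def state_derivative(topology: Topology, state: CirculationState, t: float,
                     patient: Optional[PatientParameters] = None) -> CirculationState:
    """Time derivative of the circulation state (volumes in mL/s).

    Total volume is conserved analytically: the returned volume rates sum to
    zero to machine precision.
    """
    patient = patient or PatientParameters()
    model = CompiledModel(topology, patient)
    y = model.pack(state)
    dy = model.rhs(t, y)
    d = model.unpack(dy, t)
    d.time = 1.0
    return d


def _beat(model: CompiledModel, y0: np.ndarray, rtol: float, atol: float,
          t_eval: Optional[np.ndarray] = None):
    sol = solve_ivp(model.rhs, (0.0, model.period), y0, method="LSODA",
                    rtol=rtol, atol=atol, t_eval=t_eval, max_step=0.02,
                    dense_output=False)
    if not sol.success:
        raise ConvergenceError(f"integration failed within a beat: {sol.message}")
    return sol


def run_to_limit_cycle(topology: Topology, patient: Optional[PatientParameters] = None,
                       init: Optional[CirculationState | np.ndarray] = None, *,
                       sample_dt: float = 1.0e-3, rtol: float = 1.0e-6,
                       atol: float = 1.0e-8, cycle_tol: float = 1.0e-4,
                       max_beats: int = 200) -> BeatSolution:
    """Integrate beats until the beat-start state is a periodic fixed point.

    Convergence: max-norm relative change of the state over one beat below
    ``cycle_tol``.  Returns the final beat sampled every ``sample_dt`` s.
    Raises :class:`ConvergenceError` (with the residual trace) if ``max_beats``
    is exhausted.
    """
    patient = patient or PatientParameters()
    model = CompiledModel(topology, patient)
    if init is None:
        y = model.initial_state()
    elif isinstance(init, CirculationState):
        y = model.pack(init)
    else:
        y = np.asarray(init, dtype=float).copy()
        if y.shape != (model.dim,):
            raise ValueError(f"init state has dimension {y.shape}, expected ({model.dim},)")

    total0 = float(y[:model.n_nodes].sum())
    scale = np.maximum(np.abs(y), 1.0)
    trace: list[float] = []
    converged = False
    beats = 0
    for beats in range(1, max_beats + 1):
        sol = _beat(model, y, rtol, atol)
        y_end = sol.y[:, -1]
        residual = float(np.max(np.abs(y_end - y) / scale))
        trace.append(residual)
        y = y_end
        scale = np.maximum(np.abs(y), 1.0)
        if residual < cycle_tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"no periodic steady state within {max_beats} beats "
            f"(last residual {trace[-1]:.3e})", trace)

    n_t = int(round(model.period / sample_dt)) + 1
    t_eval = np.linspace(0.0, model.period, n_t)
    sol = _beat(model, y, rtol, atol, t_eval=t_eval)
    states = sol.y.T
    drift = abs(float(states[-1, :model.n_nodes].sum()) - total0) / max(total0, 1e-12)
    return BeatSolution(time=t_eval, states=states, period=model.period, model=model,
                        beats_to_convergence=beats, residual=trace[-1],
                        residual_trace=trace, volume_drift=drift)


def beat_averages(solution: BeatSolution) -> MeanHemodynamics:
    """Beat-mean pressures and flows; CO from the aortic valve, net CO from
    the caval (SVC + IVC/conduit) return."""
    t, T = solution.time, solution.period

    def mean(series: np.ndarray) -> float:
        return float(np.trapezoid(series, t) / T)

    pressures = {k: mean(v) for k, v in solution.node_pressures().items()}
    flows = {k: mean(v) for k, v in solution.edge_flows().items()}

    topology = solution.topology
    co_mls = sum(flows[e.name] for e in topology.edges
                 if e.source == "ventricle" and e.kind == "valve")
    # caval return measured at the TCPC anastomosis: SVC inflow plus conduit
    # outflow into the pulmonary artery (after the fenestration offtake)
    classes = {n.name: n.node_class for n in topology.nodes}
    net_mls = sum(
        flows[e.name] for e in topology.edges
        if classes.get(e.source) in ("systemic_venous", "fontan_pathway")
        and classes.get(e.target) == "pulmonary_arterial"
    )
    return MeanHemodynamics(node_pressures=pressures, edge_flows=flows,
                            co=co_mls * 60.0 / 1000.0, net_co=net_mls * 60.0 / 1000.0,
                            heart_rate=solution.model.patient.heart_rate)
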