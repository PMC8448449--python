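"""Equivalent-circuit model of a weir-trap ladder street.

A street of ``n`` weir traps is modelled as a hydraulic resistor network.
Each unit cell is a hexagonal bridge: the flow arriving at junction ``J_i``
splits along two short approach channels onto the two rails of the ladder —
the *apartment rail* (through the trap constriction and the apartment
chamber, resistance ``kappa * R_A`` when the trap is occupied) and the
*serpentine rail* (the long, narrow bypass, resistance ``R_S``).  A short
bypass channel (the *rung*, resistance ``R_rung``) connects the two rails at
the trap-entrance node.  Both rails rejoin at the next junction.

This wiring is a chain of Wheatstone bridges: with equal approach arms the
rung carries zero flow exactly when ``kappa * R_A == R_S``, and the flow
direction in every rung flips as the ratio crosses one.  When
``R_A < R_S`` (an empty trap) the rung flow points *into* the trap-entrance
node, so the apartment edge is the only outflow there and the trap captures
the whole impinging stream — the high-efficiency "perfect trap" regime.
When the trap is occupied (``kappa * R_A > R_S``) the rung flow reverses and
diverts arriving fluid around the trap, which is the self-limiting switch
that makes sequential loading deterministic.

Only resistance *ratios* matter; hydraulic units are arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

__all__ = [
    "LadderSpec",
    "ResistorNetwork",
    "FlowSolution",
    "RegimeReport",
    "LadderError",
    "build_ladder",
    "solve_flows",
    "classify_regime",
    "trap_capture_fraction",
    "trap_flow_fractions",
    "flows_to_frame",
]

#: relative threshold below which a rung is considered to carry no flow
NEUTRAL_TOL = 1e-12


class LadderError(ValueError):
    """Raised for invalid ladder specifications or unsolvable networks."""


@dataclass(frozen=True)
class LadderSpec:
    """Parameters of one weir-trap street.

    Parameters
    ----------
    n_traps:
        Number of trap/apartment unit cells in series.
    R_A, R_S, R_rung:
        Hydraulic resistances (arbitrary units) of the apartment segment,
        the serpentine bypass segment and the short-bypass rung.  The rung
        default is ``R_A / 10`` (a short, wide channel).
    kappa:
        Multiplier applied to an occupied trap's apartment-path resistance.
        Self-limiting switching requires ``kappa * R_A > R_S``.
    occupied:
        Indices of traps currently holding a cell.
    inlet_pressure, outlet_pressure:
        Boundary pressures; forward flow requires inlet > outlet.
    """

    n_traps: int
    R_A: float = 1.0
    R_S: float = 10.0
    R_rung: float | None = None
    kappa: float = 100.0
    occupied: frozenset[int] = field(default_factory=frozenset)
    inlet_pressure: float = 1.0
    outlet_pressure: float = 0.0

    def __post_init__(self) -> None:
        if self.n_traps < 1:
            raise LadderError("n_traps must be a positive integer")
        if self.R_A <= 0 or self.R_S <= 0:
            raise LadderError("resistances must be strictly positive")
        if self.R_rung is not None and self.R_rung <= 0:
            raise LadderError("resistances must be strictly positive")
        if self.kappa < 1:
            raise LadderError("kappa must be >= 1")
        occ = frozenset(int(i) for i in self.occupied)
        if any(i < 0 or i >= self.n_traps for i in occ):
            raise LadderError("occupied indices must lie in [0, n_traps)")
        object.__setattr__(self, "occupied", occ)
        if not self.inlet_pressure > self.outlet_pressure:
            raise LadderError("inlet_pressure must exceed outlet_pressure")

    @property
    def rung_resistance(self) -> float:
        return self.R_rung if self.R_rung is not None else self.R_A / 10.0


@dataclass
class ResistorNetwork:
    """A solvable hydraulic circuit.

    ``graph`` is an undirected multigraph whose edges carry ``conductance``
    and ``kind`` (``apartment``, ``serpentine``, ``rung`` or ``junction``)
    attributes.  ``boundary`` maps the two fixed-pressure nodes to their
    pressures.  ``trap_nodes[i]`` is the trap-entrance node of trap ``i``.
    """

    graph: nx.MultiGraph
    boundary: dict[str, float]
    trap_nodes: list[str]
    n_traps: int

    def edges(self, kind: str | None = None):
        """Iterate ``(u, v, key, data)`` tuples, optionally by edge kind."""
        for u, v, k, d in self.graph.edges(keys=True, data=True):
            if kind is None or d["kind"] == kind:
                yield u, v, k, d

    def validate(self) -> None:
        if len(self.boundary) != 2:
            raise LadderError("exactly one inlet and one outlet are required")
        if not nx.is_connected(nx.Graph(self.graph)):
            comp = min(nx.connected_components(nx.Graph(self.graph)), key=len)
            raise LadderError(f"network is disconnected at nodes {sorted(comp)}")
        for u, v, _, d in self.edges():
            if d["conductance"] <= 0:
                raise LadderError(f"non-positive conductance on edge {u}-{v}")


@dataclass
class FlowSolution:
    """Node pressures and signed edge flows of a solved network.

    Flow sign is positive in the direction of the stored edge orientation
    (inlet-to-outlet along the rails, serpentine-rail-to-apartment-rail
    along rungs).
    """

    node_pressures: dict[str, float]
    edge_flows: dict[tuple[str, str, int], float]
    throughflow: float

    def node_outflows(self, network: ResistorNetwork, node: str) -> dict[tuple[str, str, int], float]:
        """Flows leaving ``node``, keyed by edge, as positive magnitudes."""
        out: dict[tuple[str, str, int], float] = {}
        for u, v, k, _ in network.graph.edges(node, keys=True, data=True):
            key, flow = self._oriented(u, v, k)
            leaving = flow if key[0] == node else -flow
            if leaving > 0:
                out[key] = leaving
        return out

    def node_inflow(self, network: ResistorNetwork, node: str) -> float:
        total = 0.0
        for u, v, k, _ in network.graph.edges(node, keys=True, data=True):
            key, flow = self._oriented(u, v, k)
            arriving = -flow if key[0] == node else flow
            if arriving > 0:
                total += arriving
        return total

    def _oriented(self, u: str, v: str, k: int) -> tuple[tuple[str, str, int], float]:
        if (u, v, k) in self.edge_flows:
            return (u, v, k), self.edge_flows[(u, v, k)]
        return (v, u, k), self.edge_flows[(v, u, k)]


@dataclass
class RegimeReport:
    """Per-rung flow directions and the overall trapping regime."""

    rung_direction: list[str]          # "joining" | "splitting" | "neutral"
    regime: str                        # "high-efficiency" | "low-efficiency" | "mixed"
    capture_fraction: list[float]


def _junction(i: int, n: int) -> str:
    if i == 0:
        return "inlet"
    if i == n:
        return "outlet"
    return f"J{i}"


def build_ladder(spec: LadderSpec) -> ResistorNetwork:
    """Assemble the resistor network for one street.

    Unit cell ``i`` spans junctions ``J_i`` and ``J_{i+1}`` and contributes
    five edges: two short approach arms (``junction`` kind, ``R_rung/2``
    each) from ``J_i`` onto the two rails, the apartment segment
    ``T_i -> J_{i+1}``, the serpentine segment ``B_i -> J_{i+1}`` and the
    rung ``B_i -> T_i``.  Both rails terminate on the shared junction nodes
    at each boundary.
    """
    n = spec.n_traps
    R_r = spec.rung_resistance
    r_arm = R_r / 2.0
    g = nx.MultiGraph()
    trap_nodes = []
    for i in range(n):
        J0, J1 = _junction(i, n), _junction(i + 1, n)
        T, B = f"T{i}", f"B{i}"
        trap_nodes.append(T)
        R_apt = spec.R_A * (spec.kappa if i in spec.occupied else 1.0)
        g.add_edge(J0, T, conductance=1.0 / r_arm, kind="junction", trap=i)
        g.add_edge(J0, B, conductance=1.0 / r_arm, kind="junction", trap=i)
        g.add_edge(T, J1, conductance=1.0 / R_apt, kind="apartment", trap=i)
        g.add_edge(B, J1, conductance=1.0 / spec.R_S, kind="serpentine", trap=i)
        g.add_edge(B, T, conductance=1.0 / R_r, kind="rung", trap=i)
    net = ResistorNetwork(
        graph=g,
        boundary={"inlet": spec.inlet_pressure, "outlet": spec.outlet_pressure},
        trap_nodes=trap_nodes,
        n_traps=n,
    )
    net.validate()
    return net


def solve_flows(network: ResistorNetwork) -> FlowSolution:
    """Solve the weighted graph Laplacian for node pressures and edge flows.

    The two boundary nodes are held at their fixed pressures (the outlet is
    the ground reference) and the interior pressures solve the sparse
    symmetric Kirchhoff system.  Edge flow equals conductance times pressure
    drop along the stored edge orientation.
    """
    network.validate()
    nodes = list(network.graph.nodes)
    idx = {nd: i for i, nd in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    for u, v, _, d in network.edges():
        iu, iv, c = idx[u], idx[v], d["conductance"]
        rows += [iu, iv, iu, iv]
        cols += [iu, iv, iv, iu]
        vals += [c, c, -c, -c]
    lap = scipy.sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    fixed = {idx[nd]: p for nd, p in network.boundary.items()}
    free = np.array([i for i in range(n) if i not in fixed])
    p = np.zeros(n)
    for i, val in fixed.items():
        p[i] = val
    if free.size:
        a = lap[free][:, free]
        b = -lap[free][:, sorted(fixed)] @ np.array([fixed[i] for i in sorted(fixed)])
        try:
            sol = scipy.sparse.linalg.spsolve(a.tocsc(), b)
        except Exception as exc:  # pragma: no cover - singular systems
            raise LadderError(f"singular pressure system near node {nodes[free[0]]}") from exc
        if not np.all(np.isfinite(sol)):
            bad = nodes[free[int(np.argmax(~np.isfinite(sol)))]]
            raise LadderError(f"singular pressure system near node {bad}")
        p[free] = sol

    pressures = {nd: float(p[idx[nd]]) for nd in nodes}
    flows: dict[tuple[str, str, int], float] = {}
    for u, v, k, d in network.edges():
        flows[(u, v, k)] = d["conductance"] * (pressures[u] - pressures[v])
    inlet = next(nd for nd, pr in network.boundary.items()
                 if pr == max(network.boundary.values()))
    through = 0.0
    for u, v, k, _ in network.graph.edges(inlet, keys=True, data=True):
        key = (u, v, k) if (u, v, k) in flows else (v, u, k)
        f = flows[key]
        through += f if key[0] == inlet else -f
    return FlowSolution(node_pressures=pressures, edge_flows=flows, throughflow=float(through))


def _rung_inflow(solution: FlowSolution, network: ResistorNetwork, trap: int) -> float:
    """Signed rung flow into trap ``trap``'s entrance node (positive = joining)."""
    T = network.trap_nodes[trap]
    for u, v, k, d in network.edges("rung"):
        if d["trap"] == trap:
            f = solution.edge_flows[(u, v, k)]
            return f if v == T else -f
    raise LadderError(f"trap index {trap} out of range")


def classify_regime(solution: FlowSolution, network: ResistorNetwork,
                    occupied: frozenset[int] | set[int] = frozenset()) -> RegimeReport:
    """Label every rung joining/splitting/neutral and the overall regime.

    A rung is *joining* when its flow is directed into the trap-entrance
    node on the apartment rail, *splitting* when directed away, and
    *neutral* when its magnitude is below ``NEUTRAL_TOL`` times the
    throughflow.  The street is high-efficiency iff every empty-trap rung is
    joining, low-efficiency iff every empty-trap rung is splitting.
    """
    tol = NEUTRAL_TOL * abs(solution.throughflow)
    directions = []
    for i in range(network.n_traps):
        f = _rung_inflow(solution, network, i)
        if abs(f) < tol:
            directions.append("neutral")
        elif f > 0:
            directions.append("joining")
        else:
            directions.append("splitting")
    empty = [d for i, d in enumerate(directions) if i not in occupied]
    if empty and all(d == "joining" for d in empty):
        regime = "high-efficiency"
    elif empty and all(d == "splitting" for d in empty):
        regime = "low-efficiency"
    else:
        regime = "mixed"
    fractions = [trap_capture_fraction(solution, network, i) for i in range(network.n_traps)]
    return RegimeReport(rung_direction=directions, regime=regime, capture_fraction=fractions)


def trap_capture_fraction(solution: FlowSolution, network: ResistorNetwork,
                          trap_index: int) -> float:
    """Fraction of the flow impinging on a trap entrance that sweeps through
    the apartment.

    This is the apartment-edge outflow divided by the total flow leaving the
    trap-entrance node.  In the joining regime the apartment edge is the
    only outflow, so the fraction is exactly 1 — the perfect-trap condition.
    The value lies in [0, 1] by conservation, with no numerical clamping.
    """
    if not 0 <= trap_index < network.n_traps:
        raise LadderError(f"trap index {trap_index} out of range")
    T = network.trap_nodes[trap_index]
    out = solution.node_outflows(network, T)
    total = sum(out.values())
    if total <= 0:
        return 0.0
    apt = 0.0
    for (u, v, k), f in out.items():
        d = network.graph.get_edge_data(u, v, k)
        if d["kind"] == "apartment":
            apt += f
    return apt / total


def trap_flow_fractions(solution: FlowSolution, network: ResistorNetwork,
                        trap_index: int) -> tuple[float, float]:
    """(apartment, serpentine) edge flows of one unit cell, as fractions of
    the street throughflow."""
    apt = ser = 0.0
    for u, v, k, d in network.edges():
        if d.get("trap") != trap_index:
            continue
        if d["kind"] == "apartment":
            apt = solution.edge_flows[(u, v, k)]
        elif d["kind"] == "serpentine":
            ser = solution.edge_flows[(u, v, k)]
    q = abs(solution.throughflow)
    return apt / q, ser / q


def street_entry_fractions(spec: LadderSpec) -> np.ndarray:
    """Per-trap capture fractions of a street, via an O(n) banded solve.

    Equivalent to ``build_ladder`` + ``solve_flows`` +
    ``trap_capture_fraction`` for every trap, but assembles the
    pentadiagonal pressure system directly (node order ``J_0, T_0, B_0,
    J_1, T_1, B_1, ...``) so the loading simulator can re-solve a street
    after every capture cheaply.
    """
    n = spec.n_traps
    R_r = spec.rung_resistance
    g_arm = 2.0 / R_r
    g_rung = 1.0 / R_r
    g_ser = 1.0 / spec.R_S
    g_apt = np.full(n, 1.0 / spec.R_A)
    if spec.occupied:
        g_apt[list(spec.occupied)] /= spec.kappa

    # nodes: J_i at 3i, T_i at 3i+1, B_i at 3i+2; J_n = outlet at 3n
    size = 3 * n + 1
    diag = np.zeros(size)
    off1 = np.zeros(size - 1)   # coupling (k, k+1)
    off2 = np.zeros(size - 2)   # coupling (k, k+2)
    for i in range(n):
        J, T, B = 3 * i, 3 * i + 1, 3 * i + 2
        Jn = 3 * i + 3
        for (u, v, g) in ((J, T, g_arm), (J, B, g_arm), (T, B, g_rung),
                          (T, Jn, g_apt[i]), (B, Jn, g_ser)):
            diag[u] += g
            diag[v] += g
            if v - u == 1:
                off1[u] -= g
            else:
                off2[u] -= g

    # eliminate the two boundary nodes (inlet at 0, outlet at size-1)
    p_in, p_out = spec.inlet_pressure, spec.outlet_pressure
    m = size - 2
    rhs = np.zeros(m)
    rhs[0] += -off1[0] * p_in           # T_0 <- inlet
    rhs[1] += -off2[0] * p_in           # B_0 <- inlet
    rhs[m - 1] += -off1[size - 2] * p_out
    rhs[m - 2] += -off2[size - 3] * p_out
    ab = np.zeros((3, m))               # upper banded form for solveh_banded
    ab[2] = diag[1:-1]
    ab[1, 1:] = off1[1:-1]
    ab[0, 2:] = off2[1:-1]
    p = scipy.linalg.solveh_banded(ab, rhs)
    pres = np.concatenate(([p_in], p, [p_out]))

    fractions = np.empty(n)
    for i in range(n):
        J, T, B, Jn = 3 * i, 3 * i + 1, 3 * i + 2, 3 * i + 3
        flows = np.array([
            g_arm * (pres[T] - pres[J]),      # back up the approach arm
            g_rung * (pres[T] - pres[B]),     # rung, T -> B is "out"
            g_apt[i] * (pres[T] - pres[Jn]),  # through the apartment
        ])
        out = np.clip(flows, 0.0, None)
        total = out.sum()
        fractions[i] = out[2] / total if total > 0 else 0.0
    return fractions


def flows_to_frame(solution: FlowSolution, network: ResistorNetwork) -> pd.DataFrame:
    """Solved edge flows as a table (edge kind, endpoints, flow)."""
    rows = []
    for u, v, k, d in network.edges():
        rows.append({"kind": d["kind"], "trap": d.get("trap", -1),
                     "from": u, "to": v, "flow": solution.edge_flows[(u, v, k)]})
    return pd.DataFrame(rows, columns=["kind", "trap", "from", "to", "flow"])
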