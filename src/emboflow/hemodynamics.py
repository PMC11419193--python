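"""Steady Hagen-Poiseuille network blood flow.

Each vessel segment between neighboring centerline nodes is a Poiseuille
resistor with conductance k = pi R^4 / (8 mu L). The root node is held at
mean arterial pressure (Dirichlet); every interior node enforces mass
balance; every terminal node drains into the venous sink at central venous
pressure through a lumped conductance gamma_a / mu that stands in for the
unsegmented downstream vasculature (a Robin condition). The resulting
symmetric positive-definite sparse system is solved directly.

All quantities are SI internally; the interface reports pressures in both Pa
and mmHg and flows in mL/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from emboflow.config import FlowParams
from emboflow.errors import GraphError, SolverError
from emboflow.graph import ROLE_ROOT, ROLE_TERMINAL, VascularGraph
from emboflow.units import M3S_TO_MLMIN, MM_TO_M, MMHG_TO_PA


def conductance(radius_m: float, length_m: float, mu: float) -> float:
    """Poiseuille conductance k = pi R^4 / (8 mu L), m^3/(Pa s)."""
    if radius_m <= 0 or length_m <= 0 or mu <= 0:
        raise ValueError("radius, length and viscosity must all be positive")
    return np.pi * radius_m**4 / (8.0 * mu * length_m)


@dataclass
class FlowSolution:
    """Network flow field on a vascular graph.

    ``flows[(i, j)]`` is the volumetric flow from i to j in m^3/s for each
    undirected edge stored once with i < j; it is antisymmetric by
    convention (flow j->i is the negative). ``sink_flow`` maps each terminal
    to its outflux into the venous sink.
    """

    vg: VascularGraph
    pressures: dict[int, float]
    flows: dict[tuple[int, int], float]
    velocities: dict[tuple[int, int], float]
    sink_flow: dict[int, float]
    q_total: float
    params: FlowParams

    @property
    def q_total_mlmin(self) -> float:
        return self.q_total * M3S_TO_MLMIN

    def pressure_mmhg(self, n: int) -> float:
        return self.pressures[n] / MMHG_TO_PA

    def flow(self, i: int, j: int) -> float:
        """Signed volumetric flow i -> j in m^3/s."""
        if (i, j) in self.flows:
            return self.flows[(i, j)]
        return -self.flows[(j, i)]

    def interior_residual(self) -> float:
        """Max absolute mass-balance residual over interior nodes, m^3/s."""
        res = 0.0
        for n in self.vg.nodes:
            if self.vg.g.nodes[n].get("role") not in (ROLE_ROOT, ROLE_TERMINAL):
                res = max(res, abs(sum(self.flow(n, m) for m in self.vg.g.neighbors(n))))
        return res


def _edge_conductances(vg: VascularGraph, mu: float) -> dict[tuple[int, int], float]:
    ks = {}
    for i, j, d in vg.g.edges(data=True):
        if "radius_mm" not in d:
            raise GraphError("edge geometry missing: run edge_geometry() first")
        key = (i, j) if i < j else (j, i)
        ks[key] = conductance(d["radius_mm"] * MM_TO_M, d["length_mm"] * MM_TO_M, mu)
    return ks


def solve_pressures(vg: VascularGraph, params: FlowParams) -> FlowSolution:
    """Solve the network pressure system.

    Mass balance at node i reads sum_j k_ij (P_i - P_j) = 0, with
    P_root = P_MAP and, at terminals, an extra sink term
    (gamma_a / mu) (P_i - P_CVP) added to the balance. The Dirichlet row is
    eliminated symmetrically, so the reduced matrix stays SPD.
    """
    if vg.root is None:
        raise GraphError("graph has no root: run classify_nodes() first")
    nodes = vg.nodes
    index = {n: k for k, n in enumerate(nodes)}
    n = len(nodes)
    ks = _edge_conductances(vg, params.mu)

    p_map = params.p_map * MMHG_TO_PA
    p_cvp = params.p_cvp * MMHG_TO_PA
    g_sink = params.gamma_a / params.mu

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for (i, j), k in ks.items():
        a, b = index[i], index[j]
        rows += [a, b]
        cols += [b, a]
        vals += [-k, -k]
        diag[a] += k
        diag[b] += k
    terminals = vg.terminals
    rhs = np.zeros(n)
    for t in terminals:
        diag[index[t]] += g_sink
        rhs[index[t]] += g_sink * p_cvp
    rows += list(range(n))
    cols += list(range(n))
    vals += list(diag)
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    r = index[vg.root]
    free = np.setdiff1d(np.arange(n), [r])
    A_ff = A[np.ix_(free, free)].tocsc()
    b = rhs[free] - A[np.ix_(free, [r])].toarray().ravel() * p_map
    try:
        p_free = spla.spsolve(A_ff, b)
    except Exception as exc:  # pragma: no cover - pathological systems
        raise SolverError(f"pressure system solve failed: {exc}") from exc
    if not np.all(np.isfinite(p_free)):
        raise SolverError(
            "pressure system is singular; with gamma_a = 0 the network has no "
            "outlet and only the trivial uniform solution exists"
        )
    P = np.empty(n)
    P[free] = p_free
    P[r] = p_map

    pressures = {nodes[k]: float(P[k]) for k in range(n)}
    flows, velocities = {}, {}
    for (i, j), k in ks.items():
        q = k * (pressures[i] - pressures[j])
        flows[(i, j)] = q
        r_edge = vg.g.edges[i, j]["radius_mm"] * MM_TO_M
        velocities[(i, j)] = q / (np.pi * r_edge**2)
    sink_flow = {t: g_sink * (pressures[t] - p_cvp) for t in terminals}
    q_total = float(sum(sink_flow.values()))
    return FlowSolution(
        vg=vg,
        pressures=pressures,
        flows=flows,
        velocities=velocities,
        sink_flow=sink_flow,
        q_total=q_total,
        params=params,
    )


def total_perfusion(sol: FlowSolution) -> float:
    """Total simulated perfusion, mL/min: the summed terminal sink outflux.

    Equals the root influx up to solver round-off (mass conservation).
    """
    return sol.q_total_mlmin


def root_influx(sol: FlowSolution) -> float:
    """Flow entering the network at the root, m^3/s."""
    root = sol.vg.root
    return sum(sol.flow(root, m) for m in sol.vg.g.neighbors(root))


def max_perfusion(vg: VascularGraph, params: FlowParams) -> float:
    """Network-limited perfusion ceiling, mL/min: the gamma_a -> infinity
    limit where every terminal is clamped to the sink pressure."""
    if vg.root is None:
        raise GraphError("graph has no root")
    nodes = vg.nodes
    index = {n: k for k, n in enumerate(nodes)}
    n = len(nodes)
    ks = _edge_conductances(vg, params.mu)
    p_map = params.p_map * MMHG_TO_PA
    p_cvp = params.p_cvp * MMHG_TO_PA

    L = sp.lil_matrix((n, n))
    for (i, j), k in ks.items():
        a, b = index[i], index[j]
        L[a, b] -= k
        L[b, a] -= k
        L[a, a] += k
        L[b, b] += k
    fixed = {index[vg.root]: p_map}
    for t in vg.terminals:
        fixed[index[t]] = p_cvp
    fixed_idx = np.array(sorted(fixed))
    free = np.setdiff1d(np.arange(n), fixed_idx)
    P = np.zeros(n)
    for k, v in fixed.items():
        P[k] = v
    if free.size:
        A = L.tocsr()
        b = -A[np.ix_(free, fixed_idx)] @ P[fixed_idx]
        P[free] = spla.spsolve(A[np.ix_(free, free)].tocsc(), b)
    q = 0.0
    for m in vg.g.neighbors(vg.root):
        key = (vg.root, m) if vg.root < m else (m, vg.root)
        sgn = 1.0 if vg.root < m else -1.0
        q += sgn * ks[key] * (P[index[key[0]]] - P[index[key[1]]])
    return q * M3S_TO_MLMIN
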