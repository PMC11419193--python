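"""Shared fixtures and independent oracles.

Heavy objects (the default synthetic subject and its flow field) are built
once per session; the dense flow oracle and random-graph generator live here
so both the unit suite and the acceptance suite can use them.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from emboflow.config import FlowParams
from emboflow.graph import (
    ROLE_INTERIOR,
    ROLE_ROOT,
    ROLE_TERMINAL,
    VascularGraph,
    classify_nodes,
)
from emboflow.hemodynamics import conductance, solve_pressures
from emboflow.metrics import CalibrationContext
from emboflow.transport import InjectionSpec
from emboflow.units import MM_TO_M, MMHG_TO_PA
from emboflow.volume import CenterlineVolume


def manual_graph(positions_mm, edges, radii_mm, root=0) -> VascularGraph:
    """Hand-built vascular graph: positions (n,3) mm, edge list, node radii."""
    g = nx.Graph()
    positions_mm = np.asarray(positions_mm, dtype=float)
    for n, (pos, r) in enumerate(zip(positions_mm, radii_mm)):
        g.add_node(n, ijk=(n, 0, 0), xyz=pos, radius=float(r))
    for i, j in edges:
        L = float(np.linalg.norm(positions_mm[i] - positions_mm[j]))
        g.add_edge(i, j, length_mm=L, radius_mm=0.5 * (radii_mm[i] + radii_mm[j]))
    vg = VascularGraph(g=g)
    return classify_nodes(vg, root)


def path_graph(n: int, dx_mm: float = 1.0, radius_mm: float = 1.0) -> VascularGraph:
    """Straight pipe of n nodes spaced dx_mm apart."""
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) * dx_mm
    return manual_graph(pos, [(i, i + 1) for i in range(n - 1)], [radius_mm] * n)


def random_tree_graph(rng: np.random.Generator, n_nodes: int, p_extra: float = 0.15) -> VascularGraph:
    """Random connected graph (random tree plus occasional cycle chords)."""
    pos = rng.uniform(0, 50, size=(n_nodes, 3))
    radii = rng.uniform(0.3, 2.0, size=n_nodes)
    edges = [(int(rng.integers(0, i)), i) for i in range(1, n_nodes)]
    for _ in range(int(p_extra * n_nodes)):
        i, j = rng.integers(0, n_nodes, size=2)
        if i != j and (min(i, j), max(i, j)) not in {tuple(sorted(e)) for e in edges}:
            edges.append((int(min(i, j)), int(max(i, j))))
    g = nx.Graph()
    for k in range(n_nodes):
        g.add_node(k, ijk=(k, 0, 0), xyz=pos[k], radius=float(radii[k]))
    for i, j in edges:
        L = float(np.linalg.norm(pos[i] - pos[j]))
        g.add_edge(i, j, length_mm=max(L, 0.1), radius_mm=0.5 * (radii[i] + radii[j]))
    vg = VascularGraph(g=g)
    # root: any degree-1 node (a random tree always has leaves; chords may
    # consume some, so retry until one remains)
    leaves = [m for m in vg.nodes if vg.degree(m) == 1]
    if not leaves:
        return random_tree_graph(rng, n_nodes, p_extra=0.0)
    return classify_nodes(vg, leaves[0])


def dense_flow_oracle(vg: VascularGraph, params: FlowParams) -> dict[int, float]:
    """Independent dense assembly + numpy direct solve of the pressure system."""
    nodes = vg.nodes
    idx = {n: k for k, n in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    b = np.zeros(n)
    p_map = params.p_map * MMHG_TO_PA
    p_cvp = params.p_cvp * MMHG_TO_PA
    for m in nodes:
        k_row = idx[m]
        if vg.g.nodes[m]["role"] == ROLE_ROOT:
            A[k_row, k_row] = 1.0
            b[k_row] = p_map
            continue
        for nb in vg.g.neighbors(m):
            d = vg.g.edges[m, nb]
            kij = conductance(d["radius_mm"] * MM_TO_M, d["length_mm"] * MM_TO_M, params.mu)
            A[k_row, k_row] += kij
            A[k_row, idx[nb]] -= kij
        if vg.g.nodes[m]["role"] == ROLE_TERMINAL:
            A[k_row, k_row] += params.gamma_a / params.mu
            b[k_row] += params.gamma_a / params.mu * p_cvp
    P = np.linalg.solve(A, b)
    return {m: float(P[idx[m]]) for m in nodes}


def checkerboard_volume(shape=(5, 5, 5), spacing=1.0):
    values = np.zeros(shape)
    affine = np.diag([spacing, spacing, spacing, 1.0])
    return values, affine


def make_volume(values, spacing=(1.0, 1.0, 1.0)) -> CenterlineVolume:
    affine = np.diag([*spacing, 1.0])
    return CenterlineVolume(values=np.asarray(values, dtype=float), affine=affine)


@pytest.fixture(scope="session")
def default_subject():
    """The depth-5 study fixture with labels forward-simulated at
    gamma_t_true = 14, delta_true = 1%."""
    from emboflow.synthetic import make_observed, make_subject

    sub = make_subject()
    return make_observed(sub, gamma_t_true=14.0, delta_true=0.01, flip_rate=0.0, seed=0)


@pytest.fixture(scope="session")
def subject_flow(default_subject):
    fp = FlowParams(gamma_a=default_subject.gamma_a)
    return solve_pressures(default_subject.graph, fp)


@pytest.fixture(scope="session")
def subject_ctx(default_subject, subject_flow):
    from emboflow.config import BolusParams
    from emboflow.synthetic import labels_of

    return CalibrationContext(
        vg=default_subject.graph,
        flow=subject_flow,
        bolus=BolusParams(v_dcacl_ul=default_subject.injected_ul),
        labels=labels_of(default_subject),
        injection=InjectionSpec(volume_ul=default_subject.injected_ul),
    )


@pytest.fixture(scope="session")
def pipe_flow():
    """A straight pipe with its flow solution tuned to u ~ 0.1 m/s."""
    n, dx, radius = 301, 0.2, 1.0
    vg = path_graph(n, dx_mm=dx, radius_mm=radius)
    fp = FlowParams()
    u_target = 0.1
    q_target = u_target * np.pi * (radius * MM_TO_M) ** 2
    dp = (fp.p_map - fp.p_cvp) * MMHG_TO_PA
    k_edge = conductance(radius * MM_TO_M, dx * MM_TO_M, fp.mu)
    r_net = (n - 1) / k_edge
    gamma_a = fp.mu / (dp / q_target - r_net)
    fp = FlowParams(gamma_a=gamma_a)
    return vg, solve_pressures(vg, fp)
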