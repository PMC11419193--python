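"""Synthetic vascular trees and forward-simulated observation masks.

Stands in for the imaging products of a real study: a voxelized bifurcating
arterial tree whose voxel values carry the local radius (as a centerline
NIfTI would), and an "observed embolization" mask produced by running the
full forward pipeline at a known ground-truth hydrolysis rate and painting
the tagged nodes back into voxel space, optionally with label-flip noise.
Every pipeline stage is thereby testable without animal data, including
parameter-recovery experiments where the answer is known by construction.

Tree layout is dyadic: generation-g branch endpoints sit at evenly spaced
lateral positions inside disjoint sectors, which guarantees non-adjacent
branches stay apart on the voxel grid; radii follow Murray's law
(r_parent^m = 2 r_child^m with exponent m, symmetric split).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from emboflow.config import BolusParams, FlowParams
from emboflow.errors import RasterizationError
from emboflow.graph import VascularGraph, build_graph, paint_nodes
from emboflow.hemodynamics import solve_pressures
from emboflow.metrics import ObservedLabels
from emboflow.perfusion import calibrate_gamma_a, reference_perfusion
from emboflow.transport import InjectionSpec, simulate, tag_embolization
from emboflow.volume import CenterlineVolume


@dataclass
class TreeSpec:
    """Geometry of a synthetic bifurcating tree.

    ``depth`` is the number of bifurcation generations (2**depth terminals);
    ``murray_exponent`` m sets child radii via r_c = r_p * 2**(-1/m);
    ``length_shrink`` scales the axial advance per generation; ``jitter`` is
    the endpoint position noise amplitude in voxels.
    """

    depth: int = 5
    root_radius: float = 2.5
    trunk_length: float = 20.0
    length_shrink: float = 0.8
    spacing: float = 0.5
    murray_exponent: float = 3.0
    jitter: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.root_radius <= 0 or self.trunk_length <= 0 or self.spacing <= 0:
            raise ValueError("geometry scales must be positive")

    @property
    def child_ratio(self) -> float:
        return 2.0 ** (-1.0 / self.murray_exponent)


@dataclass
class GroundTruthTree:
    """Continuous-geometry truth for round-trip checks against the rebuild."""

    n_terminals: int
    total_length_mm: float
    n_segments: int
    segments: list[dict] = field(repr=False, default_factory=list)


@dataclass
class SyntheticSubject:
    """A complete in-silico study subject."""

    subject_id: str
    weight_kg: float
    injected_ul: float
    volume: CenterlineVolume
    graph: VascularGraph
    truth: GroundTruthTree
    mask: CenterlineVolume | None = None
    gamma_t_true: float | None = None
    delta_true: float | None = None
    flip_rate: float = 0.0
    gamma_a: float | None = None


def _tree_segments(spec: TreeSpec, rng: np.random.Generator) -> list[dict]:
    """Continuous segment list (mm, y-z plane layout embedded in 3D)."""
    width = (2**spec.depth) * 4.0 * spec.spacing  # 4-voxel leaf sectors keep branches apart
    jit = spec.jitter * spec.spacing

    def jittered(p: np.ndarray) -> np.ndarray:
        return p + rng.uniform(-jit, jit, size=2) if jit > 0 else p

    # endpoint of the level-g, branch-b node in (axial, lateral) mm
    x = [0.0, spec.trunk_length]
    for g in range(1, spec.depth + 1):
        x.append(x[-1] + spec.trunk_length * spec.length_shrink**g)

    pts: dict[tuple[int, int], np.ndarray] = {(-1, 0): np.array([x[0], 0.0])}
    pts[(0, 0)] = jittered(np.array([x[1], 0.0]))
    for g in range(1, spec.depth + 1):
        for b in range(2**g):
            y = ((b + 0.5) / 2**g - 0.5) * width
            pts[(g, b)] = jittered(np.array([x[g + 1], y]))

    segments = []
    segments.append(
        {"p0": pts[(-1, 0)], "p1": pts[(0, 0)], "radius": spec.root_radius, "gen": 0,
         "sid": 0, "parent": None}
    )
    sid = 1
    ids: dict[tuple[int, int], int] = {(0, 0): 0}
    for g in range(1, spec.depth + 1):
        r = spec.root_radius * spec.child_ratio**g
        for b in range(2**g):
            parent_key = (g - 1, b // 2)
            segments.append(
                {"p0": pts[parent_key], "p1": pts[(g, b)], "radius": r, "gen": g,
                 "sid": sid, "parent": ids[parent_key]}
            )
            ids[(g, b)] = sid
            sid += 1
    return segments


def make_tree(spec: TreeSpec) -> tuple[CenterlineVolume, GroundTruthTree]:
    """Rasterize a bifurcating tree onto a voxel grid.

    Voxel values carry the local segment radius (mm). Raises
    :class:`RasterizationError` if two branches that are not neighbors in
    the tree end up on adjacent voxels (the rebuild would weld them).
    """
    rng = np.random.default_rng(spec.seed)
    segments = _tree_segments(spec, rng)

    # straight axis-aligned tails at the root and every leaf keep those open
    # ends at voxel degree 1 (diagonal chords at a bend would otherwise make
    # a tip look interior under 26-connectivity)
    tail = np.array([4.0 * spec.spacing, 0.0])
    for s in segments:
        if s["parent"] is None:
            s["pieces"] = [(s["p0"] - tail, s["p0"]), (s["p0"], s["p1"])]
        elif s["gen"] == spec.depth:
            s["pieces"] = [(s["p0"], s["p1"]), (s["p1"], s["p1"] + tail)]
        else:
            s["pieces"] = [(s["p0"], s["p1"])]

    all_pts = np.array(
        [p for s in segments for piece in s["pieces"] for p in piece]
    )
    lo = all_pts.min(axis=0) - 2 * spec.spacing
    hi = all_pts.max(axis=0) + 2 * spec.spacing
    shape2 = np.ceil((hi - lo) / spec.spacing).astype(int) + 1
    nz = 5  # thin slab; the tree lives in the mid-plane
    shape = (int(shape2[0]), int(shape2[1]), nz)
    zmid = nz // 2

    values = np.zeros(shape)
    owner: dict[tuple[int, int, int], int] = {}
    adjacency_ok = _segment_adjacency(segments)

    for s in segments:
        for a, b in s["pieces"]:
            p0 = (a - lo) / spec.spacing
            p1 = (b - lo) / spec.spacing
            n_samp = max(2, int(np.ceil(np.linalg.norm(p1 - p0) * 4)) + 1)
            for t in np.linspace(0.0, 1.0, n_samp):
                q = p0 + t * (p1 - p0)
                ijk = (int(round(q[0])), int(round(q[1])), zmid)
                prev = owner.get(ijk)
                if prev is not None and prev != s["sid"] and \
                        (min(prev, s["sid"]), max(prev, s["sid"])) not in adjacency_ok:
                    raise RasterizationError(
                        f"branches {prev} and {s['sid']} collide at voxel {ijk}; "
                        "use a larger volume or a smaller depth"
                    )
                owner[ijk] = s["sid"]
                values[ijk] = s["radius"]

    _check_clearance(owner, adjacency_ok)

    affine = np.diag([spec.spacing, spec.spacing, spec.spacing, 1.0])
    affine[:3, 3] = [lo[0], lo[1], -zmid * spec.spacing]
    truth = GroundTruthTree(
        n_terminals=2**spec.depth,
        total_length_mm=float(
            sum(np.linalg.norm(b - a) for s in segments for a, b in s["pieces"])
        ),
        n_segments=len(segments),
        segments=segments,
    )
    return CenterlineVolume(values=values, affine=affine), truth


def _segment_adjacency(segments: list[dict]) -> set[tuple[int, int]]:
    """Pairs of segment ids allowed to touch: parent-child and siblings."""
    ok = set()
    children: dict[int, list[int]] = {}
    for s in segments:
        p = s["parent"]
        if p is not None:
            ok.add((min(p, s["sid"]), max(p, s["sid"])))
            children.setdefault(p, []).append(s["sid"])
    for sibs in children.values():
        for a in sibs:
            for b in sibs:
                if a < b:
                    ok.add((a, b))
    return ok


def _check_clearance(owner: dict, adjacency_ok: set) -> None:
    """No two voxels of non-adjacent segments may be 26-neighbors."""
    for (i, j, k), sid in owner.items():
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                other = owner.get((i + di, j + dj, k))
                if other is None or other == sid:
                    continue
                if (min(sid, other), max(sid, other)) not in adjacency_ok:
                    raise RasterizationError(
                        f"branches {sid} and {other} touch at voxel distance 1; "
                        "use a larger volume or a smaller depth"
                    )


def make_subject(
    spec: TreeSpec | None = None,
    subject_id: str = "synthetic-1",
    weight_kg: float = 34.0,
    injected_ul: float = 400.0,
) -> SyntheticSubject:
    """Build a study subject: tree volume, rebuilt graph, metadata."""
    spec = spec or TreeSpec()
    vol, truth = make_tree(spec)
    vg = build_graph(vol)
    return SyntheticSubject(
        subject_id=subject_id,
        weight_kg=weight_kg,
        injected_ul=injected_ul,
        volume=vol,
        graph=vg,
        truth=truth,
    )


def make_observed(
    subject: SyntheticSubject,
    gamma_t_true: float = 14.0,
    delta_true: float = 0.01,
    flip_rate: float = 0.0,
    seed: int = 0,
    flow_params: FlowParams | None = None,
    bolus: BolusParams | None = None,
) -> SyntheticSubject:
    """Forward-simulate an observation mask for a subject.

    Calibrates gamma_a to the subject's mean weight-derived perfusion, runs
    transport at ``gamma_t_true``, tags at ``delta_true``, flips each node
    label with probability ``flip_rate``, and paints the labels into a mask
    volume registered to the centerline. Deterministic given ``seed``.
    """
    if not 0.0 <= flip_rate <= 0.5:
        raise ValueError("flip_rate must lie in [0, 0.5]")
    fp = flow_params or FlowParams()
    if subject.gamma_a is None:
        qref = reference_perfusion(subject.weight_kg)
        subject.gamma_a = calibrate_gamma_a(subject.graph, fp, qref.q_mean).gamma_a
    fp = FlowParams(p_map=fp.p_map, p_cvp=fp.p_cvp, mu=fp.mu, gamma_a=subject.gamma_a)
    flow = solve_pressures(subject.graph, fp)
    bp_dict = dict((bolus or BolusParams()).__dict__)
    bp_dict.update(gamma_t=gamma_t_true, v_dcacl_ul=subject.injected_ul)
    res = simulate(
        subject.graph,
        flow,
        BolusParams(**bp_dict),
        InjectionSpec(volume_ul=subject.injected_ul),
        track_temperature=False,
        tail_closure=True,
    )
    pred = tag_embolization(res, delta_true)

    rng = np.random.default_rng(seed)
    labels = {}
    for n in subject.graph.nodes:
        v = bool(pred.tagged[n])
        if flip_rate > 0 and rng.random() < flip_rate:
            v = not v
        labels[n] = v
    mask_arr = paint_nodes(subject.graph, {n: float(v) for n, v in labels.items()})
    subject.mask = CenterlineVolume(values=mask_arr, affine=subject.volume.affine.copy())
    subject.gamma_t_true = gamma_t_true
    subject.delta_true = delta_true
    subject.flip_rate = flip_rate
    return subject


def labels_of(subject: SyntheticSubject) -> ObservedLabels:
    """Node labels sampled from the subject's observation mask."""
    if subject.mask is None:
        raise ValueError("subject has no observation mask; run make_observed first")
    flat = subject.mask.values.ravel()
    return ObservedLabels(label={n: bool(flat[n] > 0.5) for n in subject.graph.nodes})
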