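"""Prediction scoring against observed Lipiodol labels, and gamma_t calibration.

The post-treatment CT shows where Lipiodol lodged in the vasculature; mapped
onto the graph nodes it gives a binary observation per node. Predicted
embolization sites (damage >= delta) are scored against it with a confusion
matrix and recall / precision / balanced accuracy. The hydrolysis time
constant gamma_t is calibrated by minimizing

    g(gamma_t, delta) = beta(gamma_t) + (1 - alpha(gamma_t, delta))

i.e. the escaped unreacted fraction plus the balanced-accuracy shortfall,
with multi-start Nelder-Mead (starts drawn uniformly in (10, 20) 1/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from emboflow.config import BolusParams
from emboflow.errors import CalibrationError, FormatError
from emboflow.graph import ROLE_ROOT, VascularGraph
from emboflow.hemodynamics import FlowSolution
from emboflow.transport import EmbolizationPrediction, InjectionSpec, simulate, tag_embolization
from emboflow.volume import CenterlineVolume


@dataclass
class ObservedLabels:
    """Binary observation per graph node: Lipiodol present post-treatment."""

    label: dict[int, bool]


@dataclass
class ClassificationReport:
    """Confusion-matrix counts and derived metrics.

    Ratios with zero denominator are undefined and reported as ``None``;
    balanced accuracy then averages only the defined of sensitivity and
    specificity.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def recall(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def balanced_accuracy(self) -> float | None:
        parts = [p for p in (self.recall, self.specificity) if p is not None]
        return float(np.mean(parts)) if parts else None

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "recall": self.recall,
            "precision": self.precision,
            "balanced_accuracy": self.balanced_accuracy,
        }


def labels_from_mask(
    vg: VascularGraph, mask: CenterlineVolume, threshold: float = 0.5
) -> ObservedLabels:
    """Sample a registered binary mask at each node's voxel.

    The mask must live in the graph's voxel space (same shape; same affine
    when both are known).
    """
    if vg.shape is not None and tuple(mask.values.shape) != tuple(vg.shape):
        raise FormatError(
            f"mask shape {mask.values.shape} does not match graph volume shape {vg.shape}"
        )
    if vg.affine is not None and not np.allclose(mask.affine, vg.affine, atol=1e-6):
        raise FormatError("mask affine does not match the graph's source affine")
    flat = mask.values.ravel()
    return ObservedLabels(label={n: bool(flat[n] > threshold) for n in vg.nodes})


def score(
    pred: EmbolizationPrediction, obs: ObservedLabels, vg: VascularGraph | None = None
) -> ClassificationReport:
    """Confusion matrix of predicted vs observed embolization sites.

    All graph nodes enter except the root (the injection node reacts
    trivially). When no graph is given, every node present in the
    prediction is scored.
    """
    nodes = list(pred.tagged)
    exclude = set()
    if vg is not None:
        exclude = {n for n in vg.nodes if vg.g.nodes[n].get("role") == ROLE_ROOT}
    tp = fp = tn = fn = 0
    for n in nodes:
        if n in exclude:
            continue
        p, o = pred.tagged[n], obs.label[n]
        if p and o:
            tp += 1
        elif p and not o:
            fp += 1
        elif not p and o:
            fn += 1
        else:
            tn += 1
    return ClassificationReport(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass
class CalibrationContext:
    """Everything objective_g needs: graph, flow field, bolus and labels."""

    vg: VascularGraph
    flow: FlowSolution
    bolus: BolusParams
    labels: ObservedLabels
    injection: InjectionSpec | None = None
    courant: float = 0.5
    _cache: dict = field(default_factory=dict, repr=False)


def objective_g(gamma_t: float, delta: float, ctx: CalibrationContext) -> float:
    """g = beta + (1 - alpha) at a given hydrolysis rate and tagging threshold."""
    res = simulate_at(ctx, gamma_t)
    pred = tag_embolization(res, delta)
    rep = score(pred, ctx.labels, ctx.vg)
    alpha = rep.balanced_accuracy
    if alpha is None:
        alpha = 0.0
    return res.beta + (1.0 - alpha)


def simulate_at(ctx: CalibrationContext, gamma_t: float):
    """Transport run at a candidate gamma_t, memoized per context."""
    key = round(float(gamma_t), 10)
    if key not in ctx._cache:
        bp = BolusParams(**{**ctx.bolus.__dict__, "gamma_t": float(gamma_t)})
        ctx._cache[key] = simulate(
            ctx.vg,
            ctx.flow,
            bp,
            ctx.injection,
            courant=ctx.courant,
            track_temperature=False,
            tail_closure=True,
        )
    return ctx._cache[key]


@dataclass
class ReactionCalibration:
    """Result of the multi-start gamma_t search."""

    gamma_t: float
    g: float
    starts: list[dict]
    seed: int | None

    @property
    def n_starts(self) -> int:
        return len(self.starts)


def calibrate_gamma_t(
    ctx: CalibrationContext,
    delta: float,
    n_starts: int = 10,
    seed: int | None = 0,
    bounds: tuple[float, float] = (10.0, 20.0),
    xatol: float = 1e-3,
) -> ReactionCalibration:
    """Multi-start Nelder-Mead minimization of g(gamma_t, delta).

    ``n_starts`` initial guesses are drawn uniformly in ``bounds`` from a
    seeded generator; each local search runs independently and the best
    converged optimum wins. All starts are returned for audit.
    """
    if n_starts < 1:
        raise ValueError("need at least one start")
    rng = np.random.default_rng(seed)
    starts = rng.uniform(bounds[0], bounds[1], size=n_starts)

    records = []
    for x0 in starts:
        try:
            res = minimize(
                lambda x: objective_g(max(float(x[0]), 1e-6), delta, ctx),
                np.asarray([x0]),
                method="Nelder-Mead",
                options={"xatol": xatol, "fatol": 1e-9, "maxiter": 200},
            )
            records.append(
                {"start": float(x0), "gamma_t": max(float(res.x[0]), 1e-6), "g": float(res.fun)}
            )
        except Exception as exc:
            records.append({"start": float(x0), "error": str(exc)})
    ok = [r for r in records if "gamma_t" in r]
    if not ok:
        raise CalibrationError("every gamma_t start failed")
    best = min(ok, key=lambda r: (r["g"], r["gamma_t"]))
    return ReactionCalibration(gamma_t=best["gamma_t"], g=best["g"], starts=records, seed=seed)
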