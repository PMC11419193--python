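"""Uncertainty grids, correlations, and leave-one-out cross-validation.

Neither the reference perfusion q_ref nor the tagging threshold delta is
known precisely for a subject, so the calibration is repeated over a grid of
plausible (q_ref, delta) combinations: for every q_ref the terminal
conductance gamma_a is re-calibrated, then the hydrolysis time constant
gamma_t is optimized per cell. Pearson correlations of the per-cell optimal
gamma_t against q_ref and delta quantify which input drives the calibrated
parameter. Across subjects, leave-one-out cross-validation transfers the
mean of the other subjects' optimal gamma_t to the held-out subject and
scores its predictions against its own observed labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from emboflow.config import BolusParams, FlowParams
from emboflow.graph import VascularGraph
from emboflow.hemodynamics import solve_pressures
from emboflow.metrics import (
    CalibrationContext,
    simulate_at,
    ClassificationReport,
    ObservedLabels,
    calibrate_gamma_t,
    score,
)
from emboflow.perfusion import PerfusionReference, calibrate_gamma_a, reference_perfusion
from emboflow.transport import InjectionSpec, simulate, tag_embolization


@dataclass
class SubjectRecord:
    """One study subject: metadata, graph, observed labels, perfusion band."""

    subject_id: str
    weight_kg: float
    injected_ul: float
    graph: VascularGraph
    labels: ObservedLabels
    qref: PerfusionReference = None

    def __post_init__(self) -> None:
        if self.qref is None:
            self.qref = reference_perfusion(self.weight_kg)

    @classmethod
    def from_synthetic(cls, subject) -> "SubjectRecord":
        from emboflow.synthetic import labels_of

        return cls(
            subject_id=subject.subject_id,
            weight_kg=subject.weight_kg,
            injected_ul=subject.injected_ul,
            graph=subject.graph,
            labels=labels_of(subject),
        )


@dataclass
class UncertaintyGrid:
    """Per-cell calibration results over the (q_ref, delta) grid."""

    subject_id: str
    cells: pd.DataFrame
    seed: int

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def correlations(self) -> dict[str, float]:
        ok = self.cells.dropna(subset=["gamma_t"])
        return {
            "r_qref_gammat": pearson(ok["qref"].to_numpy(), ok["gamma_t"].to_numpy()),
            "r_delta_gammat": pearson(ok["delta"].to_numpy(), ok["gamma_t"].to_numpy()),
        }


def _cell_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def run_uncertainty(
    subject: SubjectRecord,
    seed: int = 0,
    n_qref: int = 10,
    n_delta: int = 10,
    flow_params: FlowParams | None = None,
    bolus: BolusParams | None = None,
    n_starts: int = 10,
) -> UncertaintyGrid:
    """Populate the full (q_ref, delta) calibration grid for one subject.

    q_ref values are evenly spaced over the subject's [q_min, q_max] band
    (endpoints inclusive); delta spans 1%..10% inclusive. gamma_a is
    calibrated once per q_ref and shared across that row's delta cells.
    Per-cell failures are recorded as NaN rows and the grid continues.
    """
    fp = flow_params or FlowParams()
    bp = bolus or BolusParams()
    qrefs = np.linspace(subject.qref.q_min, subject.qref.q_max, n_qref)
    deltas = np.linspace(0.01, 0.10, n_delta)
    seeds = _cell_seeds(seed, n_qref * n_delta)

    rows = []
    k = 0
    for qref in qrefs:
        try:
            cal_a = calibrate_gamma_a(subject.graph, fp, float(qref))
            flow = solve_pressures(subject.graph, cal_a.params(fp))
            ctx = CalibrationContext(
                vg=subject.graph,
                flow=flow,
                bolus=BolusParams(**{**bp.__dict__, "v_dcacl_ul": subject.injected_ul}),
                labels=subject.labels,
                injection=InjectionSpec(volume_ul=subject.injected_ul),
            )
        except Exception as exc:
            for delta in deltas:
                rows.append(_nan_row(qref, delta, error=f"gamma_a: {exc}"))
                k += 1
            continue
        for delta in deltas:
            try:
                cal_t = calibrate_gamma_t(ctx, float(delta), n_starts=n_starts, seed=seeds[k])
                res = simulate_at(ctx, cal_t.gamma_t)
                rep = score(tag_embolization(res, float(delta)), subject.labels, subject.graph)
                alpha = rep.balanced_accuracy
                rows.append(
                    {
                        "qref": float(qref),
                        "delta": float(delta),
                        "gamma_a": cal_a.gamma_a,
                        "q_calc": cal_a.q_calc_mlmin,
                        "gamma_t": cal_t.gamma_t,
                        "alpha": alpha,
                        "beta": res.beta,
                        "g": cal_t.g,
                        "error": None,
                    }
                )
            except Exception as exc:
                rows.append(_nan_row(qref, delta, error=f"gamma_t: {exc}"))
            k += 1
    return UncertaintyGrid(subject_id=subject.subject_id, cells=pd.DataFrame(rows), seed=seed)


def _nan_row(qref: float, delta: float, error: str) -> dict:
    return {
        "qref": float(qref),
        "delta": float(delta),
        "gamma_a": np.nan,
        "q_calc": np.nan,
        "gamma_t": np.nan,
        "alpha": np.nan,
        "beta": np.nan,
        "g": np.nan,
        "error": error,
    }


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    return float(scipy.stats.pearsonr(x, y).statistic)


def loocv_mean_of_others(gamma_ts: list[float]) -> list[float]:
    """Held-out parameter per subject: arithmetic mean of the others' optima."""
    if len(gamma_ts) < 2:
        raise ValueError("need at least 2 subjects")
    arr = np.asarray(gamma_ts, dtype=float)
    return [float((arr.sum() - v) / (arr.size - 1)) for v in arr]


@dataclass
class LoocvSubjectResult:
    subject_id: str
    gamma_t_opt: float
    gamma_t_loocv: float
    report_opt: ClassificationReport
    report_loocv: ClassificationReport


@dataclass
class LoocvReport:
    results: list[LoocvSubjectResult]
    mean_balanced_accuracy: float
    delta: float


def loocv(
    subjects: list[SubjectRecord],
    delta: float = 0.01,
    seed: int = 0,
    flow_params: FlowParams | None = None,
    bolus: BolusParams | None = None,
    n_starts: int = 10,
) -> LoocvReport:
    """Leave-one-out cross-validation across subjects.

    Each subject's own optimal gamma_t is found at its mean weight-derived
    perfusion (gamma_a calibrated there) and the given delta. The held-out
    prediction for a subject uses the mean of the other subjects' optima;
    both the own-optimal and held-out classification reports are returned.
    The aggregate is the mean held-out balanced accuracy.
    """
    if len(subjects) < 2:
        raise ValueError("LOOCV needs at least 2 subjects")
    fp = flow_params or FlowParams()
    bp = bolus or BolusParams()
    seeds = _cell_seeds(seed, len(subjects))

    contexts, opt_gamma, opt_reports = [], [], []
    for s, s_seed in zip(subjects, seeds):
        cal_a = calibrate_gamma_a(s.graph, fp, s.qref.q_mean)
        flow = solve_pressures(s.graph, cal_a.params(fp))
        ctx = CalibrationContext(
            vg=s.graph,
            flow=flow,
            bolus=BolusParams(**{**bp.__dict__, "v_dcacl_ul": s.injected_ul}),
            labels=s.labels,
            injection=InjectionSpec(volume_ul=s.injected_ul),
        )
        cal_t = calibrate_gamma_t(ctx, delta, n_starts=n_starts, seed=s_seed)
        res = simulate_at(ctx, cal_t.gamma_t)
        opt_reports.append(score(tag_embolization(res, delta), s.labels, s.graph))
        contexts.append(ctx)
        opt_gamma.append(cal_t.gamma_t)

    heldout_gamma = loocv_mean_of_others(opt_gamma)
    results = []
    accs = []
    for s, ctx, g_opt, g_cv, rep_opt in zip(
        subjects, contexts, opt_gamma, heldout_gamma, opt_reports
    ):
        bp_cv = BolusParams(**{**ctx.bolus.__dict__, "gamma_t": g_cv})
        res = simulate(
            s.graph, ctx.flow, bp_cv, ctx.injection,
            track_temperature=False, tail_closure=True,
        )
        rep_cv = score(tag_embolization(res, delta), s.labels, s.graph)
        results.append(
            LoocvSubjectResult(
                subject_id=s.subject_id,
                gamma_t_opt=g_opt,
                gamma_t_loocv=g_cv,
                report_opt=rep_opt,
                report_loocv=rep_cv,
            )
        )
        if rep_cv.balanced_accuracy is not None:
            accs.append(rep_cv.balanced_accuracy)
    return LoocvReport(
        results=results,
        mean_balanced_accuracy=float(np.mean(accs)) if accs else float("nan"),
        delta=delta,
    )


def plot_grid(grid: UncertaintyGrid, value: str = "gamma_t", path: str | None = None):
    """Heatmap of a grid quantity over (q_ref, delta). Returns the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    piv = grid.cells.pivot_table(index="qref", columns="delta", values=value)
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(piv.to_numpy(), origin="lower", aspect="auto", cmap="viridis",
                   extent=[piv.columns.min(), piv.columns.max(), piv.index.min(), piv.index.max()])
    ax.set_xlabel("delta (damage threshold)")
    ax.set_ylabel("q_ref (mL/min)")
    ax.set_title(f"{grid.subject_id}: {value}")
    fig.colorbar(im, ax=ax, label=value)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
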