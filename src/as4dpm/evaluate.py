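"""Scenario assembly, prediction-error metrics, baseline drift and the
matching-parameter grid report.

Four model-construction scenarios are compared on one acquisition:

* ``CL`` — clinical reference: per-frame triangulated target positions.
* ``4D-CBCT`` — targets replaced by the tiled phase-sorted short-arc cycle.
* ``AS-4D-CBCT-dual`` — the tiled cycle corrected by the dual-imager shroud
  waveform.
* ``AS-4D-CBCT-single1`` / ``-single2`` — same, shroud from one imager only.

Models are fitted on the training window (default the first 60 s) and
evaluated on the held-out window (default the remaining 10 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Waveform
from .correction import (
    MatchingParams,
    PERCENTILE_CANDIDATES,
    WINDOW_CANDIDATES,
    correct_waveform,
)
from .geometry import triangulate_many
from .model import PMParameters, fit_pm, predict
from .shroud import shroud_waveform
from .simulate import SyntheticCase
from .waveform import (
    CycleSegmentation,
    TEST_SLICE,
    TRAIN_SLICE,
    detect_local_minima,
    phase_sort,
    tile_waveform,
)

__all__ = [
    "SCENARIOS",
    "ErrorMetrics",
    "ScenarioResult",
    "DriftReport",
    "PreparedCase",
    "prepare_case",
    "run_scenario",
    "error_metrics",
    "baseline_drift",
    "parameter_grid_report",
    "GridReport",
]

SCENARIOS = (
    "CL",
    "4D-CBCT",
    "AS-4D-CBCT-dual",
    "AS-4D-CBCT-single1",
    "AS-4D-CBCT-single2",
)


@dataclass(frozen=True)
class ErrorMetrics:
    """Prediction-error summary over one evaluation window."""

    rmse_mm: np.ndarray  # per direction (LR, SI, AP)
    rmse_3d_mm: float
    pct_within_mm: float  # % of frames with 3D error below the threshold
    threshold_mm: float
    errors_3d_mm: np.ndarray  # per-frame Euclidean error


@dataclass(frozen=True)
class ScenarioResult:
    scenario: str
    predicted: Waveform
    actual: Waveform
    metrics: ErrorMetrics
    train_metrics: ErrorMetrics
    pm: PMParameters
    window_label: str = "short-term"


@dataclass(frozen=True)
class DriftReport:
    """Baseline drift of the averaged IR trace between two windows.

    ``BL = (MED_ex + MED_in) / 2`` per window; positive drift = posterior.
    """

    bl_train: float
    bl_test: float
    med_ex_train: float
    med_in_train: float
    med_ex_test: float
    med_in_test: float

    @property
    def drift_mm(self) -> float:
        return self.bl_test - self.bl_train


def error_metrics(
    pred: Waveform,
    actual: Waveform,
    threshold_mm: float = 3.0,
    *,
    strict: bool = True,
) -> ErrorMetrics:
    """Per-direction RMSE, 3D RMSE and the %-within-threshold passing rate.

    The passing rate uses a strict ``<`` comparison by default ("within
    3 mm" read exclusively); set ``strict=False`` for ``<=``.
    """
    p = pred.values if pred.is_3d else pred.values[:, None]
    a = actual.values if actual.is_3d else actual.values[:, None]
    if p.shape != a.shape:
        raise ValueError("prediction and truth must have identical shapes")
    if p.shape[0] == 0:
        raise ValueError("empty evaluation window")
    diff = p - a
    rmse = np.sqrt(np.mean(diff**2, axis=0))
    err3d = np.linalg.norm(diff, axis=1)
    rmse3d = float(np.sqrt(np.mean(err3d**2)))
    within = err3d < threshold_mm if strict else err3d <= threshold_mm
    return ErrorMetrics(
        rmse_mm=rmse,
        rmse_3d_mm=rmse3d,
        pct_within_mm=100.0 * float(np.mean(within)),
        threshold_mm=threshold_mm,
        errors_3d_mm=err3d,
    )


@dataclass
class PreparedCase:
    """Per-case intermediates shared by all scenarios and grid cells."""

    case: SyntheticCase
    w_gm: Waveform  # triangulated per-frame target positions
    seg: CycleSegmentation  # IR minima in the training window
    w_4d: Waveform  # tiled short-arc waveform on the training window
    shroud: dict = field(default_factory=dict)  # variant -> ASWaveform samples
    train: slice = field(default_factory=lambda: TRAIN_SLICE)
    test: slice = field(default_factory=lambda: TEST_SLICE)


def prepare_case(
    case: SyntheticCase,
    *,
    train: slice = TRAIN_SLICE,
    test: slice = TEST_SLICE,
    shrink_4d: float = 1.0,
    min_separation: float = 2.0,
    prominence: float | None = None,
) -> PreparedCase:
    """Triangulate, segment and tile once per case.

    ``shrink_4d`` optionally contracts the tiled short-arc waveform about its
    mean, emulating the amplitude underestimation of low temporal resolution
    phase-sorted reconstructions.
    """
    angles = case.schedule.angles
    if len(case.fiducial_detections) >= 2:
        w_gm = Waveform(
            triangulate_many(
                case.fiducial_detections[0],
                case.fiducial_detections[1],
                angles,
                case.imagers[:2],
            )
        )
    else:
        w_gm = case.true_target
    ir_avg = case.ir_centroid
    seg = detect_local_minima(
        ir_avg.window(train),
        min_separation=min_separation,
        prominence=prominence,
    )
    n_train = len(ir_avg.window(train))
    cycle = phase_sort(w_gm.window(train), seg)
    w_4d = tile_waveform(cycle, seg, n_train)
    if shrink_4d != 1.0:
        mean = w_4d.values.mean(axis=0)
        w_4d = Waveform(mean + shrink_4d * (w_4d.values - mean), dt=w_4d.dt)
    return PreparedCase(
        case=case, w_gm=w_gm, seg=seg, w_4d=w_4d, train=train, test=test
    )


def _shroud_samples(prep: PreparedCase, scenario: str) -> np.ndarray:
    """Shroud waveform samples on the training window, cached per variant."""
    if scenario not in prep.shroud:
        case = prep.case
        if scenario == "AS-4D-CBCT-dual":
            if len(case.projections) < 2:
                raise ValueError("dual-imager scenario requires two stacks")
            w = shroud_waveform(case.projections)
        elif scenario == "AS-4D-CBCT-single1":
            w = shroud_waveform(case.projections[0])
        elif scenario == "AS-4D-CBCT-single2":
            if len(case.projections) < 2:
                raise ValueError("imager 2 not available")
            w = shroud_waveform(case.projections[1])
        else:
            raise ValueError(f"unknown shroud scenario {scenario!r}")
        prep.shroud[scenario] = np.asarray(w.samples, dtype=float)
    start, stop, _ = prep.train.indices(len(prep.shroud[scenario]))
    return prep.shroud[scenario][start:stop]


def run_scenario(
    case: SyntheticCase | PreparedCase,
    scenario: str,
    *,
    matching: MatchingParams | None = None,
    train: slice = TRAIN_SLICE,
    test: slice = TEST_SLICE,
    shrink_4d: float = 1.0,
    threshold_mm: float = 3.0,
    eval_case: SyntheticCase | None = None,
    window_label: str | None = None,
) -> ScenarioResult:
    """Fit the scenario's model on the training window and evaluate it.

    ``eval_case`` switches evaluation to a different acquisition (long-term
    evaluation on a later session); otherwise the held-out ``test`` window of
    the same case is used.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected {SCENARIOS}")
    if isinstance(case, PreparedCase):
        prep = case
    else:
        prep = prepare_case(case, train=train, test=test, shrink_4d=shrink_4d)
    train, test = prep.train, prep.test
    ir = prep.case.ir_traces
    if matching is None:
        matching = MatchingParams()

    if scenario == "CL":
        target_train = prep.w_gm.window(train)
    elif scenario == "4D-CBCT":
        target_train = prep.w_4d
    else:
        samples = _shroud_samples(prep, scenario)
        target_train = correct_waveform(prep.w_4d, samples, matching).waveform

    ir_train = [t.window(train) for t in ir]
    pm = fit_pm(ir_train, target_train)
    train_pred = predict(pm, ir_train)
    train_metrics = error_metrics(
        train_pred, prep.w_gm.window(train), threshold_mm
    )

    if eval_case is not None:
        ir_eval = eval_case.ir_traces
        actual = eval_case.true_target
        label = window_label or "long-term"
    else:
        ir_eval = [t.window(test) for t in ir]
        actual = prep.w_gm.window(test)
        label = window_label or "short-term"
    predicted = predict(pm, ir_eval)
    metrics = error_metrics(predicted, actual, threshold_mm)
    return ScenarioResult(
        scenario=scenario,
        predicted=predicted,
        actual=actual,
        metrics=metrics,
        train_metrics=train_metrics,
        pm=pm,
        window_label=label,
    )


def baseline_drift(
    ir_avg_train: Waveform,
    ir_avg_test: Waveform,
    *,
    min_separation: float = 2.0,
    prominence: float | None = None,
) -> DriftReport:
    """Eq.-style baseline statistic of the averaged IR trace per window.

    ``MED_in``/``MED_ex`` are the medians of the trace values at its local
    minima (end-inhalation) and maxima (end-exhalation); the baseline is
    their midpoint and the drift the between-window baseline difference.
    """

    def _bl(w: Waveform) -> tuple[float, float, float]:
        mins = detect_local_minima(
            w, min_separation=min_separation, prominence=prominence
        )
        maxs = detect_local_minima(
            Waveform(-w.values, dt=w.dt),
            min_separation=min_separation,
            prominence=prominence,
        )
        med_in = float(np.median(w.values[mins.t_lm]))
        med_ex = float(np.median(w.values[maxs.t_lm]))
        return 0.5 * (med_ex + med_in), med_ex, med_in

    bl_train, ex_tr, in_tr = _bl(ir_avg_train)
    bl_test, ex_te, in_te = _bl(ir_avg_test)
    return DriftReport(
        bl_train=bl_train,
        bl_test=bl_test,
        med_ex_train=ex_tr,
        med_in_train=in_tr,
        med_ex_test=ex_te,
        med_in_test=in_te,
    )


@dataclass(frozen=True)
class GridReport:
    """Exhaustive matching-parameter grid of pooled %-within-threshold."""

    table: pd.DataFrame  # index: window frames; columns: (P_upper, P_lower)
    best_window: int
    best_percentiles: tuple[float, float]

    @property
    def best_params(self) -> MatchingParams:
        return MatchingParams(
            p_upper=self.best_percentiles[0],
            p_lower=self.best_percentiles[1],
            window=self.best_window,
        )


def parameter_grid_report(
    cases: list[SyntheticCase | PreparedCase],
    *,
    percentile_candidates: tuple = PERCENTILE_CANDIDATES,
    window_candidates: tuple = WINDOW_CANDIDATES,
    scenario: str = "AS-4D-CBCT-dual",
    shrink_4d: float = 1.0,
    threshold_mm: float = 3.0,
) -> GridReport:
    """Evaluate every (window, percentile-pair) cell over the given cases.

    The passing rate pools frames across cases.  The reported optimum is the
    grid argmax; ties break toward the smaller window, then the wider
    percentile span.
    """
    if not cases:
        raise ValueError("need at least one case")
    prepared = [
        c
        if isinstance(c, PreparedCase)
        else prepare_case(c, shrink_4d=shrink_4d)
        for c in cases
    ]
    table = pd.DataFrame(
        index=pd.Index(window_candidates, name="window_frames"),
        columns=pd.MultiIndex.from_tuples(
            percentile_candidates, names=["P_upper", "P_lower"]
        ),
        dtype=float,
    )
    for w in window_candidates:
        for hi, lo in percentile_candidates:
            params = MatchingParams(p_upper=hi, p_lower=lo, window=w)
            hits = total = 0
            for prep in prepared:
                res = run_scenario(
                    prep, scenario, matching=params, threshold_mm=threshold_mm
                )
                err = res.metrics.errors_3d_mm
                hits += int(np.sum(err < threshold_mm))
                total += len(err)
            table.loc[w, (hi, lo)] = 100.0 * hits / total

    best_val = -np.inf
    best = (window_candidates[0], percentile_candidates[0])
    for w in sorted(window_candidates):
        for hi, lo in sorted(
            percentile_candidates, key=lambda p: -(p[0] - p[1])
        ):
            val = table.loc[w, (hi, lo)]
            if val > best_val + 1e-12:
                best_val, best = val, (w, (hi, lo))
    return GridReport(
        table=table, best_window=best[0], best_percentiles=best[1]
    )
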