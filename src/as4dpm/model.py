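"""Quadratic position-velocity regression between surrogate and target.

The model per target direction is ``F(x, v) = a x^2 + b x + c + d v^2 + e v``
where ``x`` and ``v`` are the AP position and velocity of the external IR
surrogate.  One model is fitted per IR marker by ordinary least squares; the
representative model averages the per-marker coefficients, and prediction
feeds the across-marker mean position/velocity into it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Waveform

__all__ = ["PMParameters", "compute_velocity", "fit_pm", "predict"]

_COEFF_NAMES = ("a", "b", "c", "d", "e")


@dataclass(frozen=True)
class PMParameters:
    """Fitted prediction-model coefficients.

    ``coefficients`` has shape ``(5, n_dirs)`` with rows ordered (a, b, c,
    d, e); ``per_marker`` retains each IR marker's individual fit.  The
    representative set is the element-wise mean across markers.
    """

    coefficients: np.ndarray  # (5, n_dirs)
    per_marker: np.ndarray  # (n_markers, 5, n_dirs)
    n_markers: int

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        p = np.asarray(self.per_marker, dtype=float)
        if c.shape[0] != 5 or p.shape[1] != 5:
            raise ValueError("expected 5 coefficients (a, b, c, d, e)")
        if not (np.all(np.isfinite(c)) and np.all(np.isfinite(p))):
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "coefficients", c)
        object.__setattr__(self, "per_marker", p)

    def to_dict(self) -> dict:
        return {
            "n_markers": self.n_markers,
            "representative": {
                name: self.coefficients[i].tolist()
                for i, name in enumerate(_COEFF_NAMES)
            },
            "per_marker": self.per_marker.tolist(),
        }


def compute_velocity(x: Waveform | np.ndarray, dt: float | None = None) -> np.ndarray:
    """Velocity in mm/s by central differences (one-sided at the ends)."""
    if isinstance(x, Waveform):
        vals, dt = x.values, x.dt
    else:
        vals = np.asarray(x, dtype=float)
        if dt is None:
            raise ValueError("dt required for plain arrays")
    if vals.ndim != 1:
        raise ValueError("velocity is computed per scalar trace")
    if len(vals) < 3:
        raise ValueError("need at least three samples")
    return np.gradient(vals, dt)


def _design(x: np.ndarray, v: np.ndarray) -> np.ndarray:
    return np.column_stack([x**2, x, np.ones_like(x), v**2, v])


def _check_rank(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        x, v = X[:, 1], X[:, 4]
        degenerate = []
        if np.std(x) == 0:
            degenerate.append("position x")
        if np.std(v) == 0:
            degenerate.append("velocity v")
        what = " and ".join(degenerate) if degenerate else "design matrix"
        raise ValueError(f"rank-deficient regression: constant {what}")


def fit_pm(ir_traces: list[Waveform], target: Waveform) -> PMParameters:
    """Fit the quadratic model per IR marker and average the coefficients.

    Each marker's AP trace (position and central-difference velocity) is
    regressed onto every target direction by plain OLS; the representative
    parameter set is the across-marker mean.
    """
    if not ir_traces:
        raise ValueError("need at least one IR trace")
    tvals = target.values if target.is_3d else target.values[:, None]
    n = tvals.shape[0]
    if n < 5:
        raise ValueError("need at least 5 samples to fit 5 parameters")
    per_marker = []
    for trace in ir_traces:
        if trace.n_frames != n:
            raise ValueError("IR traces and target must share the time grid")
        x = trace.values
        v = compute_velocity(trace)
        X = _design(x, v)
        _check_rank(X)
        coeffs, *_ = np.linalg.lstsq(X, tvals, rcond=None)
        per_marker.append(coeffs)
    per_marker = np.asarray(per_marker)
    return PMParameters(
        coefficients=per_marker.mean(axis=0),
        per_marker=per_marker,
        n_markers=len(ir_traces),
    )


def predict(pm: PMParameters, ir_traces: list[Waveform]) -> Waveform:
    """Predict target positions from the averaged IR input.

    The across-marker mean position and velocity are fed to the
    representative model.  A marker count different from fit time is allowed
    (the model only consumes the averaged input).
    """
    if not ir_traces:
        raise ValueError("need at least one IR trace")
    x = np.mean([t.values for t in ir_traces], axis=0)
    v = np.mean([compute_velocity(t) for t in ir_traces], axis=0)
    pred = _design(x, v) @ pm.coefficients
    if pred.shape[1] == 1:
        pred = pred[:, 0]
    return Waveform(pred, dt=ir_traces[0].dt, t0=ir_traces[0].t0)
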