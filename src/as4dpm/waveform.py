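"""Cycle segmentation, 8-phase sorting and waveform tiling.

This is the short-arc 4D-CBCT simulation chain: end-inhalation local minima
segment the surrogate trace into breathing cycles; the gold-marker waveform
is resampled into 8 respiratory phase bins and averaged across cycles (the
phase-sorted short-arc cycle); tiling stretches that single averaged cycle
back over every observed cycle to produce a full-length, low temporal
resolution target waveform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

from .core import FRAME_DT, Waveform
from .shroud import ASWaveform

__all__ = [
    "CycleSegmentation",
    "PhaseBinnedCycle",
    "ASAveragedCycle",
    "detect_local_minima",
    "phase_sort",
    "tile_waveform",
    "average_as_cycle",
]

#: Default training window: the first 60 s of a 70 s acquisition.
TRAIN_SLICE = slice(0, 302)
#: Default testing window: the remaining 10 s.
TEST_SLICE = slice(302, None)


@dataclass(frozen=True)
class CycleSegmentation:
    """End-inhalation minima of a surrogate trace, in frame indices."""

    t_lm: np.ndarray  # strictly increasing frame indices
    dt: float = FRAME_DT

    def __post_init__(self) -> None:
        t = np.asarray(self.t_lm, dtype=int)
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("need at least two detected minima")
        if np.any(np.diff(t) <= 0):
            raise ValueError("minima indices must be strictly increasing")
        object.__setattr__(self, "t_lm", t)

    @property
    def n(self) -> int:
        return len(self.t_lm)

    @property
    def t_mean(self) -> float:
        """Mean breathing-cycle length in frames."""
        return float(np.mean(np.diff(self.t_lm)))


@dataclass(frozen=True)
class PhaseBinnedCycle:
    """Per-phase mean positions: one averaged breathing cycle.

    ``values`` has shape ``(n_phases,)`` or ``(n_phases, 3)``; phase 0 is
    end-inhalation and bins advance by 1/n_phases of a cycle.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] < 2:
            raise ValueError("need at least two phase bins")
        if not np.all(np.isfinite(v)):
            raise ValueError("phase-bin values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n_phases(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ASAveragedCycle:
    """Cycle-averaged shroud waveform and its tiled full-length version."""

    cycle: np.ndarray  # (n_points,)
    tiled: Waveform


def detect_local_minima(
    trace: Waveform | np.ndarray,
    min_separation: float = 2.0,
    prominence: float | None = None,
    *,
    frame_range: slice | None = None,
    dt: float = FRAME_DT,
) -> CycleSegmentation:
    """Detect end-inhalation local minima of a surrogate trace.

    Minima must be at least ``min_separation`` seconds apart and have at
    least ``prominence`` depth (default: 20 % of the trace interquartile
    range, making the detector amplitude-scale free).  ``frame_range``
    restricts detection, e.g. to the training window.
    """
    if isinstance(trace, Waveform):
        x = trace.values
        dt = trace.dt
    else:
        x = np.asarray(trace, dtype=float)
    if x.ndim != 1:
        raise ValueError("minima detection expects a scalar trace")
    offset = 0
    if frame_range is not None:
        start, stop, step = frame_range.indices(len(x))
        if step != 1:
            raise ValueError("frame_range must be contiguous")
        x = x[start:stop]
        offset = start
    distance = max(1, int(round(min_separation / dt)))
    if len(x) < 2 * distance:
        raise ValueError("trace too short for the requested separation")
    if prominence is None:
        q75, q25 = np.percentile(x, [75, 25])
        prominence = 0.2 * (q75 - q25)
    idx, _ = find_peaks(-x, distance=distance, prominence=prominence)
    if len(idx) < 2:
        raise ValueError(
            "fewer than two local minima detected; mean cycle length undefined"
        )
    return CycleSegmentation(t_lm=idx + offset, dt=dt)


def _as_2d(values: np.ndarray) -> tuple[np.ndarray, bool]:
    if values.ndim == 1:
        return values[:, None], True
    return values, False


def phase_sort(
    w_gm: Waveform, seg: CycleSegmentation, n_phases: int = 8
) -> PhaseBinnedCycle:
    """Phase-based sorting of the gold-marker waveform into one mean cycle.

    Each cycle ``[t_lm[j], t_lm[j+1])`` is linearly resampled at the phase
    points ``k/n_phases`` (phase 0 = end-inhalation) and the per-phase values
    are averaged across cycles, per direction.
    """
    vals, squeeze = _as_2d(w_gm.values)
    n = vals.shape[0]
    if seg.t_lm[-1] >= n:
        raise ValueError("segmentation extends past the waveform")
    frames = np.arange(n, dtype=float)
    phases = np.arange(n_phases) / n_phases
    cycles = []
    for j in range(seg.n - 1):
        a, b = seg.t_lm[j], seg.t_lm[j + 1]
        if b - a < 1:
            raise ValueError("empty breathing cycle in segmentation")
        sample_at = a + phases * (b - a)
        cycles.append(
            np.column_stack(
                [np.interp(sample_at, frames, vals[:, d]) for d in range(vals.shape[1])]
            )
        )
    mean_cycle = np.mean(cycles, axis=0)
    return PhaseBinnedCycle(mean_cycle[:, 0] if squeeze else mean_cycle)


def _resample_cycle(cycle_vals: np.ndarray, length: int) -> np.ndarray:
    """Periodic linear resampling of one cycle to ``length`` frames."""
    vals, squeeze = _as_2d(np.asarray(cycle_vals, dtype=float))
    k = vals.shape[0]
    xp = np.arange(k + 1) / k
    fp = np.vstack([vals, vals[:1]])  # periodic closure: phase 1 == phase 0
    x = np.arange(length) / length
    out = np.column_stack([np.interp(x, xp, fp[:, d]) for d in range(vals.shape[1])])
    return out[:, 0] if squeeze else out


def tile_waveform(
    cycle: PhaseBinnedCycle,
    seg: CycleSegmentation,
    total_frames: int,
    *,
    dt: float | None = None,
) -> Waveform:
    """Stretch the averaged cycle over every observed cycle of the trace.

    Interior cycles get the averaged cycle resampled to their observed
    length.  The head (before the first minimum) takes the *last* frames of
    the cycle resampled to the mean cycle length, the tail (from the last
    minimum on) its *first* frames, repeated cyclically if the edge segment
    exceeds one mean cycle.
    """
    if total_frames < seg.t_lm[-1]:
        raise ValueError("total_frames must reach the last detected minimum")
    if dt is None:
        dt = seg.dt
    vals, squeeze = _as_2d(cycle.values)
    width = vals.shape[1]
    out = np.empty((total_frames, width))

    for j in range(seg.n - 1):
        a, b = seg.t_lm[j], seg.t_lm[j + 1]
        out[a:b] = _as_2d(_resample_cycle(vals, b - a))[0]

    t_mean = max(1, int(round(seg.t_mean)))
    mean_cycle = _as_2d(_resample_cycle(vals, t_mean))[0]
    head_len = int(seg.t_lm[0])
    if head_len > 0:
        idx = np.arange(-head_len, 0) % t_mean
        out[:head_len] = mean_cycle[idx]
    tail_len = total_frames - int(seg.t_lm[-1])
    if tail_len > 0:
        idx = np.arange(tail_len) % t_mean
        out[seg.t_lm[-1] :] = mean_cycle[idx]

    return Waveform(out[:, 0] if squeeze else out, dt=dt)


def average_as_cycle(
    w_as: ASWaveform | Waveform | np.ndarray,
    seg: CycleSegmentation | None = None,
    *,
    n_points: int = 301,
    min_separation: float = 2.0,
    prominence: float | None = None,
    total_frames: int | None = None,
) -> ASAveragedCycle:
    """Cycle-average the shroud waveform and tile it back to full length.

    The waveform is segmented at its own local minima; every inter-minimum
    interval is cubic-spline resampled to ``n_points`` samples, the intervals
    are averaged pointwise, and the averaged cycle is tiled over the observed
    cycles exactly like the phase-sorted target cycle.  The averaged cycle is
    the percentile source for global matching.
    """
    if isinstance(w_as, ASWaveform):
        x = np.asarray(w_as.samples, dtype=float)
        dt = float(np.median(np.diff(w_as.frame_times)))
    elif isinstance(w_as, Waveform):
        x, dt = w_as.values, w_as.dt
    else:
        x, dt = np.asarray(w_as, dtype=float), FRAME_DT
    if x.ndim != 1:
        raise ValueError("shroud waveform must be scalar")
    if seg is None:
        seg = detect_local_minima(
            x, min_separation=min_separation, prominence=prominence, dt=dt
        )
    spline = CubicSpline(np.arange(len(x)), x)
    intervals = []
    for j in range(seg.n - 1):
        a, b = seg.t_lm[j], seg.t_lm[j + 1]
        # n_points samples spanning the cycle's [0, 1) phase range
        intervals.append(spline(a + (b - a) * np.arange(n_points) / n_points))
    mean_cycle = np.mean(intervals, axis=0)
    if total_frames is None:
        total_frames = len(x)
    tiled = tile_waveform(PhaseBinnedCycle(mean_cycle), seg, total_frames, dt=dt)
    return ASAveragedCycle(cycle=mean_cycle, tiled=tiled)
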