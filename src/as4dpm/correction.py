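"""Amplitude/phase correction of the tiled short-arc target waveform.

The tiled short-arc waveform has the right motion range class but poor
temporal resolution; the shroud waveform has dense temporal sampling but
arbitrary units.  Correction proceeds per direction in three steps:

1. *Phase inversion*: flip the shroud waveform's sign where it is negatively
   correlated with the target direction (tumour LR/AP motion is often
   anti-correlated with the diaphragm).
2. *Global matching*: affine rescaling of the shroud waveform so its
   cycle-averaged percentile span ``(P_lower, P_upper)`` maps onto the tiled
   waveform's full range ``(P0, P100)``.
3. *Local matching*: in every sliding window the tiled waveform is linearly
   transformed so its min/max match the rescaled shroud waveform's;
   overlapping windows are combined by per-frame averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Waveform
from .shroud import ASWaveform
from .waveform import (
    CycleSegmentation,
    average_as_cycle,
    detect_local_minima,
)

__all__ = [
    "MatchingParams",
    "CorrectedWaveform",
    "PERCENTILE_CANDIDATES",
    "WINDOW_CANDIDATES",
    "detect_phase_inversion",
    "global_match",
    "local_match",
    "correct_waveform",
]

#: Candidate (P_upper, P_lower) pairs for global matching.
PERCENTILE_CANDIDATES = ((100.0, 0.0), (85.0, 10.0), (75.0, 15.0))
#: Candidate local-matching window widths in frames (2, 4 and 6 s at 0.2 s).
WINDOW_CANDIDATES = (11, 21, 31)


@dataclass(frozen=True)
class MatchingParams:
    """Global/local matching parameters.

    The defaults are the combination found optimal on the emulated cohort:
    ``(P85, P10)`` percentiles and a 21-frame (4 s) window, close to the
    median breathing period.
    """

    p_upper: float = 85.0
    p_lower: float = 10.0
    window: int = 21
    stride: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.p_lower < self.p_upper <= 100:
            raise ValueError("need 0 <= p_lower < p_upper <= 100")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.stride != 1:
            raise ValueError("only unit window stride is supported")


@dataclass(frozen=True)
class CorrectedWaveform:
    """Corrected target waveform with retained intermediates."""

    waveform: Waveform  # (n, 3) or (n,), mm
    signs: np.ndarray  # applied shroud sign per direction
    w_as_prime: np.ndarray  # globally matched shroud signal(s), mm
    params: MatchingParams


def _check_variance(x: np.ndarray, name: str) -> None:
    if np.std(x) == 0:
        raise ValueError(f"{name} has zero variance")


def detect_phase_inversion(
    w_as: ASWaveform | np.ndarray, w_4d: Waveform | np.ndarray
) -> int:
    """Sign to apply to the shroud waveform for one target direction.

    Returns -1 when the Pearson correlation between the shroud waveform and
    the direction's tiled waveform is negative, else +1.  The SI direction is
    evaluated like the others rather than assumed positive.
    """
    a = w_as.samples if isinstance(w_as, ASWaveform) else np.asarray(w_as, float)
    b = w_4d.values if isinstance(w_4d, Waveform) else np.asarray(w_4d, float)
    if a.shape != b.shape:
        raise ValueError("waveforms must have equal length")
    _check_variance(a, "shroud waveform")
    _check_variance(b, "target waveform")
    r = np.corrcoef(a, b)[0, 1]
    return -1 if r < 0 else 1


def global_match(
    w_as: np.ndarray,
    w_4d: np.ndarray,
    params: MatchingParams,
    percentile_source: np.ndarray | None = None,
) -> np.ndarray:
    """Affine rescaling of the shroud waveform onto the target's range.

    ``W_AS' = (P100(4D) - P0(4D)) / (P_upper - P_lower) * (W_AS - P_lower)
    + P0(4D)``, with ``P_upper``/``P_lower`` evaluated on
    ``percentile_source`` (normally the cycle-averaged shroud signal, which
    suppresses outlier excursions) and ``P100``/``P0`` on the tiled target
    waveform.
    """
    w_as = np.asarray(w_as, dtype=float)
    w_4d = np.asarray(w_4d, dtype=float)
    if percentile_source is None:
        percentile_source = w_as
    p_hi = np.percentile(percentile_source, params.p_upper)
    p_lo = np.percentile(percentile_source, params.p_lower)
    if p_hi <= p_lo:
        raise ValueError("degenerate percentile span in the shroud signal")
    p100 = np.percentile(w_4d, 100.0)
    p0 = np.percentile(w_4d, 0.0)
    return (p100 - p0) / (p_hi - p_lo) * (w_as - p_lo) + p0


def local_match(
    w_4d: np.ndarray, w_as_prime: np.ndarray, window: int
) -> np.ndarray:
    """Sliding-window min/max matching of the target to the shroud signal.

    Every length-``window`` window (stride 1) defines the affine map taking
    the target window's (min, max) onto the shroud window's (min, max); a
    flat target window degenerates to a pure shift aligning window means.
    Each output frame averages the maps of all windows covering it.
    """
    w_4d = np.asarray(w_4d, dtype=float)
    w_as_prime = np.asarray(w_as_prime, dtype=float)
    if w_4d.shape != w_as_prime.shape or w_4d.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    n = len(w_4d)
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if window > n:
        raise ValueError("window exceeds the waveform length")

    win4 = sliding_window_view(w_4d, window)
    wina = sliding_window_view(w_as_prime, window)
    mn4, mx4 = win4.min(axis=1), win4.max(axis=1)
    mna, mxa = wina.min(axis=1), wina.max(axis=1)
    span4 = mx4 - mn4
    flat = span4 == 0
    scale = np.where(flat, 1.0, (mxa - mna) / np.where(flat, 1.0, span4))
    offset = np.where(
        flat, wina.mean(axis=1) - win4.mean(axis=1), mna - scale * mn4
    )

    # out[t] = x[t] * mean(scale over covering windows) + mean(offset ...);
    # window s covers frames [s, s + window).
    n_win = n - window + 1
    csum_scale = np.concatenate([[0.0], np.cumsum(scale)])
    csum_off = np.concatenate([[0.0], np.cumsum(offset)])
    t = np.arange(n)
    lo = np.clip(t - window + 1, 0, n_win - 1)
    hi = np.minimum(t, n_win - 1)
    count = hi - lo + 1
    mean_scale = (csum_scale[hi + 1] - csum_scale[lo]) / count
    mean_off = (csum_off[hi + 1] - csum_off[lo]) / count
    return w_4d * mean_scale + mean_off


def correct_waveform(
    w_4d: Waveform,
    w_as: ASWaveform | Waveform | np.ndarray,
    params: MatchingParams | None = None,
    *,
    seg_as: CycleSegmentation | None = None,
    min_separation: float = 2.0,
    prominence: float | None = None,
    percentiles_from_cycle_average: bool = True,
) -> CorrectedWaveform:
    """Per-direction sign handling, global matching and local matching.

    ``seg_as`` overrides the shroud waveform's own minima segmentation (it is
    re-detected per direction after sign flipping otherwise).  Set
    ``percentiles_from_cycle_average=False`` to evaluate the matching
    percentiles on the full shroud waveform instead of its cycle average.
    """
    if params is None:
        params = MatchingParams()
    if isinstance(w_as, ASWaveform):
        a = np.asarray(w_as.samples, dtype=float)
    elif isinstance(w_as, Waveform):
        a = w_as.values
    else:
        a = np.asarray(w_as, dtype=float)
    vals = w_4d.values if w_4d.is_3d else w_4d.values[:, None]
    if len(a) != vals.shape[0]:
        raise ValueError("shroud and target waveforms must have equal length")

    out = np.empty_like(vals)
    signs = np.empty(vals.shape[1], dtype=int)
    primes = np.empty_like(vals)
    for d in range(vals.shape[1]):
        sign = detect_phase_inversion(a, vals[:, d])
        signed = sign * a
        if percentiles_from_cycle_average:
            seg = seg_as
            if seg is None or sign < 0:
                seg = detect_local_minima(
                    signed,
                    min_separation=min_separation,
                    prominence=prominence,
                    dt=w_4d.dt,
                )
            source = average_as_cycle(signed, seg).tiled.values
        else:
            source = signed
        prime = global_match(signed, vals[:, d], params, percentile_source=source)
        out[:, d] = local_match(vals[:, d], prime, params.window)
        signs[d] = sign
        primes[:, d] = prime

    if not w_4d.is_3d:
        return CorrectedWaveform(
            Waveform(out[:, 0], dt=w_4d.dt, t0=w_4d.t0),
            signs=signs,
            w_as_prime=primes[:, 0],
            params=params,
        )
    return CorrectedWaveform(
        Waveform(out, dt=w_4d.dt, t0=w_4d.t0),
        signs=signs,
        w_as_prime=primes,
        params=params,
    )
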