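"""Shared containers for uniformly sampled respiratory time series.

Axis conventions used throughout the package (documented in docs/methods.md):

* LR: positive = patient left
* SI: positive = inferior (so diaphragm and target move in the *positive*
  direction during inhalation)
* AP: positive = posterior (abdominal IR markers move anterior, i.e. negative,
  during inhalation; end-inhalation is a local minimum of the IR trace)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Sampling interval shared by the IR camera and the projection schedule (s).
FRAME_DT = 0.2

#: Axis order of every 3-component trajectory.
AXES = ("LR", "SI", "AP")


@dataclass(frozen=True)
class Waveform:
    """A uniformly sampled scalar or 3-component time series.

    Parameters
    ----------
    values
        Array of shape ``(n,)`` (scalar trace, mm or arbitrary units) or
        ``(n, 3)`` (LR/SI/AP trajectory in mm).
    dt
        Sampling interval in seconds.
    t0
        Time of the first sample in seconds.
    """

    values: np.ndarray
    dt: float = FRAME_DT
    t0: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim not in (1, 2):
            raise ValueError("values must be 1-D or 2-D")
        if v.ndim == 2 and v.shape[1] != 3:
            raise ValueError("3-component waveforms must have shape (n, 3)")
        if v.shape[0] < 1:
            raise ValueError("waveform must contain at least one sample")
        if not np.all(np.isfinite(v)):
            raise ValueError("waveform samples must be finite")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        object.__setattr__(self, "values", v)

    # -- basic introspection -------------------------------------------------
    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_frames)

    @property
    def is_3d(self) -> bool:
        return self.values.ndim == 2

    # -- views ---------------------------------------------------------------
    def component(self, axis: str) -> "Waveform":
        """Extract one LR/SI/AP component of a 3-component waveform."""
        if not self.is_3d:
            raise ValueError("component() requires a 3-component waveform")
        try:
            idx = AXES.index(axis)
        except ValueError:
            raise ValueError(f"unknown axis {axis!r}; expected one of {AXES}")
        return Waveform(self.values[:, idx], dt=self.dt, t0=self.t0)

    def window(self, sl: slice) -> "Waveform":
        """Frame-index slice with the time origin carried along."""
        start, _, step = sl.indices(self.n_frames)
        if step != 1:
            raise ValueError("window slicing must be contiguous (step 1)")
        vals = self.values[sl]
        if vals.shape[0] == 0:
            raise ValueError("empty window")
        return Waveform(vals, dt=self.dt, t0=self.t0 + start * self.dt)


def average_waveforms(waveforms: list[Waveform]) -> Waveform:
    """Element-wise mean of same-grid waveforms (e.g. the IR marker centroid)."""
    if not waveforms:
        raise ValueError("need at least one waveform")
    n = waveforms[0].n_frames
    dt = waveforms[0].dt
    for w in waveforms[1:]:
        if w.n_frames != n or w.dt != dt:
            raise ValueError("waveforms must share one sampling grid")
    return Waveform(
        np.mean([w.values for w in waveforms], axis=0),
        dt=dt,
        t0=waveforms[0].t0,
    )
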