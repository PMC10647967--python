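"""Synthetic free-breathing acquisition generator.

Emulates a 70 s orthogonal rotational kV acquisition on a patient breathing
freely: a quasi-periodic cos^(2n) breathing profile drives the implanted
fiducial (LR/SI/AP), the diaphragm edge seen in the projections, and the
abdominal IR surrogate markers.  The generator is the ground-truth test bed
for every downstream stage — patient data are not part of the package.

Defaults follow the published motion statistics of the emulated cohort:
breathing period 3.7 s (SD 0.3 s), fiducial peak-to-trough amplitudes
1.7 / 11.4 / 3.3 mm (LR/SI/AP), IR AP amplitude 6.2 mm, four IR markers,
0.2 mm isocenter pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import FRAME_DT, Waveform
from .geometry import (
    GantrySchedule,
    ImagerGeometry,
    ORTHOGONAL_IMAGERS,
    project_points,
)

__all__ = [
    "BreathingParams",
    "ProjectionParams",
    "BreathingTrace",
    "ProjectionStack",
    "SyntheticCase",
    "simulate_breathing",
    "render_projection",
    "simulate_case",
]


@dataclass(frozen=True)
class BreathingParams:
    """Statistical description of one synthetic breathing session.

    Amplitudes are peak-to-trough.  ``correlation_sign`` sets, per LR/SI/AP
    axis, whether the target moves with (+1) or against (-1) the diaphragm;
    tumour LR/AP motion is often negatively correlated with the diaphragm,
    hence the default signs.  ``drift_rate`` is a linear baseline drift of the
    IR markers in mm/min (positive = posterior); the internal target does not
    drift, which is exactly the mismatch that degrades a stale model.
    """

    mean_period: float = 3.7  # s
    period_sd: float = 0.3  # s
    amplitude: tuple[float, float, float] = (1.7, 11.4, 3.3)  # mm, LR/SI/AP
    correlation_sign: tuple[int, int, int] = (-1, 1, -1)
    ir_amplitude: float = 6.2  # mm, AP peak-to-trough
    n_ir_markers: int = 4
    shape_exponent: int = 2  # cos^(2n) profile
    drift_rate: float = 0.0  # mm / min on the IR baseline
    noise_sd: float = 0.1  # mm, on IR traces
    phase_lag: float = 0.0  # external surrogate lag, fraction of a cycle
    baseline: float = 0.0  # mm, offset of the bare breathing trace
    diaphragm_scale: float = 1.5  # diaphragm / target SI amplitude ratio
    diaphragm_offset_mm: float | None = None  # None: center the excursion
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_period <= 0:
            raise ValueError("mean_period must be positive")
        if self.period_sd < 0:
            raise ValueError("period_sd must be non-negative")
        if any(a < 0 for a in self.amplitude) or self.ir_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if any(s not in (-1, 1) for s in self.correlation_sign):
            raise ValueError("correlation_sign entries must be +1 or -1")
        if self.n_ir_markers < 1:
            raise ValueError("need at least one IR marker")
        if self.shape_exponent < 1:
            raise ValueError("shape_exponent must be >= 1")


@dataclass(frozen=True)
class ProjectionParams:
    """Rendering parameters for the synthetic projection frames.

    The diaphragm appears as a smooth high-to-low intensity transition
    (cranial/lung bright, caudal/abdomen dark in the attenuation sense) whose
    sub-pixel row position follows the diaphragm trace.  ``dome_sag_px``
    bows the edge across detector columns, emulating the projected curvature
    of the diaphragm dome; it spreads the shroud ridge over a band comparable
    to the breathing excursion, which real shroud images exhibit.
    """

    image_shape: tuple[int, int] = (256, 256)  # (rows, cols)
    pixel_size_mm: float = 0.2  # at the isocenter plane
    intensity_high: float = 1000.0
    intensity_low: float = 300.0
    edge_halfwidth_px: float = 20.0
    dome_sag_px: float = 0.0
    texture_amplitude: float = 30.0
    noise_sd: float = 5.0  # intensity units, per pixel per frame

    def __post_init__(self) -> None:
        if self.intensity_low <= 0 or self.intensity_high <= self.intensity_low:
            raise ValueError("need 0 < intensity_low < intensity_high")
        if self.edge_halfwidth_px <= 0:
            raise ValueError("edge_halfwidth_px must be positive")
        if self.noise_sd < 0 or self.texture_amplitude < 0:
            raise ValueError("noise/texture amplitudes must be non-negative")


@dataclass(frozen=True)
class BreathingTrace:
    """A breathing trace plus its generating ground truth."""

    waveform: Waveform  # amplitude * cos^(2n) + baseline + drift + noise
    noiseless: np.ndarray  # same, without the noise term
    phase: np.ndarray  # cumulative respiratory phase in cycles
    cycle_start_times: np.ndarray  # s, end-inhalation epochs within the trace
    inhalation_fraction: np.ndarray  # cos^(2n)(pi * phase), in [0, 1]


@dataclass(frozen=True)
class ProjectionStack:
    """Time-ordered grayscale frames of one imager."""

    frames: np.ndarray  # (n_frames, rows, cols) float32
    times: np.ndarray  # s
    angles: np.ndarray  # gantry degrees, unwrapped
    pixel_size_mm: float
    imager: ImagerGeometry

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class SyntheticCase:
    """Ground-truth bundle for one synthetic acquisition."""

    true_target: Waveform  # (n, 3) mm, LR/SI/AP
    diaphragm: Waveform  # mm, SI (positive = inferior), noiseless truth
    ir_traces: list[Waveform]  # AP position of each IR marker, mm
    projections: list[ProjectionStack]
    fiducial_detections: list[np.ndarray]  # per imager, (n, 2) u/v mm
    schedule: GantrySchedule
    imagers: tuple[ImagerGeometry, ...]
    params: BreathingParams
    projection_params: ProjectionParams

    @property
    def ir_centroid(self) -> Waveform:
        """Across-marker mean IR trace (the surrogate fed to the model)."""
        return Waveform(
            np.mean([w.values for w in self.ir_traces], axis=0),
            dt=self.ir_traces[0].dt,
            t0=self.ir_traces[0].t0,
        )


def _draw_period(params: BreathingParams, rng: np.random.Generator) -> float:
    p = rng.normal(params.mean_period, params.period_sd)
    return float(np.clip(p, 0.3 * params.mean_period, None))


def _draw_cycles(
    params: BreathingParams, total_time: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Cycle start times (first possibly negative) and cycle durations.

    The trace starts mid-cycle: the first cycle began ``phase0`` cycles
    before t = 0, so t = 0 rarely coincides with an end-inhalation epoch.
    """
    phase0 = rng.uniform(0.0, 1.0)
    periods = [_draw_period(params, rng)]
    t0 = -phase0 * periods[0]
    while t0 + sum(periods) < total_time:
        periods.append(_draw_period(params, rng))
    periods = np.asarray(periods)
    starts = t0 + np.concatenate([[0.0], np.cumsum(periods[:-1])])
    return starts, periods


def simulate_breathing(
    params: BreathingParams,
    n_frames: int,
    *,
    amplitude: float | None = None,
    rng: np.random.Generator | None = None,
    dt: float = FRAME_DT,
) -> BreathingTrace:
    """Quasi-periodic breathing trace ``A cos^(2n)(pi phase) + drift + noise``.

    Each cycle's period is drawn around ``mean_period``; phase advances
    linearly within a cycle, so cycle starts (integer phase) are the
    end-inhalation epochs where the bare profile peaks.  Returns the sampled
    trace together with the ground-truth cycle boundaries.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if amplitude is None:
        amplitude = params.amplitude[1]
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    times = dt * np.arange(n_frames)
    starts, periods = _draw_cycles(params, times[-1] + dt, rng)
    idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(periods) - 1)
    phase = idx + (times - starts[idx]) / periods[idx]
    frac = np.cos(np.pi * phase) ** (2 * params.shape_exponent)

    noiseless = (
        amplitude * frac + params.baseline + params.drift_rate * times / 60.0
    )
    values = noiseless + rng.normal(0.0, params.noise_sd, n_frames)
    boundaries = starts[(starts >= 0) & (starts <= times[-1])]
    return BreathingTrace(
        waveform=Waveform(values, dt=dt),
        noiseless=noiseless,
        phase=phase,
        cycle_start_times=boundaries,
        inhalation_fraction=frac,
    )


def _dome_profile(n_cols: int, sag_px: float) -> np.ndarray:
    """Projected diaphragm-dome curvature: edge bows caudally off-center."""
    c = (np.arange(n_cols) - (n_cols - 1) / 2.0) / ((n_cols - 1) / 2.0)
    return sag_px * c**2


def _edge_margin(params: ProjectionParams) -> float:
    """Rows to keep between the edge excursion and the image border."""
    return params.dome_sag_px + 3.0 * params.edge_halfwidth_px + 1.0


def render_projection(
    diaphragm_row: float,
    angle_deg: float = 0.0,
    image_shape: tuple[int, int] = (256, 256),
    noise_sd: float = 0.0,
    *,
    params: ProjectionParams | None = None,
    texture: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one grayscale frame with the diaphragm edge at ``diaphragm_row``.

    The edge is a smooth logistic intensity transition of scale
    ``edge_halfwidth_px`` centred, per detector column, at ``diaphragm_row``
    plus the dome-sag profile, so the vertical gradient peaks exactly at the
    (sub-pixel) edge row.  The broad scale emulates the gradual transition a
    column-collapsed projection of the diaphragm dome exhibits.
    ``angle_deg`` is accepted for schedule bookkeeping (the parallel-ray
    renderer itself is angle-independent).
    """
    del angle_deg  # orthographic rendering; kept for the schedule interface
    if params is None:
        params = ProjectionParams(
            image_shape=image_shape, noise_sd=noise_sd, dome_sag_px=0.0,
            texture_amplitude=0.0,
        )
    rows, cols = params.image_shape
    margin = _edge_margin(params)
    if not (margin <= diaphragm_row <= rows - 1 - margin):
        raise ValueError(
            f"diaphragm row {diaphragm_row:.1f} outside image extent "
            f"[{margin:.1f}, {rows - 1 - margin:.1f}]"
        )
    edge = diaphragm_row + _dome_profile(cols, params.dome_sag_px)  # per column
    r = np.arange(rows, dtype=float)[:, None]
    ramp = 1.0 / (1.0 + np.exp(-(edge[None, :] - r) / params.edge_halfwidth_px))
    frame = params.intensity_low + (params.intensity_high - params.intensity_low) * ramp
    if texture is not None:
        frame = frame + texture
    if params.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        frame = frame + rng.normal(0.0, params.noise_sd, frame.shape)
    # Detector floor: keep intensities strictly positive for the log transform.
    return np.maximum(frame, 1.0).astype(np.float32)


def _make_texture(
    shape: tuple[int, int], amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth low-frequency anatomy-like background, static per imager."""
    rows, cols = shape
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    tex = np.zeros(shape)
    for _ in range(3):
        fr = rng.uniform(0.5, 2.0) / rows
        fc = rng.uniform(0.5, 2.0) / cols
        ph_r, ph_c = rng.uniform(0, 2 * np.pi, 2)
        tex += np.cos(2 * np.pi * fr * r + ph_r) * np.cos(2 * np.pi * fc * c + ph_c)
    tex *= amplitude / max(np.abs(tex).max(), 1e-12)
    return tex


def simulate_case(
    params: BreathingParams,
    schedule: GantrySchedule,
    *,
    n_imagers: int = 2,
    projection: ProjectionParams | None = None,
    imagers: tuple[ImagerGeometry, ...] = ORTHOGONAL_IMAGERS,
) -> SyntheticCase:
    """Generate a complete synthetic acquisition for one schedule.

    The target SI motion follows the breathing profile; LR/AP are scaled
    copies with the configured correlation signs.  The diaphragm is a scaled,
    offset copy of the target SI trace (a faithful internal surrogate); IR
    traces are AP surrogates with per-marker baselines, independent noise and
    optional linear baseline drift.  Fiducial 2D detections are ideal
    projections of the true 3D positions.
    """
    if projection is None:
        projection = ProjectionParams()
    if n_imagers not in (1, 2):
        raise ValueError("n_imagers must be 1 or 2")
    n = schedule.n_frames
    rng = np.random.default_rng(params.seed)

    clean = replace(params, noise_sd=0.0, drift_rate=0.0, baseline=0.0)
    base = simulate_breathing(clean, n, amplitude=1.0, rng=rng)
    frac = base.inhalation_fraction  # in [0, 1], 1 = end-inhalation

    target = np.column_stack(
        [s * a * frac for s, a in zip(params.correlation_sign, params.amplitude)]
    )
    true_target = Waveform(target)

    # External AP surrogate: anterior (negative) excursion on inhalation.
    if params.phase_lag != 0.0:
        frac_ext = np.cos(np.pi * (base.phase - params.phase_lag)) ** (
            2 * params.shape_exponent
        )
    else:
        frac_ext = frac
    times = schedule.times
    ir_traces = []
    for _ in range(params.n_ir_markers):
        offset = rng.uniform(-2.0, 2.0)
        noise = rng.normal(0.0, params.noise_sd, n)
        ir = offset - params.ir_amplitude * frac_ext + params.drift_rate * times / 60.0
        ir_traces.append(Waveform(ir + noise))

    # Diaphragm SI displacement (positive = inferior), noiseless truth.
    offset = params.diaphragm_offset_mm
    if offset is None:
        # Center the diaphragm excursion on the detector mid-row.
        si = params.diaphragm_scale * true_target.values[:, 1]
        offset = -0.5 * (si.min() + si.max())
    diaphragm = Waveform(
        params.diaphragm_scale * true_target.values[:, 1] + offset
    )

    rows = projection.image_shape[0]
    center_row = (rows - 1) / 2.0
    edge_rows = center_row + diaphragm.values / projection.pixel_size_mm
    margin = _edge_margin(projection)
    if edge_rows.min() < margin or edge_rows.max() > rows - 1 - margin:
        raise ValueError(
            "diaphragm excursion exceeds the imager field of view; reduce the "
            "SI amplitude/diaphragm scale or enlarge the image"
        )

    stacks: list[ProjectionStack] = []
    detections: list[np.ndarray] = []
    for geom in imagers[:n_imagers]:
        texture = _make_texture(
            projection.image_shape, projection.texture_amplitude, rng
        )
        frames = np.empty((n, *projection.image_shape), dtype=np.float32)
        for i in range(n):
            frames[i] = render_projection(
                float(edge_rows[i]),
                params=projection,
                texture=texture,
                rng=rng,
            )
        stacks.append(
            ProjectionStack(
                frames=frames,
                times=times,
                angles=schedule.angles,
                pixel_size_mm=projection.pixel_size_mm,
                imager=geom,
            )
        )
        detections.append(project_points(target, schedule.angles, geom))

    return SyntheticCase(
        true_target=true_target,
        diaphragm=diaphragm,
        ir_traces=ir_traces,
        projections=stacks,
        fiducial_detections=detections,
        schedule=schedule,
        imagers=tuple(imagers[:n_imagers]),
        params=params,
        projection_params=projection,
    )
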