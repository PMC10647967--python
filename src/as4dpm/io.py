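"""CSV / TIFF / YAML import-export for traces, stacks and model parameters."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import AXES, FRAME_DT, Waveform
from .geometry import ImagerGeometry
from .model import PMParameters
from .simulate import BreathingParams, ProjectionStack

__all__ = [
    "write_waveform_csv",
    "read_waveform_csv",
    "write_traces_csv",
    "read_traces_csv",
    "write_stack",
    "read_stack",
    "write_schedule_csv",
    "write_detections_csv",
    "write_params_yaml",
    "read_params_yaml",
    "write_pm",
    "read_pm",
]


def write_waveform_csv(w: Waveform, path: str | Path) -> None:
    """Scalar -> columns (frame, time_s, value_mm); 3-D -> LR/SI/AP columns."""
    frames = np.arange(w.n_frames)
    if w.is_3d:
        df = pd.DataFrame(
            {"frame": frames, "time_s": w.times}
            | {f"{ax.lower()}_mm": w.values[:, i] for i, ax in enumerate(AXES)}
        )
    else:
        df = pd.DataFrame({"frame": frames, "time_s": w.times, "value_mm": w.values})
    df.to_csv(path, index=False)


def read_waveform_csv(path: str | Path) -> Waveform:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    dt = float(np.median(np.diff(t))) if len(t) > 1 else FRAME_DT
    if "value_mm" in df.columns:
        vals = df["value_mm"].to_numpy()
    else:
        vals = df[[f"{ax.lower()}_mm" for ax in AXES]].to_numpy()
    return Waveform(vals, dt=dt, t0=float(t[0]))


def write_traces_csv(traces: list[Waveform], path: str | Path) -> None:
    """Per-marker scalar traces as marker_1..marker_k columns."""
    df = pd.DataFrame({"frame": np.arange(traces[0].n_frames), "time_s": traces[0].times})
    for i, t in enumerate(traces, start=1):
        df[f"marker_{i}_mm"] = t.values
    df.to_csv(path, index=False)


def read_traces_csv(path: str | Path) -> list[Waveform]:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    dt = float(np.median(np.diff(t))) if len(t) > 1 else FRAME_DT
    cols = [c for c in df.columns if c.startswith("marker_")]
    return [Waveform(df[c].to_numpy(), dt=dt, t0=float(t[0])) for c in cols]


def write_stack(stack: ProjectionStack, tiff_path: str | Path) -> None:
    """Multi-page TIFF plus a frame-index CSV next to it."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, stack.frames)
    pd.DataFrame(
        {
            "frame": np.arange(stack.n_frames),
            "time_s": stack.times,
            "angle_deg": stack.angles,
        }
    ).to_csv(tiff_path.with_suffix(".csv"), index=False)


def read_stack(
    tiff_path: str | Path,
    *,
    pixel_size_mm: float = 0.2,
    imager: ImagerGeometry | None = None,
) -> ProjectionStack:
    tiff_path = Path(tiff_path)
    frames = tifffile.imread(tiff_path)
    index = pd.read_csv(tiff_path.with_suffix(".csv"))
    if imager is None:
        imager = ImagerGeometry(1, 0.0)
    return ProjectionStack(
        frames=np.asarray(frames, dtype=np.float32),
        times=index["time_s"].to_numpy(),
        angles=index["angle_deg"].to_numpy(),
        pixel_size_mm=pixel_size_mm,
        imager=imager,
    )


def write_schedule_csv(schedule, path: str | Path) -> None:
    pd.DataFrame(
        {
            "frame": np.arange(schedule.n_frames),
            "time_s": schedule.times,
            "angle_deg": schedule.angles_wrapped,
        }
    ).to_csv(path, index=False)


def write_detections_csv(
    detections: list[np.ndarray], path: str | Path
) -> None:
    """Per-imager (u, v) detections in long form."""
    rows = []
    for imager_idx, det in enumerate(detections, start=1):
        for frame, (u, v) in enumerate(det):
            rows.append((frame, imager_idx, u, v))
    pd.DataFrame(rows, columns=["frame", "imager", "u_mm", "v_mm"]).to_csv(
        path, index=False
    )


def write_params_yaml(params: BreathingParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(params), fh, sort_keys=False)


def read_params_yaml(path: str | Path) -> BreathingParams:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("amplitude", "correlation_sign"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return BreathingParams(**raw)


def write_pm(pm: PMParameters, path: str | Path, **provenance) -> None:
    """Serialize fitted model parameters (JSON or YAML by extension)."""
    payload = pm.to_dict() | {"provenance": provenance}
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(payload, fh, sort_keys=False)
        else:
            json.dump(payload, fh, indent=2)


def read_pm(path: str | Path) -> PMParameters:
    path = Path(path)
    with open(path) as fh:
        payload = (
            yaml.safe_load(fh)
            if path.suffix in (".yaml", ".yml")
            else json.load(fh)
        )
    per_marker = np.asarray(payload["per_marker"], dtype=float)
    rep = np.asarray(
        [payload["representative"][k] for k in ("a", "b", "c", "d", "e")],
        dtype=float,
    )
    return PMParameters(
        coefficients=rep, per_marker=per_marker, n_markers=per_marker.shape[0]
    )
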