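"""Gantry schedule, orthogonal-imager projection and fiducial triangulation.

The kV imaging chain is modelled as an ideal parallel-ray (orthographic)
projection: no source/detector distances enter, so magnification is unity and
the detector ``v`` axis coincides with the patient SI axis.  This is a
deliberate simplification — at isocenter-plane pixel scale the divergent-beam
correction is absorbed by the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GantrySchedule",
    "ImagerGeometry",
    "ORTHOGONAL_IMAGERS",
    "LEFT_LUNG_ARC",
    "RIGHT_LUNG_ARC",
    "build_schedule",
    "project_point",
    "project_points",
    "triangulate",
    "triangulate_many",
]


@dataclass(frozen=True)
class GantrySchedule:
    """Time-ordered gantry angles for one rotational acquisition.

    ``angles`` are stored unwrapped (strictly monotone in the rotation
    direction); :attr:`angles_wrapped` reduces them modulo 360.
    """

    speed: float  # degrees / s
    interval: float  # degrees between frames
    start_angle: float  # degrees
    direction: str  # "cw" | "ccw"
    times: np.ndarray  # s, one entry per frame
    angles: np.ndarray  # degrees, unwrapped

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def angles_wrapped(self) -> np.ndarray:
        return np.mod(self.angles, 360.0)


@dataclass(frozen=True)
class ImagerGeometry:
    """One flat-panel imager riding on the gantry.

    ``angular_offset`` is the imager's fixed rotation relative to the gantry
    reference; the two imagers of an orthogonal pair differ by 90 degrees.
    The detector ``v`` axis is the SI axis; ``u`` lies in the LR/AP plane.
    """

    imager_id: int
    angular_offset: float  # degrees


#: The orthogonal dual-imager arrangement.
ORTHOGONAL_IMAGERS = (ImagerGeometry(1, 0.0), ImagerGeometry(2, 90.0))

#: Clinical arc presets: (start_angle, direction).
LEFT_LUNG_ARC = (320.0, "cw")
RIGHT_LUNG_ARC = (40.0, "ccw")


def build_schedule(
    speed: float,
    duration: float,
    interval: float,
    start_angle: float = LEFT_LUNG_ARC[0],
    direction: str = "cw",
) -> GantrySchedule:
    """Uniform rotational acquisition schedule.

    The frame count is ``floor(duration * speed / interval) + 1`` (the initial
    frame at ``start_angle`` is included); frame times are
    ``index * interval / speed``.
    """
    if speed <= 0:
        raise ValueError("gantry speed must be positive")
    if interval <= 0:
        raise ValueError("acquisition interval must be positive")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if direction not in ("cw", "ccw"):
        raise ValueError("direction must be 'cw' or 'ccw'")
    # Tolerate float round-off for exactly representable frame counts.
    n = int(np.floor(duration * speed / interval + 1e-9)) + 1
    idx = np.arange(n)
    times = idx * (interval / speed)
    sign = 1.0 if direction == "cw" else -1.0
    angles = start_angle + sign * idx * interval
    return GantrySchedule(
        speed=speed,
        interval=interval,
        start_angle=start_angle,
        direction=direction,
        times=times,
        angles=angles,
    )


def _in_plane_angle(angle_deg: float | np.ndarray, geom: ImagerGeometry) -> np.ndarray:
    return np.deg2rad(np.asarray(angle_deg, dtype=float) + geom.angular_offset)


def project_point(
    p: np.ndarray, angle_deg: float, geom: ImagerGeometry
) -> tuple[float, float]:
    """Orthographic projection of a 3D LR/SI/AP point onto one imager.

    Returns detector coordinates ``(u, v)`` in mm: ``v`` is the SI coordinate,
    ``u`` the in-plane coordinate after rotating the LR/AP components by the
    gantry angle plus the imager offset.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (3,) or not np.all(np.isfinite(p)):
        raise ValueError("p must be a finite 3-vector (LR, SI, AP)")
    a = _in_plane_angle(angle_deg, geom)
    u = p[0] * np.cos(a) + p[2] * np.sin(a)
    return float(u), float(p[1])


def project_points(
    points: np.ndarray, angles_deg: np.ndarray, geom: ImagerGeometry
) -> np.ndarray:
    """Vectorised :func:`project_point` over per-frame points and angles."""
    points = np.asarray(points, dtype=float)
    a = _in_plane_angle(angles_deg, geom)
    u = points[:, 0] * np.cos(a) + points[:, 2] * np.sin(a)
    return np.column_stack([u, points[:, 1]])


def triangulate(
    det1: tuple[float, float],
    det2: tuple[float, float],
    angle_deg: float,
    geoms: tuple[ImagerGeometry, ImagerGeometry] = ORTHOGONAL_IMAGERS,
) -> np.ndarray:
    """Recover a 3D LR/SI/AP point from paired same-frame 2D detections.

    Solves the two in-plane ray equations in the least-squares sense; the SI
    component is the mean of the two ``v`` coordinates.  With exact orthogonal
    detections the residual is zero.
    """
    return triangulate_many(
        np.asarray(det1, dtype=float)[None, :],
        np.asarray(det2, dtype=float)[None, :],
        np.asarray([angle_deg], dtype=float),
        geoms,
    )[0]


def triangulate_many(
    det1: np.ndarray,
    det2: np.ndarray,
    angles_deg: np.ndarray,
    geoms: tuple[ImagerGeometry, ImagerGeometry] = ORTHOGONAL_IMAGERS,
) -> np.ndarray:
    """Per-frame triangulation of ``(n, 2)`` detection arrays to ``(n, 3)``."""
    det1 = np.asarray(det1, dtype=float)
    det2 = np.asarray(det2, dtype=float)
    angles_deg = np.asarray(angles_deg, dtype=float)
    if det1.shape != det2.shape or det1.shape[0] != angles_deg.shape[0]:
        raise ValueError("detections and angles must agree frame-wise")
    a1 = _in_plane_angle(angles_deg, geoms[0])
    a2 = _in_plane_angle(angles_deg, geoms[1])
    # Rows of the 2x2 system [cos a, sin a] . [LR, AP]^T = u
    det = np.cos(a1) * np.sin(a2) - np.sin(a1) * np.cos(a2)
    if np.any(np.abs(det) < 1e-9):
        raise ValueError(
            "rank-deficient imager geometry: viewing directions coincide"
        )
    u1, u2 = det1[:, 0], det2[:, 0]
    lr = (u1 * np.sin(a2) - u2 * np.sin(a1)) / det
    ap = (-u1 * np.cos(a2) + u2 * np.cos(a1)) / det
    si = 0.5 * (det1[:, 1] + det2[:, 1])
    return np.column_stack([lr, si, ap])
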