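"""Trackway geometry and trackmaker estimation.

From an ordered sequence of track reference points (IPs, in cm on the surface
frame) this module measures pace, stride, trackway width (WAP), pace
angulation and angle of rotation, then estimates trackmaker hip height,
velocity and gait:

* hip height ``h = 4 * FL`` with FL the mean track length of the trackway;
* velocity ``V = c * g^0.5 * lambda^1.67 * h^-1.17`` with ``g = 9.81`` and
  ``c = 0.25`` (the classic stride-frequency calibration) or ``c = 0.226``
  (the later recalibration), so the two variants differ by the exact factor
  0.904 for every input;
* gait ratio ``lambda / h``: below 2.0 walking, above 2.0 running.

All estimates are computed from unrounded intermediates; rounding happens
only at serialization.  Sequences of two tracks are "track associations" and
yield a pace or stride only, never kinematic estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import KinematicEstimates, Side, TrackwayMetrics, TrackwaySequence

__all__ = [
    "GRAVITY",
    "VELOCITY_COEFFICIENTS",
    "TrackwayError",
    "trackway_geometry",
    "hip_height",
    "velocity",
    "gait",
    "estimate_trackway",
]

GRAVITY = 9.81  # m s^-2, fixed
VELOCITY_COEFFICIENTS = {"alexander": 0.25, "rt": 0.226}
GAIT_THRESHOLD = 2.0
CM_PER_M = 100.0


class TrackwayError(ValueError):
    pass


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _bearing_to_vec(bearing_deg: float) -> np.ndarray:
    """Surface-frame bearing (deg clockwise from +y) to a unit vector."""
    r = math.radians(bearing_deg)
    return np.array([math.sin(r), math.cos(r)])


def trackway_geometry(seq: TrackwaySequence) -> TrackwayMetrics:
    """Measure pace, stride, WAP, pace angulation and rotation for a sequence.

    With *n* steps there are *n - 1* paces, *n - 2* strides, *n - 2* WAP
    values and *n - 2* pace angulations.  Paces and strides are reported in
    metres, WAP in cm, angles in degrees.  Rotation angles (one per step, when
    the step carries an axis bearing) are signed positive away from the
    trackway midline.
    """
    if len(seq.steps) < 2:
        raise TrackwayError("sequence too short: need at least 2 steps")

    ips = np.array([s.ip for s in seq.steps], dtype=float)  # cm
    n = len(ips)
    notes: list[str] = []

    feet = [s.foot for s in seq.steps]
    alternation_ok = all(
        Side.INDETERMINATE in (a, b) or a is not b for a, b in zip(feet, feet[1:])
    )
    if not alternation_ok:
        notes.append("feet do not alternate; paces computed but flagged")

    paces = [float(np.linalg.norm(ips[i + 1] - ips[i])) / CM_PER_M for i in range(n - 1)]
    strides = [float(np.linalg.norm(ips[i + 2] - ips[i])) / CM_PER_M for i in range(n - 2)]

    wap = []
    angulations = []
    for i in range(n - 2):
        a, b, c = ips[i], ips[i + 1], ips[i + 2]
        chord = c - a
        chord_len = np.linalg.norm(chord)
        if chord_len < 1e-12:
            wap.append(float(np.linalg.norm(b - a)))
            angulations.append(0.0)
            continue
        d = abs(chord[0] * (b[1] - a[1]) - chord[1] * (b[0] - a[0])) / chord_len
        wap.append(float(d))  # cm
        angulations.append(_angle_deg(a - b, c - b))

    # trackway midline: polyline through midpoints of consecutive pace lines
    midpoints = (ips[:-1] + ips[1:]) / 2.0
    rotations: list[float | None] = []
    for i, step in enumerate(seq.steps):
        if step.axis_bearing is None or len(midpoints) < 2:
            rotations.append(None)
            continue
        j = min(max(i - 1, 0), len(midpoints) - 2)
        mid_dir = midpoints[j + 1] - midpoints[j]
        if np.linalg.norm(mid_dir) < 1e-12:
            rotations.append(None)
            continue
        axis = _bearing_to_vec(step.axis_bearing)
        ang = _angle_deg(axis, mid_dir)
        # positive rotation points away from the midline: compare which side
        # of the midline the IP lies on with the way the axis deviates
        # (both as z-components of cross products with the midline direction)
        axis_dev = mid_dir[0] * axis[1] - mid_dir[1] * axis[0]
        side_vec = ips[i] - midpoints[j]
        ip_side = mid_dir[0] * side_vec[1] - mid_dir[1] * side_vec[0]
        outward = 1.0
        if ip_side != 0 and axis_dev != 0:
            outward = 1.0 if (ip_side > 0) == (axis_dev > 0) else -1.0
        rotations.append(outward * ang)

    Ls = [s.L for s in seq.steps if s.L is not None]
    mean_L = float(np.mean(Ls)) if Ls else None

    return TrackwayMetrics(
        trackway_id=seq.trackway_id,
        paces=tuple(paces),
        strides=tuple(strides),
        wap=tuple(wap),
        pace_angulations=tuple(angulations),
        rotation_angles=tuple(rotations),
        mean_L=mean_L,
        alternation_ok=alternation_ok,
        notes=tuple(notes),
    )


def hip_height(FL: float) -> float:
    """Hip height in m from a track length ``FL`` in cm (h = 4 FL)."""
    if not (FL > 0) or not math.isfinite(FL):
        raise ValueError(f"track length must be positive, got {FL!r}")
    return 4.0 * FL / CM_PER_M


def velocity(lam: float, h: float, variant: str = "alexander") -> float:
    """Velocity in m/s from stride ``lam`` (m) and hip height ``h`` (m)."""
    if variant not in VELOCITY_COEFFICIENTS:
        raise ValueError(f"variant must be one of {sorted(VELOCITY_COEFFICIENTS)}")
    if not (h > 0) or not math.isfinite(h):
        raise ValueError(f"hip height must be positive, got {h!r}")
    if lam < 0 or not math.isfinite(lam):
        raise ValueError(f"stride must be >= 0, got {lam!r}")
    c = VELOCITY_COEFFICIENTS[variant]
    return c * GRAVITY**0.5 * lam**1.67 * h**-1.17


@dataclass(frozen=True)
class GaitResult:
    gait_ratio: float
    gait_category: str


def gait(lam: float, h: float) -> GaitResult:
    """Gait ratio lambda/h; walking < 2.0 < running, exactly 2.0 -> boundary."""
    if not (h > 0) or not math.isfinite(h):
        raise ValueError(f"hip height must be positive, got {h!r}")
    ratio = lam / h
    if ratio < GAIT_THRESHOLD:
        cat = "walking"
    elif ratio > GAIT_THRESHOLD:
        cat = "running"
    else:
        cat = "boundary"
    return GaitResult(ratio, cat)


def estimate_trackway(seq: TrackwaySequence) -> KinematicEstimates:
    """Kinematic estimates for a trackway (>= 3 steps with a measurable stride).

    FL is the mean of the step track lengths (unrounded) and lambda the mean
    stride; all four estimates come from these unrounded intermediates.
    """
    geom = trackway_geometry(seq)
    if not geom.strides:
        raise TrackwayError("no stride measurable: need at least 3 steps")
    Ls = [s.L for s in seq.steps if s.L is not None]
    if not Ls:
        raise TrackwayError("no track lengths recorded; hip height undefined")
    FL = float(np.mean(Ls))
    lam = float(np.mean(geom.strides))
    h = hip_height(FL)
    g = gait(lam, h)
    return KinematicEstimates(
        hip_height=h,
        velocity_alexander=velocity(lam, h, "alexander"),
        velocity_rt=velocity(lam, h, "rt"),
        gait_ratio=g.gait_ratio,
        gait_category=g.gait_category,
    )
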