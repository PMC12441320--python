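"""Landmark-based footprint measurement and derived-metric computation.

The measurement model
---------------------
A tridactyl pes track is reduced to six required landmarks: the three digit
tips (at the pad terminus, excluding ungual marks), the two interdigital
hypexes, and the posterior heel margin.  From these:

* ``L``  — heel to digit-III tip (the track axis runs heel -> tip_III);
* ``W``  — straight-line distance between the lateral digit tips, i.e. the
  base of the anterior triangle;
* ``te`` — perpendicular distance from the digit-III tip to the width line
  (anterior-triangle height), so mesaxony te/W is the standard
  anterior-triangle ratio;
* ``alpha``/``beta`` — interdigital angles II–III and III–IV, measured at the
  proximal intersection of the digit midlines.  This vertex is a *virtual*
  point (digit midlines converge posterior of the footprint on weakly splayed
  tracks); when it has been digitized it travels as the extension landmark
  ``x_axis_apex``, otherwise the heel stands in for it;
* ``L_II``/``L_IV`` — digit lengths from the adjacent hypex to the tip;
  ``L_III`` from the midpoint of the two hypexes to the tip.

Decoupling the angle vertex from the tip/hypex landmarks is what lets every
plausible metric combination (narrow divarication together with wide W and
strong mesaxony) be realised by an actual planar configuration — and hence
lets the synthetic generator invert the measurement exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import replace

import numpy as np

from .types import (
    DerivedMetrics,
    LandmarkSet,
    LengthCategory,
    Side,
    Relief,
    TrackMetrics,
    TrackRecord,
    length_category,
)

__all__ = [
    "IncompleteLandmarkError",
    "DegenerateLandmarkError",
    "measure_track",
    "derive_metrics",
    "apply_relief_siding",
    "validate_record",
    "Finding",
]

#: Two landmarks closer than this (cm) are treated as coincident.
_COINCIDENT_TOL = 1e-9
#: Lateral-tip collinearity tolerance for the te = 0 degenerate case (cm).
_COLLINEAR_TOL = 1e-9


class IncompleteLandmarkError(ValueError):
    """Raised when required landmarks are missing; carries their labels."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(f"incomplete landmark set: missing {', '.join(self.missing)}")


class DegenerateLandmarkError(ValueError):
    pass


def _dist(p: tuple[float, float], q: tuple[float, float]) -> float:
    return math.hypot(p[0] - q[0], p[1] - q[1])


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Unsigned angle (deg) between two 2-D vectors."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    c = float(np.dot(u, v) / (nu * nv))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def point_line_distance(
    p: tuple[float, float], a: tuple[float, float], b: tuple[float, float]
) -> float:
    """Perpendicular distance from ``p`` to the line through ``a`` and ``b``."""
    ax, ay = a
    bx, by = b
    px, py = p
    dx, dy = bx - ax, by - ay
    norm = math.hypot(dx, dy)
    if norm < _COINCIDENT_TOL:
        raise DegenerateLandmarkError("line endpoints coincide")
    return abs(dx * (py - ay) - dy * (px - ax)) / norm


def measure_track(landmarks: LandmarkSet) -> TrackMetrics:
    """Measure primary track metrics from a labeled landmark set.

    Raises
    ------
    IncompleteLandmarkError
        If a required landmark is missing.
    DegenerateLandmarkError
        If two required landmarks coincide.

    Notes
    -----
    Collinear digit tips (within tolerance) give ``te = 0`` with a warning
    rather than an error.  Hallux landmarks never contribute to any length.
    """
    missing = landmarks.missing_required()
    if missing:
        raise IncompleteLandmarkError(missing)

    pts = {k: np.asarray(v, dtype=float) for k, v in landmarks.points.items()}
    required = ["tip_II", "tip_III", "tip_IV", "hypex_II_III", "hypex_III_IV", "heel"]
    for i, a in enumerate(required):
        for b in required[i + 1 :]:
            if np.linalg.norm(pts[a] - pts[b]) < _COINCIDENT_TOL:
                raise DegenerateLandmarkError(f"landmarks {a!r} and {b!r} coincide")

    heel = pts["heel"]
    tip2, tip3, tip4 = pts["tip_II"], pts["tip_III"], pts["tip_IV"]
    h23, h34 = pts["hypex_II_III"], pts["hypex_III_IV"]
    midhypex = (h23 + h34) / 2.0

    L = float(np.linalg.norm(tip3 - heel))
    W = float(np.linalg.norm(tip2 - tip4))

    chord = tip4 - tip2
    if np.linalg.norm(chord) < _COLLINEAR_TOL:
        raise DegenerateLandmarkError("lateral digit tips coincide")
    te = point_line_distance(tuple(tip3), tuple(tip2), tuple(tip4))
    if te < _COLLINEAR_TOL:
        warnings.warn(
            f"{landmarks.track_id}: digit tips collinear within tolerance; te = 0",
            stacklevel=2,
        )
        te = 0.0

    # Interdigital angles are measured at the proximal intersection of the
    # digit midlines.  Where that (virtual) apex has been digitized it is the
    # extension landmark "x_axis_apex"; on material where the midlines cannot
    # be traced the heel serves as the vertex.
    apex = pts.get("x_axis_apex", heel)
    if (
        np.linalg.norm(tip2 - apex) < _COINCIDENT_TOL
        or np.linalg.norm(tip3 - apex) < _COINCIDENT_TOL
        or np.linalg.norm(tip4 - apex) < _COINCIDENT_TOL
    ):
        raise DegenerateLandmarkError("angle vertex coincides with a digit tip")
    alpha = _angle_between(tip2 - apex, tip3 - apex)
    beta = _angle_between(tip4 - apex, tip3 - apex)

    return TrackMetrics(
        L=L,
        W=W,
        L_II=float(np.linalg.norm(tip2 - h23)),
        L_III=float(np.linalg.norm(tip3 - midhypex)),
        L_IV=float(np.linalg.norm(tip4 - h34)),
        te=float(te),
        alpha=alpha,
        beta=beta,
    )


def _ratio(num: float | None, den: float | None, scale: float = 1.0) -> float | None:
    if num is None or den is None or den == 0:
        return None
    return scale * num / den


def derive_metrics(m: TrackMetrics) -> DerivedMetrics:
    """Derived ratios; any missing constituent or zero denominator gives ``None``."""
    return DerivedMetrics(
        lw_ratio=_ratio(m.L, m.W),
        r_iii_ii=_ratio(m.L_III, m.L_II),
        r_iii_iv=_ratio(m.L_III, m.L_IV),
        iii_over_L=_ratio(m.L_III, m.L, scale=100.0),
        mesaxony=_ratio(m.te, m.W),
        total_div=m.total_div,
    )


_MIRROR = {Side.LEFT: Side.RIGHT, Side.RIGHT: Side.LEFT}


def apply_relief_siding(record: TrackRecord) -> TrackRecord:
    """Resolve catalogued footedness from observed footedness and relief.

    Positive-relief tracks are infill casts on the base of beds, so their
    apparent footedness is reversed: an observed right is catalogued left, and
    the ``mirrored_for_relief`` flag is set.  Negative relief passes through.
    Indeterminate observed side passes through with a warning.
    """
    if record.side_observed is Side.INDETERMINATE:
        warnings.warn(
            f"{record.specimen_id}: indeterminate side; siding not resolved", stacklevel=2
        )
        return replace(record, side_catalogued=Side.INDETERMINATE)
    if record.relief is Relief.POSITIVE:
        return replace(
            record,
            side_catalogued=_MIRROR[record.side_observed],
            mirrored_for_relief=True,
        )
    return replace(record, side_catalogued=record.side_observed, mirrored_for_relief=False)


class Finding(str):
    """A consistency finding (plain string subclass for easy reporting)."""


# Tolerances absorb the tables' 2-d.p. rounding of the raw inputs.
_TOL_ANGLE = 0.02
_TOL_RATIO = 0.02
_TOL_PCT = 0.05


def validate_record(record: TrackRecord) -> list[Finding]:
    """Check the arithmetic identities a measurement row must satisfy.

    Returns findings (never raises): divarication additivity, the derived
    ratios against their constituents, and the length-category bin.
    """
    out: list[Finding] = []
    m, d = record.metrics, record.derived

    if m.alpha is not None and m.beta is not None and d.total_div is not None:
        if abs(d.total_div - (m.alpha + m.beta)) > _TOL_ANGLE:
            out.append(
                Finding(
                    f"divarication mismatch: total {d.total_div:.2f} != "
                    f"alpha+beta {m.alpha + m.beta:.2f}"
                )
            )

    checks = [
        ("lw_ratio", d.lw_ratio, _ratio(m.L, m.W), _TOL_RATIO),
        ("mesaxony", d.mesaxony, _ratio(m.te, m.W), _TOL_RATIO),
        ("iii_over_L", d.iii_over_L, _ratio(m.L_III, m.L, 100.0), _TOL_PCT),
    ]
    for name, stored, recomputed, tol in checks:
        if stored is not None and recomputed is not None and abs(stored - recomputed) > tol:
            out.append(
                Finding(f"{name} mismatch: stored {stored:.4f} vs recomputed {recomputed:.4f}")
            )

    cat_finding = check_length_category(m.L, record.length_category_label)
    if cat_finding is not None:
        out.append(cat_finding)
    return out


def check_length_category(L: float | None, labelled: LengthCategory | str | None) -> Finding | None:
    """Compare a labelled length class against the bins; ``None`` if consistent."""
    if L is None or labelled is None:
        return None
    expected = length_category(L)
    got = LengthCategory(labelled)
    if expected is not got:
        return Finding(f"category mismatch, expected {expected.value}, labelled {got.value}")
    return None
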