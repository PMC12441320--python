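"""Synthetic tridactyl tracks, trackways and assemblages.

The generator draws track metrics uniformly inside each Hebridean subgroup's
diagnosed ranges (the least-informative choice — the diagnoses report ranges,
not distributions), realises them as landmark sets by inverting the
measurement model exactly, degrades them with a wear model, and assembles
whole surfaces with either a directed (von Mises) or undirected (uniform)
bearing model.

Geometric inversion
-------------------
``construct_landmarks`` places, in closed form:

* the digit-III tip at ``(0, L)`` and the heel at the origin;
* the interdigital-axis apex at ``(0, -a)`` with the depth ``a`` solved from
  ``W = (L - te + a) (tan alpha + tan beta)`` so that the lateral tips lie on
  the apex rays at the requested angles *and* on a width line perpendicular
  to the track axis at height ``L - te`` (making W and te exact);
* the hypexes by circle intersection so that the digit lengths II and IV and
  the midhypex-to-tip distance III are exact, with the hypex midpoint on the
  track axis.

The apex is emitted as the extension landmark ``x_axis_apex``; measurement
uses it as the vertex for the interdigital angles (falling back to the heel
when absent, e.g. on heavily worn material).  Measuring a constructed set
therefore returns the input metrics to solver precision (~1e-12), which is
the module's central contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .geometry import derive_metrics, measure_track
from .types import (
    DigitShape,
    HalluxState,
    LandmarkSet,
    MorphologyFlags,
    Relief,
    Side,
    TrackMetrics,
    TrackRecord,
    TrackwaySequence,
    TrackwayStep,
    UngualMarks,
)

__all__ = [
    "SubgroupGenerator",
    "SUBGROUP_GENERATORS",
    "WearModel",
    "InfeasibleMetricsError",
    "sample_metrics",
    "construct_landmarks",
    "apply_wear",
    "generate_trackway",
    "generate_assemblage",
    "AssemblageConfig",
    "SyntheticAssemblage",
]


class InfeasibleMetricsError(ValueError):
    """A metric combination that no planar landmark configuration realises."""


Range = tuple[float, float]


@dataclass(frozen=True)
class SubgroupGenerator:
    """Uniform metric ranges and a morphology template for one subgroup.

    ``ranges`` are the diagnosed/described ranges; ``strict_ranges`` are
    nested inside them and inside the subgroup's *exclusive* region, so a
    strict draw (with the template flags) is recovered unambiguously by the
    classifier.  Subgroups whose identity is primarily morphological
    (HBR_B1.2, HBR_B2.3) have no exclusive metric region; their strict draws
    rely on the flag template.
    """

    subgroup_id: str
    ranges: Mapping[str, Range]
    strict_ranges: Mapping[str, Range]
    flags: MorphologyFlags
    grade_range: Range = (1.5, 2.0)

    def range_for(self, metric: str, strict: bool) -> Range:
        r = self.strict_ranges.get(metric) if strict else None
        if r is None:
            r = self.ranges[metric]
        lo, hi = r
        if not lo < hi:
            raise ValueError(f"{self.subgroup_id}: empty range for {metric}: {r}")
        return r


def _gen(
    sid: str,
    L: Range,
    lw: Range,
    M: Range,
    div: Range,
    iiiL: Range,
    r32: Range,
    r34: Range,
    strict: Mapping[str, Range],
    flags: MorphologyFlags,
) -> SubgroupGenerator:
    return SubgroupGenerator(
        subgroup_id=sid,
        ranges={
            "L": L, "lw_ratio": lw, "mesaxony": M, "total_div": div,
            "iii_over_L": iiiL, "r_iii_ii": r32, "r_iii_iv": r34,
        },
        strict_ranges=strict,
        flags=flags,
    )


_PARALLEL = MorphologyFlags(digit_shape=DigitShape.PARALLEL_SIDED, hallux=HalluxState.ABSENT,
                            ungual_marks=UngualMarks.ELONGATE)
_SPINDLE = MorphologyFlags(digit_shape=DigitShape.SPINDLE, hallux=HalluxState.ABSENT,
                           ungual_marks=UngualMarks.ELONGATE)

SUBGROUP_GENERATORS: dict[str, SubgroupGenerator] = {
    g.subgroup_id: g
    for g in [
        _gen(
            "HBR_B1.1",
            L=(40.0, 55.0), lw=(1.22, 1.66), M=(0.36, 0.52), div=(40.0, 60.0),
            iiiL=(58.0, 68.0), r32=(1.05, 1.25), r34=(0.85, 1.00),
            strict={"L": (41.0, 54.0), "lw_ratio": (1.25, 1.63),
                    "mesaxony": (0.37, 0.51), "total_div": (41.0, 59.0)},
            flags=_PARALLEL,
        ),
        _gen(
            "HBR_B1.2",
            L=(38.0, 48.0), lw=(1.05, 1.30), M=(0.38, 0.52), div=(65.0, 80.0),
            iiiL=(58.0, 68.0), r32=(0.95, 1.10), r34=(0.95, 1.10),
            strict={},
            flags=MorphologyFlags(
                digit_shape=DigitShape.SUB_PARALLEL,
                hallux=HalluxState.ANTEROLATERAL,
                heel_impressed=True,
            ),
        ),
        _gen(
            "HBR_B1.3",
            L=(28.0, 33.0), lw=(1.26, 1.32), M=(0.51, 0.55), div=(61.0, 78.0),
            iiiL=(58.0, 63.0), r32=(1.15, 1.25), r34=(1.05, 1.15),
            strict={"L": (29.0, 33.0), "lw_ratio": (1.27, 1.31),
                    "mesaxony": (0.515, 0.545), "total_div": (62.0, 78.0)},
            flags=MorphologyFlags(digit_shape=DigitShape.SUB_PARALLEL,
                                  hallux=HalluxState.ABSENT,
                                  ungual_marks=UngualMarks.ELONGATE),
        ),
        _gen(
            "HBR_B1.4",
            L=(30.5, 39.5), lw=(1.51, 1.79), M=(0.50, 0.71), div=(29.0, 45.0),
            iiiL=(55.0, 69.0), r32=(1.15, 1.60), r34=(0.70, 1.10),
            strict={"L": (31.0, 39.0), "lw_ratio": (1.55, 1.75),
                    "mesaxony": (0.52, 0.70), "total_div": (30.0, 44.0)},
            flags=_PARALLEL,
        ),
        _gen(
            "HBR_B2.1",
            L=(13.5, 27.0), lw=(1.31, 2.00), M=(0.47, 0.87), div=(30.5, 60.0),
            iiiL=(60.0, 90.0), r32=(1.00, 2.00), r34=(0.80, 1.60),
            strict={"L": (15.5, 24.5), "lw_ratio": (1.35, 1.95),
                    "mesaxony": (0.52, 0.85), "total_div": (32.0, 58.0)},
            flags=_SPINDLE,
        ),
        _gen(
            "HBR_B2.2",
            L=(13.2, 19.9), lw=(1.05, 1.30), M=(0.48, 0.59), div=(61.0, 80.0),
            iiiL=(67.0, 86.0), r32=(1.20, 1.90), r34=(0.90, 1.50),
            strict={"L": (13.5, 19.5), "lw_ratio": (1.06, 1.28),
                    "mesaxony": (0.47, 0.58), "total_div": (62.0, 79.0)},
            flags=_SPINDLE,
        ),
        _gen(
            "HBR_B2.3",
            L=(13.5, 19.5), lw=(0.91, 1.45), M=(0.40, 0.59), div=(44.0, 88.0),
            iiiL=(65.0, 85.0), r32=(1.20, 1.90), r34=(0.84, 1.40),
            strict={"L": (14.0, 19.0), "lw_ratio": (0.95, 1.40),
                    "mesaxony": (0.42, 0.58), "total_div": (46.0, 85.0)},
            flags=MorphologyFlags(
                digit_shape=DigitShape.BROAD_ROUND,
                hallux=HalluxState.ABSENT,
                ungual_marks=UngualMarks.ABSENT,
                inner_margins_present=True,
            ),
        ),
        _gen(
            "HBR_B3.1",
            L=(6.6, 13.3), lw=(1.51, 2.17), M=(0.54, 0.98), div=(25.5, 58.0),
            iiiL=(62.0, 95.0), r32=(1.20, 2.20), r34=(1.00, 2.00),
            strict={"L": (6.8, 12.9), "lw_ratio": (1.52, 2.10),
                    "mesaxony": (0.72, 0.95), "total_div": (26.0, 49.0)},
            flags=MorphologyFlags(digit_shape=DigitShape.GRACILE,
                                  hallux=HalluxState.ABSENT,
                                  ungual_marks=UngualMarks.ELONGATE,
                                  digits_well_separated=False),
        ),
        _gen(
            "HBR_B3.2",
            L=(6.4, 13.1), lw=(1.04, 1.40), M=(0.41, 0.78), div=(40.0, 107.0),
            iiiL=(60.0, 96.0), r32=(1.25, 2.10), r34=(0.90, 1.70),
            strict={"L": (10.2, 12.9), "lw_ratio": (1.07, 1.38),
                    "mesaxony": (0.43, 0.68), "total_div": (52.0, 100.0)},
            flags=MorphologyFlags(digit_shape=DigitShape.GRACILE,
                                  hallux=HalluxState.ABSENT,
                                  ungual_marks=UngualMarks.ELONGATE,
                                  digits_well_separated=True),
        ),
        _gen(
            "HBR_B4",
            L=(3.9, 6.4), lw=(0.90, 1.19), M=(0.46, 0.54), div=(63.0, 92.0),
            iiiL=(72.0, 89.0), r32=(1.10, 1.65), r34=(1.10, 1.35),
            strict={"L": (4.2, 6.3), "lw_ratio": (0.92, 1.18),
                    "mesaxony": (0.46, 0.54), "total_div": (64.0, 90.0)},
            flags=MorphologyFlags(digit_shape=DigitShape.GRACILE,
                                  hallux=HalluxState.ABSENT,
                                  ungual_marks=UngualMarks.SHORT,
                                  digits_well_separated=False),
        ),
    ]
}


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


_MAX_SAMPLE_ATTEMPTS = 200


def sample_metrics(
    subgroup: str, strict: bool = False, seed: int | np.random.Generator | None = None
) -> TrackMetrics:
    """Draw an internally consistent TrackMetrics inside a subgroup's ranges.

    L, l/w, mesaxony, divarication, III/L and the digit ratios are drawn
    uniformly; W, te and the digit lengths follow (te = mesaxony * W, etc.).
    Draws that no planar configuration realises are rejected and retried.
    Reproducible under ``seed``.
    """
    if subgroup not in SUBGROUP_GENERATORS:
        raise KeyError(f"unknown subgroup {subgroup!r}")
    gen = SUBGROUP_GENERATORS[subgroup]
    rng = _rng(seed)
    last_err: Exception | None = None
    for _ in range(_MAX_SAMPLE_ATTEMPTS):
        u = lambda name: float(rng.uniform(*gen.range_for(name, strict)))
        L = u("L")
        W = L / u("lw_ratio")
        te = u("mesaxony") * W
        div = u("total_div")
        split = float(rng.uniform(0.42, 0.58))
        alpha, beta = div * split, div * (1.0 - split)
        L_III = u("iii_over_L") * L / 100.0
        L_II = L_III / u("r_iii_ii")
        L_IV = L_III / u("r_iii_iv")
        m = TrackMetrics(L=L, W=W, L_II=L_II, L_III=L_III, L_IV=L_IV,
                         te=te, alpha=alpha, beta=beta)
        try:
            construct_landmarks(m)
        except InfeasibleMetricsError as e:
            last_err = e
            continue
        return m
    raise InfeasibleMetricsError(
        f"no feasible draw for {subgroup} after {_MAX_SAMPLE_ATTEMPTS} attempts: {last_err}"
    )


def _circle_intersection(
    c1: np.ndarray, r1: float, c2: np.ndarray, r2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Both intersection points of two circles; raises if they do not meet."""
    d = float(np.linalg.norm(c2 - c1))
    if d < 1e-12:
        raise InfeasibleMetricsError("digit-length circles are concentric")
    if d > r1 + r2 or d < abs(r1 - r2):
        raise InfeasibleMetricsError(
            "digit lengths II/IV incompatible with tip geometry and digit III length"
        )
    a = (d * d + r1 * r1 - r2 * r2) / (2 * d)
    h2 = r1 * r1 - a * a
    h = math.sqrt(max(0.0, h2))
    mid = c1 + a * (c2 - c1) / d
    perp = np.array([-(c2 - c1)[1], (c2 - c1)[0]]) / d
    return mid + h * perp, mid - h * perp


def construct_landmarks(
    metrics: TrackMetrics,
    side: Side = Side.LEFT,
    seed: int | np.random.Generator | None = None,
    track_id: str = "synthetic",
    relief: Relief = Relief.NEGATIVE,
) -> LandmarkSet:
    """Geometric inverse of :func:`trackmorph.geometry.measure_track`.

    Builds a landmark set whose measurement equals ``metrics`` to solver
    precision.  The heel sits at the origin with digit III along +y; ``side``
    is realised by mirroring (which leaves every metric unchanged).  When a
    ``seed`` is given the set is additionally subjected to a random rigid
    rotation and translation, mimicking the arbitrary origin of a digitized
    outline; metrics are invariant under this.

    Raises :class:`InfeasibleMetricsError` naming the violated constraint for
    combinations no planar track can realise (e.g. te >= L).
    """
    m = metrics
    needed = {"L": m.L, "W": m.W, "te": m.te, "alpha": m.alpha, "beta": m.beta,
              "L_II": m.L_II, "L_III": m.L_III, "L_IV": m.L_IV}
    missing = [k for k, v in needed.items() if v is None]
    if missing:
        raise InfeasibleMetricsError(f"metrics incomplete: missing {', '.join(missing)}")
    if m.te >= m.L:
        raise InfeasibleMetricsError(f"te ({m.te}) must be smaller than L ({m.L})")
    if m.W <= 0 or m.L <= 0:
        raise InfeasibleMetricsError("L and W must be positive")
    if not (0.0 < m.alpha < 90.0) or not (0.0 < m.beta < 90.0):
        raise InfeasibleMetricsError("interdigital angles must lie in (0, 90) degrees")

    ta, tb = math.tan(math.radians(m.alpha)), math.tan(math.radians(m.beta))
    y_chord = m.L - m.te
    # apex depth below the heel that realises W on a chord perpendicular to
    # the track axis at the height fixed by te
    a_depth = m.W / (ta + tb) - y_chord

    tip3 = np.array([0.0, m.L])
    heel = np.array([0.0, 0.0])
    apex = np.array([0.0, -a_depth])
    reach = y_chord + a_depth  # distance from apex to chord along the axis
    if reach <= 0:
        raise InfeasibleMetricsError("width incompatible with interdigital angles")
    tip2 = np.array([-reach * ta, y_chord])
    tip4 = np.array([reach * tb, y_chord])

    if m.L_III >= m.L + 1e-12:
        raise InfeasibleMetricsError(f"digit III length ({m.L_III}) exceeds L ({m.L})")
    mid = np.array([0.0, m.L - m.L_III])
    d1, d2 = _circle_intersection(tip2 - mid, m.L_II, mid - tip4, m.L_IV)
    # prefer the branch placing the II-III hypex on the digit-II side
    d = d1 if d1[0] <= d2[0] else d2
    h23 = mid + d
    h34 = mid - d

    pts = {
        "tip_II": tip2,
        "tip_III": tip3,
        "tip_IV": tip4,
        "hypex_II_III": h23,
        "hypex_III_IV": h34,
        "heel": heel,
        "x_axis_apex": apex,
    }
    if side is Side.RIGHT:
        pts = {k: np.array([-v[0], v[1]]) for k, v in pts.items()}

    if seed is not None:
        rng = _rng(seed)
        theta = float(rng.uniform(0, 2 * math.pi))
        offset = rng.uniform(-100, 100, size=2)
        R = np.array([[math.cos(theta), -math.sin(theta)],
                      [math.sin(theta), math.cos(theta)]])
        pts = {k: R @ v + offset for k, v in pts.items()}

    return LandmarkSet(
        track_id=track_id,
        side_observed=side,
        relief=relief,
        points={k: (float(v[0]), float(v[1])) for k, v in pts.items()},
    )


@dataclass(frozen=True)
class WearModel:
    """Degradation of a landmark set emulating wear-driven grade loss.

    ``severity`` 0 is the identity (grade 3); severity 1 jitters landmarks by
    ``landmark_jitter_sd`` cm, erodes digit tips by ``margin_erosion`` cm
    toward the track centroid, drops optional landmarks with probability
    ``dropout_prob``, and maps to grade <= 0.5.  All effects scale linearly
    with severity.  The grade map is monotone non-increasing in severity.
    """

    severity: float
    landmark_jitter_sd: float = 0.35  # cm at severity 1
    margin_erosion: float = 0.30  # cm at severity 1
    dropout_prob: float = 0.35  # per optional landmark at severity 1
    grade_map: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")

    def grade(self) -> float:
        if self.grade_map is not None:
            return self.grade_map(self.severity)
        # 3 at severity 0 down to 0.5 at severity 1, in 0.5 steps
        return max(0.5, round((3.0 - 2.5 * self.severity) * 2) / 2)


def apply_wear(
    landmarks: LandmarkSet,
    model: WearModel,
    seed: int | np.random.Generator | None = None,
) -> tuple[LandmarkSet, float]:
    """Degrade a landmark set; returns (worn set, assigned preservation grade)."""
    if model.severity == 0.0:
        return landmarks, model.grade()
    rng = _rng(seed)
    s = model.severity
    pts = {k: np.asarray(v, dtype=float) for k, v in landmarks.points.items()}
    centroid = np.mean([pts[k] for k in ("tip_II", "tip_III", "tip_IV", "heel") if k in pts], axis=0)

    out: dict[str, tuple[float, float]] = {}
    for label, p in pts.items():
        required = label in {"tip_II", "tip_III", "tip_IV", "hypex_II_III", "hypex_III_IV", "heel"}
        if not required and rng.uniform() < s * model.dropout_prob:
            continue
        q = p.copy()
        if label.startswith("tip"):
            to_c = centroid - q
            norm = np.linalg.norm(to_c)
            if norm > 1e-9:
                q = q + to_c / norm * min(s * model.margin_erosion, 0.5 * norm)
        q = q + rng.normal(0.0, s * model.landmark_jitter_sd, size=2)
        out[label] = (float(q[0]), float(q[1]))
    worn = LandmarkSet(
        track_id=landmarks.track_id,
        side_observed=landmarks.side_observed,
        relief=landmarks.relief,
        points=out,
    )
    return worn, model.grade()


def generate_trackway(
    subgroup: str,
    n_steps: int,
    gait_ratio: float,
    step_width: float = 8.0,
    seed: int | np.random.Generator | None = None,
    forced_L: float | None = None,
) -> TrackwaySequence:
    """Generate a straight trackway whose kinematics invert to ``gait_ratio``.

    The track length L is drawn once from the subgroup range (or forced); the
    stride is ``gait_ratio * 4 L`` so that estimating the trackway recovers
    the requested gait exactly at zero jitter.  Feet alternate with lateral
    IP offsets of ``step_width / 2`` cm about the midline.
    """
    if n_steps < 2:
        raise ValueError("need at least 2 steps")
    if gait_ratio <= 0:
        raise ValueError("gait ratio must be positive")
    rng = _rng(seed)
    if forced_L is not None:
        L = float(forced_L)
    else:
        lo, hi = SUBGROUP_GENERATORS[subgroup].range_for("L", strict=False)
        L = float(rng.uniform(lo, hi))
    stride_cm = gait_ratio * 4.0 * L  # h = 4 L, lambda = gait * h
    steps = []
    for i in range(n_steps):
        x = (step_width / 2.0) * (1 if i % 2 else -1)
        y = i * stride_cm / 2.0
        steps.append(
            TrackwayStep(
                track_id=f"{subgroup}-t{i + 1}",
                ip=(x, y),
                foot=Side.LEFT if i % 2 == 0 else Side.RIGHT,
                L=L,
                axis_bearing=0.0,
            )
        )
    return TrackwaySequence(
        trackway_id=f"synthetic-{subgroup}", steps=tuple(steps),
        surface_frame_note="synthetic surface frame",
    )


@dataclass(frozen=True)
class AssemblageConfig:
    """Mixture + wear + bearing model for a synthetic track surface."""

    mixture: Mapping[str, float]  # subgroup -> weight (>= 0, sums to 1)
    n_tracks: int
    wear_severity: float = 0.0
    bearing_model: str = "uniform"  # uniform | vonmises
    bearing_mu: float = 0.0  # deg
    bearing_kappa: float = 8.0
    strict: bool = False
    surface_id: str = "synthetic-surface"

    def __post_init__(self) -> None:
        w = list(self.mixture.values())
        if any(x < 0 for x in w):
            raise ValueError("mixture weights must be >= 0")
        if w and abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if self.bearing_model not in ("uniform", "vonmises"):
            raise ValueError("bearing model must be 'uniform' or 'vonmises'")


@dataclass(frozen=True)
class SyntheticTrack:
    record: TrackRecord
    landmarks: LandmarkSet
    subgroup: str


@dataclass(frozen=True)
class SyntheticAssemblage:
    config: AssemblageConfig
    seed: int | None
    tracks: tuple[SyntheticTrack, ...]

    @property
    def records(self) -> list[TrackRecord]:
        return [t.record for t in self.tracks]

    @property
    def bearings(self) -> list[float]:
        return [t.record.bearing for t in self.tracks if t.record.bearing is not None]


def generate_assemblage(config: AssemblageConfig, seed: int | None = None) -> SyntheticAssemblage:
    """Draw a whole synthetic surface: records, landmark sets and bearings."""
    rng = _rng(seed)
    subs = list(config.mixture)
    weights = np.array([config.mixture[s] for s in subs], dtype=float)
    tracks: list[SyntheticTrack] = []
    for i in range(config.n_tracks):
        sub = subs[int(rng.choice(len(subs), p=weights))] if subs else None
        if sub is None:
            break
        metrics = sample_metrics(sub, strict=config.strict, seed=rng)
        side = Side.LEFT if rng.uniform() < 0.5 else Side.RIGHT
        lm = construct_landmarks(metrics, side=side, track_id=f"syn-{i + 1:03d}")
        grade = 3.0
        if config.wear_severity > 0:
            lm, grade = apply_wear(lm, WearModel(config.wear_severity), seed=rng)
        if config.bearing_model == "vonmises":
            b = math.degrees(rng.vonmises(math.radians(config.bearing_mu), config.bearing_kappa))
        else:
            b = float(rng.uniform(0.0, 360.0))
        b %= 360.0
        measured = measure_track(lm) if lm.complete else TrackMetrics()
        rec = TrackRecord(
            specimen_id=f"syn-{i + 1:03d}",
            locality=config.surface_id,
            formation="synthetic",
            side_observed=side,
            side_catalogued=side,
            relief=Relief.NEGATIVE,
            preservation_grade=grade,
            flags=SUBGROUP_GENERATORS[sub].flags,
            metrics=measured,
            derived=derive_metrics(measured),
            bearing=b,
            published_subgroup=sub,
            published_status=None,
        )
        tracks.append(SyntheticTrack(record=rec, landmarks=lm, subgroup=sub))
    return SyntheticAssemblage(config=config, seed=seed, tracks=tuple(tracks))
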