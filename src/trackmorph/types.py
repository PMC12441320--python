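"""Domain types for tridactyl track morphometrics.

All linear measurements are centimetres, all angles degrees, unless a field
says otherwise.  Missing values are represented by ``None`` (never zero-filled)
and every derived quantity propagates ``None``.

Conventions
-----------
* A track's landmark frame is planar with an arbitrary origin; after
  normalisation digit III points along +y (anterior).
* ``side_observed`` is the footedness apparent on the surface; positive-relief
  casts on the base of beds reverse it, so ``side_catalogued`` may differ
  (see :func:`trackmorph.geometry.apply_relief_siding`).
* Preservation grade is an ordinal 0–3 score in 0.5 steps; grade >= 1.5 tracks
  anchor morphotype definitions, grade-1 tracks characterize only when surface
  wear is judged acceptable, lower grades are at best referred.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

__all__ = [
    "Side",
    "Relief",
    "DigitShape",
    "HalluxState",
    "UngualMarks",
    "LengthCategory",
    "REQUIRED_LANDMARKS",
    "OPTIONAL_LANDMARKS",
    "LandmarkSet",
    "TrackMetrics",
    "DerivedMetrics",
    "MorphologyFlags",
    "TrackRecord",
    "Classification",
    "TrackwayStep",
    "TrackwaySequence",
    "TrackwayMetrics",
    "KinematicEstimates",
    "BearingSet",
    "MetricRelation",
    "AssemblageSummary",
    "length_category",
    "VALID_GRADES",
]


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    INDETERMINATE = "indeterminate"


class Relief(str, enum.Enum):
    NEGATIVE = "negative"
    POSITIVE = "positive"


class DigitShape(str, enum.Enum):
    PARALLEL_SIDED = "parallel_sided"
    SUB_PARALLEL = "sub_parallel"
    SPINDLE = "spindle"
    GRACILE = "gracile"
    BROAD_ROUND = "broad_round"


class HalluxState(str, enum.Enum):
    ABSENT = "absent"
    ANTEROLATERAL = "anterolateral"
    POSTERIOR = "posterior"
    UNCERTAIN = "uncertain"


class UngualMarks(str, enum.Enum):
    ABSENT = "absent"
    SHORT = "short"
    ELONGATE = "elongate"


class LengthCategory(str, enum.Enum):
    TINY = "tiny"
    SMALL = "small"
    MEDIUM = "medium"
    LARGE = "large"
    GIANT = "giant"


#: Length-class bins for theropod pes tracks (cm, lower inclusive).
LENGTH_BINS: Sequence[tuple[float, float, LengthCategory]] = (
    (0.0, 10.0, LengthCategory.TINY),
    (10.0, 20.0, LengthCategory.SMALL),
    (20.0, 30.0, LengthCategory.MEDIUM),
    (30.0, 50.0, LengthCategory.LARGE),
    (50.0, math.inf, LengthCategory.GIANT),
)

VALID_GRADES = frozenset(g / 2.0 for g in range(0, 7))

REQUIRED_LANDMARKS = frozenset(
    {"tip_II", "tip_III", "tip_IV", "hypex_II_III", "hypex_III_IV", "heel"}
)
OPTIONAL_LANDMARKS = frozenset({"hallux_tip", "hallux_base", "lat_II", "lat_IV"})


def length_category(L: float | None) -> LengthCategory | None:
    """Length class for a total track length ``L`` in cm (``None`` passes through)."""
    if L is None:
        return None
    if not math.isfinite(L) or L <= 0:
        raise ValueError(f"track length must be positive and finite, got {L!r}")
    for lo, hi, cat in LENGTH_BINS:
        if lo <= L < hi:
            return cat
    return LengthCategory.GIANT


@dataclass(frozen=True)
class LandmarkSet:
    """Labeled 2-D footprint points (cm) for one track.

    ``points`` maps label -> (x, y).  A set is *complete* when every label in
    :data:`REQUIRED_LANDMARKS` is present.  Hallux points never contribute to
    length measurement.
    """

    track_id: str
    side_observed: Side
    relief: Relief
    points: Mapping[str, tuple[float, float]]

    def missing_required(self) -> list[str]:
        return sorted(REQUIRED_LANDMARKS - set(self.points))

    @property
    def complete(self) -> bool:
        return not self.missing_required()

    def __post_init__(self) -> None:
        for label, (x, y) in self.points.items():
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError(f"non-finite coordinate for landmark {label!r}")


@dataclass(frozen=True)
class TrackMetrics:
    """Primary footprint measurements (Fig-3a style).

    ``te`` is the digit-III toe extension: the height of the anterior triangle
    whose base joins the lateral digit tips.  ``alpha`` is the II–III
    interdigital angle, ``beta`` the III–IV one; ``total_div`` their sum.
    Ungual marks are excluded from all lengths by convention (tips are digitized
    at the pad terminus).
    """

    L: float | None = None
    W: float | None = None
    L_II: float | None = None
    L_III: float | None = None
    L_IV: float | None = None
    te: float | None = None
    alpha: float | None = None
    beta: float | None = None

    @property
    def total_div(self) -> float | None:
        if self.alpha is None or self.beta is None:
            return None
        return self.alpha + self.beta

    def __post_init__(self) -> None:
        for name in ("L", "W", "L_II", "L_III", "L_IV", "te", "alpha", "beta"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be >= 0 and finite, got {v!r}")


@dataclass(frozen=True)
class DerivedMetrics:
    """Ratios derived from :class:`TrackMetrics`.

    ``iii_over_L`` is a percentage; the rest are dimensionless.  A field is
    ``None`` iff a constituent measurement is missing or a denominator is zero.
    """

    lw_ratio: float | None = None
    r_iii_ii: float | None = None
    r_iii_iv: float | None = None
    iii_over_L: float | None = None
    mesaxony: float | None = None
    total_div: float | None = None


@dataclass(frozen=True)
class MorphologyFlags:
    """Qualitative morphology observations; ``None`` means 'not assessable'."""

    digit_shape: DigitShape | None = None
    hallux: HalluxState | None = None
    ungual_marks: UngualMarks | None = None
    pad_formula: str | None = None
    digits_well_separated: bool | None = None
    inner_margins_present: bool | None = None
    heel_impressed: bool | None = None


@dataclass(frozen=True)
class TrackRecord:
    """One footprint: provenance + measurements + morphology."""

    specimen_id: str
    locality: str = ""
    sublocality: str = ""
    formation: str = ""
    bed: str | None = None
    side_observed: Side = Side.INDETERMINATE
    side_catalogued: Side = Side.INDETERMINATE
    relief: Relief = Relief.NEGATIVE
    mirrored_for_relief: bool = False
    preservation_grade: float | None = None
    flags: MorphologyFlags = field(default_factory=MorphologyFlags)
    metrics: TrackMetrics = field(default_factory=TrackMetrics)
    derived: DerivedMetrics = field(default_factory=DerivedMetrics)
    bearing: float | None = None
    length_category_label: str | None = None
    wear_acceptable: bool = False
    published_subgroup: str | None = None
    published_status: str | None = None
    source_table: str | None = None
    is_summary_row: bool = False  # table "average" rows: not an observation

    def __post_init__(self) -> None:
        g = self.preservation_grade
        if g is not None and not self.is_summary_row and g not in VALID_GRADES:
            raise ValueError(f"preservation grade must be in {sorted(VALID_GRADES)}, got {g!r}")

    @property
    def length_category(self) -> LengthCategory | None:
        return length_category(self.metrics.L)

    def with_derived(self, derived: DerivedMetrics) -> "TrackRecord":
        return replace(self, derived=derived)


@dataclass(frozen=True)
class Classification:
    """Outcome of the Hebridean-series rule engine for one record."""

    subgroup: str | None
    series: str | None
    status: str  # characterized | referred | unclassified
    matched: Mapping[str, tuple[float, tuple[str, ...]]]  # subgroup -> (score, predicates)
    ambiguity: tuple[str, ...] = ()
    suggested_ichnotaxon: str | None = None
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class TrackwayStep:
    """One track in an ordered trackway: reference point (IP) + foot + length."""

    track_id: str
    ip: tuple[float, float]  # cm, surface frame
    foot: Side
    L: float | None = None  # cm
    axis_bearing: float | None = None  # deg, surface frame (clockwise from +y)

    def __post_init__(self) -> None:
        x, y = self.ip
        if not (math.isfinite(x) and math.isfinite(y)):
            raise ValueError(f"non-finite IP for step {self.track_id!r}")


@dataclass(frozen=True)
class TrackwaySequence:
    trackway_id: str
    steps: tuple[TrackwayStep, ...]
    surface_frame_note: str = "hypothetical north"

    def __post_init__(self) -> None:
        if len(self.steps) < 2:
            # Accepted at type level for pace-only "track associations";
            # trackway_geometry itself insists on >= 2.
            pass


@dataclass(frozen=True)
class TrackwayMetrics:
    """Trackway geometry.  Paces and strides in m, WAP in cm, angles in deg."""

    trackway_id: str
    paces: tuple[float, ...]
    strides: tuple[float, ...]
    wap: tuple[float, ...]
    pace_angulations: tuple[float, ...]
    rotation_angles: tuple[float | None, ...]
    mean_L: float | None  # cm
    alternation_ok: bool = True
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class KinematicEstimates:
    """Trackmaker estimates from hip-height and stride relations."""

    hip_height: float  # m
    velocity_alexander: float  # m/s
    velocity_rt: float  # m/s
    gait_ratio: float
    gait_category: str  # walking | running | boundary


@dataclass(frozen=True)
class BearingSet:
    surface_id: str
    bearings: tuple[float, ...]  # deg in [0, 360)
    frame: str = "hypothetical_north"

    def __post_init__(self) -> None:
        for b in self.bearings:
            if not math.isfinite(b):
                raise ValueError("non-finite bearing")

    @staticmethod
    def wrapped(surface_id: str, bearings: Sequence[float], frame: str = "hypothetical_north") -> "BearingSet":
        return BearingSet(surface_id, tuple(b % 360.0 for b in bearings), frame)


@dataclass(frozen=True)
class MetricRelation:
    x_name: str
    y_name: str
    inclusion_rule: str
    n: int
    pearson_r: float | None
    note: str | None = None


@dataclass(frozen=True)
class AssemblageSummary:
    per_subgroup_means: Mapping[str, Mapping[str, float]]
    counts: Mapping[tuple[str, str, str], int]  # (locality, subgroup, status) -> n
    n_characterized: int
    n_referred: int
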