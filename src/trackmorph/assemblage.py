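"""Assemblage-level aggregation: subgroup summary tables, abundance counts,
track-bearing circular statistics, and metric-relationship analyses.

Summary means follow the measurement tables' own convention: they average the
recorded (display-precision) column values over characterized rows only, with
missing values excluded column-wise.  Correlations are sample Pearson
coefficients over rows selected by an explicit, named inclusion rule, because
published exclusion sets for such scatterplots are rarely recoverable exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .classify import _metric_map
from .types import (
    AssemblageSummary,
    BearingSet,
    Classification,
    MetricRelation,
    TrackRecord,
)

__all__ = [
    "summarize",
    "metric_correlation",
    "allometry_panel",
    "bearing_rose",
    "count_report",
    "RoseResult",
    "CountReport",
    "AllometryPanel",
]

#: Columns averaged in subgroup summary rows (stored display values).
SUMMARY_COLUMNS = (
    "PG",
    "L",
    "W",
    "lw_ratio",
    "L_II",
    "L_III",
    "L_IV",
    "r_iii_ii",
    "r_iii_iv",
    "iii_over_L",
    "alpha",
    "beta",
    "total_div",
    "te",
    "mesaxony",
)


def _stored_values(record: TrackRecord) -> dict[str, float | None]:
    """Stored column values (printed precision where transcribed)."""
    m, d = record.metrics, record.derived
    return {
        "PG": record.preservation_grade,
        "L": m.L,
        "W": m.W,
        "lw_ratio": d.lw_ratio,
        "L_II": m.L_II,
        "L_III": m.L_III,
        "L_IV": m.L_IV,
        "r_iii_ii": d.r_iii_ii,
        "r_iii_iv": d.r_iii_iv,
        "iii_over_L": d.iii_over_L,
        "alpha": m.alpha,
        "beta": m.beta,
        "total_div": d.total_div if d.total_div is not None else m.total_div,
        "te": m.te,
        "mesaxony": d.mesaxony,
    }


def _subgroup_of(record: TrackRecord, cl: Classification | None) -> str | None:
    if record.published_subgroup:
        return record.published_subgroup
    return cl.subgroup if cl is not None else None


def _status_of(record: TrackRecord, cl: Classification | None) -> str | None:
    if record.published_status:
        return record.published_status
    return cl.status if cl is not None else None


def summarize(
    records: Sequence[TrackRecord],
    classifications: Sequence[Classification] | None = None,
) -> AssemblageSummary:
    """Per-subgroup means over characterized rows + abundance counts.

    Subgroup and status come from the records' published columns where
    present, otherwise from the supplied classifications.
    """
    cls: Sequence[Classification | None]
    cls = classifications if classifications is not None else [None] * len(records)

    groups: dict[str, list[dict[str, float | None]]] = {}
    counts: dict[tuple[str, str, str], int] = {}
    n_char = n_ref = 0
    for rec, cl in zip(records, cls):
        sub = _subgroup_of(rec, cl) or "unassigned"
        status = _status_of(rec, cl) or "unclassified"
        key = (rec.locality or "unknown", sub, status)
        counts[key] = counts.get(key, 0) + 1
        if status == "characterized":
            n_char += 1
            groups.setdefault(sub, []).append(_stored_values(rec))
        elif status == "referred":
            n_ref += 1

    means: dict[str, dict[str, float]] = {}
    for sub, rows in groups.items():
        col_means = {}
        for col in SUMMARY_COLUMNS:
            vals = [r[col] for r in rows if r[col] is not None]
            if vals:
                col_means[col] = float(np.mean(vals))
        means[sub] = col_means

    return AssemblageSummary(
        per_subgroup_means=means,
        counts=counts,
        n_characterized=n_char,
        n_referred=n_ref,
    )


def _select_rule(
    records: Sequence[TrackRecord],
    classifications: Sequence[Classification] | None,
    inclusion_rule: str,
) -> list[TrackRecord]:
    cls = classifications if classifications is not None else [None] * len(records)
    if inclusion_rule == "both-present":
        return list(records)
    if inclusion_rule == "characterized":
        return [r for r, c in zip(records, cls) if _status_of(r, c) == "characterized"]
    if inclusion_rule.startswith("exclude-subgroups:"):
        excluded = {s.strip() for s in inclusion_rule.split(":", 1)[1].split(",")}
        return [r for r, c in zip(records, cls) if _subgroup_of(r, c) not in excluded]
    raise ValueError(f"unknown inclusion rule {inclusion_rule!r}")


def metric_correlation(
    records: Sequence[TrackRecord],
    x: str,
    y: str,
    inclusion_rule: str = "both-present",
    classifications: Sequence[Classification] | None = None,
) -> MetricRelation:
    """Sample Pearson correlation of two metrics over selected rows.

    Rows missing either metric are always dropped on top of the named rule.
    ``r`` is undefined (None) for n < 3 or zero variance in either variable.
    """
    selected = _select_rule(records, classifications, inclusion_rule)
    xs, ys = [], []
    for rec in selected:
        mm = _metric_map(rec)
        if mm.get(x) is not None and mm.get(y) is not None:
            xs.append(mm[x])
            ys.append(mm[y])
    n = len(xs)
    if n < 3:
        return MetricRelation(x, y, inclusion_rule, n, None, note="n < 3: r undefined")
    ax, ay = np.asarray(xs), np.asarray(ys)
    if np.ptp(ax) == 0 or np.ptp(ay) == 0:
        return MetricRelation(x, y, inclusion_rule, n, None, note="zero variance: r undefined")
    r = float(np.corrcoef(ax, ay)[0, 1])
    return MetricRelation(x, y, inclusion_rule, n, r)


@dataclass(frozen=True)
class AllometryPanel:
    """(L - te, te) pairs: central-digit pronouncement vs remaining length."""

    points: tuple[tuple[float, float], ...]
    slope: float | None
    intercept: float | None


def allometry_panel(records: Sequence[TrackRecord]) -> AllometryPanel:
    """Toe-extension allometry: te against the remaining track length L - te.

    Emits the coordinate pairs and a descriptive ordinary-least-squares slope
    (no inferential statistics).  Slope undefined for fewer than two distinct
    abscissae.
    """
    pts = []
    for rec in records:
        L, te = rec.metrics.L, rec.metrics.te
        if L is not None and te is not None:
            pts.append((L - te, te))
    if len(pts) >= 2 and len({round(p[0], 12) for p in pts}) >= 2:
        xs = np.array([p[0] for p in pts])
        ys = np.array([p[1] for p in pts])
        slope, intercept = np.polyfit(xs, ys, 1)
        return AllometryPanel(tuple(pts), float(slope), float(intercept))
    return AllometryPanel(tuple(pts), None, None)


@dataclass(frozen=True)
class RoseResult:
    surface_id: str
    bin_width: float
    bin_edges: tuple[float, ...]  # left edges, deg
    counts: tuple[int, ...]
    n: int
    mean_direction: float | None  # deg, None when no preferred direction
    rbar: float  # mean resultant length in [0, 1]
    note: str | None = None


#: Below this mean resultant length the mean direction is not meaningful.
_RBAR_FLOOR = 1e-9


def bearing_rose(bearings: BearingSet, bin_width: float = 15.0) -> RoseResult:
    """Bin bearings into a windrose and compute the circular summary.

    ``bin_width`` must divide 360.  Bins are [k*w, (k+1)*w).  The circular
    mean direction and mean resultant length R-bar come from the unit-vector
    sum; R-bar near 0 is reported as "no preferred direction".
    """
    if bin_width <= 0 or abs(360.0 / bin_width - round(360.0 / bin_width)) > 1e-9:
        raise ValueError(f"bin width {bin_width!r} does not divide 360")
    nbins = int(round(360.0 / bin_width))
    wrapped = np.asarray([b % 360.0 for b in bearings.bearings], dtype=float)
    counts, edges = np.histogram(wrapped, bins=nbins, range=(0.0, 360.0))
    n = len(wrapped)

    if n == 0:
        return RoseResult(
            bearings.surface_id, bin_width, tuple(edges[:-1]), tuple(int(c) for c in counts),
            0, None, 0.0, note="empty bearing set",
        )
    rad = np.radians(wrapped)
    C, S = float(np.cos(rad).sum()), float(np.sin(rad).sum())
    rbar = math.hypot(C, S) / n
    if rbar < _RBAR_FLOOR:
        mean_dir, note = None, "no preferred direction"
    else:
        mean_dir = math.degrees(math.atan2(S, C)) % 360.0
        note = "no preferred direction" if rbar < 0.1 else None
    return RoseResult(
        bearings.surface_id,
        bin_width,
        tuple(edges[:-1]),
        tuple(int(c) for c in counts),
        n,
        mean_dir,
        rbar,
        note,
    )


@dataclass(frozen=True)
class CountReport:
    by_status: Mapping[str, int]
    by_subgroup: Mapping[str, int]
    by_locality_subgroup: Mapping[tuple[str, str], int]
    n_characterized: int
    n_referred: int
    max_divarication: float | None
    max_divarication_specimen: str | None

    def to_text(self) -> str:
        lines = ["status counts:"]
        for k in sorted(self.by_status):
            lines.append(f"  {k}: {self.by_status[k]}")
        lines.append("subgroup counts:")
        for k in sorted(self.by_subgroup):
            lines.append(f"  {k}: {self.by_subgroup[k]}")
        lines.append("locality x subgroup:")
        for (loc, sub) in sorted(self.by_locality_subgroup):
            lines.append(f"  {loc} / {sub}: {self.by_locality_subgroup[(loc, sub)]}")
        if self.max_divarication is not None:
            lines.append(
                f"max ii-iv divarication: {self.max_divarication:.2f} deg "
                f"({self.max_divarication_specimen})"
            )
        return "\n".join(lines)


def count_report(
    records: Sequence[TrackRecord],
    classifications: Sequence[Classification] | None = None,
) -> CountReport:
    """Totals by status, subgroup and locality, plus the extreme divarication."""
    cls = classifications if classifications is not None else [None] * len(records)
    by_status: dict[str, int] = {}
    by_subgroup: dict[str, int] = {}
    by_loc: dict[tuple[str, str], int] = {}
    max_div: float | None = None
    max_div_spec: str | None = None
    for rec, cl in zip(records, cls):
        status = _status_of(rec, cl) or "unclassified"
        sub = _subgroup_of(rec, cl) or "unassigned"
        by_status[status] = by_status.get(status, 0) + 1
        by_subgroup[sub] = by_subgroup.get(sub, 0) + 1
        key = (rec.locality or "unknown", sub)
        by_loc[key] = by_loc.get(key, 0) + 1
        d = rec.derived.total_div
        if d is None:
            d = rec.metrics.total_div
        if d is not None and (max_div is None or d > max_div):
            max_div, max_div_spec = d, rec.specimen_id
    return CountReport(
        by_status=by_status,
        by_subgroup=by_subgroup,
        by_locality_subgroup=by_loc,
        n_characterized=by_status.get("characterized", 0),
        n_referred=by_status.get("referred", 0),
        max_divarication=max_div,
        max_divarication_specimen=max_div_spec,
    )
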