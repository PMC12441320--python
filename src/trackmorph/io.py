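"""Readers and writers for the delimited interchange formats.

All formats are comma-delimited text with ``n/a`` for missing values — the
data volumes in this domain are tiny and plain text keeps the packaged
measurement tables auditable.

Measurement table
    Core columns, in order:
    ``specimen,PG,L/R,L,W,L/W,II,III,IV,III/II,III/IV,III/L,II-III,III-IV,
    II-IV,te,M`` followed by optional extension columns (``is_average``,
    provenance, morphology flags).  Lengths in cm, III/L in percent, angles
    in degrees.  An ``L/R`` entry with a ``*`` marks a positive-relief cast
    whose catalogued side is the reverse of the side observed on the slab.

Landmark file
    One row per point: ``track_id,side,relief,label,x_cm,y_cm``.  Labels
    outside the documented set are rejected unless they use the ``x_``
    extension namespace.

Trackway file
    One row per step: ``trackway_id,track_id,foot,x_cm,y_cm,
    axis_bearing_deg,L_cm``.

Bearing file
    One row per track: ``surface_id,track_id,bearing_deg``.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import replace
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from . import __version__
from .geometry import derive_metrics
from .types import (
    OPTIONAL_LANDMARKS,
    REQUIRED_LANDMARKS,
    BearingSet,
    Classification,
    DerivedMetrics,
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
    "CORE_COLUMNS",
    "TableFormatError",
    "read_measurement_table",
    "write_measurement_table",
    "load_fixture",
    "fixture_path",
    "fixture_sha256",
    "read_landmark_file",
    "write_landmark_file",
    "read_trackway_file",
    "write_trackway_file",
    "read_bearing_file",
    "write_bearing_file",
    "write_results",
    "round_display",
]

CORE_COLUMNS = [
    "specimen", "PG", "L/R", "L", "W", "L/W", "II", "III", "IV",
    "III/II", "III/IV", "III/L", "II-III", "III-IV", "II-IV", "te", "M",
]
EXTENSION_COLUMNS = [
    "is_average", "source_table", "published_subgroup", "published_status",
    "locality", "sublocality", "formation", "bed", "bearing_deg",
    "length_category", "digit_shape", "hallux", "ungual_marks", "pad_formula",
    "digits_well_separated", "inner_margins_present", "heel_impressed",
    "wear_acceptable",
]


class TableFormatError(ValueError):
    pass


def _parse_float(value: str, column: str, row_num: int) -> float | None:
    v = value.strip()
    if v in ("", "n/a", "na", "-", "—"):
        return None
    try:
        return float(v)
    except ValueError:
        raise TableFormatError(
            f"row {row_num}: unparseable numeric value {value!r} in column {column!r}"
        ) from None


def _parse_side(value: str, row_num: int) -> tuple[Side, Relief, bool]:
    """Parse an L/R cell into (side_catalogued, relief, mirrored flag)."""
    v = value.strip()
    positive = "*" in v
    letter = v.replace("*", "").replace("?", "").strip()
    if letter in ("", "-", "—"):
        side = Side.INDETERMINATE
    elif letter.upper() == "L":
        side = Side.LEFT
    elif letter.upper() == "R":
        side = Side.RIGHT
    else:
        raise TableFormatError(f"row {row_num}: unrecognised L/R value {value!r}")
    relief = Relief.POSITIVE if positive else Relief.NEGATIVE
    return side, relief, positive


def _parse_bool(value: str) -> bool | None:
    v = value.strip().lower()
    if v in ("", "n/a", "na", "-"):
        return None
    if v in ("1", "true", "yes"):
        return True
    if v in ("0", "false", "no"):
        return False
    raise TableFormatError(f"unrecognised boolean value {value!r}")


def _parse_enum(enum_cls, value: str):
    v = value.strip()
    if v in ("", "n/a", "na", "-"):
        return None
    return enum_cls(v)


_MIRROR = {Side.LEFT: Side.RIGHT, Side.RIGHT: Side.LEFT, Side.INDETERMINATE: Side.INDETERMINATE}


def read_measurement_table(
    path: str | Path, include_averages: bool = False
) -> list[TrackRecord]:
    """Read a measurement table into TrackRecords.

    ``n/a`` denotes missing; rows flagged ``is_average`` are summary rows and
    skipped unless requested.  An unknown column or malformed numeric is a
    hard error naming the offender.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        if header[: len(CORE_COLUMNS)] != CORE_COLUMNS:
            raise TableFormatError(
                f"{path.name}: header must start with the core columns "
                f"{','.join(CORE_COLUMNS)}; got {','.join(header[:len(CORE_COLUMNS)])}"
            )
        unknown = [c for c in header[len(CORE_COLUMNS):] if c not in EXTENSION_COLUMNS and not c.startswith("x_")]
        if unknown:
            raise TableFormatError(
                f"{path.name}: unknown columns {unknown}; allowed extensions are "
                f"{EXTENSION_COLUMNS} or the x_ namespace"
            )

        records: list[TrackRecord] = []
        for i, row in enumerate(reader, start=2):
            is_avg = bool(_parse_bool(row.get("is_average", "0") or "0"))
            if is_avg and not include_averages:
                continue
            num = lambda col: _parse_float(row[col], col, i)
            side, relief, mirrored = _parse_side(row["L/R"], i)
            metrics = TrackMetrics(
                L=num("L"), W=num("W"), L_II=num("II"), L_III=num("III"),
                L_IV=num("IV"), te=num("te"),
                alpha=num("II-III"), beta=num("III-IV"),
            )
            derived = DerivedMetrics(
                lw_ratio=num("L/W"),
                r_iii_ii=num("III/II"),
                r_iii_iv=num("III/IV"),
                iii_over_L=num("III/L"),
                mesaxony=num("M"),
                total_div=num("II-IV"),
            )
            flags = MorphologyFlags(
                digit_shape=_parse_enum(DigitShape, row.get("digit_shape", "")),
                hallux=_parse_enum(HalluxState, row.get("hallux", "")),
                ungual_marks=_parse_enum(UngualMarks, row.get("ungual_marks", "")),
                pad_formula=(row.get("pad_formula") or None),
                digits_well_separated=_parse_bool(row.get("digits_well_separated", "")),
                inner_margins_present=_parse_bool(row.get("inner_margins_present", "")),
                heel_impressed=_parse_bool(row.get("heel_impressed", "")),
            )
            records.append(
                TrackRecord(
                    specimen_id=row["specimen"].strip(),
                    locality=(row.get("locality") or "").strip(),
                    sublocality=(row.get("sublocality") or "").strip(),
                    formation=(row.get("formation") or "").strip(),
                    bed=(row.get("bed") or None),
                    side_observed=_MIRROR[side] if mirrored else side,
                    side_catalogued=side,
                    relief=relief,
                    mirrored_for_relief=mirrored,
                    preservation_grade=num("PG"),
                    flags=flags,
                    metrics=metrics,
                    derived=derived,
                    bearing=_parse_float(row.get("bearing_deg", ""), "bearing_deg", i),
                    length_category_label=(row.get("length_category") or None),
                    wear_acceptable=bool(_parse_bool(row.get("wear_acceptable", "")) or False),
                    published_subgroup=(row.get("published_subgroup") or "").strip() or None,
                    published_status=(
                        (row.get("published_status") or "").strip().replace("n/a", "") or None
                    ),
                    source_table=(row.get("source_table") or "").strip() or None,
                    is_summary_row=is_avg,
                )
            )
    return records


def _fmt(v, nd: int | None = None) -> str:
    if v is None:
        return "n/a"
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float) and nd is not None:
        return str(round_display(v, nd))
    return str(v)


def round_display(value: float, ndigits: int = 2) -> float:
    """Round half up at display precision (table convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def write_measurement_table(
    records: Sequence[TrackRecord], path: str | Path, display_round: int | None = None
) -> Path:
    """Write records in the measurement-table schema (full precision by default)."""
    path = Path(path)
    nd = display_round
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        cols = CORE_COLUMNS + [
            "is_average", "source_table", "published_subgroup", "published_status",
            "locality", "sublocality", "formation", "digit_shape", "hallux",
            "ungual_marks", "digits_well_separated", "inner_margins_present",
            "heel_impressed", "wear_acceptable",
        ]
        w.writerow(cols)
        for r in records:
            m, d, f = r.metrics, r.derived, r.flags
            side = {"left": "L", "right": "R", "indeterminate": "-"}[r.side_catalogued.value]
            if r.relief is Relief.POSITIVE:
                side += "*"
            w.writerow(
                [
                    r.specimen_id,
                    _fmt(r.preservation_grade),
                    side,
                    _fmt(m.L, nd), _fmt(m.W, nd), _fmt(d.lw_ratio, nd),
                    _fmt(m.L_II, nd), _fmt(m.L_III, nd), _fmt(m.L_IV, nd),
                    _fmt(d.r_iii_ii, nd), _fmt(d.r_iii_iv, nd), _fmt(d.iii_over_L, nd),
                    _fmt(m.alpha, nd), _fmt(m.beta, nd),
                    _fmt(d.total_div if d.total_div is not None else m.total_div, nd),
                    _fmt(m.te, nd), _fmt(d.mesaxony, nd),
                    "0",
                    _fmt(r.source_table), _fmt(r.published_subgroup),
                    _fmt(r.published_status),
                    r.locality, r.sublocality, r.formation,
                    _fmt(f.digit_shape.value if f.digit_shape else None),
                    _fmt(f.hallux.value if f.hallux else None),
                    _fmt(f.ungual_marks.value if f.ungual_marks else None),
                    _fmt(f.digits_well_separated),
                    _fmt(f.inner_margins_present),
                    _fmt(f.heel_impressed),
                    "1" if r.wear_acceptable else "0",
                ]
            )
    return path


def fixture_path() -> Path:
    with resources.as_file(
        resources.files("trackmorph").joinpath("data/hebridean_tracks.csv")
    ) as p:
        return Path(p)


def fixture_sha256() -> str:
    data = resources.files("trackmorph").joinpath("data/hebridean_tracks.csv").read_bytes()
    return hashlib.sha256(data).hexdigest()


def load_fixture(include_averages: bool = False) -> list[TrackRecord]:
    """The packaged 85-track characterization table."""
    return read_measurement_table(fixture_path(), include_averages=include_averages)


# ---------------------------------------------------------------- landmarks

_KNOWN_LABELS = REQUIRED_LANDMARKS | OPTIONAL_LANDMARKS


def write_landmark_file(sets: Iterable[LandmarkSet], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["track_id", "side", "relief", "label", "x_cm", "y_cm"])
        for s in sets:
            for label, (x, y) in s.points.items():
                w.writerow([s.track_id, s.side_observed.value, s.relief.value, label,
                            repr(x), repr(y)])
    return path


def read_landmark_file(path: str | Path) -> list[LandmarkSet]:
    path = Path(path)
    groups: dict[str, dict] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        expected = ["track_id", "side", "relief", "label", "x_cm", "y_cm"]
        if reader.fieldnames != expected:
            raise TableFormatError(
                f"{path.name}: landmark header must be {','.join(expected)}"
            )
        for i, row in enumerate(reader, start=2):
            label = row["label"].strip()
            if label not in _KNOWN_LABELS and not label.startswith("x_"):
                raise TableFormatError(
                    f"row {i}: unknown landmark label {label!r}; use the x_ namespace "
                    "for extensions"
                )
            g = groups.setdefault(
                row["track_id"],
                {"side": Side(row["side"]), "relief": Relief(row["relief"]), "points": {}},
            )
            g["points"][label] = (
                _parse_float(row["x_cm"], "x_cm", i),
                _parse_float(row["y_cm"], "y_cm", i),
            )
    return [
        LandmarkSet(track_id=tid, side_observed=g["side"], relief=g["relief"], points=g["points"])
        for tid, g in groups.items()
    ]


# ---------------------------------------------------------------- trackways

def write_trackway_file(seqs: Iterable[TrackwaySequence], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trackway_id", "track_id", "foot", "x_cm", "y_cm",
                    "axis_bearing_deg", "L_cm"])
        for seq in seqs:
            for s in seq.steps:
                w.writerow([
                    seq.trackway_id, s.track_id, s.foot.value,
                    repr(s.ip[0]), repr(s.ip[1]),
                    "n/a" if s.axis_bearing is None else repr(s.axis_bearing),
                    "n/a" if s.L is None else repr(s.L),
                ])
    return path


def read_trackway_file(path: str | Path) -> list[TrackwaySequence]:
    path = Path(path)
    order: list[str] = []
    groups: dict[str, list[TrackwayStep]] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        expected = ["trackway_id", "track_id", "foot", "x_cm", "y_cm",
                    "axis_bearing_deg", "L_cm"]
        if reader.fieldnames != expected:
            raise TableFormatError(
                f"{path.name}: trackway header must be {','.join(expected)}"
            )
        for i, row in enumerate(reader, start=2):
            tid = row["trackway_id"].strip()
            if tid not in groups:
                groups[tid] = []
                order.append(tid)
            groups[tid].append(
                TrackwayStep(
                    track_id=row["track_id"].strip(),
                    ip=(
                        _parse_float(row["x_cm"], "x_cm", i),
                        _parse_float(row["y_cm"], "y_cm", i),
                    ),
                    foot=Side(row["foot"]),
                    L=_parse_float(row["L_cm"], "L_cm", i),
                    axis_bearing=_parse_float(row["axis_bearing_deg"], "axis_bearing_deg", i),
                )
            )
    return [TrackwaySequence(trackway_id=t, steps=tuple(groups[t])) for t in order]


def packaged_trackway(name: str) -> TrackwaySequence:
    """A packaged trackway fixture: 'VA10' or 'SM.1976.2004.002a'."""
    fname = {"VA10": "trackway_va10.csv", "SM.1976.2004.002a": "trackway_sm2004_002a.csv"}
    if name not in fname:
        raise KeyError(f"no packaged trackway {name!r}")
    with resources.as_file(
        resources.files("trackmorph").joinpath(f"data/{fname[name]}")
    ) as p:
        seqs = read_trackway_file(p)
    return seqs[0]


# ---------------------------------------------------------------- bearings

def write_bearing_file(bearing_sets: Iterable[BearingSet], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["surface_id", "track_id", "bearing_deg"])
        for bs in bearing_sets:
            for j, b in enumerate(bs.bearings, start=1):
                w.writerow([bs.surface_id, f"{bs.surface_id}-{j}", repr(b)])
    return path


def read_bearing_file(path: str | Path) -> list[BearingSet]:
    path = Path(path)
    order: list[str] = []
    groups: dict[str, list[float]] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        expected = ["surface_id", "track_id", "bearing_deg"]
        if reader.fieldnames != expected:
            raise TableFormatError(f"{path.name}: bearing header must be {','.join(expected)}")
        for i, row in enumerate(reader, start=2):
            sid = row["surface_id"].strip()
            if sid not in groups:
                groups[sid] = []
                order.append(sid)
            b = _parse_float(row["bearing_deg"], "bearing_deg", i)
            if b is not None:
                groups[sid].append(b)
    return [BearingSet.wrapped(sid, groups[sid]) for sid in order]


# ---------------------------------------------------------------- results

def write_results(
    records: Sequence[TrackRecord],
    classifications: Sequence[Classification] | None,
    outdir: str | Path,
    seed: int | None = None,
    config: dict | None = None,
    ruleset_version: str | None = None,
) -> dict[str, Path]:
    """Write full-precision results, a display-rounded twin, and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": write_measurement_table(records, outdir / "records.csv"),
        "records_rounded": write_measurement_table(
            records, outdir / "records_rounded.csv", display_round=2
        ),
    }
    if classifications is not None:
        p = outdir / "classifications.csv"
        with p.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["specimen", "subgroup", "series", "status", "ambiguity",
                        "suggested_ichnotaxon", "notes"])
            for rec, cl in zip(records, classifications):
                w.writerow([
                    rec.specimen_id, cl.subgroup or "n/a", cl.series or "n/a",
                    cl.status, ";".join(cl.ambiguity),
                    cl.suggested_ichnotaxon or "n/a", ";".join(cl.notes),
                ])
        paths["classifications"] = p
    manifest = {
        "software": {"name": "trackmorph", "version": __version__},
        "seed": seed,
        "ruleset_version": ruleset_version,
        "config": config or {},
        "outputs": {k: str(v.name) for k, v in paths.items()},
    }
    mp = outdir / "manifest.yaml"
    mp.write_text(yaml.safe_dump(manifest, sort_keys=False))
    paths["manifest"] = mp
    return paths
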