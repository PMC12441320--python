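"""Rule engine assigning tridactyl tracks to the Hebridean morphotype series.

The Hebridean series groups tracks into four bipedal morphotypes (HBR_B1-B4)
with ten subgroups, each diagnosed by metric ranges (length, l/w ratio,
mesaxony, digit ii-iv divarication) and morphological characters (digit
shape, hallux, inner digit margins, heel).  The engine is deterministic and
auditable: every candidate subgroup receives a normalized score together with
the list of satisfied predicates, and tie-breaks are recorded as ambiguity.

Rules live in a versioned YAML file (``data/hebridean_rules.yaml``) so the
series can be extended without code changes.

Evaluation model
----------------
* Hard gates (length class, the B2.1/B2.2 l/w split, hallux/digit-shape
  restrictions) remove candidates outright; a missing value never gates.
* Soft predicates contribute to a score normalized by the number of
  *applicable* predicates (a predicate on a missing metric or flag is not
  applicable and is never counted as satisfied).
* A candidate "fully matches" when its combination rule holds: every
  applicable metric predicate for ``all`` rules, or at least *k* satisfied
  (missing counts unsatisfied) for ``at_least`` rules such as the opposing
  B3.1/B3.2 triplets.
* Fully matching candidates outrank partial ones; ties on score are broken
  by a fixed subgroup preference order and recorded in ``ambiguity``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .geometry import derive_metrics
from .types import (
    Classification,
    DigitShape,
    HalluxState,
    LengthCategory,
    TrackRecord,
    length_category,
)

__all__ = [
    "MetricPredicate",
    "FlagPredicate",
    "SubgroupCriteria",
    "RuleSet",
    "load_rules",
    "evaluate_criteria",
    "classify",
    "classify_table",
    "AuditReport",
    "ContradictoryFlagsError",
]

_SCORE_TIE_TOL = 1e-9


class ContradictoryFlagsError(ValueError):
    pass


@dataclass(frozen=True)
class MetricPredicate:
    metric: str
    op: str  # gt | ge | lt | le | between
    value: float | None = None
    lo: float | None = None
    hi: float | None = None
    hard: bool = False
    basis: str = ""

    def describe(self) -> str:
        if self.op == "between":
            return f"{self.metric} in [{self.lo}, {self.hi}]"
        sym = {"gt": ">", "ge": ">=", "lt": "<", "le": "<="}[self.op]
        return f"{self.metric} {sym} {self.value}"

    def evaluate(self, metrics: Mapping[str, float | None]) -> bool | None:
        """True/False when the metric is present, ``None`` when not applicable."""
        v = metrics.get(self.metric)
        if v is None:
            return None
        if self.op == "between":
            return self.lo <= v <= self.hi
        if self.op == "gt":
            return v > self.value
        if self.op == "ge":
            return v >= self.value
        if self.op == "lt":
            return v < self.value
        if self.op == "le":
            return v <= self.value
        raise ValueError(f"unknown op {self.op!r}")


@dataclass(frozen=True)
class FlagPredicate:
    flag: str
    value: bool
    basis: str = ""

    def describe(self) -> str:
        return f"{self.flag} is {self.value}"

    def evaluate(self, record: TrackRecord) -> bool | None:
        v = getattr(record.flags, self.flag)
        if v is None:
            return None
        return bool(v) is self.value


@dataclass(frozen=True)
class SubgroupCriteria:
    subgroup_id: str
    series: str
    size_gate: tuple[LengthCategory, ...]
    allowed_digit_shapes: tuple[DigitShape, ...]
    metric_predicates: tuple[MetricPredicate, ...]
    flag_predicates: tuple[FlagPredicate, ...]
    combination: str | int  # "all" or int k for at-least-k
    hard_length_max: float | None = None
    hallux_required: HalluxState | None = None
    hallux_tolerated: tuple[HalluxState, ...] = (HalluxState.ABSENT, HalluxState.UNCERTAIN)
    suggested_ichnotaxon: str | None = None


@dataclass(frozen=True)
class RuleSet:
    version: str
    subgroups: tuple[SubgroupCriteria, ...]
    hallux_restrictions: Mapping[str, tuple[str, ...]]
    shape_inner_margin_restriction: Mapping[str, object]

    @property
    def order(self) -> tuple[str, ...]:
        """Deterministic preference order (file order: B1.x < B2.x < B3.x < B4)."""
        return tuple(s.subgroup_id for s in self.subgroups)

    def get(self, subgroup_id: str) -> SubgroupCriteria:
        for s in self.subgroups:
            if s.subgroup_id == subgroup_id:
                return s
        raise KeyError(subgroup_id)


def _parse_metric_predicate(d: Mapping) -> MetricPredicate:
    return MetricPredicate(
        metric=d["metric"],
        op=d["op"],
        value=d.get("value"),
        lo=d.get("lo"),
        hi=d.get("hi"),
        hard=bool(d.get("hard", False)),
        basis=d.get("basis", ""),
    )


def load_rules(path: str | Path | None = None) -> RuleSet:
    """Load the rule set; defaults to the packaged Hebridean rules."""
    if path is None:
        text = (
            resources.files("trackmorph").joinpath("data/hebridean_rules.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)

    subgroups = []
    for sid, d in raw["subgroups"].items():
        comb = d.get("combination", "all")
        if isinstance(comb, Mapping):
            comb = int(comb["at_least"])
        tolerated = d.get("hallux_tolerated")
        criteria = SubgroupCriteria(
            subgroup_id=sid,
            series=d["series"],
            size_gate=tuple(LengthCategory(c) for c in d.get("size_gate", [])),
            allowed_digit_shapes=tuple(
                DigitShape(s) for s in d.get("allowed_digit_shapes", [])
            ),
            metric_predicates=tuple(
                _parse_metric_predicate(p) for p in d.get("metric_predicates", [])
            ),
            flag_predicates=tuple(
                FlagPredicate(p["flag"], bool(p["value"]), p.get("basis", ""))
                for p in d.get("flag_predicates", [])
            ),
            combination=comb,
            hard_length_max=d.get("hard_length_max"),
            hallux_required=(
                HalluxState(d["hallux_required"]) if d.get("hallux_required") else None
            ),
            hallux_tolerated=(
                tuple(HalluxState(h) for h in tolerated)
                if tolerated
                else (HalluxState.ABSENT, HalluxState.UNCERTAIN)
            ),
            suggested_ichnotaxon=d.get("suggested_ichnotaxon"),
        )
        subgroups.append(criteria)

    engine = raw.get("engine", {})
    return RuleSet(
        version=str(raw.get("version", "unversioned")),
        subgroups=tuple(subgroups),
        hallux_restrictions={
            k: tuple(v) for k, v in engine.get("hallux_restrictions", {}).items()
        },
        shape_inner_margin_restriction=engine.get("shape_inner_margin_restriction", {}),
    )


_DEFAULT_RULES: RuleSet | None = None


def default_rules() -> RuleSet:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_rules()
    return _DEFAULT_RULES


def _metric_map(record: TrackRecord) -> dict[str, float | None]:
    """Metric values for predicate evaluation.

    Derived ratios are recomputed at full precision from the raw measurements;
    a stored (printed) derived value is used only where the constituents are
    missing, so partially measured rows still contribute what they can.
    """
    m = record.metrics
    fresh = derive_metrics(m)
    stored = record.derived

    def pick(name: str) -> float | None:
        v = getattr(fresh, name)
        return v if v is not None else getattr(stored, name)

    return {
        "L": m.L,
        "W": m.W,
        "L_II": m.L_II,
        "L_III": m.L_III,
        "L_IV": m.L_IV,
        "te": m.te,
        "alpha": m.alpha,
        "beta": m.beta,
        "lw_ratio": pick("lw_ratio"),
        "mesaxony": pick("mesaxony"),
        "total_div": pick("total_div"),
        "iii_over_L": pick("iii_over_L"),
        "r_iii_ii": pick("r_iii_ii"),
        "r_iii_iv": pick("r_iii_iv"),
    }


@dataclass(frozen=True)
class _Evaluation:
    score: float
    satisfied: tuple[str, ...]
    applicable: int
    full_match: bool
    hard_violated: bool


def _evaluate_subgroup(record: TrackRecord, crit: SubgroupCriteria) -> _Evaluation:
    metrics = _metric_map(record)
    satisfied: list[str] = []
    applicable = 0
    n_core_satisfied_strict = 0
    all_applicable_ok = True
    hard_violated = False

    for p in crit.metric_predicates:
        r = p.evaluate(metrics)
        if r is None:
            continue
        applicable += 1
        if r:
            satisfied.append(p.describe())
            n_core_satisfied_strict += 1
        else:
            all_applicable_ok = False
            if p.hard:
                hard_violated = True

    for p in crit.flag_predicates:
        r = p.evaluate(record)
        if r is None:
            continue
        applicable += 1
        if r:
            satisfied.append(p.describe())

    score = len(satisfied) / applicable if applicable else 0.0
    if isinstance(crit.combination, int):
        full = n_core_satisfied_strict >= crit.combination
    else:
        full = all_applicable_ok
    return _Evaluation(
        score=score,
        satisfied=tuple(satisfied),
        applicable=applicable,
        full_match=full and not hard_violated,
        hard_violated=hard_violated,
    )


def evaluate_criteria(
    record: TrackRecord, rules: RuleSet | None = None
) -> dict[str, tuple[float, tuple[str, ...]]]:
    """Score every subgroup for one record.

    A predicate on a missing metric counts unsatisfied and is excluded from
    the normalizing denominator; a record with no usable values scores 0
    everywhere.  Gates (size, flags) are *not* applied here — this is the raw
    per-subgroup evidence that :func:`classify` filters and ranks.
    """
    rules = rules or default_rules()
    out = {}
    for crit in rules.subgroups:
        ev = _evaluate_subgroup(record, crit)
        out[crit.subgroup_id] = (ev.score, ev.satisfied)
    return out


def _candidate_filter(record: TrackRecord, rules: RuleSet) -> tuple[list[SubgroupCriteria], list[str]]:
    notes: list[str] = []
    cands = list(rules.subgroups)

    # size gate
    cat = length_category(record.metrics.L)
    if cat is not None:
        kept = []
        for c in cands:
            if c.size_gate and cat not in c.size_gate:
                continue
            if c.hard_length_max is not None and record.metrics.L >= c.hard_length_max:
                continue
            kept.append(c)
        cands = kept

    # hallux restrictions
    hallux = record.flags.hallux
    if hallux is not None and hallux.value in rules.hallux_restrictions:
        allowed = set(rules.hallux_restrictions[hallux.value])
        cands = [c for c in cands if c.subgroup_id in allowed]
    cands = [
        c
        for c in cands
        if c.hallux_required is None
        or hallux is c.hallux_required
    ]
    if hallux is not None and hallux not in (HalluxState.UNCERTAIN,):
        cands = [
            c
            for c in cands
            if c.hallux_required is not None or hallux in c.hallux_tolerated
        ]

    # digit-shape compatibility
    shape = record.flags.digit_shape
    if shape is not None:
        cands = [c for c in cands if not c.allowed_digit_shapes or shape in c.allowed_digit_shapes]

    # broad+inner-margin morphology is definitional for B2.3
    restr = rules.shape_inner_margin_restriction
    if restr:
        if (
            shape is not None
            and shape.value == restr.get("digit_shape")
            and record.flags.inner_margins_present is True
        ):
            allowed = set(restr.get("subgroups", ()))
            narrowed = [c for c in cands if c.subgroup_id in allowed]
            if narrowed:
                cands = narrowed
            else:
                notes.append("inner-margin morphology conflicts with size gate")
    return cands, notes


def _status(record: TrackRecord, subgroup: str | None, top_score: float, full: bool) -> str:
    if subgroup is None:
        return "unclassified"
    g = record.preservation_grade
    if g is None:
        return "referred"
    if g >= 1.5:
        return "characterized"
    if g >= 1.0:
        if record.wear_acceptable:
            return "characterized"
        return "referred"
    # grade < 1: at best referred, and only with some series-level evidence
    if top_score > 0 or full:
        return "referred"
    return "unclassified"


def classify(record: TrackRecord, rules: RuleSet | None = None) -> Classification:
    """Assign one record a Hebridean subgroup and a status.

    Candidates are filtered by size gate and morphology gates, scored, and
    ranked (full matches first, then score, then the fixed preference order).
    Tie-broken choices record the co-maximal alternatives in ``ambiguity``.
    """
    rules = rules or default_rules()
    cands, notes = _candidate_filter(record, rules)

    evals: dict[str, _Evaluation] = {}
    for c in cands:
        ev = _evaluate_subgroup(record, c)
        if ev.hard_violated:
            continue
        evals[c.subgroup_id] = ev

    matched_map = {sid: (ev.score, ev.satisfied) for sid, ev in evals.items()}
    if not evals:
        notes.append("no candidate subgroup survives the gates")
        return Classification(
            subgroup=None,
            series=None,
            status=_status(record, None, 0.0, False),
            matched=matched_map,
            ambiguity=(),
            suggested_ichnotaxon=None,
            notes=tuple(notes),
        )

    order = {sid: i for i, sid in enumerate(rules.order)}
    ranked = sorted(
        evals.items(),
        key=lambda kv: (not kv[1].full_match, -kv[1].score, order[kv[0]]),
    )
    winner_id, winner_ev = ranked[0]
    co_top = [
        sid
        for sid, ev in ranked
        if ev.full_match == winner_ev.full_match
        and abs(ev.score - winner_ev.score) <= _SCORE_TIE_TOL
    ]
    ambiguity = tuple(sid for sid in co_top if sid != winner_id)

    crit = rules.get(winner_id)
    if not winner_ev.full_match and winner_ev.score == 0.0 and len(evals) > 1:
        # nothing distinguishes the surviving candidates
        notes.append("no diagnostic evidence; all surviving candidates score 0")
        return Classification(
            subgroup=None,
            series=None,
            status=_status(record, None, 0.0, False),
            matched=matched_map,
            ambiguity=tuple(co_top),
            suggested_ichnotaxon=None,
            notes=tuple(notes),
        )

    return Classification(
        subgroup=winner_id,
        series=crit.series,
        status=_status(record, winner_id, winner_ev.score, winner_ev.full_match),
        matched=matched_map,
        ambiguity=ambiguity,
        suggested_ichnotaxon=crit.suggested_ichnotaxon,
        notes=tuple(notes),
    )


@dataclass(frozen=True)
class AuditReport:
    """Agreement of rule-engine assignments with a published-subgroup column."""

    n_records: int
    n_with_published: int
    n_agree: int
    disagreements: tuple[tuple[str, str | None, str | None, str], ...]
    # (specimen_id, published, assigned, kind in {ambiguous, misassigned})
    n_ambiguous_records: int  # records whose classification carries ambiguity

    @property
    def agreement_fraction(self) -> float:
        return self.n_agree / self.n_with_published if self.n_with_published else float("nan")

    def summary(self) -> str:
        lines = [
            f"records: {self.n_records}",
            f"with published subgroup: {self.n_with_published}",
            f"agree: {self.n_agree} ({self.agreement_fraction:.1%})",
            f"records with ambiguity: {self.n_ambiguous_records}",
        ]
        for spec, pub, got, kind in self.disagreements:
            lines.append(f"  {kind}: {spec} published {pub} assigned {got}")
        return "\n".join(lines)


def classify_table(
    records: Sequence[TrackRecord], rules: RuleSet | None = None
) -> tuple[list[Classification], AuditReport]:
    """Classify a collection; deterministic and order-independent.

    Disagreements with an optional ``published_subgroup`` column are split
    into *ambiguous* (the published subgroup is among the co-maximal
    candidates or the record's recorded ambiguity) and *misassigned*.
    """
    rules = rules or default_rules()
    classifications = [classify(r, rules) for r in records]

    n_pub = n_agree = n_ambig = 0
    disagreements = []
    for rec, cl in zip(records, classifications):
        if cl.ambiguity:
            n_ambig += 1
        pub = rec.published_subgroup
        if not pub:
            continue
        n_pub += 1
        if cl.subgroup == pub:
            n_agree += 1
            continue
        top = max((s for s, _ in cl.matched.values()), default=0.0)
        pub_score = cl.matched.get(pub, (None, ()))[0]
        ambiguous = (
            pub in cl.ambiguity
            or (pub_score is not None and abs(pub_score - top) <= _SCORE_TIE_TOL)
        )
        disagreements.append(
            (rec.specimen_id, pub, cl.subgroup, "ambiguous" if ambiguous else "misassigned")
        )
    return classifications, AuditReport(
        n_records=len(records),
        n_with_published=n_pub,
        n_agree=n_agree,
        disagreements=tuple(disagreements),
        n_ambiguous_records=n_ambig,
    )
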