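"""Four-stage hierarchical ACMG/AMP variant classification engine.

The engine assigns one of the five standard tiers — Pathogenic (P), Likely
Pathogenic (LP), Variant of Uncertain Significance (VUS), Likely Benign (LB),
Benign (B) — to an evidence profile built from the 28 ACMG/AMP criteria
(PVS1, PS1-4, PM1-6, PP1-5 on the pathogenic side; BA1, BS1-4, BP1-7 on the
benign side).

Stages run strictly in order:

1. **Combination rules** — the canonical ACMG/AMP 2015 criterion-combination
   table, stored as data (:data:`COMBINATION_RULES`) so it can be enumerated
   and audited.  If rules fire on exactly one side, the strongest tier on
   that side is final.
2. **Conflict resolution** — when both pathogenic- and benign-side rules
   fire, a deterministic ladder weighs strong-or-above evidence on each side
   (see :func:`resolve_conflict`).
3. **Conditional VUS overrides** — when no rule fires and the profile holds
   no strong evidence, incomplete-evidence conditions (functional studies
   not done, assumed de novo without confirmed parentage, ...) force VUS.
4. **Weighted score fallback** — a quantitative score (BA1=1, BS=2, BP=3,
   PP=4, PM=8, PS=16, PVS1=32) mapped through fixed bands.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Strength",
    "Polarity",
    "CriterionCode",
    "CRITERIA",
    "PATHOGENIC_CODES",
    "BENIGN_CODES",
    "CATEGORY_SIZES",
    "WEIGHTS",
    "SCORE_BANDS",
    "COMBINATION_RULES",
    "CombinationRule",
    "EvidenceProfile",
    "StrengthCounts",
    "VariantContext",
    "DeNovoStatus",
    "ClassificationResult",
    "Report",
    "ValidationError",
    "evaluate_combination_rules",
    "resolve_conflict",
    "check_vus_overrides",
    "compute_weighted_score",
    "score_to_class",
    "classify",
    "summarize_report",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


# ---------------------------------------------------------------------------
# Criterion inventory
# ---------------------------------------------------------------------------

class Strength(str, enum.Enum):
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"
    STAND_ALONE = "stand_alone"


class Polarity(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"


#: Criterion categories: prefix -> (strength, polarity, number of codes).
CATEGORY_SIZES: dict[str, int] = {
    "PVS": 1, "PS": 4, "PM": 6, "PP": 5, "BA": 1, "BS": 4, "BP": 7,
}

_CATEGORY_META: dict[str, tuple[Strength, Polarity]] = {
    "PVS": (Strength.VERY_STRONG, Polarity.PATHOGENIC),
    "PS": (Strength.STRONG, Polarity.PATHOGENIC),
    "PM": (Strength.MODERATE, Polarity.PATHOGENIC),
    "PP": (Strength.SUPPORTING, Polarity.PATHOGENIC),
    "BA": (Strength.STAND_ALONE, Polarity.BENIGN),
    "BS": (Strength.STRONG, Polarity.BENIGN),
    "BP": (Strength.SUPPORTING, Polarity.BENIGN),
}


@dataclass(frozen=True)
class CriterionCode:
    """One of the 28 ACMG/AMP evidence criteria.

    Strength and polarity are fully determined by the code prefix, so the
    constructor derives them; pass only the upper-case code string.
    """

    code: str

    def __post_init__(self) -> None:
        if self.code not in CRITERIA:
            raise ValidationError(f"unknown ACMG criterion code: {self.code!r}")

    @property
    def category(self) -> str:
        return _category_of(self.code)

    @property
    def strength(self) -> Strength:
        return _CATEGORY_META[self.category][0]

    @property
    def polarity(self) -> Polarity:
        return _CATEGORY_META[self.category][1]


def _category_of(code: str) -> str:
    for prefix in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
        if code.startswith(prefix):
            return prefix
    raise ValidationError(f"unknown ACMG criterion code: {code!r}")


def _build_inventory() -> tuple[str, ...]:
    codes: list[str] = []
    for prefix, n in CATEGORY_SIZES.items():
        codes.extend(f"{prefix}{i}" for i in range(1, n + 1))
    return tuple(codes)


#: All 28 criterion code strings, in PVS -> PS -> PM -> PP -> BA -> BS -> BP order.
CRITERIA: tuple[str, ...] = _build_inventory()
PATHOGENIC_CODES = tuple(c for c in CRITERIA if _CATEGORY_META[_category_of(c)][1] is Polarity.PATHOGENIC)
BENIGN_CODES = tuple(c for c in CRITERIA if _CATEGORY_META[_category_of(c)][1] is Polarity.BENIGN)

#: Fallback-score weight per criterion category.
WEIGHTS: dict[str, int] = {
    "BA": 1, "BS": 2, "BP": 3, "PP": 4, "PM": 8, "PS": 16, "PVS": 32,
}

#: Score bands for the stage-4 fallback, as (low, high, class) with inclusive
#: bounds.  The LB-below-B ordering follows the published weight gradient
#: (BA1 = 1 maps into the LB band) and is deliberately kept literal; reports
#: carry a note flagging it.  The 9-16 gap between the printed bands defaults
#: to VUS, the safe class, and the P band is open-ended above 49.
SCORE_BANDS: tuple[tuple[int, Optional[int], str], ...] = (
    (0, 2, "LB"),
    (3, 8, "B"),
    (9, 16, "VUS"),
    (17, 25, "VUS"),
    (26, 48, "LP"),
    (49, None, "P"),
)

FIVE_CLASSES: tuple[str, ...] = ("P", "LP", "VUS", "LB", "B")


# ---------------------------------------------------------------------------
# Profiles, counts, context
# ---------------------------------------------------------------------------

@dataclass
class EvidenceProfile:
    """The set of criteria asserted for one variant, each at most once."""

    activated: frozenset[str] = frozenset()
    notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        activated = frozenset(str(c).upper() for c in self.activated)
        for code in activated:
            if code not in CRITERIA:
                raise ValidationError(f"unknown ACMG criterion code: {code!r}")
        object.__setattr__(self, "activated", activated)
        for code in self.notes:
            if code.upper() not in activated:
                raise ValidationError(f"note attached to inactive criterion: {code!r}")

    def counts(self) -> "StrengthCounts":
        return StrengthCounts.from_codes(self.activated)

    @property
    def pathogenic(self) -> frozenset[str]:
        return frozenset(c for c in self.activated if _category_of(c) in ("PVS", "PS", "PM", "PP"))

    @property
    def benign(self) -> frozenset[str]:
        return frozenset(c for c in self.activated if _category_of(c) in ("BA", "BS", "BP"))

    def sorted_codes(self) -> list[str]:
        """Activated codes in canonical PVS -> ... -> BP order."""
        order = {c: i for i, c in enumerate(CRITERIA)}
        return sorted(self.activated, key=order.__getitem__)


@dataclass(frozen=True)
class StrengthCounts:
    """Number of activated criteria per evidence-strength category."""

    nPVS: int = 0
    nPS: int = 0
    nPM: int = 0
    nPP: int = 0
    nBA: int = 0
    nBS: int = 0
    nBP: int = 0

    def __post_init__(self) -> None:
        for prefix, cap in CATEGORY_SIZES.items():
            value = getattr(self, f"n{prefix}")
            if not (0 <= value <= cap):
                raise ValidationError(
                    f"count n{prefix}={value} outside 0..{cap}"
                )

    @classmethod
    def from_codes(cls, codes: Iterable[str]) -> "StrengthCounts":
        tally = {p: 0 for p in CATEGORY_SIZES}
        for code in codes:
            tally[_category_of(code)] += 1
        return cls(**{f"n{p}": v for p, v in tally.items()})

    @property
    def total(self) -> int:
        return self.nPVS + self.nPS + self.nPM + self.nPP + self.nBA + self.nBS + self.nBP

    def as_dict(self) -> dict[str, int]:
        return {
            "PVS": self.nPVS, "PS": self.nPS, "PM": self.nPM, "PP": self.nPP,
            "BA1": self.nBA, "BS": self.nBS, "BP": self.nBP,
        }


class DeNovoStatus(str, enum.Enum):
    CONFIRMED = "confirmed"
    ASSUMED = "assumed"
    NOT_APPLICABLE = "not_applicable"


_ZYGOSITIES = ("homozygous", "heterozygous", "hemizygous")
_INHERITANCES = ("autosomal_dominant", "autosomal_recessive", "x_linked")


@dataclass
class VariantContext:
    """Variant nomenclature, clinical context, and override-relevant flags.

    Booleans default to the conservative "No"; de novo status defaults to
    not applicable.
    """

    variant_name: str = ""
    condition: str = ""
    zygosity: str = "heterozygous"
    inheritance: str = "autosomal_dominant"
    functional_studies_done: bool = False
    in_hotspot_or_critical_domain: bool = False
    de_novo_status: DeNovoStatus = DeNovoStatus.NOT_APPLICABLE
    observed_healthy_inconsistent_genotype: bool = False
    alternate_molecular_basis: bool = False

    def __post_init__(self) -> None:
        if self.zygosity not in _ZYGOSITIES:
            raise ValidationError(
                f"zygosity {self.zygosity!r} not in {_ZYGOSITIES}"
            )
        if self.inheritance not in _INHERITANCES:
            raise ValidationError(
                f"inheritance {self.inheritance!r} not in {_INHERITANCES}"
            )
        if not isinstance(self.de_novo_status, DeNovoStatus):
            object.__setattr__(self, "de_novo_status", DeNovoStatus(self.de_novo_status))


# ---------------------------------------------------------------------------
# Stage 1 — combination rules (data, not branches)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CombinationRule:
    """One row of the ACMG/AMP 2015 criterion-combination table.

    ``requires`` maps a category prefix to an inclusive (min, max) count
    constraint; ``max`` of ``None`` means unbounded.  Categories not listed
    are unconstrained.
    """

    rule_id: str
    tier: str  # P | LP | B | LB
    requires: Mapping[str, tuple[int, Optional[int]]]

    @property
    def side(self) -> Polarity:
        return Polarity.PATHOGENIC if self.tier in ("P", "LP") else Polarity.BENIGN

    def satisfied_by(self, counts: StrengthCounts) -> bool:
        for prefix, (lo, hi) in self.requires.items():
            value = getattr(counts, f"n{prefix}")
            if value < lo or (hi is not None and value > hi):
                return False
        return True


def _rule(rule_id: str, tier: str, **req: tuple[int, Optional[int]]) -> CombinationRule:
    return CombinationRule(rule_id, tier, req)


#: The ACMG/AMP 2015 combination-rule table.
COMBINATION_RULES: tuple[CombinationRule, ...] = (
    # Pathogenic
    _rule("P: PVS1+>=1PS", "P", PVS=(1, None), PS=(1, None)),
    _rule("P: PVS1+>=2PM", "P", PVS=(1, None), PM=(2, None)),
    _rule("P: PVS1+1PM+1PP", "P", PVS=(1, None), PM=(1, None), PP=(1, None)),
    _rule("P: PVS1+>=2PP", "P", PVS=(1, None), PP=(2, None)),
    _rule("P: >=2PS", "P", PS=(2, None)),
    _rule("P: 1PS+>=3PM", "P", PS=(1, None), PM=(3, None)),
    _rule("P: 1PS+2PM+>=2PP", "P", PS=(1, None), PM=(2, None), PP=(2, None)),
    _rule("P: 1PS+1PM+>=4PP", "P", PS=(1, None), PM=(1, None), PP=(4, None)),
    # Likely pathogenic
    _rule("LP: PVS1+1PM", "LP", PVS=(1, None), PM=(1, None)),
    _rule("LP: 1PS+1-2PM", "LP", PS=(1, None), PM=(1, 2)),
    _rule("LP: 1PS+>=2PP", "LP", PS=(1, None), PP=(2, None)),
    _rule("LP: >=3PM", "LP", PM=(3, None)),
    _rule("LP: 2PM+>=2PP", "LP", PM=(2, None), PP=(2, None)),
    _rule("LP: 1PM+>=4PP", "LP", PM=(1, None), PP=(4, None)),
    # Benign
    _rule("B: BA1", "B", BA=(1, None)),
    _rule("B: >=2BS", "B", BS=(2, None)),
    # Likely benign
    _rule("LB: 1BS+1BP", "LB", BS=(1, None), BP=(1, None)),
    _rule("LB: >=2BP", "LB", BP=(2, None)),
)

_TIER_RANK = {"P": 0, "LP": 1, "B": 0, "LB": 1}  # 0 = strongest on its side


@dataclass(frozen=True)
class RuleOutcome:
    """Result of the stage-1 sweep over the combination-rule table."""

    pathogenic_rules: tuple[CombinationRule, ...]
    benign_rules: tuple[CombinationRule, ...]
    tentative: Optional[str]  # P/LP/B/LB, or None, or "conflict"

    @property
    def conflict(self) -> bool:
        return bool(self.pathogenic_rules) and bool(self.benign_rules)


def _strongest_tier(rules: Sequence[CombinationRule]) -> str:
    return min(rules, key=lambda r: _TIER_RANK[r.tier]).tier


def evaluate_combination_rules(profile: EvidenceProfile) -> RuleOutcome:
    """Sweep the full combination-rule table and report every satisfied rule.

    The tentative class is the strongest tier among satisfied rules when
    exactly one side fires; ``"conflict"`` when both sides fire; ``None``
    when nothing fires.
    """
    counts = profile.counts()
    p_rules = tuple(r for r in COMBINATION_RULES
                    if r.side is Polarity.PATHOGENIC and r.satisfied_by(counts))
    b_rules = tuple(r for r in COMBINATION_RULES
                    if r.side is Polarity.BENIGN and r.satisfied_by(counts))
    if p_rules and b_rules:
        tentative: Optional[str] = "conflict"
    elif p_rules:
        tentative = _strongest_tier(p_rules)
    elif b_rules:
        tentative = _strongest_tier(b_rules)
    else:
        tentative = None
    return RuleOutcome(p_rules, b_rules, tentative)


# ---------------------------------------------------------------------------
# Stage 2 — conflict resolution
# ---------------------------------------------------------------------------

def resolve_conflict(
    profile: EvidenceProfile,
    p_rules: Sequence[CombinationRule],
    b_rules: Sequence[CombinationRule],
) -> str:
    """Resolve a profile for which both sides satisfy combination rules.

    Deterministic ladder:

    1. both sides hold strong-or-above evidence (PVS/PS vs BA1/BS) -> VUS;
    2. pathogenic side holds PVS or PS, benign side lacks BA1/BS ->
       pathogenic-side class;
    3. benign side holds BA1 or BS, pathogenic side lacks PVS/PS ->
       benign-side class;
    4. pathogenic side has >=2 PM and benign side lacks BS -> pathogenic-side
       class;
    5. otherwise VUS.
    """
    if not p_rules or not b_rules:
        raise ValidationError("resolve_conflict requires satisfied rules on both sides")
    counts = profile.counts()
    p_strong = counts.nPVS > 0 or counts.nPS > 0
    b_strong = counts.nBA > 0 or counts.nBS > 0
    if p_strong and b_strong:
        return "VUS"
    if p_strong:
        return _strongest_tier(p_rules)
    if b_strong:
        return _strongest_tier(b_rules)
    if counts.nPM >= 2:
        return _strongest_tier(p_rules)
    return "VUS"


# ---------------------------------------------------------------------------
# Stage 3 — conditional VUS overrides
# ---------------------------------------------------------------------------

_OVERRIDE_CHECKS: tuple[tuple[str, "callable"], ...] = (
    ("functional studies not done",
     lambda ctx: not ctx.functional_studies_done),
    ("not located in a known mutational hotspot or critical domain",
     lambda ctx: not ctx.in_hotspot_or_critical_domain),
    ("assumed de novo without confirmed parentage",
     lambda ctx: ctx.de_novo_status is DeNovoStatus.ASSUMED),
    ("observed in healthy individuals in a genotype inconsistent with the disease",
     lambda ctx: ctx.observed_healthy_inconsistent_genotype),
    ("alternate molecular basis for disease in this case",
     lambda ctx: ctx.alternate_molecular_basis),
)


def override_guard_passes(profile: EvidenceProfile) -> bool:
    """True when the profile holds no strong-or-above evidence (no PVS1,
    no PS, no BS; BA1 alone would already have classified at stage 1)."""
    counts = profile.counts()
    return counts.nPVS == 0 and counts.nPS == 0 and counts.nBS == 0


def check_vus_overrides(
    profile: EvidenceProfile, context: VariantContext
) -> Optional[tuple[str, list[str]]]:
    """Return ``("VUS", reasons)`` if any incomplete-evidence condition holds.

    Pure predicate; callers are responsible for the activation guard (no rule
    satisfied, no strong evidence in the profile).
    """
    reasons = [name for name, check in _OVERRIDE_CHECKS if check(context)]
    if reasons:
        return ("VUS", reasons)
    return None


# ---------------------------------------------------------------------------
# Stage 4 — weighted score
# ---------------------------------------------------------------------------

def compute_weighted_score(profile: EvidenceProfile) -> int:
    """Sum the per-criterion weights over all activated criteria."""
    return sum(WEIGHTS[_category_of(code)] for code in profile.activated)


def score_to_class(score: int) -> str:
    """Map a weighted score onto the five-tier classification via the fixed
    bands (0-2 LB, 3-8 B, 9-25 VUS, 26-48 LP, >=49 P)."""
    if score < 0:
        raise ValidationError(f"weighted score must be non-negative, got {score}")
    for lo, hi, tier in SCORE_BANDS:
        if score >= lo and (hi is None or score <= hi):
            return tier
    raise AssertionError("score bands are total; unreachable")


# ---------------------------------------------------------------------------
# The full hierarchy
# ---------------------------------------------------------------------------

@dataclass
class ClassificationResult:
    final_class: str
    deciding_stage: str  # combination_rule | conflict_resolution | vus_override | weighted_score
    satisfied_rules: list[str]
    total_score: int
    counts: StrengthCounts
    rationale: str
    activated: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def classify(profile: EvidenceProfile, context: Optional[VariantContext] = None) -> ClassificationResult:
    """Run the four classification stages in order and return the decision.

    ``total_score`` is always computed (informational) but decides the class
    only when ``deciding_stage == "weighted_score"``.
    """
    if context is None:
        context = VariantContext()
    outcome = evaluate_combination_rules(profile)
    score = compute_weighted_score(profile)
    rule_ids = [r.rule_id for r in outcome.pathogenic_rules + outcome.benign_rules]
    activated = profile.sorted_codes()
    notes: list[str] = []

    if outcome.tentative is not None and outcome.tentative != "conflict":
        return ClassificationResult(
            final_class=outcome.tentative,
            deciding_stage="combination_rule",
            satisfied_rules=rule_ids,
            total_score=score,
            counts=profile.counts(),
            rationale=" + ".join(activated),
            activated=activated,
            notes=notes,
        )

    if outcome.conflict:
        final = resolve_conflict(profile, outcome.pathogenic_rules, outcome.benign_rules)
        notes.append("pathogenic- and benign-side combination rules both satisfied")
        return ClassificationResult(
            final_class=final,
            deciding_stage="conflict_resolution",
            satisfied_rules=rule_ids,
            total_score=score,
            counts=profile.counts(),
            rationale=" + ".join(activated),
            activated=activated,
            notes=notes,
        )

    # No rule fired.  Overrides only when no strong evidence is present.
    if override_guard_passes(profile):
        override = check_vus_overrides(profile, context)
        if override is not None:
            _, reasons = override
            return ClassificationResult(
                final_class="VUS",
                deciding_stage="vus_override",
                satisfied_rules=[],
                total_score=score,
                counts=profile.counts(),
                rationale="; ".join(reasons),
                activated=activated,
                notes=notes,
            )

    if not profile.activated:
        # No evidence is not benign evidence: never let the literal score of
        # 0 fall into the LB band.
        final = "VUS"
        notes.append("no criteria activated; insufficient evidence")
    else:
        final = score_to_class(score)
        if final in ("LB", "B"):
            notes.append(
                "score-band ordering places LB (0-2) below B (3-8) by design"
            )
    return ClassificationResult(
        final_class=final,
        deciding_stage="weighted_score",
        satisfied_rules=[],
        total_score=score,
        counts=profile.counts(),
        rationale=f"Score-based {final}",
        activated=activated,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

_STRENGTH_GROUP_ORDER = ("PVS", "PS", "PM", "PP", "BA", "BS", "BP")
_GROUP_LABEL = {"BA": "BA1"}


@dataclass
class Report:
    """Serializable classification report: class + rationale, the seven
    strength counts, the total score, and the activated criteria grouped by
    evidence strength."""

    final_class: str
    deciding_stage: str
    rationale: str
    satisfied_rules: list[str]
    counts: dict[str, int]
    total_score: int
    activated: list[str]
    notes: list[str]
    variant_name: str = ""
    condition: str = ""

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "variant_name": self.variant_name,
                "condition": self.condition,
                "final_class": self.final_class,
                "deciding_stage": self.deciding_stage,
                "rationale": self.rationale,
                "satisfied_rules": self.satisfied_rules,
                "counts": self.counts,
                "total_score": self.total_score,
                "activated": self.activated,
                "notes": self.notes,
            },
            indent=indent,
        )

    def to_text(self) -> str:
        lines = []
        if self.variant_name:
            lines.append(f"Variant   : {self.variant_name}")
        if self.condition:
            lines.append(f"Condition : {self.condition}")
        lines += [
            f"Class     : {self.final_class}",
            f"Rationale : {self.rationale}",
            f"Stage     : {self.deciding_stage}",
            "Counts    : " + " ".join(
                f"{_GROUP_LABEL.get(g, g)}:{self.counts[_GROUP_LABEL.get(g, g)]}"
                for g in _STRENGTH_GROUP_ORDER
            ),
            f"Score     : {self.total_score}",
        ]
        lines.append("Criteria  :")
        grouped = False
        for group in _STRENGTH_GROUP_ORDER:
            members = [c for c in self.activated if _category_of(c) == group]
            if members:
                grouped = True
                lines.append(f"  {_GROUP_LABEL.get(group, group)}: " + ", ".join(members))
        if not grouped:
            lines.append("  (none)")
        for note in self.notes:
            lines.append(f"Note      : {note}")
        return "\n".join(lines) + "\n"


def summarize_report(
    result: ClassificationResult, context: Optional[VariantContext] = None
) -> Report:
    """Assemble the full report for a classification result."""
    context = context or VariantContext()
    return Report(
        final_class=result.final_class,
        deciding_stage=result.deciding_stage,
        rationale=result.rationale,
        satisfied_rules=list(result.satisfied_rules),
        counts=result.counts.as_dict(),
        total_score=result.total_score,
        activated=list(result.activated),
        notes=list(result.notes),
        variant_name=context.variant_name,
        condition=context.condition,
    )
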