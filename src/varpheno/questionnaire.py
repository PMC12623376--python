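"""Questionnaire-driven evidence intake.

Maps structured yes/no and multiple-choice answers about a variant onto an
:class:`~varpheno.acmg.EvidenceProfile` and a
:class:`~varpheno.acmg.VariantContext`.  The question set and its
answer-to-criterion mapping are data (a YAML definition shipped with the
package, replaceable by the user); the engine itself never hard-codes a
question.

Unanswered questions activate nothing — the conservative default answer is
"No" — so an empty answer file yields an empty profile and a default
context.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import yaml

from .acmg import (
    CRITERIA,
    DeNovoStatus,
    EvidenceProfile,
    ValidationError,
    VariantContext,
)

__all__ = [
    "Question",
    "Questionnaire",
    "AnswerSet",
    "Issue",
    "load_questionnaire",
    "default_questionnaire",
    "load_answers",
    "validate_answers",
    "derive_evidence",
]

_CONTEXT_FIELDS = {f.name for f in dataclasses.fields(VariantContext)}
_YES_VALUES = {"yes", "y", "true", "1"}
_NO_VALUES = {"no", "n", "false", "0"}


@dataclass(frozen=True)
class Question:
    """One intake question with its criterion/context mappings.

    ``criteria`` is a list of ``(code, activating answer)`` pairs;
    ``context`` a list of ``(field, answer -> value map)`` pairs.
    """

    id: str
    text: str
    kind: str  # yes_no | multiple_choice
    choices: tuple[str, ...] = ()
    criteria: tuple[tuple[str, Any], ...] = ()
    context: tuple[tuple[str, Mapping[Any, Any]], ...] = ()

    def legal_answer(self, value: Any) -> bool:
        if self.kind == "yes_no":
            return isinstance(value, bool)
        return value in self.choices


@dataclass(frozen=True)
class Questionnaire:
    questions: tuple[Question, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for q in self.questions:
            if q.id in seen:
                raise ValidationError(f"duplicate question id: {q.id!r}")
            seen.add(q.id)

    def __iter__(self):
        return iter(self.questions)

    def __len__(self) -> int:
        return len(self.questions)

    def by_id(self) -> dict[str, Question]:
        return {q.id: q for q in self.questions}

    def mapped_criteria(self) -> set[str]:
        return {code for q in self.questions for code, _ in q.criteria}


@dataclass
class AnswerSet:
    """Answers keyed by question id, plus the variant/disease context."""

    answers: dict[str, Any] = field(default_factory=dict)
    variant_name: str = ""
    condition: str = ""
    zygosity: str = "heterozygous"
    inheritance: str = "autosomal_dominant"


@dataclass(frozen=True)
class Issue:
    question_id: str
    reason: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.question_id}: {self.reason}"


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _parse_question(raw: Mapping[str, Any]) -> Question:
    qid = raw.get("id")
    if not qid or not isinstance(qid, str):
        raise ValidationError(f"question missing id: {raw!r}")
    kind = raw.get("kind")
    if kind not in ("yes_no", "multiple_choice"):
        raise ValidationError(f"question {qid!r}: unknown kind {kind!r}")
    choices = tuple(raw.get("choices") or ())
    if kind == "multiple_choice" and not choices:
        raise ValidationError(f"question {qid!r}: multiple_choice requires choices")

    criteria: list[tuple[str, Any]] = []
    for entry in raw.get("criteria") or ():
        code = str(entry.get("code", "")).upper()
        if code not in CRITERIA:
            raise ValidationError(
                f"question {qid!r}: maps to unknown criterion {entry.get('code')!r}"
            )
        when = entry.get("when", True if kind == "yes_no" else None)
        if kind == "multiple_choice" and when not in choices:
            raise ValidationError(
                f"question {qid!r}: activation value {when!r} not among choices"
            )
        criteria.append((code, when))

    context: list[tuple[str, Mapping[Any, Any]]] = []
    for entry in raw.get("context") or ():
        fname = entry.get("field")
        if fname not in _CONTEXT_FIELDS:
            raise ValidationError(
                f"question {qid!r}: maps to unknown context field {fname!r}"
            )
        context.append((fname, dict(entry.get("map") or {})))

    return Question(
        id=qid,
        text=str(raw.get("text", "")).strip(),
        kind=kind,
        choices=choices,
        criteria=tuple(criteria),
        context=tuple(context),
    )


def load_questionnaire(source: Union[str, Path, Mapping[str, Any]]) -> Questionnaire:
    """Load a questionnaire definition from a YAML/JSON file or a mapping."""
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    else:
        data = source
    if not isinstance(data, Mapping) or "questions" not in data:
        raise ValidationError("questionnaire definition must contain a 'questions' list")
    return Questionnaire(tuple(_parse_question(q) for q in data["questions"]))


def default_questionnaire() -> Questionnaire:
    """The questionnaire definition shipped with the package (covers all 28
    criteria and every context flag)."""
    text = resources.files("varpheno.data").joinpath("questionnaire.yaml").read_text("utf-8")
    return load_questionnaire(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Answers
# ---------------------------------------------------------------------------

def _coerce_answer(question: Question, value: Any) -> Any:
    if question.kind == "yes_no" and isinstance(value, str):
        low = value.strip().lower()
        if low in _YES_VALUES:
            return True
        if low in _NO_VALUES:
            return False
    return value


def load_answers(path: Union[str, Path]) -> AnswerSet:
    """Read an answer file (YAML or JSON)."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise ValidationError("answer file must be a mapping")
    return AnswerSet(
        answers=dict(data.get("answers") or {}),
        variant_name=str(data.get("variant_name", "")),
        condition=str(data.get("condition", "")),
        zygosity=str(data.get("zygosity", "heterozygous")),
        inheritance=str(data.get("inheritance", "autosomal_dominant")),
    )


def validate_answers(
    answers: AnswerSet, questionnaire: Optional[Questionnaire] = None
) -> list[Issue]:
    """Collect validation issues; an empty list means the answer set is valid."""
    questionnaire = questionnaire or default_questionnaire()
    by_id = questionnaire.by_id()
    issues: list[Issue] = []
    for qid, value in answers.answers.items():
        question = by_id.get(qid)
        if question is None:
            issues.append(Issue(qid, "unknown question id"))
            continue
        if not question.legal_answer(_coerce_answer(question, value)):
            expected = ("yes/no" if question.kind == "yes_no"
                        else "one of " + ", ".join(question.choices))
            issues.append(Issue(qid, f"illegal answer {value!r}; expected {expected}"))
    return issues


def derive_evidence(
    answers: AnswerSet, questionnaire: Optional[Questionnaire] = None
) -> tuple[EvidenceProfile, VariantContext]:
    """Turn an answer set into an evidence profile and variant context.

    Deterministic in answer content (order-independent); unanswered
    questions contribute nothing.
    """
    questionnaire = questionnaire or default_questionnaire()
    issues = validate_answers(answers, questionnaire)
    if issues:
        raise ValidationError(
            "invalid answers: " + "; ".join(str(i) for i in issues)
        )
    activated: set[str] = set()
    context_kwargs: dict[str, Any] = {
        "variant_name": answers.variant_name,
        "condition": answers.condition,
        "zygosity": answers.zygosity,
        "inheritance": answers.inheritance,
    }
    for question in questionnaire:
        if question.id not in answers.answers:
            continue
        value = _coerce_answer(question, answers.answers[question.id])
        for code, when in question.criteria:
            if value == when:
                activated.add(code)
        for fname, value_map in question.context:
            if value in value_map:
                mapped = value_map[value]
                if fname == "de_novo_status":
                    mapped = DeNovoStatus(mapped)
                context_kwargs[fname] = mapped
    return EvidenceProfile(frozenset(activated)), VariantContext(**context_kwargs)
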