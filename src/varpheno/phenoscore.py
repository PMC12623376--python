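"""Two-part phenotype screening and disease prioritization (NMPhenoscore).

Part one is a rapid screen: a fixed panel of binary clinical indicators
(default 24), each worth one point.  The percentage of indicators present is
compared against a diagnostic threshold (default 30%); at or above the
threshold the patient is flagged "NMGD likely Positive", below it "NMGD
likely Negative".

Part two prioritizes candidate conditions: user-reported symptoms are
validated against the symptom index of a binary symptom x condition
knowledgebase, each condition scores the number of validated symptoms it is
associated with, and conditions are ranked by score in descending order.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .acmg import ValidationError

__all__ = [
    "normalize_symptom",
    "ScreeningPanel",
    "ScreeningResult",
    "Knowledgebase",
    "PrioritizationResult",
    "default_panel",
    "load_panel",
    "screen",
    "validate_symptoms",
    "prioritize",
    "sunburst_summary",
]

POSITIVE_LABEL = "NMGD likely Positive"
NEGATIVE_LABEL = "NMGD likely Negative"

_WS = re.compile(r"\s+")


def normalize_symptom(name: str) -> str:
    """Canonical form for matching: trim, case-fold, collapse whitespace."""
    return _WS.sub(" ", str(name).strip()).casefold()


def _round_half_up_1dp(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Part one — screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreeningPanel:
    """An ordered panel of binary clinical indicators."""

    indicators: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.indicators:
            raise ValidationError("screening panel must contain at least one indicator")
        normalized = [normalize_symptom(i) for i in self.indicators]
        if len(set(normalized)) != len(normalized):
            dupes = {n for n in normalized if normalized.count(n) > 1}
            raise ValidationError(f"duplicate indicators after normalization: {sorted(dupes)}")

    @property
    def size(self) -> int:
        return len(self.indicators)

    def normalized(self) -> set[str]:
        return {normalize_symptom(i) for i in self.indicators}


@dataclass(frozen=True)
class ScreeningResult:
    selected_count: int
    total: int
    percentage: float  # rounded half-up to one decimal, for display
    label: str

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "selected_count": self.selected_count,
                "total": self.total,
                "percentage": self.percentage,
                "label": self.label,
            },
            indent=indent,
        )

    def to_text(self) -> str:
        return (
            f"Indicators present : {self.selected_count} / {self.total}\n"
            f"Screening score    : {self.percentage}%\n"
            f"Result             : {self.label}\n"
        )


def default_panel() -> ScreeningPanel:
    """The packaged 24-indicator screening panel.

    The first ten indicators are the documented core screen for
    neuromuscular involvement; the remaining fourteen are synthetic but
    clinically plausible placeholders standing in for the full curated
    panel, which is configuration-replaceable.
    """
    text = resources.files("varpheno.data").joinpath("screening_panel.yaml").read_text("utf-8")
    return ScreeningPanel(tuple(yaml.safe_load(text)["indicators"]))


def load_panel(path) -> ScreeningPanel:
    """Load a panel from a YAML/JSON file with an ``indicators`` list."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, dict):
        data = data.get("indicators")
    if not isinstance(data, list):
        raise ValidationError("panel file must contain an 'indicators' list")
    return ScreeningPanel(tuple(str(x) for x in data))


def screen(
    panel: ScreeningPanel,
    present: Iterable[str],
    threshold_percent: float = 30.0,
) -> ScreeningResult:
    """Score a set of present indicators against the panel.

    percentage = 100 * |present| / panel size.  The label is Positive iff
    the *unrounded* percentage is at or above ``threshold_percent``; the
    reported percentage is rounded half-up to one decimal for display.
    """
    panel_norm = panel.normalized()
    selected: set[str] = set()
    for name in present:
        norm = normalize_symptom(name)
        if norm not in panel_norm:
            raise ValidationError(f"indicator not in panel: {name!r}")
        selected.add(norm)
    pct = 100.0 * len(selected) / panel.size
    label = POSITIVE_LABEL if pct >= threshold_percent else NEGATIVE_LABEL
    return ScreeningResult(
        selected_count=len(selected),
        total=panel.size,
        percentage=_round_half_up_1dp(pct),
        label=label,
    )


# ---------------------------------------------------------------------------
# Part two — knowledgebase-driven prioritization
# ---------------------------------------------------------------------------

@dataclass
class Knowledgebase:
    """Binary symptom x condition association matrix.

    Rows are symptoms, columns are conditions; ``matrix[s, c] = 1`` records a
    prominent association.  A lookup index maps normalized symptom names to
    row positions.
    """

    symptoms: list[str]
    conditions: list[str]
    matrix: np.ndarray
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.shape != (len(self.symptoms), len(self.conditions)):
            raise ValidationError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.symptoms)} symptoms x {len(self.conditions)} conditions"
            )
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValidationError("knowledgebase matrix entries must be 0 or 1")
        self.index = {}
        for pos, name in enumerate(self.symptoms):
            norm = normalize_symptom(name)
            if norm in self.index:
                raise ValidationError(f"duplicate symptom after normalization: {name!r}")
            self.index[norm] = pos
        norm_conditions = [normalize_symptom(c) for c in self.conditions]
        if len(set(norm_conditions)) != len(norm_conditions):
            raise ValidationError("duplicate condition columns")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.symptoms, columns=self.conditions)


def example_knowledgebase() -> Knowledgebase:
    """The packaged example knowledgebase (synthetic).

    A small symptom x condition matrix emulating the structure of the
    curated neuromuscular knowledgebase; its content is illustrative, not
    curated clinical truth.  Includes the dystroglycanopathy column used in
    the worked prioritization example.
    """
    from .kb_io import read_knowledgebase  # local import to avoid a cycle

    path = resources.files("varpheno.data").joinpath("example_kb_synthetic.csv")
    with resources.as_file(path) as p:
        return read_knowledgebase(p)


@dataclass(frozen=True)
class PrioritizationResult:
    ranking: tuple[tuple[str, int], ...]  # (condition, score), score descending
    top: tuple[str, ...]  # all conditions sharing the maximum score
    unrecognized: tuple[str, ...]
    n_validated: int
    validated: tuple[str, ...] = ()  # validated symptoms, knowledgebase spelling

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "ranking": [{"condition": c, "score": s} for c, s in self.ranking],
                "top": list(self.top),
                "validated": list(self.validated),
                "unrecognized": list(self.unrecognized),
                "n_validated": self.n_validated,
            },
            indent=indent,
        )

    def to_text(self) -> str:
        lines = [f"Validated symptoms : {self.n_validated}"]
        if self.unrecognized:
            lines.append("Unrecognized       : " + ", ".join(self.unrecognized))
        lines.append("Top recommendation : " + ", ".join(self.top))
        lines.append("Ranking:")
        for pos, (condition, score) in enumerate(self.ranking, start=1):
            lines.append(f"  {pos:>2}. {condition}  (matched symptoms: {score})")
        return "\n".join(lines) + "\n"


def validate_symptoms(
    inputs: Sequence[str], kb: Knowledgebase
) -> tuple[list[int], list[str]]:
    """Split user symptoms into validated knowledgebase rows and unrecognized names.

    Duplicates (after normalization) collapse to the first occurrence;
    unrecognized names keep their original spelling.
    """
    validated: list[int] = []
    seen: set[str] = set()
    unrecognized: list[str] = []
    for name in inputs:
        norm = normalize_symptom(name)
        if norm in seen:
            continue
        if norm in kb.index:
            seen.add(norm)
            validated.append(kb.index[norm])
        else:
            unrecognized.append(name)
    return validated, unrecognized


def prioritize(inputs: Sequence[str], kb: Knowledgebase) -> PrioritizationResult:
    """Rank conditions by the number of validated symptoms associated with each.

    score(c) = sum over validated rows s of matrix[s, c]; ranking is sorted
    by score descending, ties broken by knowledgebase column order (stable).
    """
    rows, unrecognized = validate_symptoms(inputs, kb)
    if rows:
        scores = kb.matrix[rows, :].sum(axis=0)
    else:
        scores = np.zeros(len(kb.conditions), dtype=np.int64)
    order = np.argsort(-scores, kind="stable")
    ranking = tuple((kb.conditions[i], int(scores[i])) for i in order)
    max_score = int(scores.max()) if len(scores) else 0
    top = tuple(kb.conditions[i] for i in order if int(scores[i]) == max_score)
    return PrioritizationResult(
        ranking=ranking,
        top=top,
        unrecognized=tuple(unrecognized),
        n_validated=len(rows),
        validated=tuple(kb.symptoms[r] for r in rows),
    )


def sunburst_summary(
    result: PrioritizationResult, kb: Knowledgebase
) -> dict[str, list[str]]:
    """Nested condition -> matched-symptom summary backing a sunburst plot.

    For each ranked condition, lists exactly the validated input symptoms the
    knowledgebase associates with it (conditions with score 0 get an empty
    leaf list).
    """
    rows = [kb.index[normalize_symptom(s)] for s in result.validated]
    summary: dict[str, list[str]] = {}
    cond_pos = {c: i for i, c in enumerate(kb.conditions)}
    for condition, _score in result.ranking:
        col = cond_pos[condition]
        summary[condition] = [kb.symptoms[r] for r in rows if kb.matrix[r, col] == 1]
    return summary
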