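"""Flat-file I/O, synthetic fixture generation, and concordance evaluation.

Covers:

* the knowledgebase CSV/TSV dialect (first column header ``Symptom``, one
  column per condition, cells ``+`` / empty — ``1`` / ``0`` also accepted);
* the gene table TSV (symbol, chromosome, position, diseases, inheritance,
  and external identifiers), with per-row error reporting;
* seeded synthetic generators for knowledgebases, gene tables, and
  oracle-labelled evidence profiles;
* the 5x5 confusion matrix / percent-agreement evaluation used to compare
  two classification sources at exact-label or merged-category resolution.

The evidence-profile generator labels each profile with a self-contained
count-based classifier written independently of the rule-table engine in
:mod:`varpheno.acmg`, so generated expected classes can serve as an
external reference when exercising the engine end to end.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .acmg import (
    CATEGORY_SIZES,
    DeNovoStatus,
    EvidenceProfile,
    FIVE_CLASSES,
    ValidationError,
    VariantContext,
)
from .phenoscore import Knowledgebase, normalize_symptom, _round_half_up_1dp

__all__ = [
    "GeneRecord",
    "GeneTableResult",
    "ConcordanceTable",
    "SyntheticSpec",
    "read_knowledgebase",
    "write_knowledgebase",
    "read_gene_table",
    "write_gene_table",
    "summarize_genes_by_chromosome",
    "generate_synthetic_knowledgebase",
    "generate_synthetic_gene_table",
    "generate_synthetic_evidence_profiles",
    "oracle_classify_counts",
    "evaluate_concordance",
]

CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")
INHERITANCE_MODES = ("AD", "AR", "XL", "mitochondrial", "other")

GENE_TABLE_COLUMNS = (
    "symbol", "chromosome", "position", "diseases", "inheritance",
    "omim_id", "phenotype_mim", "orphanet_id", "malacards_id",
    "entrez_id", "ensembl_id",
)
_MANDATORY_GENE_COLUMNS = ("symbol", "chromosome", "position", "diseases", "inheritance")


# ---------------------------------------------------------------------------
# Knowledgebase I/O
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_knowledgebase(source: Union[str, Path]) -> Knowledgebase:
    """Read a symptom x condition matrix from CSV/TSV.

    ``+`` (or ``1``) marks an association, empty/whitespace (or ``0``) its
    absence; any other cell token is a parse error reported with its row and
    column.  Duplicate symptom rows or condition columns are rejected.
    """
    path = Path(source)
    sep = _sep_for(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        rows = [row for row in reader if any(cell.strip() for cell in row)]
    if len(rows) < 2:
        raise ValidationError(f"{path}: need a header row and at least one symptom row")
    header = rows[0]
    conditions = [c.strip() for c in header[1:]]
    if not conditions:
        raise ValidationError(f"{path}: no condition columns found")
    symptoms: list[str] = []
    matrix: list[list[int]] = []
    for line_no, row in enumerate(rows[1:], start=2):
        symptom = row[0].strip()
        if not symptom:
            raise ValidationError(f"{path}: row {line_no}: empty symptom name")
        cells = row[1:]
        if len(cells) != len(conditions):
            raise ValidationError(
                f"{path}: row {line_no}: expected {len(conditions)} cells, got {len(cells)}"
            )
        encoded: list[int] = []
        for col_no, cell in enumerate(cells):
            token = cell.strip()
            if token in ("+", "1"):
                encoded.append(1)
            elif token in ("", "0"):
                encoded.append(0)
            else:
                raise ValidationError(
                    f"{path}: row {line_no}, column {conditions[col_no]!r}: "
                    f"unknown cell token {cell!r} (expected '+', '1', '0', or empty)"
                )
        symptoms.append(symptom)
        matrix.append(encoded)
    return Knowledgebase(symptoms, conditions, np.array(matrix, dtype=np.int8))


def write_knowledgebase(kb: Knowledgebase, target: Union[str, Path]) -> None:
    """Write a knowledgebase in the ``+``/empty CSV/TSV dialect."""
    path = Path(target)
    sep = _sep_for(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["Symptom", *kb.conditions])
        for symptom, row in zip(kb.symptoms, kb.matrix):
            writer.writerow([symptom, *("+" if v else "" for v in row)])


# ---------------------------------------------------------------------------
# Gene table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    symbol: str
    chromosome: str
    position: str = ""
    diseases: tuple[str, ...] = ()
    inheritance: tuple[str, ...] = ()
    omim_id: str = ""
    phenotype_mim: str = ""
    orphanet_id: str = ""
    malacards_id: str = ""
    entrez_id: str = ""
    ensembl_id: str = ""

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValidationError("gene symbol must be non-empty")
        if self.chromosome not in CHROMOSOMES:
            raise ValidationError(f"chromosome {self.chromosome!r} not in 1..22/X/Y/MT")
        for mode in self.inheritance:
            if mode not in INHERITANCE_MODES:
                raise ValidationError(f"inheritance {mode!r} not in {INHERITANCE_MODES}")


@dataclass
class GeneTableResult:
    """Accepted records plus a per-line error report for rejected rows."""

    records: list[GeneRecord]
    errors: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return len(self.records)


def _split_list(cell: str) -> tuple[str, ...]:
    return tuple(x.strip() for x in str(cell).split(";") if x.strip())


def read_gene_table(source: Union[str, Path]) -> GeneTableResult:
    """Read a gene table TSV/CSV; malformed rows go to the error report."""
    path = Path(source)
    sep = _sep_for(path)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY_GENE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    result = GeneTableResult(records=[])
    for i, row in frame.iterrows():
        line_no = int(i) + 2  # header is line 1
        try:
            record = GeneRecord(
                symbol=row["symbol"].strip(),
                chromosome=row["chromosome"].strip(),
                position=row.get("position", "").strip(),
                diseases=_split_list(row.get("diseases", "")),
                inheritance=_split_list(row.get("inheritance", "")),
                omim_id=row.get("omim_id", "").strip(),
                phenotype_mim=row.get("phenotype_mim", "").strip(),
                orphanet_id=row.get("orphanet_id", "").strip(),
                malacards_id=row.get("malacards_id", "").strip(),
                entrez_id=row.get("entrez_id", "").strip(),
                ensembl_id=row.get("ensembl_id", "").strip(),
            )
        except ValidationError as err:
            result.errors.append((line_no, str(err)))
            continue
        result.records.append(record)
    return result


def write_gene_table(records: Iterable[GeneRecord], target: Union[str, Path]) -> None:
    path = Path(target)
    sep = _sep_for(path)
    rows = []
    for r in records:
        rows.append({
            "symbol": r.symbol,
            "chromosome": r.chromosome,
            "position": r.position,
            "diseases": ";".join(r.diseases),
            "inheritance": ";".join(r.inheritance),
            "omim_id": r.omim_id,
            "phenotype_mim": r.phenotype_mim,
            "orphanet_id": r.orphanet_id,
            "malacards_id": r.malacards_id,
            "entrez_id": r.entrez_id,
            "ensembl_id": r.ensembl_id,
        })
    pd.DataFrame(rows, columns=list(GENE_TABLE_COLUMNS)).to_csv(path, sep=sep, index=False)


def summarize_genes_by_chromosome(
    records: Iterable[GeneRecord],
) -> dict[str, dict[str, int]]:
    """Per-chromosome gene counts stratified by inheritance pattern.

    A record is counted once for every (chromosome, inheritance) pair it
    carries; records without an inheritance entry count under ``"other"``.
    """
    summary: dict[str, dict[str, int]] = {}
    for record in records:
        modes = record.inheritance or ("other",)
        per_chrom = summary.setdefault(record.chromosome, {})
        for mode in modes:
            per_chrom[mode] = per_chrom.get(mode, 0) + 1
    return summary


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters for the synthetic fixture generators.

    Knowledgebase defaults (141 symptoms x 34 conditions) mirror the scale
    of the curated neuromuscular knowledgebase so structural tests run at a
    realistic size.
    """

    n_symptoms: int = 141
    n_conditions: int = 34
    density: float = 0.15
    seed: int = 0
    n_profiles: int = 100
    activation_probs: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.n_symptoms < 1 or self.n_conditions < 1:
            raise ValidationError("knowledgebase dimensions must be positive")
        if not (0.0 < self.density < 1.0):
            raise ValidationError(
                f"density must lie strictly in (0, 1), got {self.density} "
                "(each condition needs at least one association)"
            )
        if self.n_profiles < 1:
            raise ValidationError("n_profiles must be positive")


def generate_synthetic_knowledgebase(spec: SyntheticSpec) -> Knowledgebase:
    """Random binary symptom x condition matrix, reproducible from the seed.

    Every condition is guaranteed at least one associated symptom; realized
    density tracks ``spec.density`` closely for matrices of 100+ cells.
    """
    rng = np.random.default_rng(spec.seed)
    matrix = (rng.random((spec.n_symptoms, spec.n_conditions)) < spec.density).astype(np.int8)
    for col in range(spec.n_conditions):
        if matrix[:, col].sum() == 0:
            matrix[rng.integers(spec.n_symptoms), col] = 1
    symptoms = [f"symptom {i + 1:03d}" for i in range(spec.n_symptoms)]
    conditions = [f"condition {j + 1:02d}" for j in range(spec.n_conditions)]
    return Knowledgebase(symptoms, conditions, matrix)


def generate_synthetic_gene_table(
    n_genes: int = 747, seed: int = 0
) -> list[GeneRecord]:
    """Synthetic gene table emulating a curated neuromuscular gene collection."""
    rng = np.random.default_rng(seed)
    records: list[GeneRecord] = []
    for i in range(n_genes):
        chrom = CHROMOSOMES[rng.integers(len(CHROMOSOMES))]
        n_modes = 1 + int(rng.random() < 0.15)
        modes = tuple(dict.fromkeys(
            INHERITANCE_MODES[rng.integers(len(INHERITANCE_MODES))] for _ in range(n_modes)
        ))
        n_dis = 1 + int(rng.integers(3))
        records.append(GeneRecord(
            symbol=f"GENE{i + 1:04d}",
            chromosome=chrom,
            position=f"{chrom}:{int(rng.integers(1, 250_000_000))}",
            diseases=tuple(f"disorder {i + 1:04d}.{k + 1}" for k in range(n_dis)),
            inheritance=modes,
            omim_id=str(600000 + i),
            phenotype_mim=str(250000 + i),
            orphanet_id=f"ORPHA:{1000 + i}",
            malacards_id=f"MC{i + 1:05d}",
            entrez_id=str(10000 + i),
            ensembl_id=f"ENSG{i + 1:011d}",
        ))
    return records


# ---------------------------------------------------------------------------
# Independent count-based classification oracle
# ---------------------------------------------------------------------------

def oracle_classify_counts(
    counts: Mapping[str, int], context: Optional[VariantContext] = None
) -> str:
    """Classify a strength-count vector with hand-written branch logic.

    Self-contained reference classifier over the full four-stage hierarchy,
    written as explicit conditionals on the seven category counts (keys
    ``PVS``, ``PS``, ``PM``, ``PP``, ``BA``, ``BS``, ``BP``) — deliberately
    not sharing the data-driven rule table of :mod:`varpheno.acmg`.
    """
    pvs = counts.get("PVS", 0)
    ps = counts.get("PS", 0)
    pm = counts.get("PM", 0)
    pp = counts.get("PP", 0)
    ba = counts.get("BA", 0)
    bs = counts.get("BS", 0)
    bp = counts.get("BP", 0)

    is_p = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2))
        or ps >= 2
        or (ps >= 1 and (pm >= 3 or (pm >= 2 and pp >= 2) or (pm >= 1 and pp >= 4)))
    )
    is_lp = (
        (pvs >= 1 and pm >= 1)
        or (ps >= 1 and 1 <= pm <= 2)
        or (ps >= 1 and pp >= 2)
        or pm >= 3
        or (pm >= 2 and pp >= 2)
        or (pm >= 1 and pp >= 4)
    )
    is_b = ba >= 1 or bs >= 2
    is_lb = (bs >= 1 and bp >= 1) or bp >= 2

    p_tier = "P" if is_p else ("LP" if is_lp else None)
    b_tier = "B" if is_b else ("LB" if is_lb else None)

    if p_tier and b_tier:  # conflict ladder
        p_strong = pvs >= 1 or ps >= 1
        b_strong = ba >= 1 or bs >= 1
        if p_strong and b_strong:
            return "VUS"
        if p_strong:
            return p_tier
        if b_strong:
            return b_tier
        if pm >= 2:
            return p_tier
        return "VUS"
    if p_tier:
        return p_tier
    if b_tier:
        return b_tier

    # overrides, guarded on the absence of strong evidence
    if pvs == 0 and ps == 0 and bs == 0 and context is not None:
        if (
            not context.functional_studies_done
            or not context.in_hotspot_or_critical_domain
            or context.de_novo_status is DeNovoStatus.ASSUMED
            or context.observed_healthy_inconsistent_genotype
            or context.alternate_molecular_basis
        ):
            return "VUS"

    total = pvs + ps + pm + pp + ba + bs + bp
    if total == 0:
        return "VUS"
    score = 32 * pvs + 16 * ps + 8 * pm + 4 * pp + 1 * ba + 2 * bs + 3 * bp
    if score <= 2:
        return "LB"
    if score <= 8:
        return "B"
    if score <= 25:
        return "VUS"
    if score <= 48:
        return "LP"
    return "P"


def oracle_stage1_counts(counts: Mapping[str, int]) -> Optional[str]:
    """Stage-1-only outcome of the hand-written oracle: the tentative class
    when one side fires, ``"conflict"`` when both do, ``None`` otherwise."""
    pvs, ps, pm, pp = (counts.get(k, 0) for k in ("PVS", "PS", "PM", "PP"))
    ba, bs, bp = (counts.get(k, 0) for k in ("BA", "BS", "BP"))
    is_p = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2))
        or ps >= 2
        or (ps >= 1 and (pm >= 3 or (pm >= 2 and pp >= 2) or (pm >= 1 and pp >= 4)))
    )
    is_lp = (
        (pvs >= 1 and pm >= 1)
        or (ps >= 1 and 1 <= pm <= 2)
        or (ps >= 1 and pp >= 2)
        or pm >= 3
        or (pm >= 2 and pp >= 2)
        or (pm >= 1 and pp >= 4)
    )
    is_b = ba >= 1 or bs >= 2
    is_lb = (bs >= 1 and bp >= 1) or bp >= 2
    p_tier = "P" if is_p else ("LP" if is_lp else None)
    b_tier = "B" if is_b else ("LB" if is_lb else None)
    if p_tier and b_tier:
        return "conflict"
    return p_tier or b_tier


_CATEGORY_CODES: dict[str, tuple[str, ...]] = {
    prefix: tuple(f"{prefix}{i}" for i in range(1, size + 1))
    for prefix, size in CATEGORY_SIZES.items()
}

#: Per-class proposal distributions (activation probability per category)
#: used by the balanced profile generator.
_CLASS_PROPOSALS: dict[str, dict[str, float]] = {
    "P": {"PVS": 0.7, "PS": 0.45, "PM": 0.30, "PP": 0.25, "BA": 0.0, "BS": 0.0, "BP": 0.05},
    "LP": {"PVS": 0.15, "PS": 0.12, "PM": 0.40, "PP": 0.35, "BA": 0.0, "BS": 0.0, "BP": 0.05},
    "VUS": {"PVS": 0.05, "PS": 0.05, "PM": 0.25, "PP": 0.25, "BA": 0.02, "BS": 0.10, "BP": 0.15},
    "LB": {"PVS": 0.0, "PS": 0.0, "PM": 0.02, "PP": 0.05, "BA": 0.0, "BS": 0.15, "BP": 0.30},
    "B": {"PVS": 0.0, "PS": 0.0, "PM": 0.02, "PP": 0.05, "BA": 0.35, "BS": 0.45, "BP": 0.20},
}

_DEFAULT_ACTIVATION = {"PVS": 0.1, "PS": 0.1, "PM": 0.15, "PP": 0.15, "BA": 0.05, "BS": 0.1, "BP": 0.15}


def _draw_profile(rng: np.random.Generator, probs: Mapping[str, float]) -> EvidenceProfile:
    activated = [
        code
        for prefix, codes in _CATEGORY_CODES.items()
        for code in codes
        if rng.random() < probs.get(prefix, 0.0)
    ]
    return EvidenceProfile(frozenset(activated))


def _draw_context(rng: np.random.Generator) -> VariantContext:
    return VariantContext(
        variant_name=f"NM_{int(rng.integers(1, 999999)):06d}.1:c.{int(rng.integers(1, 5000))}A>G",
        condition="synthetic neuromuscular disorder",
        zygosity=("homozygous", "heterozygous", "hemizygous")[rng.integers(3)],
        inheritance=("autosomal_dominant", "autosomal_recessive", "x_linked")[rng.integers(3)],
        functional_studies_done=bool(rng.random() < 0.5),
        in_hotspot_or_critical_domain=bool(rng.random() < 0.5),
        de_novo_status=(
            DeNovoStatus.CONFIRMED, DeNovoStatus.ASSUMED, DeNovoStatus.NOT_APPLICABLE
        )[rng.integers(3)],
        observed_healthy_inconsistent_genotype=bool(rng.random() < 0.1),
        alternate_molecular_basis=bool(rng.random() < 0.1),
    )


def _profile_counts(profile: EvidenceProfile) -> dict[str, int]:
    c = profile.counts()
    return {"PVS": c.nPVS, "PS": c.nPS, "PM": c.nPM, "PP": c.nPP,
            "BA": c.nBA, "BS": c.nBS, "BP": c.nBP}


def generate_synthetic_evidence_profiles(
    spec: SyntheticSpec,
    balanced: bool = True,
    max_attempts_per_profile: int = 5000,
) -> list[tuple[EvidenceProfile, VariantContext, str]]:
    """Seeded evidence profiles with oracle-computed expected classes.

    With ``balanced=True`` (the default) the request is filled with equal
    numbers of profiles per class (``spec.n_profiles`` must divide evenly by
    five), drawn by per-class rejection sampling against
    :func:`oracle_classify_counts`.  With ``balanced=False`` profiles are
    drawn from ``spec.activation_probs`` (or a generic default) and labelled
    as they come.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[tuple[EvidenceProfile, VariantContext, str]] = []
    if balanced:
        if spec.n_profiles % len(FIVE_CLASSES) != 0:
            raise ValidationError(
                f"balanced request: n_profiles={spec.n_profiles} is not a "
                f"multiple of {len(FIVE_CLASSES)}"
            )
        per_class = spec.n_profiles // len(FIVE_CLASSES)
        for cls in FIVE_CLASSES:
            probs = _CLASS_PROPOSALS[cls]
            found = 0
            attempts = 0
            while found < per_class:
                attempts += 1
                if attempts > max_attempts_per_profile * per_class:
                    raise ValidationError(
                        f"could not generate {per_class} profiles of class {cls} "
                        f"within {attempts - 1} attempts"
                    )
                profile = _draw_profile(rng, probs)
                context = _draw_context(rng)
                if oracle_classify_counts(_profile_counts(profile), context) == cls:
                    out.append((profile, context, cls))
                    found += 1
    else:
        probs = dict(spec.activation_probs or _DEFAULT_ACTIVATION)
        for _ in range(spec.n_profiles):
            profile = _draw_profile(rng, probs)
            context = _draw_context(rng)
            label = oracle_classify_counts(_profile_counts(profile), context)
            out.append((profile, context, label))
    return out


# ---------------------------------------------------------------------------
# Concordance evaluation
# ---------------------------------------------------------------------------

_CATEGORY_OF_CLASS = {
    "P": "pathogenic", "LP": "pathogenic",
    "VUS": "uncertain",
    "LB": "benign", "B": "benign",
}
UNKNOWN_LABEL = "unknown"


@dataclass
class ConcordanceTable:
    """Confusion matrix (reference rows x predicted columns) with percent
    agreement under exact and merged-category readings.

    ``unknown`` reference labels, when present, occupy an extra matrix row
    and are discordant under both modes.
    """

    labels: list[str]
    reference_labels: list[str]
    matrix: np.ndarray
    n: int
    percent_exact: float
    percent_category: float
    mode: str = "exact"

    @property
    def percent_agreement(self) -> float:
        return self.percent_exact if self.mode == "exact" else self.percent_category

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=self.reference_labels, columns=self.labels
        ).rename_axis(index="reference", columns="predicted")

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "mode": self.mode,
                "n": self.n,
                "percent_exact": self.percent_exact,
                "percent_category": self.percent_category,
                "percent_agreement": self.percent_agreement,
                "labels": self.labels,
                "reference_labels": self.reference_labels,
                "matrix": self.matrix.tolist(),
            },
            indent=indent,
        )

    def to_text(self) -> str:
        lines = [self.to_frame().to_string(), ""]
        lines.append(f"n                : {self.n}")
        lines.append(f"Exact agreement  : {self.percent_exact}%")
        lines.append(f"Category agreement: {self.percent_category}%")
        return "\n".join(lines) + "\n"


def evaluate_concordance(
    predictions: Sequence[str],
    references: Sequence[str],
    mode: str = "exact",
) -> ConcordanceTable:
    """Compare predicted against reference five-tier classes.

    Predictions must come from the five-tier set; references may also carry
    ``"unknown"`` (always discordant).  Both percentages are computed and
    reported to one decimal; ``mode`` selects which one ``percent_agreement``
    exposes.
    """
    if mode not in ("exact", "category"):
        raise ValidationError(f"mode must be 'exact' or 'category', got {mode!r}")
    if len(predictions) != len(references):
        raise ValidationError(
            f"length mismatch: {len(predictions)} predictions vs "
            f"{len(references)} references"
        )
    if not predictions:
        raise ValidationError("cannot evaluate concordance on empty label lists")
    for i, label in enumerate(predictions):
        if label not in FIVE_CLASSES:
            raise ValidationError(f"prediction {i}: unknown class label {label!r}")
    has_unknown = any(r == UNKNOWN_LABEL for r in references)
    for i, label in enumerate(references):
        if label not in FIVE_CLASSES and label != UNKNOWN_LABEL:
            raise ValidationError(f"reference {i}: unknown class label {label!r}")

    labels = list(FIVE_CLASSES)
    ref_labels = labels + ([UNKNOWN_LABEL] if has_unknown else [])
    row = {lab: i for i, lab in enumerate(ref_labels)}
    col = {lab: i for i, lab in enumerate(labels)}
    matrix = np.zeros((len(ref_labels), len(labels)), dtype=np.int64)
    exact = category = 0
    for pred, ref in zip(predictions, references):
        matrix[row[ref], col[pred]] += 1
        if ref == UNKNOWN_LABEL:
            continue
        if pred == ref:
            exact += 1
        if _CATEGORY_OF_CLASS[pred] == _CATEGORY_OF_CLASS[ref]:
            category += 1
    n = len(predictions)
    return ConcordanceTable(
        labels=labels,
        reference_labels=ref_labels,
        matrix=matrix,
        n=n,
        percent_exact=_round_half_up_1dp(100.0 * exact / n),
        percent_category=_round_half_up_1dp(100.0 * category / n),
        mode=mode,
    )
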