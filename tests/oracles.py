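"""Independent reference logic used only by the tests.

These oracles are written as flat, literal conditionals transcribed straight
from the published criterion-combination table and score bands, on purpose
not sharing any code with the package's data-driven rule engine, so that the
two can be compared across the full input space.
"""

from __future__ import annotations

from typing import Optional


def stage1_oracle(
    pvs: int, ps: int, pm: int, pp: int, ba: int, bs: int, bp: int
) -> Optional[str]:
    """Stage-1 outcome for a strength-count vector.

    Returns "P"/"LP"/"B"/"LB" when exactly one side fires (strongest tier),
    "conflict" when both sides fire, None when no rule is satisfied.
    """
    pathogenic = None
    # Pathogenic
    if pvs >= 1 and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2):
        pathogenic = "P"
    elif ps >= 2:
        pathogenic = "P"
    elif ps >= 1 and (pm >= 3 or (pm >= 2 and pp >= 2) or (pm >= 1 and pp >= 4)):
        pathogenic = "P"
    # Likely pathogenic
    elif pvs >= 1 and pm >= 1:
        pathogenic = "LP"
    elif ps >= 1 and pm in (1, 2):
        pathogenic = "LP"
    elif ps >= 1 and pp >= 2:
        pathogenic = "LP"
    elif pm >= 3:
        pathogenic = "LP"
    elif pm >= 2 and pp >= 2:
        pathogenic = "LP"
    elif pm >= 1 and pp >= 4:
        pathogenic = "LP"

    benign = None
    if ba >= 1 or bs >= 2:
        benign = "B"
    elif (bs >= 1 and bp >= 1) or bp >= 2:
        benign = "LB"

    if pathogenic and benign:
        return "conflict"
    return pathogenic or benign


def score_band_oracle(score: int) -> str:
    """Literal transcription of the published score bands (gap 9-16 -> VUS)."""
    if score <= 2:
        return "LB"
    if score <= 8:
        return "B"
    if score <= 16:
        return "VUS"
    if score <= 25:
        return "VUS"
    if score <= 48:
        return "LP"
    return "P"


def count_vectors():
    """All 33,600 admissible strength-count vectors."""
    for pvs in range(2):
        for ps in range(5):
            for pm in range(7):
                for pp in range(6):
                    for ba in range(2):
                        for bs in range(5):
                            for bp in range(8):
                                yield pvs, ps, pm, pp, ba, bs, bp


def profile_codes_for_counts(pvs, ps, pm, pp, ba, bs, bp) -> frozenset[str]:
    """A concrete criterion set realizing a count vector (first k per category)."""
    codes: list[str] = []
    if pvs:
        codes.append("PVS1")
    codes += [f"PS{i}" for i in range(1, ps + 1)]
    codes += [f"PM{i}" for i in range(1, pm + 1)]
    codes += [f"PP{i}" for i in range(1, pp + 1)]
    if ba:
        codes.append("BA1")
    codes += [f"BS{i}" for i in range(1, bs + 1)]
    codes += [f"BP{i}" for i in range(1, bp + 1)]
    return frozenset(codes)
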