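"""e-Frail-CH scoring: eight dimension scores, the 0-12 total, and frailty bands.

The instrument sums eight dimension scores derived from routine hospital
data: cognition, general health status, functional independence, and social
support are scored 0-2; medication, mood, continence, and self-reported
performance are scored 0-1, giving a theoretical range of 0-12. A total
>= 6 flags frailty and >= 9 severe frailty (both cutoffs configurable;
they were anchored on Functional Independence Measure bands).

Scoring is a pure function of the record. Cluster-derived rule tables (see
:mod:`efrailch.twostep`) may replace the built-in condition strings for the
four clustered dimensions. Missing indicators score as the worst level of
their dimension — the instrument is a conservative clinical alert — except
the two mood flags, where an absent code is read as "no code".

The exact reading of the published condition strings for the intermediate
cognition/functional categories is ambiguous in two places; the chosen
formalization is isolated in `_COGNITION_RULES` / `_FUNCTIONAL_RULES` below
so it can be revised in one spot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .records_io import Hospitalization, IndicatorPanel

__all__ = [
    "DIMENSIONS",
    "DIMENSION_MAX",
    "FRAIL_CUTOFF",
    "SEVERE_CUTOFF",
    "DimensionScore",
    "EFrailResult",
    "score_cognition",
    "score_general_health",
    "score_functional",
    "score_social",
    "score_medication",
    "score_mood",
    "score_continence",
    "score_performance",
    "compute_total",
    "classify",
]

DIMENSIONS = (
    "cognition",
    "general_health",
    "functional",
    "social_support",
    "medication",
    "mood",
    "continence",
    "performance",
)

DIMENSION_MAX = {
    "cognition": 2,
    "general_health": 2,
    "functional": 2,
    "social_support": 2,
    "medication": 1,
    "mood": 1,
    "continence": 1,
    "performance": 1,
}

MAX_TOTAL = sum(DIMENSION_MAX.values())  # 12
FRAIL_CUTOFF = 6
SEVERE_CUTOFF = 9

#: dimensions whose built-in conditions may be replaced by cluster-derived
#: rule tables
CLUSTERED_DIMENSIONS = ("cognition", "functional", "social_support", "performance")


@dataclass(frozen=True)
class DimensionScore:
    dimension: str
    score: int
    source: str = "rule"  # "rule" | "cluster-derived"

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSION_MAX:
            raise ValueError(f"unknown dimension {self.dimension!r}")
        if not 0 <= self.score <= DIMENSION_MAX[self.dimension]:
            raise ValueError(
                f"{self.dimension} score {self.score} outside "
                f"[0, {DIMENSION_MAX[self.dimension]}]"
            )


@dataclass(frozen=True)
class EFrailResult:
    phase: str
    dimension_scores: tuple[DimensionScore, ...]
    total: int
    frail: bool
    severe: bool
    category: str
    category_efs_style: str

    def score_of(self, dimension: str) -> int:
        for ds in self.dimension_scores:
            if ds.dimension == dimension:
                return ds.score
        raise KeyError(dimension)


def _worst_if_missing(values: Sequence[Optional[int]], worst: int) -> tuple[int, ...]:
    return tuple(worst if v is None else v for v in values)


def _check_phase(phase: str) -> None:
    if phase not in ("admission", "discharge"):
        raise ValueError(f"unknown phase {phase!r}")


# --- cognition ------------------------------------------------------------
# Indicator order: alertness, orientation, concentration, learning/ADL demand.
# Intermediate category:
#   admission "0+0+(1 + 1)": alert and oriented, both of concentration and
#       learning mildly impaired;
#   discharge "0+(1 or 1 or 1)": alert, exactly one mild impairment among
#       the other three.


def _cognition_admission(c: tuple[int, ...]) -> int:
    if c == (0, 0, 0, 0):
        return 0
    if c[0] == 0 and c[1] == 0 and c[2] == 1 and c[3] == 1:
        return 1
    return 2


def _cognition_discharge(c: tuple[int, ...]) -> int:
    if c == (0, 0, 0, 0):
        return 0
    if c[0] == 0 and sorted(c[1:]) == [0, 0, 1]:
        return 1
    return 2


_COGNITION_RULES = {"admission": _cognition_admission, "discharge": _cognition_discharge}


def score_cognition(indicators: Sequence[Optional[int]], phase: str) -> int:
    _check_phase(phase)
    if len(indicators) != 4:
        raise ValueError("cognition takes 4 indicators")
    return _COGNITION_RULES[phase](_worst_if_missing(indicators, 2))


# --- functional independence ---------------------------------------------
# Indicator order: upper-body care, lower-body care, upper-body dressing,
# lower-body dressing.
#   admission "(0 or 1) + 1+0+0": lower-body care mildly impaired, upper-body
#       care at most mildly impaired, dressing unimpaired;
#   discharge "One or (1 or 2)+0+0": dressing unimpaired and exactly one of
#       the two care indicators impaired (to any degree), the other intact.


def _functional_admission(f: tuple[int, ...]) -> int:
    if f == (0, 0, 0, 0):
        return 0
    if f[0] in (0, 1) and f[1] == 1 and f[2] == 0 and f[3] == 0:
        return 1
    return 2


def _functional_discharge(f: tuple[int, ...]) -> int:
    if f == (0, 0, 0, 0):
        return 0
    care = (f[0], f[1])
    one_impaired = sum(v in (1, 2) for v in care) == 1 and 0 in care
    if f[2] == 0 and f[3] == 0 and one_impaired:
        return 1
    return 2


_FUNCTIONAL_RULES = {
    "admission": _functional_admission,
    "discharge": _functional_discharge,
}


def score_functional(indicators: Sequence[Optional[int]], phase: str) -> int:
    _check_phase(phase)
    if len(indicators) != 4:
        raise ValueError("functional takes 4 indicators")
    return _FUNCTIONAL_RULES[phase](_worst_if_missing(indicators, 2))


# --- remaining dimensions -------------------------------------------------


def score_general_health(n_codes: int) -> int:
    """Score from the ICD-10 + CHOP code count at discharge: 1 code -> 0,
    2 codes -> 1, more -> 2. A hospitalization implies at least one code."""
    if n_codes is None or n_codes < 1:
        raise ValueError("a hospitalization carries at least one ICD-10/CHOP code")
    if n_codes == 1:
        return 0
    if n_codes == 2:
        return 1
    return 2


def score_social(marital_status: Optional[str], residence: Optional[str]) -> int:
    """Married and living at home -> 0; single/divorced at home, or coming
    out of a hospital stay while living at home -> 1; anything else
    (including unknown combinations) -> 2."""
    if marital_status == "married" and residence == "home":
        return 0
    if residence == "home" and marital_status in ("single", "divorced"):
        return 1
    if marital_status == "hospital" and residence == "home":
        return 1
    return 2


def score_medication(n_medications: Optional[int]) -> int:
    """Polypharmacy flag: fewer than 5 concurrent medications -> 0, else 1.
    An unknown count scores 1 (missing-as-worst)."""
    if n_medications is None:
        return 1
    if n_medications < 0:
        raise ValueError("medication count cannot be negative")
    return 0 if n_medications < 5 else 1


def score_mood(exhaustion: Optional[int], mood_disorder_code: Optional[int]) -> int:
    """Mood disorder or exhaustion coded -> 1; an absent flag reads as no code."""
    return 1 if bool(exhaustion) or bool(mood_disorder_code) else 0


def score_continence(indicators: Sequence[Optional[int]]) -> int:
    if len(indicators) != 2:
        raise ValueError("continence takes 2 indicators")
    return 0 if _worst_if_missing(indicators, 1) == (0, 0) else 1


def score_performance(indicators: Sequence[Optional[int]]) -> int:
    if len(indicators) != 5:
        raise ValueError("performance takes 5 indicators")
    return 0 if _worst_if_missing(indicators, 1) == (0,) * 5 else 1


# --- totals ---------------------------------------------------------------


def _cluster_combo(rec: Hospitalization, panel: IndicatorPanel, dimension: str):
    if dimension == "cognition":
        return panel.cognition
    if dimension == "functional":
        return panel.functional
    if dimension == "performance":
        return panel.performance
    if dimension == "social_support":
        return (rec.marital_status, rec.residence)
    raise KeyError(dimension)


def compute_total(
    record: Hospitalization,
    phase: str,
    rule_tables: Optional[Mapping[str, "RuleTableLike"]] = None,
    frail_cutoff: int = FRAIL_CUTOFF,
    severe_cutoff: int = SEVERE_CUTOFF,
) -> EFrailResult:
    """Score one episode at one phase.

    ``rule_tables`` may map any of the four clustered dimensions to a
    cluster-derived rule table (anything with a ``score_for(combo)``
    method); those replace the built-in conditions for that dimension.
    Scoring a died episode at discharge is an error: such episodes have no
    discharge assessment.
    """
    _check_phase(phase)
    panel = record.panel(phase)
    if panel is None:
        raise ValueError(
            f"episode {record.episode_id}: no {phase} panel "
            "(died episodes cannot be scored at discharge)"
        )
    rule_tables = rule_tables or {}

    def clustered(dimension: str, builtin) -> DimensionScore:
        table = rule_tables.get(dimension)
        if table is not None:
            combo = _cluster_combo(record, panel, dimension)
            return DimensionScore(dimension, table.score_for(combo), "cluster-derived")
        return DimensionScore(dimension, builtin(), "rule")

    n_meds = (
        record.n_medications_admission
        if phase == "admission"
        else record.n_medications_discharge
    )
    scores = (
        clustered("cognition", lambda: score_cognition(panel.cognition, phase)),
        DimensionScore("general_health", score_general_health(record.n_codes)),
        clustered("functional", lambda: score_functional(panel.functional, phase)),
        clustered(
            "social_support",
            lambda: score_social(record.marital_status, record.residence),
        ),
        DimensionScore("medication", score_medication(n_meds)),
        DimensionScore(
            "mood", score_mood(panel.exhaustion, panel.mood_disorder_code)
        ),
        DimensionScore("continence", score_continence(panel.continence)),
        clustered("performance", lambda: score_performance(panel.performance)),
    )
    total = sum(ds.score for ds in scores)
    return EFrailResult(
        phase=phase,
        dimension_scores=scores,
        total=total,
        frail=total >= frail_cutoff,
        severe=total >= severe_cutoff,
        category=classify(total, frail_cutoff, severe_cutoff),
        category_efs_style=_efs_style_band(total),
    )


def classify(
    total: int, frail_cutoff: int = FRAIL_CUTOFF, severe_cutoff: int = SEVERE_CUTOFF
) -> str:
    """Band a 0-12 total: below the frail cutoff -> "not frail", at or above
    the severe cutoff -> "severely frail", otherwise "frail"."""
    if not 0 <= total <= MAX_TOTAL:
        raise ValueError(f"total {total} outside [0, {MAX_TOTAL}]")
    if total >= severe_cutoff:
        return "severely frail"
    if total >= frail_cutoff:
        return "frail"
    return "not frail"


def _efs_style_band(total: int) -> str:
    # Legacy annotation using the Edmonton Frail Scale's 0-17 bands
    # (8-9 mild, 10-11 moderate, >=12 severe). Reported for reference only;
    # the frail/severe flags never use it, because this instrument spans
    # 0-12, not 0-17.
    if total >= 12:
        return "severe"
    if total >= 10:
        return "moderate"
    if total >= 8:
        return "mild"
    return "not frail"


class RuleTableLike:  # pragma: no cover - typing aid only
    def score_for(self, combo) -> int: ...
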