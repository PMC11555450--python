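"""Hospitalization data model, delimited-text I/O, and cohort filtering rules.

One record is one admission->discharge episode of an inpatient aged >=65.
Each episode carries an indicator panel per phase (admission / discharge),
sociodemographics, diagnosis/procedure code counts, medication counts, and
an optional Functional Independence Measure (FIM) total at discharge.
Episodes that end in in-hospital death have no discharge panel and no FIM.

Files are plain delimited text (comma by default, tab accepted), UTF-8,
"." decimal separator, empty string for missing. A schema mapping lets
site-specific column names be remapped onto the canonical header.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "IndicatorPanel",
    "Hospitalization",
    "ExclusionReport",
    "ParseLog",
    "COLUMNS",
    "DIMENSION_FIELDS",
    "read_cohort",
    "write_cohort",
    "apply_inclusion",
    "drop_sparse_dimensions",
]

PHASES = ("admission", "discharge")

#: categories accepted for the sociodemographic fields
GENDERS = ("woman", "man")
PROVENANCES = ("home", "health_care_setting")
DESTINATIONS = ("home", "health_care_setting", "died")


@dataclass(frozen=True)
class IndicatorPanel:
    """One phase's raw health indicators.

    Ordinal indicators take levels 0 (best) .. 2 (worst); flags take 0/1.
    ``None`` means missing.  Vector layouts:

    * cognition (4): alertness/consciousness, orientation, concentration,
      learning / capacity to meet daily-living demands
    * functional (4): upper-body care, lower-body care, upper-body
      dressing, lower-body dressing
    * continence (2): urinary incontinence, urine drainage device
    * performance (5): general mobility, position change, gait,
      balance disorder, fall risk
    """

    cognition: tuple[Optional[int], ...]
    functional: tuple[Optional[int], ...]
    continence: tuple[Optional[int], ...]
    performance: tuple[Optional[int], ...]
    exhaustion: Optional[int] = None
    mood_disorder_code: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.cognition) != 4 or len(self.functional) != 4:
            raise ValueError("cognition and functional indicators need 4 entries")
        if len(self.continence) != 2:
            raise ValueError("continence indicators need 2 entries")
        if len(self.performance) != 5:
            raise ValueError("performance indicators need 5 entries")
        for vec, levels in (
            (self.cognition, (0, 1, 2)),
            (self.functional, (0, 1, 2)),
            (self.continence, (0, 1)),
            (self.performance, (0, 1)),
            ((self.exhaustion, self.mood_disorder_code), (0, 1)),
        ):
            for v in vec:
                if v is not None and v not in levels:
                    raise ValueError(f"indicator level {v!r} outside {levels}")

    def fields(self) -> tuple[Optional[int], ...]:
        """All 17 indicator values in canonical order."""
        return (
            *self.cognition,
            *self.functional,
            *self.continence,
            *self.performance,
            self.exhaustion,
            self.mood_disorder_code,
        )


@dataclass(frozen=True)
class Hospitalization:
    episode_id: str
    age: Optional[float]
    gender: Optional[str]
    admitted_from: Optional[str]
    discharged_to: Optional[str]
    length_of_stay: Optional[int]
    marital_status: Optional[str]
    residence: Optional[str]
    n_codes: Optional[int]
    n_medications_admission: Optional[int]
    n_medications_discharge: Optional[int]
    admission_panel: IndicatorPanel
    discharge_panel: Optional[IndicatorPanel]
    fim_total: Optional[int] = None
    nutrition_weight_loss_admission: Optional[int] = None
    nutrition_weight_loss_discharge: Optional[int] = None

    @property
    def died(self) -> bool:
        return self.discharged_to == "died"

    def __post_init__(self) -> None:
        if self.fim_total is not None and not (18 <= self.fim_total <= 126):
            raise ValueError(f"fim_total {self.fim_total} outside [18, 126]")

    def panel(self, phase: str) -> Optional[IndicatorPanel]:
        if phase == "admission":
            return self.admission_panel
        if phase == "discharge":
            return self.discharge_panel
        raise ValueError(f"unknown phase {phase!r}")


@dataclass(frozen=True)
class ExclusionReport:
    n_input: int
    n_retained: int
    n_excluded_missing: int
    n_excluded_sociodemo: int
    n_excluded_age: int

    def __post_init__(self) -> None:
        total = (
            self.n_retained
            + self.n_excluded_missing
            + self.n_excluded_sociodemo
            + self.n_excluded_age
        )
        if total != self.n_input:
            raise ValueError("exclusion counts do not reconcile with input size")


@dataclass
class ParseLog:
    n_rows: int = 0
    n_unparseable_cells: int = 0
    inconsistencies: list[str] = field(default_factory=list)


# ---------------------------------------------------------------- schema ---

_PANEL_COLS = (
    [f"cog{i}" for i in range(1, 5)]
    + [f"fun{i}" for i in range(1, 5)]
    + [f"con{i}" for i in range(1, 3)]
    + [f"per{i}" for i in range(1, 6)]
    + ["exhaustion", "mood_code"]
)

#: canonical file header, in order
COLUMNS: tuple[str, ...] = tuple(
    [
        "episode_id",
        "age",
        "gender",
        "admitted_from",
        "discharged_to",
        "length_of_stay",
        "marital_status",
        "residence",
        "n_codes",
        "n_medications_admission",
        "n_medications_discharge",
        "fim_total",
        "nutrition_weight_loss_admission",
        "nutrition_weight_loss_discharge",
    ]
    + [f"adm_{c}" for c in _PANEL_COLS]
    + [f"dis_{c}" for c in _PANEL_COLS]
)

_MANDATORY = ("episode_id", "age", "discharged_to")

#: raw-field groups backing each instrument dimension, per phase prefix.
#: "nutrition" is carried in input but never scored (too sparse; see
#: drop_sparse_dimensions).
DIMENSION_FIELDS: dict[str, dict[str, tuple[str, ...]]] = {
    "cognition": {
        "admission": tuple(f"adm_cog{i}" for i in range(1, 5)),
        "discharge": tuple(f"dis_cog{i}" for i in range(1, 5)),
    },
    "functional": {
        "admission": tuple(f"adm_fun{i}" for i in range(1, 5)),
        "discharge": tuple(f"dis_fun{i}" for i in range(1, 5)),
    },
    "continence": {
        "admission": tuple(f"adm_con{i}" for i in range(1, 3)),
        "discharge": tuple(f"dis_con{i}" for i in range(1, 3)),
    },
    "performance": {
        "admission": tuple(f"adm_per{i}" for i in range(1, 6)),
        "discharge": tuple(f"dis_per{i}" for i in range(1, 6)),
    },
    "mood": {
        "admission": ("adm_exhaustion", "adm_mood_code"),
        "discharge": ("dis_exhaustion", "dis_mood_code"),
    },
    "general_health": {"admission": ("n_codes",), "discharge": ("n_codes",)},
    "medication": {
        "admission": ("n_medications_admission",),
        "discharge": ("n_medications_discharge",),
    },
    "social_support": {
        "admission": ("marital_status", "residence"),
        "discharge": ("marital_status", "residence"),
    },
    "nutrition": {
        "admission": ("nutrition_weight_loss_admission",),
        "discharge": ("nutrition_weight_loss_discharge",),
    },
}


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def record_to_row(rec: Hospitalization) -> dict[str, str]:
    row = {
        "episode_id": rec.episode_id,
        "age": _fmt(rec.age),
        "gender": _fmt(rec.gender),
        "admitted_from": _fmt(rec.admitted_from),
        "discharged_to": _fmt(rec.discharged_to),
        "length_of_stay": _fmt(rec.length_of_stay),
        "marital_status": _fmt(rec.marital_status),
        "residence": _fmt(rec.residence),
        "n_codes": _fmt(rec.n_codes),
        "n_medications_admission": _fmt(rec.n_medications_admission),
        "n_medications_discharge": _fmt(rec.n_medications_discharge),
        "fim_total": _fmt(rec.fim_total),
        "nutrition_weight_loss_admission": _fmt(rec.nutrition_weight_loss_admission),
        "nutrition_weight_loss_discharge": _fmt(rec.nutrition_weight_loss_discharge),
    }
    for prefix, panel in (("adm", rec.admission_panel), ("dis", rec.discharge_panel)):
        values = panel.fields() if panel is not None else (None,) * 17
        for col, val in zip(_PANEL_COLS, values):
            row[f"{prefix}_{col}"] = _fmt(val)
    return row


def write_cohort(records: Iterable[Hospitalization], path, sep: str = ",") -> None:
    """Write a cohort as delimited text with the canonical header."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=COLUMNS, delimiter=sep)
        writer.writeheader()
        for rec in records:
            writer.writerow(record_to_row(rec))


def _parse_int(cell: str, log: ParseLog) -> Optional[int]:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return int(float(cell))
    except ValueError:
        log.n_unparseable_cells += 1
        return None


def _parse_float(cell: str, log: ParseLog) -> Optional[float]:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        log.n_unparseable_cells += 1
        return None


def _parse_str(cell: str) -> Optional[str]:
    cell = cell.strip()
    return cell if cell else None


def _row_to_record(row: Mapping[str, str], log: ParseLog) -> Hospitalization:
    def panel(prefix: str) -> Optional[IndicatorPanel]:
        vals = [_parse_int(row.get(f"{prefix}_{c}", ""), log) for c in _PANEL_COLS]
        if prefix == "dis" and all(v is None for v in vals):
            return None
        return IndicatorPanel(
            cognition=tuple(vals[0:4]),
            functional=tuple(vals[4:8]),
            continence=tuple(vals[8:10]),
            performance=tuple(vals[10:15]),
            exhaustion=vals[15],
            mood_disorder_code=vals[16],
        )

    fim = _parse_int(row.get("fim_total", ""), log)
    if fim is not None and not (18 <= fim <= 126):
        log.n_unparseable_cells += 1
        fim = None
    rec = Hospitalization(
        episode_id=_parse_str(row.get("episode_id", "")) or "",
        age=_parse_float(row.get("age", ""), log),
        gender=_parse_str(row.get("gender", "")),
        admitted_from=_parse_str(row.get("admitted_from", "")),
        discharged_to=_parse_str(row.get("discharged_to", "")),
        length_of_stay=_parse_int(row.get("length_of_stay", ""), log),
        marital_status=_parse_str(row.get("marital_status", "")),
        residence=_parse_str(row.get("residence", "")),
        n_codes=_parse_int(row.get("n_codes", ""), log),
        n_medications_admission=_parse_int(row.get("n_medications_admission", ""), log),
        n_medications_discharge=_parse_int(row.get("n_medications_discharge", ""), log),
        admission_panel=panel("adm") or IndicatorPanel((None,) * 4, (None,) * 4, (None,) * 2, (None,) * 5),
        discharge_panel=panel("dis"),
        fim_total=fim,
        nutrition_weight_loss_admission=_parse_int(
            row.get("nutrition_weight_loss_admission", ""), log
        ),
        nutrition_weight_loss_discharge=_parse_int(
            row.get("nutrition_weight_loss_discharge", ""), log
        ),
    )
    if rec.died and rec.fim_total is not None:
        log.inconsistencies.append(
            f"{rec.episode_id}: FIM present although the episode ended in death"
        )
    if rec.died and rec.discharge_panel is not None:
        log.inconsistencies.append(
            f"{rec.episode_id}: discharge panel present although the episode ended in death"
        )
    return rec


def read_cohort(
    source,
    schema: Optional[Mapping[str, str]] = None,
    sep: Optional[str] = None,
) -> tuple[list[Hospitalization], ParseLog]:
    """Read a cohort file.

    Parameters
    ----------
    source
        Path to a delimited-text file with a header row.
    schema
        Optional mapping of canonical field name -> column name in the file,
        for sites whose export uses different headers. Unmapped canonical
        names are looked up verbatim.
    sep
        Field delimiter; sniffed between "," and tab when omitted.

    Returns
    -------
    (records, log)
        Typed records plus a parse log counting unparseable cells and
        listing internal inconsistencies (kept in the data, only flagged).
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    log = ParseLog()
    if not text.strip():
        warnings.warn(f"{path} is empty; returning an empty cohort", stacklevel=2)
        return [], log
    if sep is None:
        header_line = text.splitlines()[0]
        sep = "\t" if header_line.count("\t") > header_line.count(",") else ","
    reader = csv.DictReader(text.splitlines(), delimiter=sep)
    header = set(reader.fieldnames or ())
    rename = dict(schema or {})
    missing_cols = [
        canon for canon in _MANDATORY if rename.get(canon, canon) not in header
    ]
    if missing_cols:
        raise ValueError(f"missing mandatory columns: {missing_cols}")
    records = []
    for raw in reader:
        log.n_rows += 1
        row = {canon: raw.get(rename.get(canon, canon), "") or "" for canon in COLUMNS}
        records.append(_row_to_record(row, log))
    return records, log


# ----------------------------------------------------------- inclusion ----

_SOCIODEMO_FIELDS = (
    "age",
    "gender",
    "admitted_from",
    "discharged_to",
    "marital_status",
    "residence",
    "length_of_stay",
)

# Health denominator for the missing-data rule: every indicator-panel field
# plus code and medication counts, pooled over the phases the episode has.
# Nutrition is outside the instrument and outside this denominator.


def _health_fields(rec: Hospitalization, phase: Optional[str] = None) -> list:
    vals: list = []
    if phase in (None, "admission"):
        vals.extend(rec.admission_panel.fields())
        vals.append(rec.n_medications_admission)
        vals.append(rec.n_codes)
    if phase in (None, "discharge") and not rec.died:
        panel = rec.discharge_panel
        vals.extend(panel.fields() if panel is not None else (None,) * 17)
        vals.append(rec.n_medications_discharge)
        if phase == "discharge":
            vals.append(rec.n_codes)
    return vals


def _missing_fraction(values: Sequence) -> float:
    return sum(v is None for v in values) / len(values) if values else 0.0


def apply_inclusion(
    cohort: Sequence[Hospitalization],
    missing_threshold: float = 0.20,
    per_phase: bool = False,
) -> tuple[list[Hospitalization], ExclusionReport]:
    """Apply the study's inclusion rules.

    Retains episodes of patients aged >=65 whose sociodemographic block is
    complete and whose health-indicator missingness does not exceed
    ``missing_threshold`` (pooled over phases by default; ``per_phase=True``
    applies the rule separately to each phase and excludes on either).
    Each excluded episode is counted under its first failing reason, in the
    order age -> sociodemographics -> missingness, so the counts are
    unambiguous.
    """
    if not 0.0 <= missing_threshold <= 1.0:
        raise ValueError("missing_threshold must be in [0, 1]")
    retained: list[Hospitalization] = []
    n_age = n_socio = n_missing = 0
    for rec in cohort:
        if rec.age is None or rec.age < 65:
            n_age += 1
            continue
        if any(getattr(rec, f) is None for f in _SOCIODEMO_FIELDS):
            n_socio += 1
            continue
        if per_phase:
            fractions = [_missing_fraction(_health_fields(rec, "admission"))]
            if not rec.died:
                fractions.append(_missing_fraction(_health_fields(rec, "discharge")))
            too_sparse = any(f > missing_threshold for f in fractions)
        else:
            too_sparse = _missing_fraction(_health_fields(rec)) > missing_threshold
        if too_sparse:
            n_missing += 1
            continue
        retained.append(rec)
    report = ExclusionReport(
        n_input=len(cohort),
        n_retained=len(retained),
        n_excluded_missing=n_missing,
        n_excluded_sociodemo=n_socio,
        n_excluded_age=n_age,
    )
    return retained, report


def _field_value(rec: Hospitalization, name: str):
    if name.startswith(("adm_", "dis_")):
        prefix, col = name.split("_", 1)
        panel = rec.admission_panel if prefix == "adm" else rec.discharge_panel
        if panel is None:
            return None
        return dict(zip(_PANEL_COLS, panel.fields()))[col]
    return getattr(rec, name)


def drop_sparse_dimensions(
    cohort: Sequence[Hospitalization],
    dimensions: Optional[Sequence[str]] = None,
    missing_rate_threshold: float = 0.50,
) -> tuple[list[str], dict[str, dict[str, float]]]:
    """Drop instrument dimensions whose data are too sparse to score.

    A dimension is dropped when the fraction of missing cells among its raw
    fields exceeds ``missing_rate_threshold`` in either phase (discharge
    rates are computed over survivors, whose panels are expected). Returns
    the retained dimension names, in input order, together with the realized
    missingness rate per dimension and phase.
    """
    if dimensions is None:
        dimensions = list(DIMENSION_FIELDS)
    unknown = [d for d in dimensions if d not in DIMENSION_FIELDS]
    if unknown:
        raise ValueError(f"unknown dimension name(s): {unknown}")
    rates: dict[str, dict[str, float]] = {}
    retained = []
    for dim in dimensions:
        rates[dim] = {}
        for phase in PHASES:
            fields_ = DIMENSION_FIELDS[dim][phase]
            pool = [
                _field_value(rec, f)
                for rec in cohort
                if phase == "admission" or not rec.died
                for f in fields_
            ]
            rates[dim][phase] = _missing_fraction(pool)
        if all(rates[dim][p] <= missing_rate_threshold for p in PHASES):
            retained.append(dim)
    return retained, rates
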