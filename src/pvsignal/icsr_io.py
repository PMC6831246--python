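"""Reading, writing, and inclusion filtering of ICSR tables.

File schema
-----------
One row per report, CSV (default) or TSV. Columns::

    report_id, is_initial, report_year, report_type, reporter, sex,
    age_years, causality, serious, seriousness_type, drugs, events, note

``drugs`` packs the report's drug list into one cell: entries separated by
``|``, each entry ``<ATC>:s`` (suspected) or ``<ATC>:c`` (concomitant); an
empty ATC before the colon encodes a missing drug code. ``events`` is a
``|``-separated list of adverse-event preferred terms. Empty cells encode
missing values. Enum tokens are case-insensitive on read and written in
canonical lower case.

Inclusion filtering mirrors the usual spontaneous-report analysis set:
keep initial reports with complete sex/age/drug/event coding, causality
assessed certain/probable/possible, and at least one suspected drug. Each
excluded report is attributed to the *first* failing rule in the fixed
order ``missing_field -> non_initial -> causality -> no_suspected_drug``
and the :class:`FilterLog` reconciles counts exactly.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from pvsignal.types import (
    Causality,
    DrugEntry,
    IcsrReport,
    Reporter,
    ReportSet,
    ReportType,
    SeriousnessType,
    Sex,
)

COLUMNS = [
    "report_id",
    "is_initial",
    "report_year",
    "report_type",
    "reporter",
    "sex",
    "age_years",
    "causality",
    "serious",
    "seriousness_type",
    "drugs",
    "events",
    "note",
]

LIST_DELIMITER = "|"

#: Fixed attribution order: an excluded report is counted once, under the
#: first rule it fails.
EXCLUSION_ORDER = ("missing_field", "non_initial", "causality", "no_suspected_drug")


class SchemaError(ValueError):
    """The file header does not match the documented column schema."""


class ValidationError(ValueError):
    """A cell value could not be interpreted; names the row and column."""


@dataclass(frozen=True)
class FilterCriteria:
    """Which inclusion rules are active.

    Defaults reproduce the standard analysis set: initial reports only,
    complete coding required, causality in {certain, probable, possible},
    and at least one suspected drug.
    """

    allowed_causality: frozenset[Causality] = frozenset(
        {Causality.CERTAIN, Causality.PROBABLE, Causality.POSSIBLE}
    )
    require_initial: bool = True
    require_complete: bool = True
    suspected_only: bool = True

    def __post_init__(self) -> None:
        if not self.allowed_causality:
            raise ValueError("allowed_causality must be non-empty")
        object.__setattr__(self, "allowed_causality", frozenset(self.allowed_causality))

    @classmethod
    def permissive(cls) -> "FilterCriteria":
        """Criteria under which filtering is the identity."""
        return cls(
            allowed_causality=frozenset(Causality),
            require_initial=False,
            require_complete=False,
            suspected_only=False,
        )


@dataclass
class FilterLog:
    """Audit record of one filtering pass; counts reconcile exactly."""

    n_in: int = 0
    n_out: int = 0
    counts_removed_by_reason: dict[str, int] = field(
        default_factory=lambda: {reason: 0 for reason in EXCLUSION_ORDER}
    )

    def reconciles(self) -> bool:
        return self.n_in - self.n_out == sum(self.counts_removed_by_reason.values())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_in": self.n_in,
            "n_out": self.n_out,
            "counts_removed_by_reason": self.counts_removed_by_reason,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _parse_bool(token: str, row: int, column: str) -> bool:
    t = token.strip().lower()
    if t in {"true", "t", "1", "yes", "y"}:
        return True
    if t in {"false", "f", "0", "no", "n"}:
        return False
    raise ValidationError(f"row {row}, column {column!r}: cannot parse boolean {token!r}")


def _parse_enum(enum_cls, token: str, row: int, column: str, missing_default=None):
    t = token.strip().lower()
    if not t and missing_default is not None:
        return missing_default
    try:
        return enum_cls(t)
    except ValueError:
        raise ValidationError(
            f"row {row}, column {column!r}: unknown {enum_cls.__name__} token {token!r}"
        ) from None


def _parse_drugs(cell: str) -> list[DrugEntry]:
    entries: list[DrugEntry] = []
    if not cell.strip():
        return entries
    for part in cell.split(LIST_DELIMITER):
        part = part.strip()
        if not part:
            continue
        if ":" in part:
            code, role = part.rsplit(":", 1)
            suspected = role.strip().lower() != "c"
        else:
            code, suspected = part, True
        entries.append(DrugEntry(atc_code=code.strip() or None, suspected=suspected))
    return entries


def _parse_events(cell: str) -> list[str]:
    # Empty PT entries are preserved here; completeness is a filter concern.
    if not cell.strip():
        return []
    return [p.strip() for p in cell.split(LIST_DELIMITER)]


def _parse_row(rec: dict[str, str], row: int) -> IcsrReport:
    age_cell = rec.get("age_years", "").strip()
    if age_cell:
        try:
            age: float | None = float(age_cell)
        except ValueError:
            raise ValidationError(
                f"row {row}, column 'age_years': cannot parse number {age_cell!r}"
            ) from None
    else:
        age = None
    try:
        year = int(rec["report_year"].strip())
    except ValueError:
        raise ValidationError(
            f"row {row}, column 'report_year': cannot parse year {rec['report_year']!r}"
        ) from None
    serious = _parse_bool(rec["serious"], row, "serious")
    stype = _parse_enum(
        SeriousnessType, rec.get("seriousness_type", ""), row, "seriousness_type",
        missing_default=SeriousnessType.NONE,
    )
    report = IcsrReport(
        report_id=rec["report_id"].strip(),
        is_initial=_parse_bool(rec["is_initial"], row, "is_initial"),
        report_year=year,
        report_type=_parse_enum(ReportType, rec["report_type"], row, "report_type"),
        reporter=_parse_enum(Reporter, rec["reporter"], row, "reporter"),
        sex=_parse_enum(Sex, rec["sex"], row, "sex", missing_default=Sex.MISSING),
        age_years=age,
        causality=_parse_enum(
            Causality, rec["causality"], row, "causality", missing_default=Causality.MISSING
        ),
        serious=serious,
        seriousness_type=stype,
        drugs=_parse_drugs(rec.get("drugs", "")),
        events=_parse_events(rec.get("events", "")),
        note=rec.get("note", "").strip(),
    )
    if not report.report_id:
        raise ValidationError(f"row {row}, column 'report_id': empty id")
    return report


def read_reports(path: str | Path, delimiter: str | None = None, strict: bool = False) -> ReportSet:
    """Read an ICSR table.

    Parameters
    ----------
    path
        CSV or TSV file following the documented schema.
    delimiter
        Cell delimiter; inferred from the extension when omitted
        (``.tsv`` -> tab, else comma).
    strict
        If True, the first malformed row raises :class:`ValidationError`.
        Otherwise malformed rows are collected in ``ReportSet.rejects``
        (dicts with ``row``, ``error`` and the raw record), never silently
        dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    reports: list[IcsrReport] = []
    rejects: list[dict] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for c in COLUMNS if c != "note" and c not in header]
        if missing:
            raise SchemaError(f"{path}: header is missing required columns {missing}")
        for row_no, rec in enumerate(reader, start=2):
            try:
                reports.append(_parse_row(rec, row_no))
            except (ValidationError, ValueError) as exc:
                if strict:
                    raise
                rejects.append({"row": row_no, "error": str(exc), "record": dict(rec)})
    return ReportSet(reports, rejects=rejects)


def _format_drugs(drugs: Iterable[DrugEntry]) -> str:
    return LIST_DELIMITER.join(
        f"{d.atc_code or ''}:{'s' if d.suspected else 'c'}" for d in drugs
    )


def write_reports(reports: ReportSet, path: str | Path, delimiter: str | None = None) -> None:
    """Write a :class:`ReportSet` in the documented schema (round-trip safe)."""
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(COLUMNS)
        for r in reports:
            age = "" if r.age_years is None or (
                isinstance(r.age_years, float) and math.isnan(r.age_years)
            ) else (repr(int(r.age_years)) if float(r.age_years).is_integer() else repr(r.age_years))
            writer.writerow([
                r.report_id,
                str(r.is_initial).lower(),
                r.report_year,
                r.report_type.value,
                r.reporter.value,
                r.sex.value if r.sex != Sex.MISSING else "",
                age,
                r.causality.value if r.causality != Causality.MISSING else "",
                str(r.serious).lower(),
                r.seriousness_type.value,
                _format_drugs(r.drugs),
                LIST_DELIMITER.join(r.events),
                r.note,
            ])


def write_rejects(reports: ReportSet, path: str | Path) -> None:
    """Write the parse-reject report as CSV (row, error)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "error"])
        for rej in reports.rejects:
            writer.writerow([rej["row"], rej["error"]])


def _is_missing_age(r: IcsrReport) -> bool:
    return r.age_years is None or (
        isinstance(r.age_years, float) and math.isnan(r.age_years)
    )


def _clean_report(r: IcsrReport) -> IcsrReport:
    """Drop empty-PT events and missing-ATC drug entries (completeness pass)."""
    events = [e for e in r.events if e and e.strip()]
    drugs = [d for d in r.drugs if d.atc_code]
    if events == r.events and drugs == r.drugs:
        return r
    return r.copy(drugs=drugs, events=events)


def _first_failing_rule(r: IcsrReport, criteria: FilterCriteria) -> str | None:
    if criteria.require_complete:
        if (
            r.sex == Sex.MISSING
            or _is_missing_age(r)
            or not r.events
            or not r.drugs
        ):
            return "missing_field"
    if criteria.require_initial and not r.is_initial:
        return "non_initial"
    if r.causality not in criteria.allowed_causality:
        return "causality"
    if criteria.suspected_only and not r.suspected_drugs():
        return "no_suspected_drug"
    return None


def apply_inclusion_filters(
    reports: ReportSet, criteria: FilterCriteria | None = None
) -> tuple[ReportSet, FilterLog]:
    """Apply the inclusion rules; returns the retained set and an audit log.

    When ``require_complete`` is active, events with empty PT codes and drug
    entries with missing ATC codes are dropped from each report before the
    rules run, so a partially coded report survives if anything valid
    remains. Input order is preserved; an empty result is valid. Filtering
    is idempotent, and :meth:`FilterCriteria.permissive` criteria leave the
    input untouched.
    """
    criteria = criteria or FilterCriteria()
    log = FilterLog(n_in=len(reports))
    kept: list[IcsrReport] = []
    for r in reports:
        candidate = _clean_report(r) if criteria.require_complete else r
        reason = _first_failing_rule(candidate, criteria)
        if reason is None:
            kept.append(candidate)
        else:
            log.counts_removed_by_reason[reason] += 1
    log.n_out = len(kept)
    assert log.reconciles()
    return ReportSet(kept), log
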