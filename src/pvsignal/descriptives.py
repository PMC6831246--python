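"""Descriptive summaries: characteristics tables and annual trends.

Characteristics are tabulated per drug at report level: counts and
percentages by sex, age group, report type, reporter profession, causality
level, and seriousness type, plus the total report count and the SAE ratio
(serious reports / all reports for the drug). Percentages are computed at
full precision internally and rounded half-up to one decimal only for
presentation. Annual trends count AE and SAE reports per (drug, year) over
a contiguous year range with explicit zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from pvsignal.types import (
    AgeGroup,
    Causality,
    IcsrReport,
    Reporter,
    ReportSet,
    ReportType,
    SeriousnessType,
    Sex,
    round_half_up,
)

_SECTIONS: dict[str, tuple] = {
    "sex": ([s.value for s in (Sex.MALE, Sex.FEMALE)], lambda r: r.sex.value),
    "age_group": (
        [g.value for g in AgeGroup],
        lambda r: r.age_group.value if r.age_group else None,
    ),
    "report_type": ([t.value for t in ReportType], lambda r: r.report_type.value),
    "reporter": ([p.value for p in Reporter], lambda r: r.reporter.value),
    "causality": (
        [c.value for c in (Causality.CERTAIN, Causality.PROBABLE, Causality.POSSIBLE)],
        lambda r: r.causality.value,
    ),
    "seriousness": (
        [t.value for t in SeriousnessType],
        lambda r: r.seriousness_type.value,
    ),
}


@dataclass
class CharacteristicsTable:
    """Long-format characteristics summary; one row per (drug, section, level)."""

    frame: pd.DataFrame
    totals: dict[str, int]

    def percent(self, drug: str, section: str, level: str) -> float:
        """Presentation percentage (half-up, one decimal); NaN if total is 0."""
        sel = self.frame[
            (self.frame["drug"] == drug)
            & (self.frame["section"] == section)
            & (self.frame["level"] == level)
        ]
        if sel.empty:
            raise KeyError((drug, section, level))
        return float(sel["percent"].iloc[0])

    def count(self, drug: str, section: str, level: str) -> int:
        sel = self.frame[
            (self.frame["drug"] == drug)
            & (self.frame["section"] == section)
            & (self.frame["level"] == level)
        ]
        if sel.empty:
            raise KeyError((drug, section, level))
        return int(sel["count"].iloc[0])

    def sae_ratio(self, drug: str) -> float:
        return self.percent(drug, "sae", "serious")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def text(self) -> str:
        lines = []
        for drug in self.totals:
            lines.append(f"=== {drug} (n = {self.totals[drug]}) ===")
            sub = self.frame[self.frame["drug"] == drug]
            for section in sub["section"].unique():
                lines.append(f"  {section}:")
                for _, row in sub[sub["section"] == section].iterrows():
                    pct = "" if math.isnan(row["percent"]) else f" ({row['percent']:.1f}%)"
                    lines.append(f"    {row['level']:<28}{int(row['count']):>5}{pct}")
        return "\n".join(lines)


def summarize_characteristics(reports: ReportSet, drugs: list[str]) -> CharacteristicsTable:
    """Tabulate report-level characteristics for each drug of interest.

    A report counts toward a drug when that drug appears among its
    suspected drugs. A drug with zero reports gets rows of zeros with blank
    (NaN) percentages.
    """
    rows = []
    totals: dict[str, int] = {}
    for drug in drugs:
        sub: list[IcsrReport] = [r for r in reports if r.has_drug(drug)]
        total = len(sub)
        totals[drug] = total

        def pct(count: int) -> float:
            return round_half_up(100.0 * count / total, 1) if total else math.nan

        for section, (levels, keyfn) in _SECTIONS.items():
            for level in levels:
                count = sum(1 for r in sub if keyfn(r) == level)
                rows.append((drug, section, level, count, pct(count)))
        n_serious = sum(1 for r in sub if r.serious)
        rows.append((drug, "total", "reports", total, pct(total)))
        rows.append((drug, "sae", "serious", n_serious, pct(n_serious)))
    frame = pd.DataFrame(rows, columns=["drug", "section", "level", "count", "percent"])
    return CharacteristicsTable(frame=frame, totals=totals)


def annual_trends(reports: ReportSet, drugs: list[str]) -> pd.DataFrame:
    """Per-(drug, year) AE report counts, SAE counts, and the SAE ratio.

    Years are contiguous from the first to the last observed year of each
    drug, with explicit zero rows; ``sae_ratio`` is a half-up one-decimal
    percentage, NaN where a year has no reports.
    """
    rows = []
    for drug in drugs:
        sub = [r for r in reports if r.has_drug(drug)]
        if not sub:
            continue
        years = [r.report_year for r in sub]
        for year in range(min(years), max(years) + 1):
            in_year = [r for r in sub if r.report_year == year]
            n_ae = len(in_year)
            n_sae = sum(1 for r in in_year if r.serious)
            ratio = round_half_up(100.0 * n_sae / n_ae, 1) if n_ae else math.nan
            rows.append((drug, year, n_ae, n_sae, ratio))
    return pd.DataFrame(rows, columns=["drug", "year", "n_ae", "n_sae", "sae_ratio"])
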