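"""Drug-event pair construction and 2x2 contingency tables.

Disproportionality analysis works on drug-AE *pairs*: each filtered report
is exploded into the cartesian product of its qualifying drugs and its
distinct adverse-event terms, carrying the report's covariates along. For a
target (drug, event) the 2x2 table counts pairs::

              event        other events
    drug        a               b
    others      c               d

with the comparator being all other drugs present in the supplied pair set;
no external background is consulted.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from pvsignal.types import ReportSet

PAIR_COLUMNS = [
    "report_id",
    "atc_code",
    "event_pt",
    "sex",
    "age_group",
    "report_year",
    "serious",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 pair counts for one (drug, event)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_drug(self) -> int:
        """Pairs involving the target drug (row margin a+b)."""
        return self.a + self.b

    @property
    def n_event(self) -> int:
        """Pairs involving the target event (column margin a+c)."""
        return self.a + self.c

    @property
    def expected_a(self) -> float:
        """Expected a-cell under independence: (a+b)(a+c)/n."""
        if self.n_total == 0:
            raise ZeroDivisionError("empty contingency table")
        return self.n_drug * self.n_event / self.n_total

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def _dedupe(seq):
    seen = set()
    out = []
    for x in seq:
        if x not in seen:
            seen.add(x)
            out.append(x)
    return out


def build_pairs(reports: ReportSet, suspected_only: bool = True) -> pd.DataFrame:
    """Explode reports into drug-event pairs.

    Each report contributes ``#qualifying drugs x #distinct events`` rows;
    duplicate event terms and duplicate drug codes within one report are
    de-duplicated first so a repeated coding never double-counts. Row order
    is deterministic: report order, then drug order, then event order.
    """
    rows = []
    for r in reports:
        drugs = r.suspected_drugs() if suspected_only else r.drugs
        codes = _dedupe(d.atc_code for d in drugs if d.atc_code)
        events = _dedupe(e for e in r.events if e and e.strip())
        group = r.age_group
        for code in codes:
            for ev in events:
                rows.append(
                    (
                        r.report_id,
                        code,
                        ev,
                        r.sex.value,
                        group.value if group is not None else None,
                        r.report_year,
                        r.serious,
                    )
                )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def build_contingency(pairs: pd.DataFrame, drug: str, event: str) -> ContingencyTable:
    """2x2 table for one (drug, event); absent drug or event gives a=0."""
    if pairs.empty:
        raise ValueError("pair set is empty")
    is_drug = (pairs["atc_code"] == drug).to_numpy()
    is_event = (pairs["event_pt"] == event).to_numpy()
    a = int((is_drug & is_event).sum())
    b = int((is_drug & ~is_event).sum())
    c = int((~is_drug & is_event).sum())
    d = int(len(pairs) - a - b - c)
    return ContingencyTable(a, b, c, d)


def build_all_contingency(pairs: pd.DataFrame, min_a: int = 0) -> pd.DataFrame:
    """2x2 tables for every observed (drug, event) with ``a >= min_a``.

    Returns a frame with columns ``drug, event, a, b, c, d``, sorted by
    (drug, event) for determinism.
    """
    if min_a < 0:
        raise ValueError("min_a must be >= 0")
    n = len(pairs)
    a = (
        pairs.groupby(["atc_code", "event_pt"], sort=True)
        .size()
        .rename("a")
        .reset_index()
    )
    drug_totals = pairs.groupby("atc_code").size()
    event_totals = pairs.groupby("event_pt").size()
    a["b"] = a["atc_code"].map(drug_totals) - a["a"]
    a["c"] = a["event_pt"].map(event_totals) - a["a"]
    a["d"] = n - a["a"] - a["b"] - a["c"]
    a = a.rename(columns={"atc_code": "drug", "event_pt": "event"})
    a = a[a["a"] >= min_a].reset_index(drop=True)
    return a[["drug", "event", "a", "b", "c", "d"]]


def table_from_row(row) -> ContingencyTable:
    """Build a :class:`ContingencyTable` from one ``build_all_contingency`` row."""
    return ContingencyTable(int(row["a"]), int(row["b"]), int(row["c"]), int(row["d"]))
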