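"""Signal calls from disproportionality estimates, and label expectedness.

A (drug, event) is a *signal* when all three disproportionality criteria
hold simultaneously:

* PRR criterion:  PRR >= 2  and  chi-square >= 4  and  n >= 3,
* ROR criterion:  ROR >= 2  and  chi-square >= 4  and  n >= 3,
* IC criterion:   the 95% interval's lower bound is strictly > 0.

Signals are then compared with the drug's approved label: a signal whose
event term appears among the labeled terms is *expected*, otherwise
*unexpected*; drugs absent from the label reference are flagged
``unknown_drug``. Term matching is exact on canonicalized strings
(case-folded, whitespace-collapsed) — no synonym or hierarchy expansion.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from pvsignal.disproportionality import DisproportionalityResult, ScreenResults


class Expectedness(str, Enum):
    EXPECTED = "expected"
    UNEXPECTED = "unexpected"
    UNKNOWN_DRUG = "unknown_drug"


@dataclass(frozen=True)
class SignalCriteria:
    """Thresholds of the triple signal criterion.

    PRR/ROR/n use >= per the usual convention; the IC lower bound uses a
    strict inequality (> ``ic_lower_min``).
    """

    prr_min: float = 2.0
    ror_min: float = 2.0
    chi2_min: float = 4.0
    n_min: int = 3
    ic_lower_min: float = 0.0

    def __post_init__(self) -> None:
        if self.n_min < 0:
            raise ValueError("n_min must be >= 0")


@dataclass
class SignalDecision:
    """Per-(drug, event) criterion flags and the conjunction signal call."""

    drug: str
    event: str
    n_cases: int
    prr_criterion: bool
    ror_criterion: bool
    ic_criterion: bool
    is_signal: bool
    expectedness: Expectedness | None = None


def evaluate_criteria(
    result: DisproportionalityResult, criteria: SignalCriteria | None = None
) -> SignalDecision:
    """Apply the triple criterion to one disproportionality result."""
    criteria = criteria or SignalCriteria()
    base = result.chi2 >= criteria.chi2_min and result.n_cases >= criteria.n_min
    prr_ok = base and result.prr >= criteria.prr_min
    ror_ok = base and result.ror >= criteria.ror_min
    ic_ok = result.ic_ci_low > criteria.ic_lower_min
    return SignalDecision(
        drug=result.drug,
        event=result.event,
        n_cases=result.n_cases,
        prr_criterion=prr_ok,
        ror_criterion=ror_ok,
        ic_criterion=ic_ok,
        is_signal=prr_ok and ror_ok and ic_ok,
    )


def evaluate_all(
    results: ScreenResults | Iterable[DisproportionalityResult],
    criteria: SignalCriteria | None = None,
) -> list[SignalDecision]:
    return [evaluate_criteria(r, criteria) for r in results]


_WS = re.compile(r"\s+")


def canonicalize_term(term: str) -> str:
    return _WS.sub(" ", term.strip().casefold())


@dataclass
class LabelReference:
    """Drug -> set of labeled adverse-event preferred terms, per jurisdiction."""

    jurisdiction: str
    entries: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = {
            drug: {canonicalize_term(t) for t in terms}
            for drug, terms in self.entries.items()
        }

    def is_labeled(self, drug: str, term: str) -> bool | None:
        """True/False if the drug is known; None for an unknown drug."""
        if drug not in self.entries:
            return None
        return canonicalize_term(term) in self.entries[drug]

    @classmethod
    def from_json(cls, path: str | Path) -> "LabelReference":
        payload = json.loads(Path(path).read_text())
        return cls(jurisdiction=payload["jurisdiction"], entries={
            drug: set(terms) for drug, terms in payload["drugs"].items()
        })

    @classmethod
    def packaged(cls, jurisdiction: str) -> "LabelReference":
        """Load the packaged synthetic anti-VEGF label file ('KR' or 'US').

        These fixtures list only the handful of event terms needed by the
        worked example; they are synthetic stand-ins, not authoritative
        label extracts.
        """
        name = f"labels_{jurisdiction.lower()}_synthetic.json"
        with resources.files("pvsignal.data").joinpath(name).open() as fh:
            payload = json.load(fh)
        return cls(jurisdiction=payload["jurisdiction"], entries={
            drug: set(terms) for drug, terms in payload["drugs"].items()
        })

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "jurisdiction": self.jurisdiction,
            "drugs": {d: sorted(t) for d, t in self.entries.items()},
        }, indent=2) + "\n")


def classify_expectedness(
    decisions: Iterable[SignalDecision], labels: LabelReference
) -> list[SignalDecision]:
    """Set ``expectedness`` on every signal; non-signals pass through unset."""
    out = []
    for dec in decisions:
        if dec.is_signal:
            labeled = labels.is_labeled(dec.drug, dec.event)
            if labeled is None:
                dec.expectedness = Expectedness.UNKNOWN_DRUG
            elif labeled:
                dec.expectedness = Expectedness.EXPECTED
            else:
                dec.expectedness = Expectedness.UNEXPECTED
        out.append(dec)
    return out


def decisions_frame(decisions: Iterable[SignalDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                d.drug, d.event, d.n_cases, d.prr_criterion, d.ror_criterion,
                d.ic_criterion, d.is_signal,
                d.expectedness.value if d.expectedness else "",
            )
            for d in decisions
        ],
        columns=[
            "drug", "event", "n", "prr_criterion", "ror_criterion",
            "ic_criterion", "is_signal", "expectedness",
        ],
    )
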