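"""Sex- and age-adjusted reporting odds ratios by case/non-case logistic regression.

The analysis unit is the *report*: the outcome is "the report mentions the
target event", the exposure is "the report mentions the target drug (as a
suspected drug)", and sex plus the four age strata enter as covariates.
``exp(beta_exposure)`` is then the adjusted reporting odds ratio. This is
the standard case/non-case design; modelling at report rather than pair
level avoids within-report pseudo-replication.

The maximum-likelihood fit is iteratively reweighted least squares
(Newton scoring on the canonical-link binomial, which is IRLS) with
convergence when the maximum absolute coefficient change drops below 1e-8,
capped at 50 iterations; Wald 95% CIs are ``exp(beta +- 1.96 SE)``.
Separation or non-convergence is reported via ``converged=False`` and the
diagnostics — never silently "fixed".
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from pvsignal.types import AgeGroup, ReportSet, Sex

_Z95 = 1.959963984540054

AGE_ORDER = [AgeGroup.LT20, AgeGroup.A20_39, AgeGroup.A40_59, AgeGroup.GE60]


@dataclass
class CaseNonCaseDesign:
    """Report-level design matrix for one (drug, event) adjusted OR.

    ``frame`` has one row per retained report with columns ``outcome``,
    ``exposure``, ``sex_male`` and one dummy per non-reference, non-empty
    age group; ``age_reference`` is the youngest non-empty group. Degenerate
    designs (single outcome or exposure class) are flagged, not errors.
    """

    drug: str
    event: str
    frame: pd.DataFrame
    age_reference: str
    dropped_age_levels: list[str] = field(default_factory=list)

    @property
    def degenerate(self) -> bool:
        return (
            self.frame["outcome"].nunique() < 2 or self.frame["exposure"].nunique() < 2
        )

    def covariate_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("outcome", "exposure")]


def build_design(reports: ReportSet, drug: str, event: str) -> CaseNonCaseDesign:
    """Derive outcome/exposure flags and covariate dummies from reports.

    Reports with missing sex or age are not usable as covariate rows and
    are omitted (the standard inclusion filters remove them anyway). Row
    order follows the report order. Age enters as categorical strata with
    the youngest non-empty group as reference; empty levels are dropped
    with a warning.
    """
    rows = []
    for r in reports:
        group = r.age_group
        if r.sex == Sex.MISSING or group is None:
            continue
        rows.append(
            (
                int(event in r.events),
                int(r.has_drug(drug, suspected_only=True)),
                int(r.sex == Sex.MALE),
                group.value,
            )
        )
    df = pd.DataFrame(rows, columns=["outcome", "exposure", "sex_male", "age_group"])
    present = [g.value for g in AGE_ORDER if g.value in set(df["age_group"])]
    dropped = [g.value for g in AGE_ORDER if g.value not in present]
    if dropped:
        warnings.warn(f"empty age levels dropped from design: {dropped}", stacklevel=2)
    reference = present[0] if present else ""
    for level in present[1:]:
        df[f"age_{level}"] = (df["age_group"] == level).astype(int)
    df = df.drop(columns=["age_group"])
    return CaseNonCaseDesign(
        drug=drug, event=event, frame=df, age_reference=reference,
        dropped_age_levels=dropped,
    )


@dataclass
class AdjustedORResults:
    """Adjusted reporting odds ratio for one (drug, event)."""

    drug: str
    event: str
    or_adjusted: float
    ci_low: float
    ci_high: float
    params: dict[str, float]
    bse: dict[str, float]
    converged: bool
    n_used: int
    age_reference: str
    message: str = ""

    def summary(self) -> str:
        lines = [
            f"Case/non-case logistic fit: drug={self.drug} event={self.event}",
            f"n = {self.n_used}, converged = {self.converged}"
            + (f" ({self.message})" if self.message else ""),
            f"adjusted OR = {self.or_adjusted:.3f} "
            f"(95% CI {self.ci_low:.3f}-{self.ci_high:.3f}), "
            f"age reference = {self.age_reference or 'n/a'}",
            f"{'term':<14}{'coef':>10}{'SE':>10}",
        ]
        for name, b in self.params.items():
            lines.append(f"{name:<14}{b:>10.4f}{self.bse.get(name, float('nan')):>10.4f}")
        return "\n".join(lines)

    def coefficients_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "drug": self.drug, "event": self.event,
            "params": self.params, "bse": self.bse,
            "converged": self.converged, "n_used": self.n_used,
            "age_reference": self.age_reference,
        }, indent=2) + "\n")


class CaseNonCaseLogit:
    """Model object wrapping design construction and the IRLS fit."""

    def __init__(self, design: CaseNonCaseDesign):
        self.design = design

    @classmethod
    def from_reports(cls, reports: ReportSet, drug: str, event: str) -> "CaseNonCaseLogit":
        return cls(build_design(reports, drug, event))

    def fit(self, maxiter: int = 50, tol: float = 1e-8) -> AdjustedORResults:
        d = self.design
        df = d.frame
        y = df["outcome"].to_numpy(dtype=float)
        # constant covariates carry no information and break the design rank
        covs = [c for c in d.covariate_columns() if df[c].nunique() > 1]
        xcols = ["exposure"] + covs
        X = sm.add_constant(df[xcols].to_numpy(dtype=float), has_constant="add")
        names = ["const"] + xcols
        message = ""
        if d.degenerate:
            nan = float("nan")
            return AdjustedORResults(
                d.drug, d.event, nan, nan, nan, {}, {}, False, len(df),
                d.age_reference, message="degenerate design: single outcome or exposure class",
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, X, family=sm.families.Binomial())
            res = model.fit(maxiter=maxiter, tol=tol, tol_criterion="params")
        params = np.asarray(res.params, dtype=float)
        bse = np.asarray(res.bse, dtype=float)
        converged = bool(getattr(res, "converged", True))
        # crude separation diagnostic: runaway coefficient or exploding SE
        if not np.all(np.isfinite(bse)) or np.max(np.abs(params)) > 15:
            converged = False
            message = "possible separation: runaway coefficient or non-finite SE"
        elif not converged:
            message = f"IRLS did not converge within {maxiter} iterations"
        i = names.index("exposure")
        beta, se = params[i], bse[i]
        return AdjustedORResults(
            drug=d.drug,
            event=d.event,
            or_adjusted=float(np.exp(beta)),
            ci_low=float(np.exp(beta - _Z95 * se)),
            ci_high=float(np.exp(beta + _Z95 * se)),
            params=dict(zip(names, params.tolist())),
            bse=dict(zip(names, bse.tolist())),
            converged=converged,
            n_used=len(df),
            age_reference=d.age_reference,
            message=message,
        )


def fit_logistic(design: CaseNonCaseDesign, maxiter: int = 50, tol: float = 1e-8) -> AdjustedORResults:
    """Fit the case/non-case logistic model for one design."""
    return CaseNonCaseLogit(design).fit(maxiter=maxiter, tol=tol)


def adjusted_screen(
    reports: ReportSet, pairs_of_interest: Sequence[tuple[str, str]]
) -> list[AdjustedORResults]:
    """Adjusted OR for each (drug, event) of interest; failures reported per pair."""
    return [
        CaseNonCaseLogit.from_reports(reports, drug, event).fit()
        for drug, event in pairs_of_interest
    ]


def results_frame(results: Iterable[AdjustedORResults]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.drug, r.event, r.or_adjusted, r.ci_low, r.ci_high, r.converged, r.n_used)
            for r in results
        ],
        columns=["drug", "event", "or", "ci_l", "ci_u", "converged", "n_used"],
    )
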