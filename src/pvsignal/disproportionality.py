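"""Disproportionality statistics on 2x2 drug-event tables.

For a table (a, b, c, d) — a = target drug with target event, b = target
drug with other events, c = other drugs with target event, d = the rest —
the module computes:

PRR
    proportional reporting ratio ``(a/(a+b)) / (c/(c+d))`` with the
    log-scale Wald 95% CI, SE = sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)).
ROR
    reporting odds ratio ``(a*d)/(b*c)`` with log-scale Wald 95% CI,
    SE = sqrt(1/a + 1/b + 1/c + 1/d).
chi-square
    Pearson chi-square of the 2x2, Yates-corrected by default (the
    classical companion to the PRR signal criterion).
IC
    the BCPNN information component, a shrunk log2 observed/expected
    co-reporting measure: ``log2((a + s) / (E + s))`` with expected count
    ``E = (a+b)(a+c)/n`` and shrinkage ``s`` (default 0.5). Its 95%
    credible interval comes from a seeded Monte-Carlo draw of the cell
    probabilities from a Dirichlet(cells + 0.5) posterior, recomputing the
    IC per draw and taking empirical quantiles.

Zero cells: the Haldane-Anscombe correction (+0.5 on all four cells) is
applied — and flagged via ``corrected`` — before the ROR, and before the
PRR confidence interval, whenever any cell is zero.

The screening surface is a Model/Results pair: build a
:class:`DisproportionalityScreen` from a pair set or a table collection,
``fit()`` it, and read estimates off the returned :class:`ScreenResults`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from pvsignal.pairs import ContingencyTable, build_all_contingency, table_from_row

#: Default seed for the IC Monte-Carlo interval; override per call.
DEFAULT_MC_SEED = 1234

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class IcPrior:
    """Shrinkage and Monte-Carlo settings for the information component.

    ``shrinkage`` is the pseudo-count added to both the observed and the
    expected count in the point estimate; ``dirichlet_pseudo`` is the
    pseudo-count added to each cell of the Dirichlet posterior used for the
    credible interval. The 0.5/0.5 default is a flat-prior shrinkage
    estimator; alternative BCPNN parameterizations are configured here.
    """

    shrinkage: float = 0.5
    dirichlet_pseudo: float = 0.5
    n_mc: int = 100_000
    credible_level: float = 0.95
    mc_se_tolerance: float = 0.05

    def __post_init__(self) -> None:
        if self.shrinkage <= 0 or self.dirichlet_pseudo <= 0:
            raise ValueError("pseudo-counts must be positive")
        if not 0 < self.credible_level < 1:
            raise ValueError("credible_level must be in (0, 1)")
        if self.n_mc < 100:
            raise ValueError("n_mc too small for a quantile interval")


class Estimate(NamedTuple):
    value: float
    ci_low: float
    ci_high: float
    corrected: bool


class IcEstimate(NamedTuple):
    value: float
    ci_low: float
    ci_high: float
    mc_se_low: float


def _corrected_cells(table: ContingencyTable) -> tuple[float, float, float, float, bool]:
    cells = table.cells()
    if min(cells) == 0:
        return tuple(x + 0.5 for x in cells) + (True,)  # type: ignore[return-value]
    return tuple(float(x) for x in cells) + (False,)  # type: ignore[return-value]


def compute_prr(table: ContingencyTable, zero_correction: bool = True) -> Estimate:
    """Proportional reporting ratio with its 95% CI.

    With ``zero_correction`` disabled, a zero a-cell yields ``prr=0`` with
    an undefined (NaN) interval rather than an error.
    """
    a, b, c, d = table.cells()
    if not zero_correction:
        if a + b == 0 or c + d == 0 or c == 0:
            raise ZeroDivisionError("empty margin in PRR without zero correction")
        prr = (a / (a + b)) / (c / (c + d))
        if a == 0:
            return Estimate(0.0, math.nan, math.nan, False)
        se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
        return Estimate(prr, prr * math.exp(-_Z95 * se), prr * math.exp(_Z95 * se), False)
    af, bf, cf, df, corrected = _corrected_cells(table)
    prr = (af / (af + bf)) / (cf / (cf + df))
    se = math.sqrt(1 / af - 1 / (af + bf) + 1 / cf - 1 / (cf + df))
    return Estimate(
        prr, prr * math.exp(-_Z95 * se), prr * math.exp(_Z95 * se), corrected
    )


def compute_ror(table: ContingencyTable, zero_correction: bool = True) -> Estimate:
    """Reporting odds ratio (a*d)/(b*c) with its 95% CI."""
    if not zero_correction and min(table.cells()) == 0:
        raise ZeroDivisionError("zero cell in ROR without zero correction")
    af, bf, cf, df, corrected = _corrected_cells(table)
    ror = (af * df) / (bf * cf)
    se = math.sqrt(1 / af + 1 / bf + 1 / cf + 1 / df)
    return Estimate(
        ror, ror * math.exp(-_Z95 * se), ror * math.exp(_Z95 * se), corrected
    )


def compute_chi2(table: ContingencyTable, yates: bool = True) -> float:
    """Pearson chi-square of the 2x2; Yates continuity correction by default.

    A zero margin makes the statistic undefined; by convention 0 is
    returned with a warning (such a pair can never meet the chi-square
    signal criterion anyway).
    """
    a, b, c, d = table.cells()
    if table.n_total == 0 or a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        warnings.warn("chi-square undefined for a zero margin; returning 0", stacklevel=2)
        return 0.0
    stat, _, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=yates)
    return float(stat)


def compute_ic(
    table: ContingencyTable,
    prior: IcPrior | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> IcEstimate:
    """Information component with a Monte-Carlo credible interval.

    Point estimate: ``log2((a + s)/(E + s))`` with E the expected a-cell
    under independence. Interval: cell probabilities drawn from
    Dirichlet(cells + pseudo), the IC ``log2(p_a / (p_drug * p_event))``
    recomputed per draw, and empirical quantiles taken. Reproducible given
    ``seed`` (or an explicit generator). A warning is raised when the
    Monte-Carlo standard error of the lower quantile exceeds the prior's
    tolerance.
    """
    prior = prior or IcPrior()
    if table.n_total == 0:
        raise ValueError("IC undefined for an empty table")
    if rng is None:
        rng = np.random.default_rng(DEFAULT_MC_SEED if seed is None else seed)
    a = table.a
    expected = table.expected_a
    ic = math.log2((a + prior.shrinkage) / (expected + prior.shrinkage))

    alpha = np.asarray(table.cells(), dtype=float) + prior.dirichlet_pseudo
    draws = rng.dirichlet(alpha, size=prior.n_mc)
    pa = draws[:, 0]
    p_drug = draws[:, 0] + draws[:, 1]
    p_event = draws[:, 0] + draws[:, 2]
    ic_draws = np.log2(pa / (p_drug * p_event))
    lo_q = (1 - prior.credible_level) / 2
    ci_low, se_low = _quantile_with_se(ic_draws, lo_q)
    ci_high, _ = _quantile_with_se(ic_draws, 1 - lo_q)
    if se_low > prior.mc_se_tolerance:
        warnings.warn(
            f"IC interval Monte-Carlo SE {se_low:.3g} exceeds tolerance "
            f"{prior.mc_se_tolerance}; increase n_mc",
            stacklevel=2,
        )
    return IcEstimate(ic, float(ci_low), float(ci_high), float(se_low))


def _quantile_with_se(draws: np.ndarray, q: float) -> tuple[float, float]:
    """Empirical quantile and an order-statistic estimate of its MC SE."""
    x = np.sort(draws)
    n = x.size
    value = float(np.quantile(x, q))
    k = int(round(q * (n - 1)))
    m = max(1, int(round(math.sqrt(n * q * (1 - q)))))
    lo, hi = max(0, k - m), min(n - 1, k + m)
    # density estimate from the spacing of +-m order statistics
    spacing = x[hi] - x[lo]
    if spacing <= 0:
        return value, 0.0
    density = (hi - lo) / (n * spacing)
    se = math.sqrt(q * (1 - q) / n) / density
    return value, se


@dataclass
class DisproportionalityResult:
    """All disproportionality estimates for one (drug, event)."""

    drug: str
    event: str
    n_cases: int
    prr: float
    prr_ci_low: float
    prr_ci_high: float
    ror: float
    ror_ci_low: float
    ror_ci_high: float
    chi2: float
    ic: float
    ic_ci_low: float
    ic_ci_high: float
    corrected: bool


RESULT_COLUMNS = [
    "drug", "event", "n", "prr", "prr_l", "prr_u",
    "ror", "ror_l", "ror_u", "chi2", "ic", "ic_l", "ic_u", "corrected",
]


class ScreenResults:
    """Fitted disproportionality estimates for a collection of tables."""

    def __init__(self, results: list[DisproportionalityResult], model: "DisproportionalityScreen"):
        self.results = results
        self.model = model
        self.frame = pd.DataFrame(
            [
                (
                    r.drug, r.event, r.n_cases, r.prr, r.prr_ci_low, r.prr_ci_high,
                    r.ror, r.ror_ci_low, r.ror_ci_high, r.chi2,
                    r.ic, r.ic_ci_low, r.ic_ci_high, r.corrected,
                )
                for r in results
            ],
            columns=RESULT_COLUMNS,
        )

    def __len__(self) -> int:
        return len(self.results)

    def __iter__(self):
        return iter(self.results)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def summary(self, top: int = 20) -> str:
        """Human-readable table of the strongest associations by IC lower bound."""
        df = self.frame.sort_values("ic_l", ascending=False).head(top)
        lines = [
            "Disproportionality screen"
            f" ({len(self)} drug-event tables, yates={self.model.yates},"
            f" n_mc={self.model.prior.n_mc}, seed={self.model.seed})",
            f"{'drug':<12}{'event':<26}{'n':>5}{'PRR':>8}{'ROR':>8}"
            f"{'chi2':>8}{'IC':>7}{'IC025':>7}",
        ]
        for _, r in df.iterrows():
            lines.append(
                f"{r['drug']:<12}{r['event']:<26}{r['n']:>5d}{r['prr']:>8.2f}"
                f"{r['ror']:>8.2f}{r['chi2']:>8.2f}{r['ic']:>7.2f}{r['ic_l']:>7.2f}"
            )
        return "\n".join(lines)


class DisproportionalityScreen:
    """Model object: disproportionality statistics over many 2x2 tables.

    Parameters
    ----------
    tables
        Frame with columns ``drug, event, a, b, c, d`` (as produced by
        :func:`pvsignal.pairs.build_all_contingency`).
    yates
        Continuity-correct the chi-square (default True).
    prior
        IC shrinkage / Monte-Carlo settings.
    seed
        Seed for the IC credible intervals; fit is deterministic given it.
    """

    def __init__(
        self,
        tables: pd.DataFrame,
        yates: bool = True,
        prior: IcPrior | None = None,
        seed: int = DEFAULT_MC_SEED,
        zero_correction: bool = True,
    ):
        self.tables = tables.reset_index(drop=True)
        self.yates = yates
        self.prior = prior or IcPrior()
        self.seed = seed
        self.zero_correction = zero_correction

    @classmethod
    def from_pairs(cls, pairs: pd.DataFrame, min_a: int = 1, **kwargs) -> "DisproportionalityScreen":
        return cls(build_all_contingency(pairs, min_a=min_a), **kwargs)

    def fit(self) -> ScreenResults:
        rng = np.random.default_rng(self.seed)
        results: list[DisproportionalityResult] = []
        for _, row in self.tables.iterrows():
            table = table_from_row(row)
            prr = compute_prr(table, zero_correction=self.zero_correction)
            ror = compute_ror(table, zero_correction=self.zero_correction)
            chi2 = compute_chi2(table, yates=self.yates)
            ic = compute_ic(table, prior=self.prior, rng=rng)
            results.append(
                DisproportionalityResult(
                    drug=row["drug"],
                    event=row["event"],
                    n_cases=table.a,
                    prr=prr.value, prr_ci_low=prr.ci_low, prr_ci_high=prr.ci_high,
                    ror=ror.value, ror_ci_low=ror.ci_low, ror_ci_high=ror.ci_high,
                    chi2=chi2,
                    ic=ic.value, ic_ci_low=ic.ci_low, ic_ci_high=ic.ci_high,
                    corrected=prr.corrected or ror.corrected,
                )
            )
        return ScreenResults(results, self)


def screen(
    tables: pd.DataFrame,
    prior: IcPrior | None = None,
    yates: bool = True,
    seed: int = DEFAULT_MC_SEED,
) -> ScreenResults:
    """Functional wrapper over :class:`DisproportionalityScreen`."""
    return DisproportionalityScreen(tables, yates=yates, prior=prior, seed=seed).fit()
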