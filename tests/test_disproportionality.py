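"""PRR/ROR/chi-square/IC against independent brute-force oracles."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal.disproportionality import (
    IcPrior,
    compute_chi2,
    compute_ic,
    compute_prr,
    compute_ror,
    screen,
)
from pvsignal.pairs import ContingencyTable

# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)
# ---------------------------------------------------------------------------


def oracle_prr(a, b, c, d):
    return (a / (a + b)) / (c / (c + d))


def oracle_ror(a, b, c, d):
    return (a * d) / (b * c)


def oracle_log_se_prr(a, b, c, d):
    return math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))


def oracle_log_se_ror(a, b, c, d):
    return math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)


def oracle_chi2(a, b, c, d, yates):
    n = a + b + c + d
    obs = np.array([[a, b], [c, d]], dtype=float)
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            diff = abs(obs[i, j] - e)
            if yates:
                diff = max(0.0, diff - 0.5)
            stat += diff**2 / e
    return stat


def positive_tables(rng, n):
    """Random all-positive 2x2 tables of varied magnitude."""
    for _ in range(n):
        yield ContingencyTable(*(int(x) for x in rng.integers(1, 500, size=4)))


def test_prr_one_when_row_rates_equal():
    est = compute_prr(ContingencyTable(5, 45, 10, 90))
    assert est.value == pytest.approx(1.0)
    assert est.ci_low < 1.0 < est.ci_high


def test_prr_hand_value():
    # (10/100)/(10/900) = 9
    est = compute_prr(ContingencyTable(10, 90, 10, 890))
    assert est.value == pytest.approx(9.0, abs=1e-12)
    assert not est.corrected


def test_ror_hand_value():
    # (10*890)/(90*10)
    est = compute_ror(ContingencyTable(10, 90, 10, 890))
    assert est.value == pytest.approx(8900 / 900, abs=1e-12)


def test_uniform_table_ror_ci_contains_one():
    est = compute_ror(ContingencyTable(5, 5, 5, 5))
    assert est.value == pytest.approx(1.0)
    assert est.ci_low < 1.0 < est.ci_high


def test_zero_cell_triggers_haldane_correction():
    est = compute_prr(ContingencyTable(3, 0, 5, 7))
    assert est.corrected
    est = compute_ror(ContingencyTable(3, 2, 0, 7))
    assert est.corrected
    af, bf, cf, df = 3.5, 2.5, 0.5, 7.5
    assert est.value == pytest.approx(af * df / (bf * cf))


def test_estimates_and_cis_match_oracles_on_random_tables():
    rng = np.random.default_rng(12345)
    z = 1.959963984540054
    for t in positive_tables(rng, 1000):
        a, b, c, d = t.cells()
        prr = compute_prr(t)
        assert prr.value == pytest.approx(oracle_prr(a, b, c, d), abs=1e-9)
        se = oracle_log_se_prr(a, b, c, d)
        assert math.log(prr.ci_high / prr.value) / z == pytest.approx(se, abs=1e-9)
        ror = compute_ror(t)
        assert ror.value == pytest.approx(oracle_ror(a, b, c, d), abs=1e-9)
        se = oracle_log_se_ror(a, b, c, d)
        assert math.log(ror.value / ror.ci_low) / z == pytest.approx(se, abs=1e-9)
        for yates in (False, True):
            assert compute_chi2(t, yates=yates) == pytest.approx(
                oracle_chi2(a, b, c, d, yates), abs=1e-9
            )


def test_yates_correction_never_increases_chi2():
    t = ContingencyTable(10, 90, 10, 890)
    assert compute_chi2(t, yates=True) <= compute_chi2(t, yates=False)


def test_chi2_zero_on_proportional_rows():
    t = ContingencyTable(10, 90, 30, 270)
    assert compute_chi2(t, yates=False) == pytest.approx(0.0, abs=1e-12)
    assert compute_chi2(t, yates=True) == pytest.approx(0.0, abs=1e-12)


def test_chi2_zero_margin_convention():
    with pytest.warns(UserWarning, match="zero margin"):
        assert compute_chi2(ContingencyTable(0, 0, 5, 5)) == 0.0


def test_ic_hand_value():
    # E = 100*20/1000 = 2; ic = log2(10.5/2.5)
    est = compute_ic(ContingencyTable(10, 90, 10, 890), seed=1)
    assert est.value == pytest.approx(math.log2(10.5 / 2.5), abs=1e-12)
    assert est.value == pytest.approx(2.070, abs=0.005)
    assert est.ci_low < est.value < est.ci_high


def test_ic_near_zero_under_independence():
    est = compute_ic(ContingencyTable(100, 900, 900, 8100), seed=1)
    assert abs(est.value) < 0.05
    assert est.ci_low < 0 < est.ci_high


def test_ic_negative_when_observed_deficit():
    est = compute_ic(ContingencyTable(0, 100, 100, 800), seed=1)
    assert est.value < 0


def test_ic_interval_matches_independent_sampler():
    """MC credible bounds agree with a second, independently coded sampler."""
    t = ContingencyTable(10, 90, 10, 890)
    prior = IcPrior(n_mc=100_000)
    est = compute_ic(t, prior=prior, seed=2)
    # independent route: four gamma draws, explicit normalization
    rng = np.random.default_rng(987654321)
    g = rng.standard_gamma(
        np.asarray(t.cells(), dtype=float) + 0.5, size=(100_000, 4)
    )
    p = g / g.sum(axis=1, keepdims=True)
    ic = np.log2(p[:, 0] / ((p[:, 0] + p[:, 1]) * (p[:, 0] + p[:, 2])))
    lo, hi = np.quantile(ic, [0.025, 0.975])
    assert est.ci_low == pytest.approx(lo, abs=3 * max(est.mc_se_low, 1e-3))
    assert est.ci_high == pytest.approx(hi, abs=3 * max(est.mc_se_low, 1e-3))


def test_ic_interval_converges_with_more_draws():
    t = ContingencyTable(25, 200, 150, 3000)
    small = compute_ic(t, prior=IcPrior(n_mc=20_000), seed=3)
    big = compute_ic(t, prior=IcPrior(n_mc=40_000), seed=4)
    assert abs(small.ci_low - big.ci_low) < 3 * small.mc_se_low + 1e-9


def test_ic_empty_table_errors():
    with pytest.raises(ValueError):
        compute_ic(ContingencyTable(0, 0, 0, 0), seed=1)


def test_ic_warns_when_mc_error_large():
    with pytest.warns(UserWarning, match="Monte-Carlo SE"):
        compute_ic(ContingencyTable(1, 3, 2, 5), prior=IcPrior(n_mc=200), seed=5)


@given(
    st.tuples(
        st.integers(1, 300), st.integers(1, 300),
        st.integers(1, 300), st.integers(1, 300),
    )
)
@settings(max_examples=200, derandomize=True)
def test_ror_dominates_prr_iff_algebraic_condition(cells):
    a, b, c, d = cells
    t = ContingencyTable(a, b, c, d)
    ror = compute_ror(t).value
    prr = compute_prr(t).value
    if d * (a + b) > b * (c + d):
        assert ror >= prr - 1e-12
    elif d * (a + b) < b * (c + d):
        assert ror <= prr + 1e-12
    else:
        assert ror == pytest.approx(prr)


@given(st.integers(2, 10))
@settings(max_examples=20, derandomize=True)
def test_scaling_cells_narrows_wald_intervals(k):
    base = ContingencyTable(8, 40, 20, 400)
    scaled = ContingencyTable(8 * k, 40 * k, 20 * k, 400 * k)
    for f in (compute_prr, compute_ror):
        wide = f(base)
        narrow = f(scaled)
        assert narrow.value == pytest.approx(wide.value)
        assert (narrow.ci_high / narrow.ci_low) < (wide.ci_high / wide.ci_low)


def test_screen_is_empty_on_empty_input():
    import pandas as pd

    res = screen(pd.DataFrame(columns=["drug", "event", "a", "b", "c", "d"]))
    assert len(res) == 0 and res.frame.empty


def test_screen_singleton_matches_per_statistic_ops():
    import pandas as pd

    tables = pd.DataFrame(
        [("X", "Y", 10, 90, 10, 890)], columns=["drug", "event", "a", "b", "c", "d"]
    )
    res = screen(tables, prior=IcPrior(n_mc=50_000), seed=9)
    r = res.results[0]
    t = ContingencyTable(10, 90, 10, 890)
    assert r.n_cases == 10
    assert r.prr == pytest.approx(compute_prr(t).value)
    assert r.ror == pytest.approx(compute_ror(t).value)
    assert r.chi2 == pytest.approx(compute_chi2(t, yates=True))
    assert r.ic == pytest.approx(compute_ic(t, seed=0).value)


def test_screen_deterministic_given_seed():
    import pandas as pd

    tables = pd.DataFrame(
        [("X", "Y", 10, 90, 10, 890), ("X", "Z", 4, 96, 40, 860)],
        columns=["drug", "event", "a", "b", "c", "d"],
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r1 = screen(tables, prior=IcPrior(n_mc=20_000), seed=11)
        r2 = screen(tables, prior=IcPrior(n_mc=20_000), seed=11)
    assert r1.frame.equals(r2.frame)
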