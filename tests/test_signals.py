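"""Triple signal criterion and label-expectedness classification."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pvsignal as pv
from pvsignal.disproportionality import DisproportionalityResult
from pvsignal.signals import (
    Expectedness,
    LabelReference,
    SignalCriteria,
    classify_expectedness,
    evaluate_all,
    evaluate_criteria,
)


def _result(**kw):
    base = dict(
        drug="X", event="Y", n_cases=10,
        prr=9.0, prr_ci_low=4.0, prr_ci_high=20.0,
        ror=9.9, ror_ci_low=4.4, ror_ci_high=22.0,
        chi2=70.0, ic=2.07, ic_ci_low=1.2, ic_ci_high=2.7,
        corrected=False,
    )
    base.update(kw)
    return DisproportionalityResult(**base)


def test_fewer_than_three_cases_never_signals():
    dec = evaluate_criteria(_result(n_cases=2, prr=50, ror=50, chi2=500, ic_ci_low=3.0))
    assert not dec.prr_criterion and not dec.ror_criterion
    assert not dec.is_signal


def test_strong_table_meets_all_three_criteria():
    dec = evaluate_criteria(_result())
    assert dec.prr_criterion and dec.ror_criterion and dec.ic_criterion
    assert dec.is_signal


def test_independence_table_is_not_a_signal():
    dec = evaluate_criteria(
        _result(prr=1.0, ror=1.0, chi2=0.0, ic=0.0, ic_ci_low=-0.4, ic_ci_high=0.4)
    )
    assert not dec.is_signal


def test_ic_criterion_is_strict_inequality():
    assert not evaluate_criteria(_result(ic_ci_low=0.0)).ic_criterion
    assert evaluate_criteria(_result(ic_ci_low=1e-9)).ic_criterion


def test_signal_is_conjunction_of_criteria():
    for missing in ("prr", "ror", "chi2", "ic_ci_low"):
        weak = {"prr": 1.5, "ror": 1.5, "chi2": 2.0, "ic_ci_low": -0.1}
        dec = evaluate_criteria(_result(**{missing: weak[missing]}))
        assert dec.is_signal == (dec.prr_criterion and dec.ror_criterion and dec.ic_criterion)
        assert not dec.is_signal


@given(
    prr_min=st.floats(0.5, 10), ror_min=st.floats(0.5, 10),
    chi2_min=st.floats(0, 20), n_min=st.integers(0, 12),
    ic_lower_min=st.floats(-1, 2),
    bump=st.floats(0, 5),
)
@settings(max_examples=200, derandomize=True)
def test_raising_any_threshold_never_creates_a_signal(
    prr_min, ror_min, chi2_min, n_min, ic_lower_min, bump
):
    res = _result()
    lo = SignalCriteria(prr_min, ror_min, chi2_min, n_min, ic_lower_min)
    base = evaluate_criteria(res, lo).is_signal
    for f in ("prr_min", "ror_min", "chi2_min", "ic_lower_min"):
        hi = dataclasses.replace(lo, **{f: getattr(lo, f) + bump})
        assert not (evaluate_criteria(res, hi).is_signal and not base)
    hi = dataclasses.replace(lo, n_min=lo.n_min + 1)
    assert not (evaluate_criteria(res, hi).is_signal and not base)


def test_packaged_label_examples():
    kr = LabelReference.packaged("KR")
    # aflibercept conjunctivitis is off-label; ranibizumab medicine
    # ineffective is off-label; endophthalmitis is labeled for both
    assert kr.is_labeled("S01LA05", "conjunctivitis") is False
    assert kr.is_labeled("S01LA04", "medicine ineffective") is False
    assert kr.is_labeled("S01LA05", "endophthalmitis") is True
    assert kr.is_labeled("S01LA04", "Endophthalmitis  ") is True  # canonicalized
    assert kr.is_labeled("UNKNOWN", "rash") is None


def test_expectedness_classification_and_partition(fixture_screen):
    decisions = evaluate_all(fixture_screen)
    decisions = classify_expectedness(decisions, LabelReference.packaged("KR"))
    by_pair = {(d.drug, d.event): d for d in decisions}
    afl_conj = by_pair[("S01LA05", "conjunctivitis")]
    assert afl_conj.is_signal and afl_conj.expectedness == Expectedness.UNEXPECTED
    ran_ineff = by_pair[("S01LA04", "medicine ineffective")]
    assert ran_ineff.is_signal and ran_ineff.expectedness == Expectedness.UNEXPECTED
    # expectedness partitions the signals exactly
    signals = [d for d in decisions if d.is_signal]
    classified = [d for d in signals if d.expectedness is not None]
    assert len(classified) == len(signals)
    n_by_class = {
        cls: sum(1 for d in signals if d.expectedness == cls) for cls in Expectedness
    }
    assert sum(n_by_class.values()) == len(signals)
    # non-signals pass through unclassified
    assert all(d.expectedness is None for d in decisions if not d.is_signal)


def test_worked_example_signal_lists(fixture_screen):
    """The worked example recovers 3 aflibercept and 8 ranibizumab signals."""
    decisions = evaluate_all(fixture_screen)
    afl = sorted(d.event for d in decisions if d.is_signal and d.drug == "S01LA05")
    ran = sorted(d.event for d in decisions if d.is_signal and d.drug == "S01LA04")
    assert afl == ["conjunctivitis", "endophthalmitis", "muscae volitantes"]
    assert ran == sorted([
        "retinal disorder", "medicine ineffective", "endophthalmitis",
        "retinal detachment", "retinal haemorrhage", "vision abnormal",
        "conjunctivitis", "muscae volitantes",
    ])


def test_empty_label_set_makes_every_signal_unexpected():
    labels = LabelReference(jurisdiction="KR", entries={"X": set()})
    decisions = classify_expectedness([evaluate_criteria(_result())], labels)
    assert decisions[0].expectedness == Expectedness.UNEXPECTED


def test_label_reference_roundtrip(tmp_path):
    labels = LabelReference(jurisdiction="US", entries={"X": {"Rash", "Eye  Pain"}})
    path = tmp_path / "labels.json"
    labels.to_json(path)
    back = LabelReference.from_json(path)
    assert back.jurisdiction == "US"
    assert back.is_labeled("X", "eye pain") is True


def test_unknown_drug_flagged():
    labels = LabelReference.packaged("US")
    dec = classify_expectedness([evaluate_criteria(_result(drug="Z99ZZ99"))], labels)
    assert dec[0].expectedness == Expectedness.UNKNOWN_DRUG
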