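"""Seeded synthetic spontaneous-report generators and the worked-example fixture.

Three generators live here:

``generate_reports``
    A configurable ICSR simulator. Drugs are drawn from a weighted
    vocabulary; adverse-event terms are drawn with probability
    proportional to ``baseline weight x lambda(drug, event)``, so the
    ``signal_multipliers`` map injects reporting disproportionality with a
    known strength (lambda = 1 everywhere is exact drug-event
    independence). Contamination knobs plant records that each inclusion
    rule must remove. Identical config + seed gives byte-identical output.

``generate_confounded_reports``
    A case/non-case simulator on the logit scale: exposure probability
    depends on age group, and the outcome follows a logistic model in age,
    sex, and exposure, so the *conditional* odds ratio equals the
    configured value exactly and the adjusted-OR fit has a ground truth to
    recover while the crude OR is biased by design.

``anti_vegf_fixture``
    A fully deterministic raw dataset reconstructing the report-level
    marginals of a published anti-VEGF reporting-pattern study: after the
    standard inclusion filters exactly 103 ranibizumab (ATC S01LA04) and
    32 aflibercept (S01LA05) reports remain, with category counts
    back-calculated from the printed percentages (count =
    round(percent x total / 100), each verified to re-round to the printed
    value under half-up one-decimal rounding). Seven planted contaminant
    records — one per inclusion rule — carry ``planted:<reason>`` note
    tags, and 400 deterministic comparator-drug reports provide the 2x2
    background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from pvsignal.types import (
    AgeGroup,
    Causality,
    DrugEntry,
    IcsrReport,
    Reporter,
    ReportSet,
    ReportType,
    SeriousnessType,
    Sex,
)

RANIBIZUMAB = "S01LA04"
AFLIBERCEPT = "S01LA05"

_AGE_RANGES = {
    AgeGroup.LT20: (1, 19),
    AgeGroup.A20_39: (20, 39),
    AgeGroup.A40_59: (40, 59),
    AgeGroup.GE60: (60, 89),
}

CONTAMINATION_REASONS = (
    "missing_sex",
    "missing_age",
    "missing_event",
    "missing_atc",
    "follow_up",
    "bad_causality",
    "no_suspected",
)


def _default_drug_vocabulary(n: int = 25) -> list[tuple[str, float]]:
    return [(f"A{i:02d}AA{i:02d}", 1.0) for i in range(1, n + 1)]


def _default_event_vocabulary(n: int = 20) -> list[tuple[str, float]]:
    return [(f"event {i:02d}", 1.0) for i in range(1, n + 1)]


@dataclass
class SyntheticConfig:
    """Generative settings for :func:`generate_reports`.

    Defaults describe a mid-sized reporting database slice: 10,000 reports
    over 25 drugs and 20 event terms, mostly single-drug single-event
    reports, ~10% serious, no injected signals and no contamination.
    """

    n_reports: int = 10_000
    drug_vocabulary: list[tuple[str, float]] = field(default_factory=_default_drug_vocabulary)
    event_vocabulary: list[tuple[str, float]] = field(default_factory=_default_event_vocabulary)
    signal_multipliers: dict[tuple[str, str], float] = field(default_factory=dict)
    drugs_per_report: dict[int, float] = field(default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1})
    events_per_report: dict[int, float] = field(default_factory=lambda: {1: 0.6, 2: 0.3, 3: 0.1})
    sex_dist: dict[Sex, float] = field(
        default_factory=lambda: {Sex.MALE: 0.45, Sex.FEMALE: 0.55}
    )
    age_dist: dict[AgeGroup, float] = field(
        default_factory=lambda: {
            AgeGroup.LT20: 0.10, AgeGroup.A20_39: 0.25,
            AgeGroup.A40_59: 0.35, AgeGroup.GE60: 0.30,
        }
    )
    p_serious: float = 0.10
    report_type_dist: dict[ReportType, float] = field(
        default_factory=lambda: {
            ReportType.SPONTANEOUS: 0.60,
            ReportType.POST_MARKETING_SURVEILLANCE: 0.25,
            ReportType.LITERATURE: 0.10,
            ReportType.OTHER: 0.05,
        }
    )
    reporter_dist: dict[Reporter, float] = field(
        default_factory=lambda: {
            Reporter.DOCTOR: 0.45, Reporter.PHARMACIST: 0.20, Reporter.NURSE: 0.20,
            Reporter.CONSUMER: 0.05, Reporter.OTHER: 0.05, Reporter.UNKNOWN: 0.05,
        }
    )
    causality_dist: dict[Causality, float] = field(
        default_factory=lambda: {
            Causality.CERTAIN: 0.10, Causality.PROBABLE: 0.30, Causality.POSSIBLE: 0.60,
        }
    )
    year_range: tuple[int, int] = (2007, 2016)
    contamination: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        for name, vocab in (("drug", self.drug_vocabulary), ("event", self.event_vocabulary)):
            if not vocab:
                raise ValueError(f"{name} vocabulary is empty")
            for code, w in vocab:
                if not (w > 0 and math.isfinite(w)):
                    raise ValueError(f"{name} weight for {code!r} must be positive finite")
        for pair, lam in self.signal_multipliers.items():
            if not (lam > 0 and math.isfinite(lam)):
                raise ValueError(f"signal multiplier for {pair} must be positive finite")
        for name, dist in (
            ("drugs_per_report", self.drugs_per_report),
            ("events_per_report", self.events_per_report),
            ("sex_dist", self.sex_dist),
            ("age_dist", self.age_dist),
            ("report_type_dist", self.report_type_dist),
            ("reporter_dist", self.reporter_dist),
            ("causality_dist", self.causality_dist),
        ):
            total = sum(dist.values())
            if any(p < 0 for p in dist.values()) or abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability distribution (sums to {total})")
        if not 0 <= self.p_serious <= 1:
            raise ValueError("p_serious must be in [0, 1]")
        for reason, rate in self.contamination.items():
            if reason not in CONTAMINATION_REASONS:
                raise ValueError(f"unknown contamination reason {reason!r}")
            if not 0 <= rate <= 1:
                raise ValueError(f"contamination rate for {reason} must be in [0, 1]")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range start must not exceed end")


def _sample_categorical(rng: np.random.Generator, keys: list, probs: np.ndarray):
    return keys[int(rng.choice(len(keys), p=probs))]


def generate_reports(config: SyntheticConfig) -> ReportSet:
    """Sample a :class:`ReportSet` from the configured generative model."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    drug_codes = [c for c, _ in config.drug_vocabulary]
    drug_w = np.array([w for _, w in config.drug_vocabulary], dtype=float)
    drug_p = drug_w / drug_w.sum()
    event_terms = [e for e, _ in config.event_vocabulary]
    event_w = np.array([w for _, w in config.event_vocabulary], dtype=float)
    lam = {pair: m for pair, m in config.signal_multipliers.items()}

    nd_keys = list(config.drugs_per_report)
    nd_p = np.array([config.drugs_per_report[k] for k in nd_keys], dtype=float)
    ne_keys = list(config.events_per_report)
    ne_p = np.array([config.events_per_report[k] for k in ne_keys], dtype=float)
    sex_keys = list(config.sex_dist)
    sex_p = np.array(list(config.sex_dist.values()), dtype=float)
    age_keys = list(config.age_dist)
    age_p = np.array(list(config.age_dist.values()), dtype=float)
    rt_keys = list(config.report_type_dist)
    rt_p = np.array(list(config.report_type_dist.values()), dtype=float)
    rep_keys = list(config.reporter_dist)
    rep_p = np.array(list(config.reporter_dist.values()), dtype=float)
    cau_keys = list(config.causality_dist)
    cau_p = np.array(list(config.causality_dist.values()), dtype=float)
    y0, y1 = config.year_range

    reports: list[IcsrReport] = []
    for i in range(config.n_reports):
        n_drugs = min(_sample_categorical(rng, nd_keys, nd_p), len(drug_codes))
        idx = rng.choice(len(drug_codes), size=n_drugs, replace=False, p=drug_p)
        drugs = [DrugEntry(drug_codes[j], suspected=True) for j in idx]
        # secondary drugs may be concomitant; the first stays suspected
        drugs = [drugs[0]] + [
            DrugEntry(d.atc_code, suspected=bool(rng.random() < 0.8)) for d in drugs[1:]
        ]
        suspected_codes = [d.atc_code for d in drugs if d.suspected]

        w = event_w.copy()
        if lam:
            for k, term in enumerate(event_terms):
                for code in suspected_codes:
                    m = lam.get((code, term))
                    if m is not None:
                        w[k] *= m
        n_events = min(_sample_categorical(rng, ne_keys, ne_p), len(event_terms))
        eidx = rng.choice(len(event_terms), size=n_events, replace=False, p=w / w.sum())
        events = [event_terms[j] for j in eidx]

        serious = bool((rng.random(n_events) < config.p_serious).any())
        stype = (
            (SeriousnessType.HOSPITALIZATION if rng.random() < 0.5
             else SeriousnessType.OTHER_INCLUDING_DEATH)
            if serious else SeriousnessType.NONE
        )
        age_group = _sample_categorical(rng, age_keys, age_p)
        lo, hi = _AGE_RANGES[age_group]
        report = IcsrReport(
            report_id=f"SYN-{i + 1:06d}",
            is_initial=True,
            report_year=int(rng.integers(y0, y1 + 1)),
            report_type=_sample_categorical(rng, rt_keys, rt_p),
            reporter=_sample_categorical(rng, rep_keys, rep_p),
            sex=_sample_categorical(rng, sex_keys, sex_p),
            age_years=float(rng.integers(lo, hi + 1)),
            causality=_sample_categorical(rng, cau_keys, cau_p),
            serious=serious,
            seriousness_type=stype,
            drugs=drugs,
            events=events,
        )
        for reason in CONTAMINATION_REASONS:
            rate = config.contamination.get(reason, 0.0)
            if rate and rng.random() < rate:
                report = _contaminate(report, reason)
        reports.append(report)
    return ReportSet(reports)


def _contaminate(r: IcsrReport, reason: str) -> IcsrReport:
    tag = f"contaminated:{reason}"
    note = f"{r.note};{tag}" if r.note else tag
    if reason == "missing_sex":
        return r.copy(sex=Sex.MISSING, note=note)
    if reason == "missing_age":
        return r.copy(age_years=None, note=note)
    if reason == "missing_event":
        return r.copy(events=[], note=note)
    if reason == "missing_atc":
        return r.copy(drugs=[DrugEntry(None, suspected=True)], note=note)
    if reason == "follow_up":
        return r.copy(is_initial=False, note=note)
    if reason == "bad_causality":
        return r.copy(causality=Causality.UNLIKELY, note=note)
    if reason == "no_suspected":
        return r.copy(
            drugs=[DrugEntry(d.atc_code, suspected=False) for d in r.drugs], note=note
        )
    raise ValueError(reason)


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def generate_confounded_reports(
    n_reports: int = 20_000,
    drug: str = "X01XX01",
    event: str = "event of interest",
    or_true: float = 3.0,
    confounded: bool = True,
    seed: int = 0,
) -> ReportSet:
    """Case/non-case simulation with a known conditional odds ratio.

    Age group index g in {0,1,2,3} and sex are sampled first. Exposure to
    ``drug`` has probability expit(-2.2 + 0.8 g) when ``confounded`` (age
    drives exposure), else a constant 0.3. The outcome (report mentions
    ``event``) follows ``logit p = -3 + 0.5 g + 0.3 male +
    log(or_true) exposed``, so the conditional OR for exposure is exactly
    ``or_true`` while age confounds the crude OR upward when exposure is
    age-linked. Unexposed reports carry one of five comparator drugs;
    non-outcome reports carry a cycling background event.
    """
    rng = np.random.default_rng(seed)
    comparators = ["N02BE01", "J01CA04", "C09AA05", "A02BC01", "M01AE01"]
    background_events = [f"background event {i:02d}" for i in range(1, 11)]
    groups = list(_AGE_RANGES)
    age_p = np.array([0.10, 0.20, 0.30, 0.40])
    log_or = math.log(or_true)
    reports = []
    for i in range(n_reports):
        g = int(rng.choice(4, p=age_p))
        male = rng.random() < 0.45
        p_exp = _expit(-2.2 + 0.8 * g) if confounded else 0.3
        exposed = rng.random() < p_exp
        p_out = _expit(-3.0 + 0.5 * g + 0.3 * male + (log_or if exposed else 0.0))
        outcome = rng.random() < p_out
        lo, hi = _AGE_RANGES[groups[g]]
        reports.append(
            IcsrReport(
                report_id=f"CNC-{i + 1:06d}",
                is_initial=True,
                report_year=2010 + i % 7,
                report_type=ReportType.SPONTANEOUS,
                reporter=Reporter.DOCTOR,
                sex=Sex.MALE if male else Sex.FEMALE,
                age_years=float(rng.integers(lo, hi + 1)),
                causality=Causality.POSSIBLE,
                serious=False,
                seriousness_type=SeriousnessType.NONE,
                drugs=[DrugEntry(drug if exposed else comparators[i % 5], suspected=True)],
                events=[event if outcome else background_events[i % 10]],
            )
        )
    return ReportSet(reports)


# ---------------------------------------------------------------------------
# deterministic worked-example fixture
# ---------------------------------------------------------------------------

_GENERIC_EVENTS = [
    "nausea", "rash", "headache", "dizziness", "pyrexia",
    "vomiting", "pruritus", "urticaria", "diarrhoea", "abdominal pain",
]

#: background occurrences of the ophthalmic terms among comparator drugs,
#: sized so the worked example's signal lists come out as published
_BACKGROUND_OPHTHALMIC = [
    ("endophthalmitis", 4),
    ("conjunctivitis", 4),
    ("retinal disorder", 4),
    ("muscae volitantes", 2),
    ("vision abnormal", 3),
    ("retinal detachment", 2),
    ("retinal haemorrhage", 3),
    ("conjunctival haemorrhage", 30),
    ("acanthosis", 25),
    ("ocular haemorrhage", 30),
    ("eye abnormality", 25),
]

_BACKGROUND_DRUGS = [
    "N02BE01", "J01CA04", "C09AA05", "A02BC01",
    "M01AE01", "L01XC03", "A10BA02", "C10AA01",
]


def _counts_to_list(counts: list[tuple[str, int]]) -> list[str]:
    out: list[str] = []
    for value, n in counts:
        out.extend([value] * n)
    return out


def _study_drug_reports(
    prefix: str,
    atc: str,
    n: int,
    n_male: int,
    n_ge60: int,
    other_ages: list[tuple[AgeGroup, int]],
    years: list[str | int],
    serious_idx: set[int],
    n_pms: int,
    pms_at: int,
    n_literature: int,
    consumer_idx: set[int],
    events: list[str],
) -> list[IcsrReport]:
    assert len(years) == n and len(events) == n
    age_groups = [AgeGroup.GE60] * n_ge60 + _counts_to_list(
        [(g, k) for g, k in other_ages]  # type: ignore[misc]
    )
    assert len(age_groups) == n
    reports = []
    for i in range(n):
        group = age_groups[i]
        lo, hi = _AGE_RANGES[group]
        age = lo + (i * 7) % (hi - lo + 1)
        serious = i in serious_idx
        if pms_at <= i < pms_at + n_pms:
            rtype = ReportType.POST_MARKETING_SURVEILLANCE
        elif i >= n - n_literature:
            rtype = ReportType.LITERATURE
        else:
            rtype = ReportType.SPONTANEOUS
        if i in consumer_idx:
            reporter = Reporter.CONSUMER
        else:
            reporter = [Reporter.DOCTOR, Reporter.DOCTOR, Reporter.PHARMACIST, Reporter.NURSE][i % 4]
        reports.append(
            IcsrReport(
                report_id=f"{prefix}-{i + 1:03d}",
                is_initial=True,
                report_year=int(years[i]),
                report_type=rtype,
                reporter=reporter,
                sex=Sex.MALE if i < n_male else Sex.FEMALE,
                age_years=float(age),
                causality=[Causality.POSSIBLE, Causality.PROBABLE, Causality.CERTAIN][i % 3],
                serious=serious,
                seriousness_type=(
                    (SeriousnessType.HOSPITALIZATION if i % 2 == 0
                     else SeriousnessType.OTHER_INCLUDING_DEATH)
                    if serious else SeriousnessType.NONE
                ),
                drugs=[DrugEntry(atc, suspected=True)],
                events=[events[i]],
            )
        )
    return reports


def anti_vegf_fixture() -> ReportSet:
    """Deterministic raw dataset for the anti-VEGF worked example.

    Regeneration is byte-identical (no randomness). After the default
    inclusion filters the set contains exactly 103 ranibizumab and 32
    aflibercept reports whose category counts re-round to the published
    percentages; see the module docstring for the construction rules.
    """
    # --- ranibizumab: 103 retained reports -------------------------------
    ran_years = (
        [2008] * 2 + [2009] * 3 + [2010] * 3 + [2011] * 4 + [2012] * 1
        + [2013] * 12 + [2014] * 20 + [2015] * 28 + [2016] * 30
    )
    # 20 serious: the 12 reports of 2013 (a 100% SAE year) + 8 of 2016
    ran_serious = set(range(13, 25)) | set(range(73, 81))
    ran_events = _counts_to_list([
        ("retinal disorder", 15),
        ("medicine ineffective", 15),
        ("endophthalmitis", 12),
        ("retinal detachment", 10),
        ("conjunctival haemorrhage", 10),
        ("retinal haemorrhage", 9),
        ("vision abnormal", 9),
        ("conjunctivitis", 8),
        ("acanthosis", 8),
        ("muscae volitantes", 7),
    ])
    ran = _study_drug_reports(
        prefix="RAN", atc=RANIBIZUMAB, n=103, n_male=64, n_ge60=80,
        other_ages=[(AgeGroup.A40_59, 10), (AgeGroup.A20_39, 8), (AgeGroup.LT20, 5)],
        years=ran_years, serious_idx=ran_serious,
        n_pms=48, pms_at=0, n_literature=50,
        consumer_idx={50, 51}, events=ran_events,
    )

    # --- aflibercept: 32 retained reports --------------------------------
    afl_years = [2013] * 2 + [2014] * 6 + [2015] * 10 + [2016] * 14
    afl_serious = {0} | set(range(2, 7)) | set(range(8, 16)) | set(range(18, 28))
    afl_events = _counts_to_list([
        ("endophthalmitis", 12),
        ("conjunctivitis", 6),
        ("muscae volitantes", 5),
        ("ocular haemorrhage", 4),
        ("eye abnormality", 3),
        ("retinal disorder", 2),
    ])
    afl = _study_drug_reports(
        prefix="AFL", atc=AFLIBERCEPT, n=32, n_male=23, n_ge60=27,
        other_ages=[(AgeGroup.A40_59, 3), (AgeGroup.A20_39, 1), (AgeGroup.LT20, 1)],
        years=afl_years, serious_idx=afl_serious,
        n_pms=10, pms_at=0, n_literature=6,
        consumer_idx={10, 11, 12}, events=afl_events,
    )

    # --- comparator background: 400 reports ------------------------------
    bg_events = _counts_to_list(_BACKGROUND_OPHTHALMIC)
    while len(bg_events) < 400:
        bg_events.append(_GENERIC_EVENTS[len(bg_events) % len(_GENERIC_EVENTS)])
    # fixed-seed shuffle decouples the event list from the cyclic drug
    # assignment below; the fixture stays byte-identical across runs
    np.random.default_rng(42).shuffle(bg_events)
    bg = []
    for i in range(400):
        serious = i % 10 == 0
        group = list(_AGE_RANGES)[i % 4]
        lo, hi = _AGE_RANGES[group]
        bg.append(
            IcsrReport(
                report_id=f"BG-{i + 1:03d}",
                is_initial=True,
                report_year=2007 + i % 10,
                report_type=list(ReportType)[i % 4],
                reporter=list(Reporter)[i % 6],
                sex=Sex.MALE if i % 2 == 0 else Sex.FEMALE,
                age_years=float(lo + (i * 5) % (hi - lo + 1)),
                causality=[Causality.POSSIBLE, Causality.PROBABLE, Causality.CERTAIN][i % 3],
                serious=serious,
                seriousness_type=(
                    SeriousnessType.HOSPITALIZATION if serious else SeriousnessType.NONE
                ),
                drugs=[DrugEntry(_BACKGROUND_DRUGS[i % 8], suspected=True)],
                events=[bg_events[i]],
            )
        )

    # --- planted contaminants: one per inclusion rule ---------------------
    def planted(idx: int, reason: str, **overrides) -> IcsrReport:
        base = IcsrReport(
            report_id=f"CON-{idx:02d}",
            is_initial=True,
            report_year=2015,
            report_type=ReportType.SPONTANEOUS,
            reporter=Reporter.DOCTOR,
            sex=Sex.FEMALE,
            age_years=70.0,
            causality=Causality.POSSIBLE,
            serious=False,
            seriousness_type=SeriousnessType.NONE,
            drugs=[DrugEntry(RANIBIZUMAB, suspected=True)],
            events=["endophthalmitis"],
            note=f"planted:{reason}",
        )
        return base.copy(**overrides)

    contaminants = [
        planted(1, "missing_sex", sex=Sex.MISSING),
        planted(2, "missing_age", age_years=None, drugs=[DrugEntry(AFLIBERCEPT, True)]),
        planted(3, "missing_event", events=[]),
        planted(4, "missing_atc", drugs=[DrugEntry(None, suspected=True)]),
        planted(5, "follow_up", is_initial=False),
        planted(6, "bad_causality", causality=Causality.UNLIKELY,
                drugs=[DrugEntry(AFLIBERCEPT, True)]),
        planted(7, "no_suspected", drugs=[DrugEntry(RANIBIZUMAB, suspected=False)]),
    ]

    return ReportSet(ran + afl + bg + contaminants)
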