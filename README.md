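# pvsignal

Signal detection from spontaneous adverse-event reports.

`pvsignal` is a Python toolkit for pharmacovigilance analysts working with
individual case safety reports (ICSRs) — the spontaneous reports collected
by national systems such as KAERS, FAERS, or VigiBase. It implements the
standard disproportionality pipeline end to end:

1. **Inclusion filtering** — keep initial reports with complete
   sex/age/drug/event coding, WHO-UMC causality certain/probable/possible,
   and at least one suspected drug, with an auditable exclusion log.
2. **Drug–event pairs** — explode each report into (ATC drug, WHO-ART/
   MedDRA preferred term) pairs, the unit of disproportionality analysis.
3. **2×2 statistics** — for each pair's table (a, b, c, d):
   - PRR = (a/(a+b)) / (c/(c+d)), 95% CI
     exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d)))
   - ROR = ad/bc, 95% CI exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)),
     with the Haldane–Anscombe +0.5 correction on zero cells
   - Pearson χ² (Yates-corrected by default)
   - BCPNN information component IC = log₂((a + 0.5)/(E + 0.5)),
     E = (a+b)(a+c)/n, with a seeded Monte-Carlo 95% credible interval
     from a Dirichlet(cells + 0.5) posterior
4. **Signal calls** — the triple criterion: (PRR ≥ 2 ∧ χ² ≥ 4 ∧ n ≥ 3) ∧
   (ROR ≥ 2 ∧ χ² ≥ 4 ∧ n ≥ 3) ∧ (IC 95% lower bound > 0); detected signals
   are compared with drug-label references and classed
   expected/unexpected.
5. **Adjusted reporting odds ratios** — case/non-case logistic regression
   at report level (outcome: report mentions the event; exposure: report
   mentions the drug), controlling sex and four age strata
   (<20, 20–39, 40–59, ≥60).
6. **Descriptives** — characteristics tables (counts and half-up
   percentages) and annual AE/SAE trend series.

A seeded synthetic-report generator with controllable signal strength
(λ multipliers) and confounding supports calibration and recovery studies,
and a deterministic anti-VEGF worked example (ranibizumab vs aflibercept)
ships with the package.

## Worked example

The packaged fixture reconstructs the report-level marginals of a published
anti-VEGF reporting-pattern comparison (ranibizumab, ATC S01LA04, vs
aflibercept, S01LA05, against a comparator background):

```python
import pvsignal as pv

raw = pv.anti_vegf_fixture()
kept, log = pv.apply_inclusion_filters(raw)
pairs = pv.build_pairs(kept)
screen = pv.DisproportionalityScreen.from_pairs(
    pairs, min_a=1, prior=pv.IcPrior(n_mc=50_000), seed=7
).fit()
decisions = pv.classify_expectedness(
    pv.evaluate_all(screen), pv.LabelReference.packaged("KR")
)
```

This prints (via the filter log and the decision list):

```
raw reports: 542  retained: 535  removed: {'missing_field': 4, 'non_initial': 1,
                                           'causality': 1, 'no_suspected_drug': 1}
S01LA04  conjunctivitis         n=8   expected
S01LA04  endophthalmitis        n=12  expected
S01LA04  medicine ineffective   n=15  unexpected
S01LA04  muscae volitantes      n=7   expected
S01LA04  retinal detachment     n=10  expected
S01LA04  retinal disorder       n=15  expected
S01LA04  retinal haemorrhage    n=9   expected
S01LA04  vision abnormal        n=9   expected
S01LA05  conjunctivitis         n=6   unexpected
S01LA05  endophthalmitis        n=12  expected
S01LA05  muscae volitantes      n=5   expected
```

103 ranibizumab and 32 aflibercept reports survive filtering; the triple
criterion flags 8 ranibizumab and 3 aflibercept signals, of which
"medicine ineffective" (ranibizumab) and "conjunctivitis" (aflibercept) are
absent from the packaged label reference — unexpected signals, the finding
this kind of screen exists to surface.

Adjusted reporting odds ratios are fitted as statsmodels-style
Model/Results objects. On a confounded simulation whose true conditional
OR is 3.0 (age drives both exposure and outcome):

```python
rs = pv.generate_confounded_reports(20_000, or_true=3.0, seed=5)
fit = pv.CaseNonCaseLogit.from_reports(rs, "X01XX01", "event of interest").fit()
print(fit.summary())
```

```
Case/non-case logistic fit: drug=X01XX01 event=event of interest
n = 20000, converged = True
adjusted OR = 3.162 (95% CI 2.937-3.404), age reference = lt20
term                coef        SE
const            -2.9327    0.0912
exposure          1.1511    0.0376
sex_male          0.2790    0.0363
age_20_39         0.4279    0.1026
age_40_59         0.9041    0.0956
age_ge60          1.4051    0.0937
```

The crude ROR on the same data is 4.098 (95% CI 3.820–4.397): the
adjustment removes the designed upward confounding bias and its CI covers
the true value.

The same pipeline is scriptable from the shell:

```bash
pvsignal fixture --out raw.csv
pvsignal filter --in raw.csv --out kept.csv --log filterlog.json
pvsignal pairs --in kept.csv --out pairs.csv
pvsignal tables --in pairs.csv --out tables.csv --min-a 1
pvsignal screen --tables tables.csv --out dispro.csv --seed 1234
pvsignal signals --dispro dispro.csv --labels-kr --out signals.csv
pvsignal adjust --in kept.csv --signals signals.csv --out adjusted.csv
pvsignal describe --in kept.csv --drugs S01LA04,S01LA05 --out table1.csv
```

or end to end with a manifest recording parameters, seed, and artifact
digests: `pvsignal run --config pipeline.yaml --outdir out/`.

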