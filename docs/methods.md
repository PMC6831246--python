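# Methods

## The analysis model

`pvsignal` treats a spontaneous-reporting database as a collection of
drug–event *pairs*: each retained report contributes one pair per
(suspected drug, distinct event preferred term) combination. For a target
pair the 2×2 table

|            | target event | other events |
|------------|--------------|--------------|
| target drug| a            | b            |
| other drugs| c            | d            |

is built with the comparator being *all other drugs in the supplied pair
set* — no external background rates are consulted. Disproportionality is
measured four ways:

- **PRR** = (a/(a+b)) / (c/(c+d)); log-scale Wald 95% CI with
  SE = √(1/a − 1/(a+b) + 1/c − 1/(c+d)).
- **ROR** = ad/bc; log-scale Wald 95% CI with SE = √(1/a + 1/b + 1/c + 1/d).
- **Pearson χ²** on the 2×2, Yates-corrected by default. The continuity
  correction is the classical companion of the PRR ≥ 2 / χ² ≥ 4 / n ≥ 3
  criterion; the uncorrected statistic is available by flag (and is what
  the null-calibration study uses, since its reference point is the
  asymptotic χ²₁ 5% quantile 3.84).
- **Information component** IC = log₂((a + s)/(E + s)) with expected count
  E = (a+b)(a+c)/n and shrinkage s = 0.5. The 95% interval is a Monte-Carlo
  credible interval: cell probabilities are drawn from a
  Dirichlet(a+0.5, b+0.5, c+0.5, d+0.5) posterior, the IC
  log₂(p₁₁/(p₁·p·₁)) is recomputed per draw, and empirical 2.5%/97.5%
  quantiles are taken. Both pseudo-counts, the draw count, and the credible
  level live in `IcPrior`, so other BCPNN parameterizations can be
  configured. This shrinkage form is one of several in use in the BCPNN
  literature; it is documented here as this package's convention rather
  than asserted to match any specific implementation.

A pair is a **signal** when all three criteria hold: PRR ≥ 2 with χ² ≥ 4
and n = a ≥ 3; ROR ≥ 2 with χ² ≥ 4 and n ≥ 3; and the IC interval's lower
bound strictly > 0. The strict inequality on the IC bound versus the
inclusive ones elsewhere mirrors the criterion's usual statement. Signals
are compared against per-jurisdiction label term sets by exact match on
canonicalized strings (case-folded, whitespace-collapsed); no synonym or
terminology-hierarchy expansion is attempted.

## Zero cells and degenerate tables

ROR (and the PRR interval) are undefined with a zero cell; when any cell is
zero the Haldane–Anscombe correction adds 0.5 to all four cells before
computation and the result is flagged `corrected`. χ² with a zero margin is
reported as 0 with a warning — such a pair cannot meet the χ² ≥ 4 criterion
regardless of convention. The IC is defined for a = 0 (it is then negative)
but errors on an empty table.

## Inclusion filtering

The default criteria retain initial reports, with complete sex/age coding,
at least one non-missing event term and one suspected drug with an ATC
code, and WHO-UMC causality in {certain, probable, possible}. "Missing
event code" is handled per event: empty PT entries are dropped and the
report survives if any valid term remains — this preserves partially coded
reports, matching the pair-level unit of analysis. Each excluded report is
attributed to exactly one rule, the first failing one in the fixed order
*missing_field → non_initial → causality → no_suspected_drug*, so the
exclusion log reconciles exactly (n_in − n_out equals the sum over
reasons). Filtering is idempotent, and fully permissive criteria are the
identity.

## Adjusted reporting odds ratios

The case/non-case model is fitted at *report* level: outcome = report
mentions the target event, exposure = report mentions the target drug among
its suspected drugs, covariates = sex and the age strata
[0,20), [20,40), [40,60), [60,∞) with the youngest non-empty stratum as
reference. Report level rather than pair level avoids within-report
pseudo-replication when one report carries several events. The fit is
maximum likelihood by iteratively reweighted least squares, converged when
the largest absolute coefficient change falls below 1e−8 (cap 50
iterations); Wald 95% CIs are exp(β ± 1.96·SE). Empty covariate levels are
dropped with a warning, as are constant columns (whose presence would only
break the design rank — with all covariates constant the model collapses
exactly to the crude 2×2 odds ratio). Separation is *reported* — runaway
coefficients or non-finite standard errors set `converged=False` with a
diagnostic message — never silently corrected; no Firth or exact method is
applied by default. On the packaged worked example the
aflibercept–endophthalmitis fit exhibits exactly this: the youngest age
stratum contains no cases, the age dummies run away, and the result is
flagged rather than patched.

## Age grouping conventions

The four strata are closed on the left: ages 20, 40, and 60 fall in the
higher group. "60 and over" was chosen over "strictly over 60" as the
conventional reading of an upper age class; the boundary matters only for
reports aged exactly 60.

## Percentages and rounding

All internal computation is at full precision. Presentation percentages are
rounded half *up* (away from zero) to one decimal — banker's rounding would
print 31.25% as 31.2 rather than the conventional 31.3. Completed
stratifications re-sum to 100.0 within rounding slack (±0.2). The annual
trend table reports, per drug-year, AE report counts, SAE counts, and the
SAE/AE ratio; the year axis is contiguous with explicit zeros. The annual
rate of increase, where needed, is the simple year-over-year count ratio.

## The synthetic generator

`generate_reports` emulates the structure of a national ICSR extract:
per-report covariates, one or more drugs with suspected/concomitant roles,
one or more event terms, causality, seriousness, reporter and report type,
and optional contaminant records that each inclusion rule must catch.
Event terms are drawn with probability proportional to
`baseline weight × λ(drug, event)` given the report's suspected drugs, so
λ ≡ 1 is exact drug–event independence and λ > 1 injects reporting
disproportionality of known strength. With single-drug, single-event
reports and uniform vocabularies the selection odds ratio equals λ exactly,
which is what the recovery studies exploit. Defaults (10,000 reports,
25 drugs × 20 event terms, mostly single-drug/single-event reports, 10%
serious, 2007–2016) describe a mid-sized database slice. Identical config
and seed give byte-identical output.

What the generator does **not** emulate: duplicate and split reports,
secular reporting trends and media-triggered clusters, terminology
migration, drug–drug interaction signals, dose or latency information, and
any pharmacological plausibility of drug–event co-occurrence. Passing the
calibration and recovery suites therefore demonstrates statistical
correctness of the pipeline under clean reporting assumptions, not
robustness to the artefacts of real spontaneous data.

`generate_confounded_reports` works directly on the logit scale:
exposure probability rises with age group (expit(−2.2 + 0.8·g)) and the
outcome follows logit p = −3 + 0.5·g + 0.3·male + ln(OR)·exposed, so the
true *conditional* odds ratio equals the configured value exactly and the
crude OR is upward-biased by construction. This gives the adjusted-OR
module a ground truth to recover.

## The worked-example fixture

`anti_vegf_fixture()` deterministically reconstructs the report-level
marginals of a published ranibizumab/aflibercept reporting-pattern
comparison: 103 and 32 retained reports with category counts back-derived
from the printed percentages via count = round(percent × total / 100), each
verified to re-round to the printed value under the half-up rule (e.g.
71.9% of 32 → 23; 23/32 = 71.875 → 71.9). Event-term counts per drug are
*not* pinned by any published denominators; they were chosen once so that
the triple criterion recovers the published signal lists (3 aflibercept,
8 ranibizumab) against a 400-report comparator background, and are fixture
design, not data. Seven planted contaminants (one per inclusion rule)
carry `planted:<reason>` tags so filter tests can assert exactly which
records each rule removes. The packaged KR/US label files are synthetic
stand-ins listing only the terms the example needs — they are not extracts
of any approved label, and real-label expectedness classification requires
supplying authoritative term sets.

## Problem sizes and numerical tolerances

The calibration studies use sizes at which the relevant asymptotics hold
while keeping a laptop run comfortable: null calibration uses 4 replicate
datasets of 10,000 single-drug/single-event reports over a 25 × 20
vocabulary (2,000 tables, expected a-cell ≈ 20); signal recovery injects
λ = 8 into 20,000 reports; adjusted-OR coverage uses 100 replicates of
4,000 reports. IC intervals default to 100,000 Monte-Carlo draws
(quantile MC error ≈ 0.01–0.03 log₂ units on small-count tables); mass
screens may lower `n_mc`, and a warning fires when the estimated MC
standard error of the lower quantile exceeds the configured tolerance
(default 0.05). Formula-level checks (PRR, ROR, χ², log-scale SEs) hold to
1e−9 against naive reimplementations; the constant-covariate collapse of
the adjusted OR to the crude OR holds to 1e−6 relative.

## Known limitations

- Disproportionality quantifies *reporting* association, not risk;
  no causal reading is supported, and no multiple-comparison control is
  applied across the screen.
- The IC interval is a posterior credible interval under one specific
  prior; criterion decisions near IC₀₂₅ = 0 can flip with the prior or the
  Monte-Carlo draw count.
- Term matching for expectedness is exact; label synonymy (e.g. "muscae
  volitantes" vs "vitreous floaters") must be resolved in the label files.
- The case/non-case model adjusts for sex and age only, as is conventional
  for adjusted RORs; richer confounding control is out of scope.
- No duplicate detection, multi-item shrinkage (EBGM/MGPS), or time-scan
  methods are implemented.
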