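# Methods

This note records the models, conventions and design choices behind
`pvsignals`, in the order the pipeline runs.

## Report model and ingestion

A `SafetyReport` is one version of one spontaneous AE report: opaque
report key, longitudinal case key, receipt date, demographics, a list of
drug entries (name, normalized name, active ingredient, role, route,
therapy start date) and lists of event and indication PTs. Events are a
set per report — a repeated PT in the reactions table counts once —
because the counting unit everywhere downstream is the report, the
standard case-count semantics of disproportionality analysis.

Dates are stored as (year, month, day) with the day and month optional,
since FAERS writes YYYY, YYYYMM or YYYYMMDD and CVARD ISO dates may omit
the day. Comparisons use the zero-padded numeric form, so a partial date
orders before any fuller date in the same period; stages that need exact
arithmetic (time-to-onset) require full precision and log what they drop.

Unit conversion: ages DEC×10, YR×1, MON÷12, WK×7/365.25, DY÷365.25,
HR÷8760; weights LBS×0.45359237, GMS÷1000. Unparseable codes become
missing, as do ages above 120 years (a defensive, testable bound for
data-entry errors). Free-text routes map through a small shipped
dictionary onto {oral, topical, other}; unknown non-empty strings are
`other`, absent is `missing`. The report-level route is taken from the
first suspect-role entry with a known route.

Deduplication keeps, per case key, the version with the maximal receipt
date, breaking ties by the larger report key (numeric comparison when the
keys are digits). Output is sorted by case key, so the operation is
deterministic and idempotent; both properties are tested.

Drug selection matches query names case-insensitively as substrings of
both product name and active-ingredient fields, so combination products
containing a queried ingredient match — the same rule the sensitivity
stage uses to drop formoterol-containing dual/triple therapies. Whether a
regulatory analysis matches trade names against the product name only is
generally unstated; matching both is the more inclusive choice and is
documented rather than hidden.

Noise-term exclusion removes, by case-insensitive exact PT match, terms
that are indications for the query drug (COPD, chronic bronchitis,
psoriasis) or unrelated to therapy (off label use, medication error,
intentional product misuse); reports left with no events are dropped and
counts logged. The shipped list is editable.

## Vocabulary and labeledness

MedDRA is licensed, so the package ships a small PT→SOC fixture (~55 PTs
over the case study's organ classes) and accepts any user-supplied
two-column table; only the PT and SOC levels are modeled. Label
dictionaries are explicit term sets per agency with a user-editable
synonym map (e.g. US "diarrhea" → "diarrhoea") applied before the exact
match — no fuzzy matching, because the medical-evaluation step it would
imitate is not algorithmically specifiable. The shipped dictionaries
encode only terms whose labeledness the case study states explicitly;
they are fixtures, not a reconstruction of the full labels.

## Contingency tables

Background = all deduplicated reports not selected for the target drug,
same period. At SOC level a report contributes once per SOC even when
several of its PTs share it; consequently the sum of SOC-level case
numbers counts (report, SOC) pairs, not reports — which is exactly how
the case study's SOC table totals 8,481 AEs from 2,962 reports. Whether a
published "case number" counts reports or PT mentions is usually
unstated; report-level counting is the default here and the brute-force
recount invariant in the tests pins it down.

## Disproportionality statistics

The four statistics use the standard formula set of the FAERS
disproportionality literature; the positivity thresholds
(ROR: a≥3 ∧ lower CI >1; PRR: a≥3 ∧ PRR≥2 ∧ χ²≥4; BCPNN: IC025>0;
MGPS: a≥3 ∧ EBGM05>2) were validated by reproducing the published SOC
positivity pattern of the roflumilast FAERS analysis exactly (5/2/1/5
positive SOCs per algorithm, one SOC positive on all four). Choices that
matter:

* χ² carries the Yates continuity correction and is floored at 0 when
  |ad−bc| ≤ N/2 — the convention the "χ²≥4" rule assumes.
* An infinite PRR (c=0 with a>0) is reported as +inf, never silently
  corrected; the ROR zero-cell correction is Haldane–Anscombe +0.5 with
  an explicit flag.
* BCPNN uses the closed-form posterior expectation and variance of the
  information component with pseudo-counts (α₁=β₁=γ₁₁=1, α=β=2);
  IC025 = E(IC) − 2√V(IC). A Monte-Carlo posterior exists for validation
  only and agrees with the closed form to ~0.02 bits on realistic tables.
* MGPS is unstratified; the prior is fitted on the full (drug, PT) pair
  universe of the ingested database (≥50 pairs required), by multi-start
  L-BFGS on the log/logit-transformed five-parameter marginal likelihood,
  with deterministic seeded start points and the smaller-mean component
  reported first. EBGM follows the geometric-mean convention
  2^{E[log₂λ|a]} (hence the EBGM05 naming); EBGM05 is found by bisection
  on the posterior mixture CDF to 1e-8. Tests verify both against
  numerical integration of the posterior density to 3 decimals.

## Time-to-onset

TTO = event date − earliest full-precision start date among matching drug
entries, in whole days ≥1. Records with partial dates are excluded rather
than imputed (the alternative — month-midpoint imputation — would
manufacture precision the source lacks); intervals over a configurable
cap (default 3,650 days) are treated as date-entry errors. All
percentiles including the median use linear interpolation — stated
explicitly because published analyses rarely say, which is one reason
exact replication of a printed median/IQR on real data is not claimed.

The Weibull fit is a plain MLE (no censoring: every stored report has an
observed event) maximized in (ln α, ln β), with Wald 95% intervals from
the numerical observed information on the log scale. A recorded onset of
d whole days covers continuous times (d−1, d], so the likelihood is
evaluated at midpoints d−0.5 by default; piling the sub-day mass at t=1
would bias β upward by ~0.07 at shape 0.8. Failure classification: early
if β<1 and CI upper <1, wear-out if β>1 and CI lower >1, random if the CI
contains 1, indeterminate otherwise. The cumulative-incidence curve is
the empirical CDF of observed TTOs.

## Subgroups and sensitivity

Subgroup comparisons are within-drug: for each of the top-K (default 50)
most frequent PTs, a 2×2 of event-vs-other-events against
target-vs-control stratum. The "adjusted ROR" is the crude stratified ROR
with BH-adjusted p-values — the printed outputs (ROR, CI, p.adj) are
fully determined by this reading, and no covariate-adjustment model is
specified by the convention; orientation is female vs male, ≥65 vs 18–64,
oral vs topical, so target-stratum enrichment gives adj_ROR > 1. P-values
use Fisher's exact test when any expected cell is below 5, else the Yates
χ² — a documented, configurable small-cell rule. BH is the step-up
procedure (via statsmodels), property-tested against the quadratic-time
definition.

The sensitivity reanalysis drops target-drug reports mentioning any
co-medication from the shipped list (formoterol and its dual/triple
combinations, umeclidinium, vilanterol) in any role, then reruns the
unchanged contingency and signal stages.

## Synthetic generator

The generator emulates the structure the pipeline consumes: drug
assignment multinomial (uniform by default over 10 drugs); events per
report zero-truncated Poisson with mean 2.9; event draws with replacement
from a Zipf-like background (or a user vector), uniquified, with planted
(drug, event) pairs tilted by their relative risk and renormalized;
demographics from marginals calibrated to the case study's report mix
(45.7% male, 51.6% age missing, 73% weight missing, 89.5% oral) — a
cosmetic calibration so fixture summaries resemble published tables, not
a reproduction claim. Onset dates are drawn for 16.7% of reports with
TTO ~ Weibull(scale 30 d, shape 0.8) rounded up to ≥1 day (the
early-failure regime); indication terms contaminate event lists at 5% to
exercise the exclusion stage. Duplicates are exact clones except report
key and a +90-day receipt date, because the deduplication rule resolves
only on those keys; the manifest records them for round-trip checks.

What it does not emulate: reporting-volume dynamics over time (Weber
effect), correlated demographics, multi-drug reports beyond the suspect
entry, conflicting-field duplicates, and real MedDRA term frequencies.
Passing calibration on this generator therefore shows the statistical
machinery is correct and calibrated under a faithful null, not that real
FAERS data would yield any particular signal list.

`pair_report_counts` exposes the generator's drug/event assignment as a
count matrix without building report objects; it consumes the seeded
generator stream identically to `generate` (equality is tested), which
keeps the 100-replicate calibration studies at 100,000 reports within a
few minutes on one CPU.

## Problem sizes and calibration results

The shipped studies use: null calibration at 20 drugs × 200 events,
100,000 reports, 100 replicates (observed all-four false-positive rate
0/400,000 pairs, bound <1%); recovery of a planted RR=5 pair at 1%
background in 50,000 reports, 100 replicates (recovered in 100/100, bound
≥95%); Weibull shape recovery at n=1,000 over 20 seeds (mean β̂ ≈ 0.82
for truth 0.8, all classified early). These sizes are the package's
standard calibration conditions; `scripts/acceptance.py` recomputes all
of them from a given seed.

## Known limitations

No stratified MGPS, no regression-based or shrinkage-ROR variants, no
interval-censored TTO models, no propensity or comorbidity adjustment in
subgroups, no MedDRA LLT/HLT levels, no handling of FAERS outcome (OUTC)
codes. Published decimal values that depend on the full regulatory
databases (e.g. a real drug's exact ROR) are out of reach by design; the
reference tables shipped with the package cover what can be verified
without them.
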