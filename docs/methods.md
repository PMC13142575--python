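# Methods

This package studies how two analytic choices shape genomic risk estimates
in EHR-linked cohort studies of coronary heart disease (CHD): how cases are
ascertained (billing-code algorithm, self-report, or their union) and where
observation is taken to begin for left-truncated time-to-event analysis. No
individual-level clinical data ship with the package; a synthetic-cohort
generator with known ground truth stands in for the restricted study data,
so every downstream stage is testable against known answers.

## Synthetic cohort model

**Exposures and covariates.** Each participant carries a monogenic risk flag
(Bernoulli, default prevalence 0.006 — the order of familial-
hypercholesterolemia carriage), a standardized polygenic risk score (PRS,
standard normal), sex (female fraction 0.674) and a clinical site (uniform
over 10 sites). The "high PRS" flag uses the *theoretical* standard-normal
quantile for the configured tail (1.6449 for the default top 5%), mirroring
a fixed, externally calibrated cut-off rather than an in-sample quantile.
Enrollment age is truncated normal (mean 51.2, sd 14.9, bounds 18–90) and is
drawn independently of disease onset: the design is retrospective over the
full EHR span, so participants whose onset precedes enrollment remain in the
cohort.

**Onset ages.** Latent CHD onset follows a Gompertz proportional-hazards
model: baseline hazard h0(t) = a·exp(b·t) with age t in years, defaults
a = 2·10⁻⁵/yr and b = 0.085/yr (baseline cumulative incidence ≈ 0.13 by age
75 for an unexposed woman, lifetime ≈ 0.28 by 85 — the order of lifetime
"hard CHD" risk), multiplied by exp of the applicable log hazard ratios
(defaults: log 1.85 monogenic, log 2.0 high PRS, log 1.7 male). Onset is
drawn by inverting the cumulative hazard at a uniform deviate:
T = (1/b)·log(1 − b·log U /(a·r)); b = 0 falls back to the exponential
closed form, and a non-positive log argument (possible for b < 0) or
T beyond the administrative limit (85 y) means no lifetime onset.

**Billing streams.** Each participant enters the EHR at a truncated-normal
age (mean 40, sd 15, bounds 1–70; the floor of 1 year reflects that EHR
histories include pediatric records) and is nominally observable to the
administrative limit. Generic billing codes arrive as a homogeneous Poisson
process at 5 codes/person-year inside observation windows. With probability
0.45 the span is split by one long gap (1.5 y threshold + exponential excess,
mean 5.5 y), emulating fragmented utilization; with probability 0.10 a single
spurious "backfilled" code is placed uniformly at ages 2–15, followed by a
long silent gap — the early-artifact pattern that motivates the
most-recent-period entry definition. If the true onset falls inside an
observation window the stream contains the case-defining codes (two MI
diagnosis codes ≤ 5 days apart, or one PCI/CABG procedure code; component
mix 0.5/0.3/0.2); onsets falling in gaps or before EHR entry leave no trace,
which is exactly the case-misclassification mechanism under study. Ages are
stored as integer days (365.25 days/year) because the MI rule needs day
resolution while the survival models use years.

The encounter rate matters more than it may appear: under a homogeneous
Poisson process, silent gaps exceeding 1.5 years arise spontaneously with
probability e^(−1.5·rate) per inter-encounter interval. At 5/person-year
roughly half of all records contain no spontaneous split, so deliberate
fragmentation dominates — reproducing the reported cohort features this
generator emulates (about half of participants with maximum observation
equal to the most recent period; median entry age moving from ~40 to ~50
when switching entry definitions; finite cumulative incidence at 75 under
all scenarios). At 2/person-year nearly every record fragments spontaneously
and the most-recent-period entry collapses to old ages.

**Self-report.** Survey CHD status is a misclassified version of truth
(sensitivity 0.60, specificity 0.98 — chosen to produce the moderate
case-level agreement characteristic of survey-vs-EHR comparisons); 97% of
participants complete the survey. True cases who self-report name their true
component; false positives endorse a random component half the time.

**What the generator does not emulate.** Encounters are homogeneous within
windows (no bursts around diagnosis, no visit structure), misclassification
is independent of covariates (no differential reporting by age, sex, or
site), fragmentation is independent of disease status and exposures, and
entry-shift magnitudes are heavier-tailed than in the real cohort (the split
point is uniform over a long span). Passing tests therefore demonstrate
estimator correctness and the direction/stability findings under independent
truncation — not robustness to differential misclassification or
informative observation, which the real-data problem may contain.

## Phenotyping

MI requires ≥ 2 MI diagnosis codes within a 5-day window (inclusive;
same-day distinct records qualify; the window is read inclusively). Onset is the earlier
age of the earliest qualifying pair, found by a scan over age-sorted codes
(equivalent to exhaustive pair enumeration, which the tests verify).
PCI/CABG require one procedure code; onset is the earliest match. CHD is
the disjunction; its onset the component minimum. Codes are matched by
exact string equality after trimming, uppercasing, and removing dots (ICD
dialects differ in dot usage). Self-reported CHD is positive if either the
"currently have" or "had in the past" answer is positive; sub-phenotype
answers map heart attack → MI, bypass surgery → CABG, stenting → PCI and
are honored only when CHD itself is reported (survey skip logic). The
combined definition is the union, with missing self-report counting as
negative; agreement denominators, by contrast, are restricted to
participants with both sources available.

## Observation periods and entry times

The maximum observation span runs from first to last billing code.
Consecutive periods are maximal runs of codes separated by gaps below 548
days (⌈1.5 × 365.25⌉; "less than 1.5 years" is read strictly, so a gap of
exactly 548 days splits). Entry-time scenarios: (1) first billing code, (2) start of the most
recent consecutive period, (3) no truncation (birth). Exit is always the
last billing code age for non-cases and the onset age for cases. Cohort
filters, applied in a fixed order so the exclusion log is deterministic:
≥ 365 days of maximum observation, adult (≥ 18) at enrollment, no CHD onset
before age 17.

## Agreement statistics

Overall agreement (both-positive + both-negative over the restricted total),
positive agreement (both-positive over ever-positive), per-source
discordance rates, and Cohen's kappa (a companion statistic reported
alongside, not used in any acceptance decision). Percentages are rounded
half-up to one decimal for report output.

## Relative-risk regression

A Poisson working model with log link on the binary case indicator
("modified Poisson"), so exponentiated coefficients are relative risks.
Fitting is IRLS from a zero start with step-halving; convergence on a
coefficient change below 10⁻⁸ (sup-norm), with a relative likelihood-change
fallback (10⁻¹³) that terminates cleanly when a nuisance column has an
infinite MLE (e.g. zero events among a handful of carriers in a stratum).
The robust variance is the HC0 sandwich A⁻¹BA⁻¹, A = XᵀD(μ)X,
B = Σ xxᵀ(y−μ)² — the conventional modified-Poisson choice; no small-sample
correction is applied. Covariates: enrollment age (linear), sex indicator
(omitted in sex-stratified fits), site dummies (reference = lexicographically
first site; the block is dropped with a note in single-site strata), and
maximum observation length in years (linear). Age bands are left-closed,
right-open ([40, 50) etc.), resolving the ambiguity of "40–49" for
fractional ages. Strata with no events, or with an exposure absent from the
stratum, are reported as "N/A" rather than fit. Wald 95% intervals and
two-sided normal p-values throughout.

## Survival analysis

Kaplan–Meier estimation uses counting-process risk sets n(t) = #{entry <
t ≤ exit} (half-open: a subject entering exactly at an event age is not at
risk for it). Variance is Greenwood's accumulator V(t) = Σ d/(n(n−d)) and
95% limits use the complementary log-log transform S^exp(±z√V/log S),
clipped to [0, 1]. Events whose recorded onset precedes the scenario entry
are retained by moving entry to onset − 0.5 days (in years): the retention
constant is this package's explicit operationalization of keeping
prevalent-at-entry events, and is configurable. Records degenerate after
adjustment are dropped with a logged reason.

The Cox model maximizes the site-stratified partial likelihood with the same
risk-set convention by Newton–Raphson (tolerance 10⁻⁹ on the log-likelihood
change, step-halving, max 50 iterations), Efron tie correction by default
(Breslow selectable). Risk-set sums are computed in O(n) per iteration from
prefix sums over entry- and exit-sorted orders, using the identity
Σ_risk = Σ_{entry<t} − Σ_{exit<t} (valid because entry < exit for every
record). Monotone likelihood (separation) is flagged — a coefficient
escaping beyond |β| > 20 — rather than reported as a finite estimate. The
model-based variance is the inverse observed information.

A consequence worth noting: holding events and exits fixed, moving every
entry later (with retained events) can only shrink risk sets, so each
hazard increment d/n grows and the estimated cumulative incidence at every
age is non-decreasing — the entry-scenario ordering (most-recent-period ≥
first-code ≥ no-truncation) is a pointwise theorem given the retention
rule, which the property tests verify on random data.

## Validation design and problem sizes

Estimator validation uses two direct generators rather than the billing
pipeline, because each makes a different "true effect = 2" statement exact:
a log-link binary-risk model (risk = 0.02·exp(Σ effects), so the true
*relative risk* of high PRS is exactly 2) for the modified-Poisson
estimator, and the Gompertz proportional-hazards generator (true *hazard
ratio* exactly 2) with independent truncated-normal entries for the Cox
estimator — a hazard ratio of 2 is not a risk ratio of 2, so one generator
cannot serve both. Recovery runs 50 replicates at n = 20,000 and checks the
mean log effect against log 2 (3 Monte-Carlo SEs) and 95% CI coverage
(accepted in [0.92, 0.98]; at 50 replicates that band is itself a noisy
instrument, with binomial SD ≈ 0.03 around a nominal 0.95).

The entry-scenario experiments run the full pipeline (simulate → phenotype →
segment → filter → model) on simulator defaults: 10 seeds at n = 5,000 for
the cumulative-incidence ordering at age 75, and 3 seeds at n = 20,000 for
hazard-ratio stability across scenarios (spread summarized as max/min − 1
for the high-PRS HR). Oracle equivalences (untruncated product-limit,
brute-force partial-likelihood maximization on a six-subject fixture,
saturated-model closed forms, adjacent-gap segmentation scan) run at small
n in seconds. Cross-checks against independent library implementations
(GLM with HC0 covariance; KM and Cox with delayed entry, strata and ties)
live in the test suite; the package's own estimators are used everywhere
else.

## Known limitations

- Misclassification and truncation are generated independently of exposures;
  the robustness findings say nothing about differential mechanisms.
- The left-truncated KM is unstable where risk sets are tiny (youngest event
  ages under late-entry scenarios); with degenerate configurations (e.g. a
  hard entry-age floor equal to the adult age) the curve can absorb to 1.
- The retention adjustment (0.5 days) is one of several defensible
  operationalizations of keeping prevalent events; alternatives (excluding
  prevalent cases, interval-censoring them) are not implemented.
- No proportional-hazards diagnostics, no interval/left-censoring model, and
  no genotype-level simulation (exposures are generated directly as flags).
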