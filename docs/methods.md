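# Methods

This note documents the modelling choices behind `dermflow`: what is
assumed, what is calibrated, what the defaults mean, and what the test
suite does and does not establish.

## Scope and design

Two arms of urgent suspected skin-cancer (USC) referral care are modelled
from referral to diagnosis communication. The *intervention* arm is a
community-based store-and-forward teledermatology service (image capture
by a Band 3 health care assistant at a community diagnostic centre,
asynchronous remote review by a consultant dermatologist); the
*comparator* arm is the standard face-to-face consultant clinic. The
analysis stops at diagnosis communication: no treatment, no long-term
costs, no false-negative follow-up, no quality-of-life weighting — the
cost analysis is a budgetary comparison, not a cost-effectiveness study.

Pathways are defined purely structurally (ordered stage lists in
configuration), with the shipped interpretation: A — image capture →
remote review → discharge; B — … → F2F follow-up → discharge; C — … →
follow-up → biopsy → histopathology; D — … → direct biopsy →
histopathology; E — biopsy scheduled then cancelled (administrative
closure, direct to communication, no histopathology endpoint); F — F2F
consult → discharge; G — F2F consult → biopsy → histopathology. Routing
is purely probabilistic over published referral shares; there is no
clinical decision logic. Two share sets ship as named configurations:
`"cca"` (cost analysis; the intervention shares as printed sum to 99%
because of whole-percent rounding — weighted sums use them as printed,
and a normalised view is used wherever a true probability vector is
required) and `"des"` (simulation; sums to 100%).

## Cost model

Arm mean cost per referral is the exact dot product `Σᵢ pᵢ·cᵢ` of shares
and unit costs (GBP, 2023 prices). Unit costs are used directly as
published; a bottom-up `activity_cost` (minutes/60 × hourly rate + tariff
add-on) is provided for users who want to rebuild them from staff time,
biopsy tariffs and platform licensing, but the published breakdown is not
available, so baseline configs do not rely on it.

**PSA.** The published analysis states only that staff-involvement SEs
were propagated. The default uncertainty spec is a normal distribution on
each pathway unit cost with SE = 12% of the cost, truncated at zero, with
pathway shares held fixed; 1000 iterations; percentile (2.5/97.5) CI.
This centres the PSA on the deterministic saving (£48.24 from the
published table); the spread is a modelling default, configurable per
parameter (a gamma family is also available). With all SEs set to zero
every iteration reproduces the deterministic saving exactly — a property
the tests assert.

**DSA.** One-way analysis over named parameters (`unit_cost.<pathway>`,
`n_referrals`, `biopsy_offset`). `biopsy_offset` re-routes a fraction of
the intervention biopsy-reliant mass (C, D) to the remaining pathways in
proportion to their baseline shares; since C and D carry the highest
intervention unit costs this is monotonically saving-increasing. The
published "up to £135 per referral if biopsies are offset" scenario
cannot be reconstructed exactly from the printed unit costs, so no
specific offset fraction is hard-coded.

**t test.** "Unpaired t test" is ambiguous; Welch's unequal-variance form
is the default (Student's pooled variant via `equal_var=True`). Patient
level cost samples are the pathway mixture with optional multiplicative
lognormal staff-time noise (CV 0.12 by default, matching the PSA spread).

## Discrete event simulation

**Time and calendars.** Time is fractional days; day 0 is a Monday. All
timestamps are days since the patient's own referral. Staffed activities
run inside 08:30–18:30 windows; weekend capacity is
`floor(0.7 × weekday headcount)` per role (zero for GPs). A service must
start and finish within one window. Queueing is first-come first-served
within a priority class; all USC referrals share one priority class by
default (the field is retained and configurable).

**Arrivals.** A seasonal Poisson stream: the year is split into 12
equal-length months, month *m* receiving Poisson(volume × w_m / 12)
arrivals uniform within the month, weights normalised to sum to 12
(uniform by default — no published monthly profile exists, and a 12-weight
vector is accepted in configuration). Default annual volume is 3,000
referrals per arm: the comparator cohort (4,011 referrals over 16 months)
pro-rated to one year, matched across arms for comparability. Arrivals
stop at day 365 but the simulation runs to drain, so every agent
contributes a complete record (100% retention, no no-shows, no
mortality, no equipment constraints — by assumption). There is no warm-up
discard: the system starts empty and idle, as for a newly launched
service.

**Delays.** Inter-stage waits are lognormal parameterised by (mean, CV),
CV 0.5 by default — non-negative and right-skewed, the conventional shape
for clinic waiting times; no distributional family is published. CV 0 or
the `fixed` family gives deterministic delays. Diagnosis communication
consumes no staffed capacity; a per-pathway method mix (letter, email,
telephone, F2F slot) assigns each method a relative delay multiplier,
rescaled so the mixture mean equals the pathway's configured
communication delay exactly. The per-method multipliers are calibrated
stand-ins (no per-method table is available), so only the pathway-level
mean is meaningful.

**Staffing defaults.** Headcounts (2 HCA, 1 Band 5, 2 Band 9,
3 consultants, 1 GP) are sized so that baseline offered load stays well
below 0.9 per role; no published counts exist. A stability check warns
when estimated offered load exceeds 0.9 and the event log carries
queue-length diagnostics. Hourly rates are 2023 cost-norm-style values
including overheads.

**Endpoints.** Clinical diagnosis = completion of remote review (
intervention) or F2F consult (comparator); histopathological diagnosis =
completion of histopathology reporting, defined only on biopsy-reliant
pathways (C, D, G); communication = pathway exit. Summaries report
mean, SE (= pooled patient-level SD/√n), normal-approximation 95% CI and
maximum per endpoint and per pathway, pooled over five independent
replications (seeds derived from one master seed).

## Calibration

Published aggregates anchor the simulation: per-pathway communication
means (A = 8 d; combined C&D = 52.4 d; G = 131.1 d), arm-level weighted
communication means (18.97 / 73.16 d), clinical-diagnosis means
(7.38 / 17.29 d) and histopathological-diagnosis means (66.42 / 129.21 d).
Missing per-pathway means follow from the arm-level weighted average by a
linear solve: F = (73.16 − 0.48×131.1)/0.52 ≈ 19.68 d, and with the tie
rule E = B (the cancelled-biopsy pathway carries 1% of referrals, making
the choice numerically negligible) B = E ≈ 12.81 d. The combined C&D
anchor is applied to both C and D, which preserves any C/D share split.

Calibration proceeds per target: an analytic scale first equates the
selected stage-delay means with the anchor (exact in the no-congestion
limit); the configuration is then simulated under common random numbers
and a bisection on a further scale factor absorbs what the analytic
assignment cannot see — queueing and shift-window alignment add roughly
0.1–0.2 days per staffed stage, so converged factors sit slightly below
one. Targets measuring a pathway subset are evaluated on that subset with
volume pro-rated (floor 2,000/year for Monte-Carlo precision); this is
accurate because the dominant wait components are pathway-local and
cross-pathway queueing is negligible at sub-critical staffing.

Three scenarios are calibrated separately — communication (per-pathway
anchors), clinical diagnosis (referral-to-triage booking delay as the
knob) and histopathology (biopsy-plus-reporting chain as the knob over
biopsy-reliant pathways) — because the published aggregates are not
mutually consistent as outputs of a single parameterisation: the combined
C&D communication mean (52.4 d) is *shorter* than the intervention
histopathology mean (66.42 d), although communication follows
histopathology for those patients. Each scenario reports only its own
endpoint, leaving that tension visible rather than resolving it.

The arm-level weighted communication means and all three incremental
deltas are *not* calibrated directly; recovering them from per-pathway /
per-arm anchors is the parameter-recovery check the acceptance suite
performs. Stochastic checks compare a fresh estimate against a published
anchor that is itself a simulation output with a printed SE, so the band
is two pooled standard errors, `2·sqrt(SE_sim² + SE_published²)`.

## Synthetic cohorts

`generate_cohort` draws ages from Normal(61.5, 17.6²) years truncated
below at 18 (the USC pathway is an adult route; no minimum age is
published), sex female with probability 0.575, pathway labels from the
arm's referral distribution, and uniform referral dates. It emulates the
published cohort's marginals only: no within-patient correlation between
age, sex and pathway, no lesion-level detail, no deprivation geography.
Tests passing on these cohorts therefore establish the pipeline's
statistical machinery, not fidelity to any real patient population.

## Numerical choices and problem sizes

Bisection brackets start at [0.25, 1.6] and expand geometrically; common
random numbers make the objective deterministic and monotone. Calibration
uses 5 replications per evaluation; default tolerances are 0.15 d
(communication), 0.04 d (clinical) and 0.25 d (histopathology) — about one
Monte-Carlo SE of the respective estimator at the evaluation sample size.
The reproduction pipeline runs five fresh 1-year replications per arm per
scenario at 3,000 referrals/arm/year (≈15,000 patients per arm pooled), a
desk-scale setting at which every published aggregate is recovered within
its pooled-SE band in about a minute of CPU time. Ties in the event queue
break by insertion order; weekend capacity rounds down; zero-variance
collapse and empty-endpoint handling are covered by dedicated tests.

## Known limitations

- Stage-level delay splits within a pathway are modelling choices; only
  anchored totals are identified by published data.
- The PSA spread (12% SE) is a default, not an estimated quantity; the
  published PSA CI (£22–£60) is narrower than the default model's, and
  only the mean saving is treated as a reproduction target.
- Staffing levels, seasonality and communication-method delays are
  calibrated stand-ins; conclusions about capacity bottlenecks under
  *other* staffing levels require user-supplied counts.
- The comparator arm is itself a synthetic reconstruction in the source
  study; this package reproduces that reconstruction, not raw records.
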