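# Methods

`webrds` models the full life cycle of a web-based respondent-driven
sampling (web-RDS) study of a hidden population — here, users of
electronic nicotine delivery systems (ENDS) embedded in a large, mostly
ineligible urban population. The package has five layers: a synthetic
population generator, a recruitment simulator, an intake cleaning funnel,
a network-size (degree) instrument with deterministic imputation, and
RDS diagnostics and weighting. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Synthetic population

A population of `n_total` people contains a Bernoulli(`prevalence_eligible`)
subpopulation of eligible members (past-12-month ENDS use, age ≥ 15,
city resident). Only eligible–eligible contact ties are modelled: they are
the only edges a peer-referral chain can traverse.

**Degree distribution.** True degrees are drawn from a negative binomial
truncated to `[1, degree_max]` (default cap 99). The distribution family is
a modelling choice — only *reported* degrees are ever observed in a real
study — chosen because it reproduces a right-skewed, low-mode shape with
two interpretable knobs (mean, dispersion). The untruncated mean is
recalibrated by root finding so that the *truncated* mean equals the
configured `mean_degree`; targets too close to the cap for the given
dispersion are rejected as infeasible rather than silently missed.

**Graph construction.** Stubs are paired uniformly (configuration model);
self-loops and multi-edges are then repaired by degree-preserving edge
swaps, so the realized degree sequence equals the drawn one rather than a
simplification-biased version. Homophily is imposed per trait by biased
degree-preserving double-edge swaps: the number of accepted
same-label-increasing swaps scales with `homophily[trait] × |E|`, so 0
leaves the trait-blind configuration graph untouched (assortativity ≈ 0)
and larger values push assortativity up monotonically.

**Identities.** Every person gets a synthetic `first.last@example.test`
address from a name pool; collisions fall back to double surnames, never
digit suffixes, so no two *honest* addresses collide after the fraud
normalization (case folding, separator/plus-tag removal, trailing-digit
stripping). Likewise, eligible members receive pairwise-distinct dates of
birth. These uniqueness guarantees are deliberate: in this synthetic world
a repeated or near-duplicate identity in a roster is *always* an injected
signal. Real rosters contain benign birthday collisions and name twins, so
the cleaning performance measured here (recall ≥ 95%, false positives
≤ 1%) is a property of the heuristics under clean identities, not a
real-world error rate.

**Degree heaping.** Respondents report network sizes of at most 5
exactly; larger sizes are rounded to the nearest multiple of 5 with
probability `heap_prob` (default 0.5 — surveys report the *tendency*, not
a rate, so half is a neutral choice, exposed in config). Reports are
capped at 99.

## Recruitment simulator

Time advances in discrete days. Seeds (default 12), selected by
stratified round-robin over zones with age-group interleaving and a
preference for well-connected members, enroll on day 0. Every completer
receives 3 single-use alphanumeric invitation codes. Each coupon is
earmarked for a uniformly chosen not-yet-enrolled eligible neighbor (or,
with `p_ineligible_use`, an ineligible contact) and is presented after a
geometric delay (`spend_prob` per day). The contact participates with
probability `participation_prob(level)`, where the incentive level follows
`incentive_schedule` (default: low until day 60, then high, with
`participation_prob(low) = 0` — recruitment stalls completely until the
incentive is raised, reproducing the qualitative enrollment curve of a
low-then-raised gift-card design). Decliners retry later, so chains
resume when the incentive changes. Enrollment closes at the end of the
first day on which the count of valid completers reaches `target_n`.

Injected pathologies, each emitted to the roster and labelled in a hidden
truth table:

* **ineligible use** — a coupon spent on an ineligible contact; the
  attempt fails the screen and the coupon is invalidated;
* **duplicate participation** (`p_duplicate_attempt`) — an enrolled person
  attempts again under a mutated address (token inversion, digit
  append/increment, separator toggle), with their exact date of birth half
  the time and a ±1-day variant otherwise;
* **self-recruitment** (`p_self_recruit`) — a participant spends one of
  their own coupons under a fresh fake address but their own date of birth;
* **incomplete questionnaires** (`p_incomplete`, default 0.043) and
  **inconsistent device answers** (`p_inconsistent`, default 0.018), the
  observed rates of the emulated study.

Fraudulent attempts are incentive-gated like genuine participation (the
motive is the same gift card), and a coupon consumed by fraud is dead for
its intended recipient. Fraudulent attempts never enroll or receive
coupons; the recruitment forest contains exactly the valid completers.
Default fraud rates (`p_ineligible_use = 0.24`, `p_duplicate_attempt =
0.10`, `p_self_recruit = 0.02`) were calibrated once so that
ineligible + duplicate + self-recruitment attempts make up ≈ 31% of the
roster, the emulation target, and then frozen.

## Intake cleaning funnel

Five ordered stages, first-arrival-wins within each, every removal
carrying a stage and reason code:

1. **Automatic block** — exact repeat of invitation code, case-folded
   email, or date of birth against an earlier kept attempt (`auto_keys`
   configurable). Malformed rows are quarantined, never silently dropped.
2. **Manual-pattern review** — normalized-equality matches (token-sorted
   username tokens with trailing digits stripped: catches inversions,
   numeric variants, separator toggles), normalized edit distance ≤ 0.2
   (edlib, scaled by the longer string) *combined with* a date of birth
   within ±1 day, and self-recruitment (attempt DOB equals the coupon
   issuer's registration DOB under a different email, with the issuer
   resolved through the ledger). The 0.2/±1-day thresholds operationalize
   "implausibly similar" and are config knobs; ties resolve to the
   earliest kept attempt.
3. **Eligibility screen** — all three answers affirmative; missing answers
   are conservatively ineligible; spent coupons of ineligible attempts are
   invalidated in the ledger.
4. **Completeness** — unfinished questionnaires.
5. **Consistency** — eligible completers whose three device-use fields are
   all empty/negative despite the affirmative screen are excluded from
   analysis but retained in the recruitment forest.

Percentages in the funnel report are recomputed from counts and rounded
half-up to one decimal. The pipeline is idempotent on its own output, and
permuting arrival order changes which clone of an identity survives, never
how many.

## Network size and imputation

The instrument asks q1 (ENDS users known in the city) and q2 (those aged
≥ 15 — the operative degree). A report is implausible when it is zero or
smaller than the respondent's tree degree (recruiter plus recruits in the
forest). Implausible q2 is replaced by q1 when q1 passes the same test;
otherwise by the mean of the plausible q2 values, rounded half-up (degree
is a count) and floored at max(tree degree, 1) so imputation can never
produce a degree below the visible connections — artificially small
degrees would explode the reciprocal-degree weights. The valid mean is
frozen in a first pass, so results are independent of record order. Each
record carries a flag (`none` / `q1_substituted` / `mean_substituted`)
for a full audit trail.

## Diagnostics, weighting, design effect

* **Sample size**: n = ⌈p(1−p)/SE²⌉, times the design effect, times
  (1 + loss). The reference design (p = 0.5, SE = 0.05, deff = 2.5,
  loss = 20%) gives 100 → 250 → 300.
* **Wave statistics**: per-wave counts, maximum depth, unproductive seeds.
* **Convergence**: cumulative sample proportion (or mean) in enrollment
  order; `converged` iff every value in the final `window_frac` (default
  0.25) of enrollments deviates from the final value by less than `tol`
  (default 0.02). The defaults are conventions replacing a visual read of
  the plot, not empirical constants.
* **Recruitment homophily index** per category c: (share of c-recruiters'
  recruitments staying in c) / (sample share of c); 1 = proportionate
  mixing.
* **RDS-II (Volz–Heckathorn)**: weights ∝ 1/degree_final; the estimate for
  category c is Σ_{x_i=c} d_i⁻¹ / Σ d_i⁻¹. Seeds are included by default
  (flag to exclude). Chosen as the standard reciprocal-degree framework;
  it sits behind a small interface so alternatives can be added.
* **Chain-bootstrap design effect**: seeds are resampled with replacement,
  each carrying its whole chain; deff = bootstrap variance of the RDS-II
  estimate over p̂(1−p̂)/n. Whole-chain resampling respects the dependence
  structure without the complexity of tree bootstraps; with independent
  single-member chains and equal degrees it recovers deff ≈ 1.

## Estimator validation

Because the emulated study deliberately applied no estimator to its own
data, the weighting machinery is validated by parameter recovery
(`webrds.validation.estimator_recovery`): populations of 40,000 (10%
eligible, mean degree 8) receive a planted binary trait with expected
share 0.30 whose probability rises with degree; 100 pathology-free chain
samples of n = 500 are drawn across 10 populations. Chain referral
oversamples high-degree members, so the unweighted mean is biased upward
by ≈ +0.15 while the mean RDS-II estimate stays within ±0.05 of the
realized truth (typically ≈ −0.02; the residual is the usual
with-replacement approximation plus the finite sampling fraction).

## Reference bundle

`make_reference_fixture()` deterministically constructs (no RNG, no I/O)
an attempt roster, coupon ledger, forest and truth table whose cleaning
funnel, productivity split, coupon exhaustion, degree distribution, seed
composition and wave structure land exactly on the headline counts of the
emulated single-city study (508 → 330 → 324, 75/60/39 of 174, 113/218,
47.5%/25.6%/max 99, 12 seeds/5 unproductive/21 waves). Two printed counts
only reconcile under explicit conventions, both adopted here: recruiter
productivity counts recruits in the *analysis* set, and the
coupon-exhaustion denominator (218) is the number of participants with at
least one consumed coupon. The bundle is run with an intake configuration
whose automatic stage matches code and email only, routing
date-of-birth patterns (including self-recruitment) to manual review.

## Problem sizes and numerical choices

Default test/acceptance scales, chosen as package conventions: fraud
recall/precision over 20 simulated rosters (5 populations × 4 runs),
invalid-share Monte Carlo over 20–30 replicates, estimator recovery over
100 replicates, bootstrap deff at ≥ 300 replicates. All randomness flows
from a single top-level seed through named substreams, so every module is
reproducible in isolation; re-running a pipeline with an identical
manifest reproduces byte-identical CSVs. Rounding of printed percentages
and imputed means is half-up; degenerate inputs (no eligible network, no
plausible degrees, stalled seeds, empty rosters) raise explicit errors or
produce all-zero reports rather than silent output.

## Known limitations

The generator does not model benign identity collisions, ineligible-side
network structure, geographic coordinates, or time-varying questionnaire
content. The simulator's day-level geometric contact process is a
convenience, not a fitted model of referral latency. Cleaning thresholds
(edit distance 0.2, ±1 day) are conventions exposed as configuration, and
passing the synthetic recall/precision property says nothing about rosters
whose honest identities collide. RDS-II recovery is demonstrated under
pathology-free sampling from a single connected component; bottlenecked or
heavily heaped-degree settings will degrade it, which the convergence and
homophily diagnostics are there to reveal.
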