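# webrds

Simulation, intake cleaning, degree imputation and diagnostics for
**web-based respondent-driven sampling (web-RDS)** studies of hidden
populations.

Rare or stigmatized groups — here, users of electronic nicotine delivery
systems (ENDS) in a city where their sale is banned — cannot be reached
efficiently by household or telephone surveys. Web-RDS recruits them
through their own contact network: researcher-selected *seeds* complete an
online questionnaire and receive 3 single-use invitation codes for
eligible peers; recruits become recruiters in turn, wave after wave, until
a target sample size is reached. Because an incentive-driven open web
survey also attracts ineligible contacts, repeat participation under
disguised emails, and self-recruitment, the raw access log must pass a
multistep verification funnel before analysis, and self-reported network
sizes (the basis of RDS weighting) need plausibility checks against the
recruitment tree.

`webrds` packages that entire workflow for methodologists who want to
exercise, validate or re-deploy the design without any real survey data:

* **`webrds.population`** — synthetic city population with a hidden
  eligible subpopulation, truncated-negative-binomial contact degrees,
  controllable per-trait homophily, and degree heaping (multiples of 5,
  capped at 99) in self-reports;
* **`webrds.simulator`** — discrete-day chain-referral recruitment with
  coupon ledger, incentive-dependent participation (recruitment stalls at
  a low incentive and takes off when it is raised), and injected fraud
  with a hidden ground-truth table;
* **`webrds.intake`** — the cleaning funnel: automatic blocking of
  repeated codes/emails/dates of birth, manual-pattern review (name
  inversions, numeric variants, small edits with adjacent birth dates,
  self-recruitment), eligibility screen, completeness, device-answer
  consistency — every removal with a reason code;
* **`webrds.degrees`** — the two-question network-size instrument, tree
  degrees, and deterministic imputation of implausible reports;
* **`webrds.analysis`** — design-effect sample-size calculation, wave
  statistics, convergence traces, a recruitment homophily index, RDS-II
  (Volz–Heckathorn) reciprocal-degree weighting, and a seed-level chain
  bootstrap for the design effect;
* **`webrds.reporting` / `webrds.cli`** — one-command pipeline with a
  reproducibility manifest and a markdown study report.

The core weighting identity: with operative degree $d_i$, participant
$i$'s selection probability under chain referral is approximately
proportional to $d_i$, so the RDS-II estimate of the share of category
$c$ is

$$\hat p_c \;=\; \frac{\sum_{i:\,x_i=c} d_i^{-1}}{\sum_i d_i^{-1}},$$

and the design sample size is
$n = \lceil p(1-p)/SE^2 \rceil \times \text{deff} \times (1+\text{loss})$.

## Worked example

The package ships a deterministic reference bundle emulating a completed
single-city study. Run it through the funnel and diagnostics:

```python
from webrds import (
    REFERENCE_INTAKE_CONFIG, make_reference_fixture, run_intake,
    build_degree_records, impute_degrees, degree_summary, wave_statistics,
)
from webrds.simulator import coupon_exhaustion, recruiter_productivity
from webrds.reporting import analysis_person_ids

bundle = make_reference_fixture()
cleaned = run_intake(bundle.roster, bundle.ledger, REFERENCE_INTAKE_CONFIG)
print(cleaned.funnel.to_text())
```

```
Access attempts recorded           508
  blocked automatically            40 (7.9%)
  removed in manual review         38 (7.5%)
  ineligible at screen             78 (15.4%)
  [duplicate or ineligible total   156 (30.7%)]
  incomplete questionnaires        22 (4.3%)
Valid participants                 330 (65.0%)
  device-use inconsistencies       6 (1.8% of valid)
Analysis roster                    324
```

Of 508 access attempts, 156 (30.7%) were duplicates or ineligible, 22
(4.3%) abandoned the questionnaire, and 6 of the 330 valid participants
(1.8%) gave device answers contradicting their screen, leaving 324 for
analysis (the 6 stay in the recruitment forest).

```python
ids = analysis_person_ids(cleaned, bundle)
print(recruiter_productivity(bundle.forest, include=ids))  # {1: 75, 2: 60, 3: 39}
print(coupon_exhaustion(bundle.ledger))                    # (113, 218, 51.8)

degrees = impute_degrees(build_degree_records(cleaned.analysis_roster, bundle.forest))
s = degree_summary(degrees)
print(s["pct_le5"], s["pct_gt10"], s["max"], s["mode"])    # 47.5 25.6 99 5

ws = wave_statistics(bundle.forest)
print(ws.max_depth, ws.n_unproductive_seeds)               # 21 5
```

Of the 174 recruiters with at least one analyzed recruit, 75 (43.1%)
enrolled one, 60 (34.5%) two and 39 (22.4%) three; 113 of the 218
participants who spent any invitation (51.8%) spent all three. Half of
the analyzed respondents (47.5%) report knowing at most 5 other eligible
users (mode 5, maximum 99), and chains reach 21 waves while 5 of the 12
seeds recruited nobody.

The design sample-size calculation:

```python
from webrds import SampleSizeSpec, sample_size
sample_size(SampleSizeSpec(p=0.5, se=0.05, deff=2.5, loss_rate=0.2))
# (100, 250, 300)  — unadjusted, × design effect, + 20% loss
```

A full synthetic run (population → recruitment → cleaning → imputation →
report) from a JSON config:

```bash
webrds run-all --config examples/config.json --out out/
webrds power --p 0.5 --se 0.05 --deff 2.5 --loss 0.2
webrds fixture --out out/reference/
```

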