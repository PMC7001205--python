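# Methods

## Model structure

The model is a discrete-time Markov cohort simulation of renal replacement
therapy with five principal states: peritoneal dialysis (PD), hospital-based
haemodialysis (HOSP_HD), nocturnal home haemodialysis (HOME_HD), a combined
transplant/post-transplant state, and absorbing death. Cycles are one year;
the cohort enters at age 60 fully in one first-line dialysis modality and is
followed for `horizon_years` cycles (default 45, i.e. to age 105).

Structural assumptions, all encoded as hard constraints:

- switching HOME_HD → PD is impossible (no observed data for it);
- transplanted patients never return to dialysis;
- the annual transplantation probability is identical across dialysis
  modalities;
- mortality depends only on the current modality, not on history;
- utilities and mortality are age- and duration-independent.

Each alive state is expanded by *years-in-state* (tunnel states). This
carries exactly the duration information the payoffs need: annual costs are
split into an initial year on the modality versus subsequent years, and PD
patients are retrained every `pd_retraining_interval` (default 5) years.
Years-in-state is tracked exactly up to a configurable cap (default: the
horizon, 181 expanded states). If a smaller cap is set, the counter wraps
back by one retraining interval instead of saturating, which preserves both
the initial/subsequent distinction and the retraining phase; lifetime
results are insensitive to the cap (tested to 0.1%).

### Event composition within a cycle

The model composes competing risks multiplicatively in the fixed order
death → transplant → switch: `P(death) = p_d`,
`P(transplant) = (1−p_d)·p_tx`, and the remaining mass is split by the
origin's conditional switching row. The ordering is a modelling commitment,
not a flag: changing it changes every transition probability. The
transplant-first alternative was evaluated during development and produced
clearly worse agreement with the reference results (lifetime QALYs ~0.6 too
high), so the death-first composition is fixed.

### Rate conversion

Mortality inputs are rates in cases per 100 person-years. The default
conversion assumes a constant hazard within the year,
`p = 1 − exp(−rate/100)`; a linear convention `p = min(rate/100, 1)` is
available (`Conventions.rate_conversion`). The linear form is also what
makes the "certain death" degenerate configuration expressible exactly.

### Home-HD mortality

Two readings of the source material exist: the parameter table lists a
home-HD mortality rate (10.6/100 py), while the narrative asserts home-HD
patients are always admitted and switched to hospital HD before dying. The
default (`TABLE_RATE`) applies the table rate directly — the zero-mortality
reading produces home-HD QALYs around 11, far above the reported 8.4, so it
cannot be what generated the reference results. The routed variant
(`ZERO_ROUTED_VIA_HOSP`), which diverts the home-HD death mass to hospital
HD, is implemented behind the flag for completeness.

## Payoffs and discounting

Per cycle, the cohort accrues occupancy-weighted annual state costs
(initial-year or subsequent-year, by tunnel position; transplant follow-up
is likewise split) and occupancy-weighted utilities (1 − disutility; death
contributes zero). Annual totals are discounted at 3%/year and summed.

Two conventions deserve emphasis because the source leaves them open:

- **Discount exponent.** By default every annual total is discounted,
  including the first year's (`discount_start = 1`, end-of-year
  accounting). This choice reproduces all six published QALY totals to
  within ±0.05; starting the exponent at zero (first year undiscounted,
  available via the flag) overshoots the published QALYs by 0.19–0.30.
- **One-time event costs.** A complete event-cost layer exists —
  access-surgery insertion/removal (HD access blended 30% catheter / 70%
  arteriovenostomy), modality training, 5-yearly PD retraining, the
  transplant operation — with accrual rules on transitions: training plus
  access surgery when initiating a modality, removal of the old access on
  switching or transplantation, no access change between the two HD forms,
  nothing charged on death. It is **off by default**: the annual cost
  aggregates come from a bottom-up micro-costing study and evidently already
  include these items — charging the layer on top inflates every strategy's
  lifetime cost by 10–19%, whereas without it four of six published
  lifetime costs reproduce to within 1.5% (the home-HD strategy remains
  ~6–7.5% low under either setting; the residual is consistent with the
  original implementation allocating slightly more time to hospital HD and
  is not derivable from the printed inputs). `--event-costs` /
  `Conventions.include_event_costs` re-enables the layer, which is fully
  unit-tested and respected identically by both engines.

Half-cycle correction is off by default (the reference model shows no sign
of it); when enabled it half-weights the first and last cycle's state
accruals. Results are reported per patient; the 100,000-patient cohort size
is presentational.

A truncation caveat: because post-transplant mortality is low (2/100 py),
roughly 9–15% of the cohort (most for the home-HD strategy) is still alive
at the 45-year cap, almost entirely in the transplant state. The published
totals are consistent with this horizon; extending it materially increases
undiscounted survival but is heavily damped by discounting.

## Incremental analysis

Strategies are compared pairwise against PD: incremental cost, incremental
QALYs, and ICER when the QALY gain is positive. A strategy costing more and
yielding less than PD is *dominated* (no ICER reported); cheaper-and-better
is *dominant* (cost-saving). Threshold classification uses the
opportunity-cost willingness-to-pay band for the setting, USD 18,609–20,223
per QALY. An inconsistency in the source is worth recording: its narrative
quotes pairwise ICERs (≈12.0k provider, ≈10.4k societal) that contradict its
own results table (16,934 and 1,195); this package's provider ICER (≈10.6k)
happens to fall between the two accounts. No reconciliation is attempted.

## Deterministic sensitivity analysis

One parameter at a time is set to each end of its published 95% CI — the
four state disutilities and the six annual costs of the active perspective —
plus the discount rate over 0–5% (a conventional span; no interval is
published for it). Mortality and transplantation rates are registry-derived
and excluded by design. The outcome is the ICER of home HD versus PD; the
tornado table sorts parameters by the absolute ICER swing, with incremental
cost/QALYs at each bound as secondary columns. When home HD is cost-saving
(societal perspective) the raw negative ratio is reported rather than a
dominance label so the swing remains well-defined. Switching probabilities
carry Dirichlet evidence rather than CIs and are varied only by the PSA.

## Probabilistic sensitivity analysis

Per draw, jointly: PD and hospital-HD switching rows ~ Dirichlet(159,19,1)
and Dirichlet(131,26,10); home-HD stay probability ~ Beta with mean 0.950,
complement routed to hospital HD; every disutility and annual cost (both
perspectives, initial and subsequent year) ~ Gamma(shape, scale) as
published, with `shape × scale` verified against each printed mean to within
2%. Initial- and subsequent-year costs are drawn independently (no
correlation information is published). Sampled disutilities are clipped to
[0, 1]; mortality and transplant rates stay fixed. Default 10,000 draws; the
seed is mandatory.

The Beta parameterization is a documented reconstruction: the source prints
the stay probability "0.950" alongside a bare "412", which this package
reads as an effective sample size, i.e. Beta(412·0.95, 412·0.05). The test
suite checks that varying that sample size across 50–1000 leaves the
qualitative CEAC conclusions unchanged (hospital HD never optimal; home HD
favoured under the provider perspective at the threshold).

Acceptability curves evaluate net monetary benefit on a threshold grid of
0–60,000 USD/QALY in 500-USD steps with 18,609 and 20,223 inserted exactly;
ties split equally. Because the baseline provider ICER here (~10.6k) is
lower than the reference value (~16.9k), the probability that home HD is
optimal at 18,609 USD/QALY comes out higher than the published 60% (~0.80 at
10,000 draws), and under the societal perspective — where home HD is
cost-saving at baseline — PD's probability is correspondingly far below the
published 54%. These probabilities inherit the base-case incremental-cost
discrepancy discussed above and should be read with it.

## Validation

An independent patient-level Monte-Carlo simulator samples individual
trajectories from the *same* transition model object (per-cycle
distributions and per-transition event costs) that the cohort engine
propagates in expectation, with identical accrual timing and discounting.
Agreement within 3 Monte-Carlo standard errors at n = 200,000 is asserted
for cost and QALYs, per strategy, on the baseline and on random synthetic
configurations — so the two propagation methods cross-check each other while
sharing only the parameterization.

The synthetic-configuration generator draws structurally valid random models
(mortality U(0,40)/100 py, transplant rate U(0,0.2), Dirichlet switching
rows respecting the structural zeros, disutilities U(0,0.6), costs
log-uniform over 10³–10⁵ USD with initial ≥ subsequent, PSA distributions
moment-matched exactly). It emulates the model's *structure*, not any
registry's joint distributions: passing property tests demonstrates engine
correctness (conservation, monotone absorption, limit identities,
serialization round-trips), not real-world calibration. Named degenerate
configurations (IMMORTAL, INSTANT_DEATH, NO_SWITCHING, FREE_CARE) pin down
closed-form limits.

## Numerical notes

- Switch-row sums and cohort conservation are enforced to 1e-9.
- Dominance ties: zero incremental QALYs with positive incremental cost is
  classified dominated; exact zero/zero is "equivalent".
- NMB ties in the CEAC are split equally among maximizers (1e-9 tolerance).
- The printed SD for the transplant disutility (0.492) is inconsistent with
  its own CI and Gamma parameters (≈0.046); exported SDs are derived from
  the Gamma (shape, scale) instead.
- Config files are versioned YAML; packaged baselines are code constants, so
  no on-disk asset can break them. Validation reports *all* violations with
  machine-readable paths rather than failing at the first.

## Known limitations

- No age- or duration-dependent mortality or utility; no PD subtypes
  (CAPD/APD); no capital/overhead costs — deliberate, matching the model's
  scope.
- The residual ~7% understatement of the home-HD strategy's lifetime cost
  relative to the reference results is unexplained by any documented
  convention combination (see the event-cost discussion above).
- Extended dominance / efficiency-frontier analysis is not the headline
  output (pairwise comparison against PD is); no EVPI computation.
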