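# renalcea

A lifetime Markov cohort model for the cost-effectiveness of first-line
dialysis strategies in end-stage renal disease (ESRD), built for settings
operating a "Peritoneal Dialysis First" policy. It compares three first-line
renal replacement strategies — peritoneal dialysis (PD), hospital-based
haemodialysis (HD) and nocturnal home HD — on lifetime discounted cost (2017
USD) and quality-adjusted life-years (QALYs) from both the healthcare-provider
and the societal perspective, and quantifies decision uncertainty with
one-way (tornado) and probabilistic sensitivity analyses.

It is intended for health-economics researchers and HTA analysts who want a
transparent, scriptable and fully tested re-implementation of this class of
decision model, with every structural convention exposed as a flag.

## The model

Five health states: `PD`, `HOSP_HD`, `HOME_HD`, `TRANSPLANT` (combined
transplant/post-transplant) and absorbing `DEATH`. A cohort enters at age 60
entirely in one dialysis modality and is propagated in annual cycles. Within
a cycle, competing events compose multiplicatively in a fixed order — death,
transplantation, modality switching:

    P(death)        = p_d            (modality-specific, from rates per 100 person-years)
    P(transplant)   = (1 − p_d) · p_tx      (p_tx identical across modalities)
    P(switch to s)  = (1 − p_d)(1 − p_tx) · q_s

Switching from home HD back to PD is structurally impossible, and
transplanted patients never return to dialysis. Each alive state is expanded
by years-in-state (tunnel states) so that the first year on a modality can
carry a different annual cost than subsequent years and PD retraining can
recur every 5 years. Annual costs and utilities (utility = 1 − disutility)
accrue per cycle, are discounted at 3% per year and summed:

    Cost  = Σ_t c_t / (1+r)^(t+1),   QALYs = Σ_t u_t / (1+r)^(t+1)

Pairwise comparison against the PD reference yields incremental cost ΔC,
incremental effectiveness ΔE and the incremental cost-effectiveness ratio
ICER = ΔC/ΔE, with dominance labels when signs disagree. The probabilistic
sensitivity analysis re-draws switching rows from Dirichlet(observed counts),
the home-HD stay probability from a Beta, and every disutility and annual
cost from Gamma distributions, then reports cost-effectiveness acceptability
curves via net monetary benefit (NMB = λ·QALYs − cost).

## Worked example

```python
from renalcea import baseline_config, run_base_case

result = run_base_case(baseline_config())   # provider perspective
print(result.to_frame().round(2).to_string(index=False))
```

```
perspective strategy  cost_usd  incremental_cost_usd  qalys  incremental_qalys  icer_usd_per_qaly     label
   PROVIDER       PD  76573.16                   NaN   7.11                NaN                NaN REFERENCE
   PROVIDER  HOSP_HD 143007.76              66434.61   6.60              -0.51                NaN DOMINATED
   PROVIDER  HOME_HD  90529.76              13956.61   8.42               1.31           10625.75      ICER
```

Read: a patient starting on PD accrues a discounted lifetime cost of about
USD 76.6k and 7.11 QALYs. Hospital HD costs 66.4k more and yields 0.51 fewer
QALYs — it is dominated by PD. Nocturnal home HD yields 1.31 extra QALYs for
13.96k extra cost, an ICER of roughly USD 10.6k per QALY gained, well below
the local opportunity-cost willingness-to-pay threshold of USD 18,609/QALY,
so home HD is cost-effective as a first-line strategy. Under the societal
perspective (`baseline_config("SOCIETAL")`) home HD is both cheaper and more
effective than PD (cost-saving).

The same analyses are available from the shell:

```bash
renalcea base-case --perspective societal --out out/
renalcea dsa --out out/                      # tornado table, widest swing first
renalcea psa --seed 7 --n-draws 10000 --out out/   # draws, CEAC, summary JSON
renalcea validate my_config.yaml
renalcea demo --seed 1                       # synthetic-config smoke run
```

Every structural convention (rate-to-probability conversion, home-HD
mortality handling, half-cycle correction, the one-time event-cost layer for
access surgery/training/retraining, discount conventions, horizon) is a
field of `Conventions` and a CLI flag; outputs are CSV/JSON with a manifest
recording the exact configuration.

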