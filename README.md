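# vte-sim

Microsimulation decision analysis of extended anticoagulation after venous
thromboembolism (VTE).

After at least three months of anticoagulation for VTE, treatment can be
stopped or continued indefinitely. Continuing prevents recurrent VTE but
raises the risk of clinically relevant bleeding (the ISTH composite of
major and clinically relevant nonmajor bleeding). `vte-sim` asks: *at what
exchange rate between the two harms does extending treatment maximize
quality-adjusted life years (QALYs)?* It is intended for health-economics
and clinical-epidemiology researchers studying treatment-duration policy.

## The model

1. **Synthetic cohort.** 10,000 virtual patients are drawn so their
   marginals match a published post-anticoagulation VTE cohort (mean age
   60.2 y, 36% female, 89% unprovoked index events, 48% PE, …), with
   estrogen-provoked events restricted to women and provoked events
   implying a VTE history.
2. **Risk prediction.** A calibrated surrogate risk model assigns each
   patient 5-year risks of recurrent VTE and clinically relevant bleeding
   off treatment (calibrated to median 8.9% / 3.4% with the published IQRs
   and ranges). Extended anticoagulation rescales the risks as
   proportional hazards on the cumulative risk,
   `p_on = 1 − (1 − p_off)^HR`, with defaults `HR_vte = 0.15`,
   `HR_bleed = 2.0` (full-dose DOAC). This yields per-patient absolute
   recurrence risk reduction (ARR) and bleeding risk increase (ARI).
3. **Decision rule.** For a ratio `r`, extended treatment is assigned when
   `ARR > r × ARI` — a bleed is valued `r` times a recurrence. The grid
   `r = 0.1 … 10` (step 0.1) is compared against guideline standard of
   care (treat unless the index event was provoked by a major transient
   factor or the ACCP bleeding-risk factor count is ≥ 2).
4. **Microsimulation.** Each patient is simulated through twenty 3-month
   cycles with states for recurrent PE/DVT, CRNMB, major bleeding,
   intracranial hemorrhage, their chronic sequelae (PTS, CTEPH, post-ICH)
   and death (Weibull background mortality calibrated to 10.6% 5-year
   mortality). QALYs accrue per cycle from state utilities minus acute
   disutilities.
5. **Optimal ratio and uncertainty.** The ratio with the most QALYs is the
   optimum. A probabilistic analysis redraws probabilities, utilities and
   treatment effects from beta / log-normal / gamma distributions across
   replications (common random numbers elsewhere) and reports the mean
   optimal ratio with a 2.5–97.5 percentile interval, plus one-way
   sensitivity and scenario analyses (reduced-dose DOAC, random
   discontinuation, a 0.99-per-cycle treatment disutility, uniform
   mortality).

## Worked example

```python
import numpy as np
from vte_sim import (build_base_case, ratio_policy, guideline_policy,
                     run_cohort, RatioGrid, sweep_ratios, optimal_ratio)

base = build_base_case(seed=1)          # 10,000 patients, calibrated
p = base.profiles
print(round(np.median(p.p_vte_5y_off) * 100, 1))   # 8.9  (% 5-y recurrence risk, untreated)
print(round(np.median(p.p_bleed_5y_off) * 100, 1)) # 3.4  (% 5-y bleeding risk, untreated)
print(round(ratio_policy(p, 0.90).mean() * 100, 1))   # 100.0 (% treated at ratio 0.90)
print(round(guideline_policy(base.cohort).mean() * 100, 1))  # 63.0 (% treated, standard of care)

sweep = sweep_ratios(base.cohort, p, RatioGrid.base(),
                     base.mort_cycle, base.params, seed=1)
print(optimal_ratio(sweep))             # 1.2  (deterministic point estimate)
```

The first two numbers are the calibrated medians of the untreated 5-year
risk distributions. At ratio 0.90 essentially the whole cohort clears the
benefit–harm bar, versus 63% treated under the guideline rule. The
deterministic single-run optimum (1.2) carries substantial Monte Carlo
noise; the probabilistic mean and interval from `run_psa` are the primary
estimate.

The same analyses are available from the shell:

```bash
vte-sim generate --n 10000 --seed 42 --out cohort.csv
vte-sim psa --reps 1000 --seed 42 --out results/
vte-sim scenario --scenario reduced_dose --reps 400 --seed 42 --out results/reduced/
```

## Layout

- `src/vte_sim/cohort.py` — synthetic cohort generation and CSV I/O
- `src/vte_sim/risk.py` — surrogate risk model, calibration, treatment
  effects, Weibull mortality
- `src/vte_sim/policies.py` — ratio rule, ACCP bleeding score, guideline
  policy
- `src/vte_sim/microsim.py` — vectorised state-transition engine and its
  deterministic expectation twin
- `src/vte_sim/psa.py` — ratio sweep, probabilistic / one-way / scenario
  analyses
- `src/vte_sim/reporting.py`, `src/vte_sim/cli.py` — tables, figure data,
  manifests, `vte-sim` CLI
- `docs/methods.md` — modelling assumptions, parameter defaults and
  limitations
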