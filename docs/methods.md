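# Methods

## Scope and structure

`vte-sim` models the decision to stop or extend anticoagulation after the
initial (≥3-month) treatment of venous thromboembolism. The pipeline is:
synthetic cohort → individual 5-year risks → treatment assignment →
individual-level state-transition simulation → QALY-optimal benefit–harm
ratio with uncertainty analysis. No patient-level data ship with the
package; the cohort generator reproduces published summary statistics.

## Synthetic cohort

Covariates are sampled independently given their published marginals:
binary covariates as Bernoulli, continuous covariates as truncated
normals (age 60.2 ± 14.3 on [18, 100], BMI 31.0 ± 6.7 on [15, 60], SBP
118 ± 16.3 on [80, 220], Hb 14.2 ± 1.5 on [8, 20], eGFR 82.6 ± 21 on
[15, 150], platelets 240.5 ± 65.2 on [50, 600]). The truncation bounds
are physiological-plausibility choices; truncation shifts the age mean by
under 0.1 years. Two structural constraints are imposed without
disturbing the marginals in expectation:

* estrogen-provoked index events are assigned only to women
  (P(estrogen | female) = p_estrogen / p_female);
* a provoked index event implies a history of VTE (the source cohort's
  inclusion criterion); the history prevalence among unprovoked patients
  is lowered so the overall 36.14% marginal is preserved.

The published provocation counts sum to more than the cohort size
(8862 + 601 + 571 = 10,034 per 10,000), so the three category
probabilities are normalised to sum to one (88.32% / 5.99% / 5.69%).
History of cancer, liver disease, alcohol abuse, recent surgery and
pregnancy are structural zeros. No other covariate correlations are
modelled: the published table reports only marginals, and marginal
alignment is the fidelity criterion. This means the synthetic cohort
lacks the age–comorbidity and comorbidity–comorbidity correlations of
real populations; tests that pass on it validate the machinery, not the
joint distribution of any real cohort.

## Individual 5-year risks

The external risk score used in the original analysis is not reproduced;
its published coefficients live in a separate publication. Instead each
outcome (recurrent VTE; clinically relevant bleeding, ISTH composite) has
a surrogate linear predictor whose directions follow clinical priors
(recurrence ↑ with VTE history, male sex, unprovoked events, PE index,
age, BMI; bleeding ↑ with age, prior bleeding/stroke, antiplatelets,
NSAIDs, cardiovascular disease, diabetes, anemia, renal impairment). The
predictor is centred at its cohort median, scaled by its IQR and mapped
through a logistic link whose intercept and slope are solved (Brent's
method) so the cohort's predicted off-treatment distribution matches the
published anchors exactly at the median and IQR width (recurrence: median
8.9%, IQR 7.8–9.6%; bleeding: 3.4%, 2.8–4.2%); predictions are clipped to
the published ranges (4.6–13.4% and 1.1–6.1%). Only the location and
spread are calibrated, so real risk-score coefficients can be substituted
through the weight dictionaries without code change.

Extended anticoagulation rescales cumulative risk as a proportional
hazard: `p_on = 1 − (1 − p_off)^HR`. Defaults: HR 0.15 (recurrence) and
2.0 (bleeding) for full-dose DOAC; 0.20 and 1.2 for reduced dose. These
are literature-informed defaults, fully config-exposed and swept in the
sensitivity analyses; they are the single most influential assumption
(see Limitations).

Per-cycle probabilities assume a constant hazard over the horizon:
`p_cycle = 1 − (1 − p_5y)^(1/20)`, so recurrence/bleeding incidence does
not decay over the five years.

## Background mortality

Weibull survival with shape 1.2 and per-patient scale
`scale_i = scale0 · exp(−lp_i / shape)`, where `lp` adds 0.7 per decade of
age and 0.3 for male sex (log-hazard scale). `scale0` is calibrated so
the cohort-mean 5-year mortality equals 10.6%, chosen so that background
plus event-fatality deaths land near the published total of ~1070–1092
per 10,000. The conditional per-cycle death probability is
`1 − S(t_{k+1})/S(t_k)`. The uniform-mortality scenario zeroes both
covariate effects (same death rate for everyone, same cohort mean).

## Treatment policies

* **Ratio rule**: treat iff `ARR > r × ARI`, strict inequality — "benefit
  outweighs weighted harm" reads as strict dominance, so ties are not
  treated. Patients with `ARI = 0` and any benefit are treated at every
  ratio (the rule's limit). Grid 0.10–10.00 step 0.10, extended to 50 for
  the reduced-dose scenario; ratios below the largest all-treated ratio
  or above the smallest none-treated ratio are pruned as uninformative.
* **Guideline standard of care**: treat unless the index event was
  provoked by a major transient factor (surgery/trauma/immobilization —
  the only major transient category the covariates support; estrogen
  counts as minor) or the ACCP bleeding-risk factor count is ≥ 2. The
  factor list is restricted to covariates the cohort carries: age > 65
  (one more factor when > 75), prior bleeding, prior stroke, diabetes,
  anemia (Hb < 13 g/dL men, < 12 women), eGFR < 60, platelets < 150,
  antiplatelet therapy, NSAID use. Those thresholds are declared
  defaults. With the synthetic marginals this yields ≈ 33% high-risk and
  ≈ 63% treated; a real cohort with correlated comorbidity (and factors
  such as reduced functional capacity that these covariates cannot
  express) would classify more patients high-risk and treat fewer.

## State-transition engine

Twenty 3-month cycles. Per cycle, in order: background death check →
bleeding → recurrence → sequelae; at most one acute event per cycle
(same-cycle double events are negligible at 3-month resolution, and the
fixed order makes runs reproducible). Acute events last one cycle.
Severity splits and consequences (all config-exposed defaults): bleeding
is CRNMB vs major 0.7 : 0.3, major → ICH 0.15; case fatality 0.40 (ICH),
0.08 (other major), 0.05 (recurrent PE); survivors acquire chronic states
with probability 0.60 (post-ICH), 0.03 (CTEPH after PE), 0.25 (PTS after
DVT); recurrence is PE vs DVT 0.48 : 0.52, mirroring the cohort's index
distribution. Chronic states and death are absorbing (a newer chronic
state overwrites an older one — the latest event dominates quality of
life).

Utilities: event-free 0.85; PTS 0.75; CTEPH 0.65; post-ICH 0.55; acute
one-cycle disutilities PE 0.20, DVT 0.15, major bleed 0.20, CRNMB 0.05.
A cycle's utility is the start-of-cycle state utility minus any acute
disutility, floored at zero, times 0.25 years; a cycle in which the
patient dies accrues nothing. No half-cycle correction and no
discounting (5-year horizon).

Treatment dynamics: an on-treatment major bleed (including ICH) stops
anticoagulation permanently; an off-treatment recurrence restarts it for
the remaining horizon; random discontinuation (scenario) is permanent.
All three are config flags; the first two defaults mirror usual clinical
behaviour and are declared assumptions.

Randomness: one uniform number per patient × cycle × decision slot, drawn
from a generator keyed by the run seed and indexed by patient id. Results
are therefore invariant to cohort ordering, and identical uniforms can be
reused across policies (common random numbers), so two assignments differ
only through patients whose treatment flag flips.

A deterministic twin (`expectation_oracle`) propagates the exact joint
distribution over (base state × treatment status) through the same event
tree, giving closed-form expected events, deaths and QALYs; the test
suite holds the stochastic engine to within 3 standard errors of it at
10⁵ replicates.

## Optimal ratio, probabilistic and scenario analyses

The optimal ratio is the argmax of total QALYs over the pruned grid, ties
to the lowest ratio. The probabilistic analysis draws parameters per
replication — probabilities and utilities from beta distributions
parameterised by (base value as mean, effective sample size), hazard
ratios log-normal around the base value (σ 0.25 / 0.20), disutilities
gamma with CV 0.3, and the 5-year mortality target beta with a small
effective sample size (20) reflecting the wide published death
uncertainty — then reruns the whole sweep. The microsimulation uniforms
are shared across replications as well as ratios: replication-to-
replication variation is purely parameter-driven, and degenerate
(zero-variance) distributions reproduce identical replications. The grid
is pruned once on the base-case profiles so all replications share one
ratio axis. Summary: mean of per-replication argmax ratios, 2.5/97.5
percentile interval, running-mean convergence trace. Defaults: 1000
replications base case, 400 for scenarios (the base case converges well
before 400); the test suite and the acceptance script use 100–200
replications to keep desk runtimes at a few minutes, stated here as the
package's own scaling choice.

Scenarios: reduced-dose DOAC (HR 0.20/1.2, grid to 50); random
discontinuation at the per-cycle equivalent of 10%/year, permanent, with
off-treatment risks thereafter; treatment disutility as a ×0.99
multiplier on every on-treatment cycle's utility (a subtractive 0.99
would annihilate utility, so the phrase is read multiplicatively);
uniform mortality as above.

## Numerical choices

* Calibration solves the logistic slope by Brent bracketing on [10⁻⁹, 50]
  with xtol 10⁻¹²; the intercept is exact at the target median by
  construction. Re-calibration is idempotent.
* Mortality calibration solves log-scale0 by Brent on [ln 0.01, ln 10⁴].
* `1 − (1 − p)^x` transformations are evaluated directly; the per-cycle
  inverse property holds to machine precision.
* Degenerate inputs: p = 1 cannot be rescaled by HR ≠ 1 (domain error);
  zero-spread calibration targets put every patient at the intercept
  risk; an empty pruned grid, empty cohort or mismatched assignment raise
  immediately.

## Known limitations

* The treatment-effect hazard ratios and all event/utility parameters are
  defaults, not fitted values; the QALY surface over ratios is nearly
  flat (<1% variation), so the optimal ratio is highly sensitive to them.
  Under the defaults the smallest per-patient ARR/ARI is ≈ 1.0, so no
  ratio below 1.0 leaves anyone untreated and the probabilistic mean
  optimum lands near 1.1–1.4.
* Marginal-only cohort realism, and an ACCP factor list limited to the
  available covariates, overstate guideline-eligible patients relative to
  a real population (≈ 63% treated under standard of care here).
* Risks are constant over the horizon; recurrence and bleeding rates that
  decay with time would favour shorter treatment.
* Patients can have multiple events driven by the same first-event risks,
  which slightly overstates event counts in high-risk patients.
* No costs, no discounting, no competing-risk estimation from
  time-to-event data.
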