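# Methods

## Model structure

Three mutually exclusive health states — progression-free (PFS),
progressed disease (PD), dead — describe a cohort of patients with
advanced gastric or gastro-oesophageal junction adenocarcinoma receiving
second-line ramucirumab + paclitaxel (RAM) or placebo + paclitaxel (PLA).
The engine is a partitioned survival model: state occupancy at each cycle
boundary is read directly off two parametric curves per arm,

    occ_PFS(u) = S_PFS(t_u),  occ_dead(u) = 1 − S_OS(t_u),
    occ_PD(u)  = S_OS(t_u) − S_PFS(t_u)   (clamped at 0 if the fits cross),

so both fitted curves are used without extra structural assumptions.
Clamping is counted; if more than 5% of cycles need it, the curve pair is
rejected as inconsistent with the state model. A per-cycle Markov
formulation driven by the conditional probabilities
`stay(u) = S(t_{u+1})/S(t_u)` is included as a cross-check engine
(`build_trace_markov`); because everyone alive faces the overall-survival
event probability, it telescopes to the same trace, and a test asserts
this equivalence. The conditional form
`(1 + e^θ u^κ)/(1 + e^θ (u+1)^κ)` is exposed under its truthful name,
`stay_probability` — it is the probability of *remaining* event-free over
a cycle, not a progression probability, however it may be labelled
elsewhere.

## Survival curves

Both endpoints use the two-parameter log-logistic survival function
`S(t) = 1/(1 + e^θ t^κ)` with `κ > 0` and median `exp(−θ/κ)`. The
baseline parameters (months):

| arm | endpoint | θ | κ | implied median (mo) |
|-----|----------|--------|-------|------|
| RAM | PFS | −3.157 | 2.058 | 4.64 |
| PLA | PFS | −2.268 | 2.042 | 3.04 |
| RAM | OS  | −4.671 | 2.089 | 9.36 |
| PLA | OS  | −3.337 | 1.681 | 7.28 |

The month time-unit reading is adopted because only it makes the implied
medians line up with the trial arms these curves describe (second-line
gastric cancer: OS ≈ 9.6 vs 7.4 months). Cycle indices convert to months
as `t_u = u·28/30.4375`. `t^κ` is evaluated in log space (logistic
sigmoid of `θ + κ ln t`), so no overflow occurs at any horizon.

Fitting: `fit_loglogistic` performs censored maximum likelihood on
pseudo-individual-patient data via `lifelines.LogLogisticFitter`
(re-parameterised to (θ, κ) with delta-method standard errors), or
least squares on digitized curve points via `scipy.optimize.least_squares`
with a logit-linear starting value. MLE requires ≥ 10 observations and
≥ 2 events; degenerate inputs raise `FitError`. Parameter recovery is
verified by simulation (200 replicates, n = 500, ~20% censoring: truth
within 3 SE in ≥ 95% of fits).

## Time grid, discounting, outcomes

28-day cycles over 5 years → `floor(5·365/28) = 65` whole cycles (no
partial final cycle). Discount weight `(1.03)^(−u·28/365)`; the 3%/year
rate applies to costs and QALYs, with a flag (default off) to also
discount life-years, since published practice on LY discounting is mixed.
Half-cycle correction is trapezoid averaging of adjacent-boundary values,
applied uniformly to life-years, QALYs and state-dependent costs; tests
assert the corrected totals lie strictly between the left and right
Riemann sums. Utilities: 0.68 (PFS), 0.42 (PD), 0 (dead), per year of
occupancy.

## Costing (2018 USD)

While progression-free (on treatment, per the trial's treat-to-progression
design): ramucirumab at the scenario price per 4-week cycle (8 mg/kg on
days 1 and 15 → 1040 mg/cycle at 65 kg; per-mg and per-cycle prices
interconvert through that quantity), paclitaxel 80 mg/m² on days 1, 8, 15
at $116.2/30 mg (continuous per-mg pricing, no vial rounding),
administration $18.6 per infusion day (3 days/cycle; the day-1/15
co-infusions add no extra unit), one laboratory panel $88.2 per cycle,
and CT at $105.9 every 6 weeks → 2/3 unit per cycle. In PD: best
supportive care $1425.1 per cycle. Adverse events: the five grade-3/4
categories enter as a one-off expected cost at model entry
(Σ risk × episode cost ≈ $244.9 RAM / $117.2 PLA), because the risks are
whole-treatment incidences, not per-cycle hazards. No separate terminal /
hospice cost item is modelled: no value is published for it. Total cost is
linear in every unit price (tested), and the placebo arm is independent of
the ramucirumab price.

## Incremental analysis and value-based pricing

`compare` reports ΔC, ΔLY, ΔQALY, ICERs and `NMB = λΔQALY − ΔC`, with
standard dominance flags; a |ΔQALY| below 1e-9 makes the ICER undefined
(explicitly signalled, NMB still returned). Because ΔC is affine in the
per-cycle drug price with slope equal to the discounted half-cycle-
corrected RAM-treated (PFS) cycle count (~7.25 cycles), `threshold_price`
inverts ICER(p) = λ by bisection to $0.01 and cross-checks against the
closed form; disagreement raises. The bracket may extend below zero: a
negative algebraic threshold price is meaningful — it says even a free
drug cannot meet the threshold because the added progression-free time
itself costs more than the threshold values its QALYs. The CLI refuses to
report a negative price unless `--allow-negative` is passed.

## Sensitivity analysis

Probabilistic: all cost items, AE risks, utilities, weight and body
surface area are sampled (lognormal for costs/weight/BSA, beta for risks
and utilities), moment-matched to mean = baseline and SE = 10% of the
baseline; the discount rate and the survival parameters stay fixed (the
latter carry no published uncertainty). Weight/BSA sampling can be
switched off (`default_distributions(include_weight_bsa=False)`) since
descriptions of the original scheme are ambiguous on them. Utility draws
violating `u_PD ≤ u_PFS` are re-drawn in pairs and counted. Each of the
n = 1000 iterations re-runs both arms end to end; a fixed numpy
`default_rng` seed makes replays bit-identical. Acceptability at λ is the
fraction of iterations with positive NMB; `ceac_by_price` reuses the same
seed at every price (common random numbers) so the price–acceptability
curves are monotone draw-by-draw.

One-way: each parameter moves to the low/high end of its published range
(ranges with scrambled ±20%/±50% footnotes are taken as printed) with all
else at baseline; the ramucirumab price, which has no published range, is
varied ±50% around the scenario price. Bars are sorted by ICER swing;
bars crossing an undefined-ICER region are truncated with a warning.

## Synthetic data

`simulate_ipd` draws event times by inverse CDF
(`t = exp(−θ/κ)(1/U − 1)^{1/κ}`), censored by min(administrative cutoff,
exponential censoring draw); defaults (30-month cutoff, 0.01/month hazard)
emulate trial-like follow-up. `km_estimate` wraps the product-limit
estimator; `add_digitization_noise` adds ±3σ-truncated Gaussian jitter on
the survival scale and restores monotonicity by isotonic (least-squares)
repair, mimicking hand-digitization of published curves while keeping the
point count stable. The generator reproduces the statistical structure the
fitting stage assumes — independent censoring, exact log-logistic truth —
but none of the real-world violations (informative censoring, covariate
mixtures, digitization bias at plateaus), so green tests certify the
pipeline's internal correctness, not the adequacy of the log-logistic for
any particular trial. An end-to-end test (simulate → KM → refit → cohort
model) requires the refitted model's LY/QALYs within 2% of the
truth-parameter model at n = 5000.

## Fidelity to the source analysis

The published inputs do not reproduce the published outputs, and the
package sides with the inputs. Under the conventions above, the RAM arm
accrues 1.082 undiscounted LY and 0.586 discounted QALYs (reported: 1.22 /
0.64; within ~11% and ~8%, plausibly a time-grid/correction variant), but
the between-arm increments are ΔLY = 0.105 and ΔQALY = 0.091 against
reported values of 0.04 / 0.07 — which are themselves mutually
inconsistent with the reported ICER pair ($/LY × ΔLY ≠ $/QALY × ΔQALY).
The curve-implied 2.1-month OS median gap cannot yield ΔLY = 0.04 on a
5-year horizon under any accrual convention tried (left/right/trapezoid
sums, month-vs-cycle grids, alternative cost–state mappings). Consequently
the base-case ICERs here ($49.7k and $78.3k/QALY at $244 and $604 per
cycle) exceed the reported $26,014 / $56,260, the mainland threshold price
is negative rather than $244, and the PSA acceptability at the reported
prices is far from the reported ~50%. The convention-independent
identities — threshold-price self-inversion to < $1/QALY, affine ICER,
near-median acceptability at the model's *own* threshold price — all hold
and are tested. Three acceptance tests that pin the reported ICER,
acceptability and tornado-ranking values are intentionally left failing
rather than forcing agreement.

## Numerical choices and limitations

Survival evaluated in log space; probabilities exact at t = 0; bisection
tolerance $0.01 with closed-form guard; trace conservation enforced to
1e-12. Cohort proportions only (no microsimulation); two strategies only
(no frontier); no dose interruptions/reductions, subsequent-line therapy
costs, EVPI, or correlated-parameter sampling; log-logistic is the only
built-in family. All tabular outputs are delimited text; every CLI run
writes a YAML manifest (config snapshot, seeds, file checksums, version,
timings) for auditability.
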