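# Methods

## Model overview

`natalcap` models, for each country independently, a static one-way chain:

```
coverage scale-up → PAF → Δ prevalence of LBW/PTB → school years/child
                 → cohort school years → secondary completers
                 → NPV lifetime income gain
```

The chain is linear and deterministic: it quantifies average population
behaviour at fixed parameter values, with no dynamic feedback (no fertility
response, no labour-market general equilibrium, no interaction between
interventions). Scenario estimates for different interventions must not be
summed: they share births and would double-count overlapping target
populations.

The population attributable fraction of moving coverage from `p_cur` to
`p_tgt` at relative risk `RR` is

```
PAF = (p_tgt − p_cur)(1 − RR) / (1 + p_cur (RR − 1)).
```

The denominator is the relative baseline outcome prevalence under current
coverage, so the PAF is exactly the proportional change in outcome
prevalence implied by a two-arm risk model; the test suite verifies this
against an individual-level microsimulation. Scenarios never model coverage
*reduction*: if current coverage already exceeds the target the PAF is
clamped to 0 with a warning.

## Intervention rules

| intervention | mediator | baseline coverage | target population |
|---|---|---|---|
| IFA | LBW | national survey coverage | all pregnancies |
| calcium | PTB | 0 | all pregnancies |
| MMS | LBW | 0 (for MMS as such) | all pregnancies |
| BEP | LBW | 0 | underweight women (BMI < 18.5) |

BEP's effective target coverage is `target × underweight_prev`: the
intervention is modelled for underweight individuals, not for whole
populations crossing a prevalence threshold.

MMS effects are anemia-stratified and measured **relative to IFA**. For a
target `t` and current IFA coverage `c`, the covered fraction splits into
switchers `min(c, t)` (risk `RR_σ` versus status quo) and newly covered
women `max(0, t − c)` (multiplicative combined risk `RR_σ × RR_IFA` versus
no supplementation). Stratum reductions are weighted by anemia prevalence.
The `min`/`max` partition extends the description to targets below current
coverage; at `t ≥ c` it reduces to the plain switching-plus-new rule. A
consequence checked by tests: calcium/BEP outputs are exactly linear in the
target (the 90%:50% ratio is exactly 1.8), while MMS is super-linear in the
presence of baseline IFA coverage, because newly covered women carry the
larger combined effect.

## Default evidence base

Relative risks (95% CI): IFA→LBW 0.84 (0.69, 1.03); calcium→PTB 0.76
(0.60, 0.97); BEP→LBW 0.83 (0.61, 1.12); MMS→LBW 0.81 (0.74, 0.89) among
anemic and 0.91 (0.85, 0.98) among non-anemic women. Schooling deficits:
−0.29 (−0.48, −0.10) years per LBW birth and −0.32 (−0.57, −0.06) per PTB
birth. All registry values are overridable from the run configuration so an
updated meta-analysis requires no code change.

CIs are converted to SEs as half-width / 1.959964, on the log scale for
ratios. Sampling laws for the bootstrap are log-normal for relative risks
and normal for additive effects — the conventional meta-analytic scales;
ratio draws are therefore strictly positive. Draws of distinct parameters
are independent: no correlation structure is asserted.

## Schooling and income

Per-child gain = `ΔP × |β|` (β the schooling deficit). Cohort totals
multiply by the 5-year birth-cohort size and the probability of surviving
to age 25, which proxies for delayed secondary completion. Additional
completers use the marginal-grade rule: with a 12-year system and students
uniform across secondary grades, only the penultimate grade can cross the
completion threshold from a marginal gain, so completers =
`births × surv25 × incomplete_secondary × grade11_fraction × per-child
gain`. `grade11_fraction` defaults to 1/6 (a six-grade secondary phase,
grades 7–12); 1/12 is selectable where all twelve grades are treated as the
eligible pool. The constant rescales completers only — school years and
income are unaffected.

NPV of one working life sums ages 20–59 of
`(2/3 GDP per capita) × (1.02)^t × S(a) / (1.03)^t`, with `S(a)` cumulative
survival from birth and `t = a − reference age`. The reference age defaults
to 0 (discounting from the cohort's birth year); it is configurable, and a
test pins the convention (`NPV(ref=20) = NPV(ref=0) / r^20`). In the
equal-rates limit with full survival the NPV is exactly `40 × 2/3 × GDP`.
Income gains enter linearly — `school years × returns rate × NPV` — not as
per-year compounding. PPP adjustment multiplies GDP per capita by the
country's PPP factor and nothing else, so every income output scales by
exactly that factor; this mirrors a sensitivity analysis rather than a
separate model.

Units: GDP per capita in 2010 constant USD/year; rates per year (discount
0.03, wage growth 0.02); proportions in [0, 1]; births as counts.

## Uncertainty propagation

1000 bootstrap replicates (configurable). Per replicate, one draw of every
relative risk and schooling effect is shared by **all** countries, while
prevalences and returns rates are drawn per country; regional and global
totals are summed within each replicate and the 95% UI is the 2.5th/97.5th
percentile (linear interpolation between order statistics) of the summed
draws. Summing interval endpoints instead would assume perfect positive
dependence and is never done. The reported point estimate is the chain
evaluated at the parameter points — not the draw mean — which preserves the
exact linearity properties above. IFA coverage and demographic/economic
inputs (births, survival, GDP) are treated as fixed; uncertainty is carried
by the evidence base, the prevalences and the returns rate.

Prevalence draws are truncated (clipped) to [0, 1] and returns-rate draws
floored at 0. Non-finite replicate outputs are excluded with a logged
count; more than 1% of them is an error. Intervals are not clipped at zero:
when an RR interval crosses 1, the gain UI legitimately extends below 0.

Calibration is tested on 500 replicate synthetic worlds with known truth
(2 countries each, 200 bootstrap replicates — sizes chosen to make the
check cheap while keeping the binomial tolerance meaningful): nominal 95%
intervals must cover the true chain output in 90–98% of worlds; the
observed rate is ~95%.

## Regional imputation

Countries missing an LBW or PTB estimate are flagged at read time (never
dropped) and imputed with a DerSimonian–Laird random-effects pool of their
region's observed prevalences. Pooling is on the logit scale with
delta-method SEs — the pooled value is then guaranteed to be a valid
proportion and to lie within the region's observed range — and the imputed
record carries the back-transformed pooled SE. A region with fewer than two
informative countries is an error unless global fallback is enabled.
Pooling is delegated to `statsmodels.stats.meta_analysis.combine_effects`
(DL moment estimator); the raw moment estimate of τ² is floored at zero, as
the DL definition requires, and the random-effects pool is recomputed from
the floored value (statsmodels reports the unfloored estimate, which goes
negative for homogeneous studies).

Missing IFA coverage defaults to 0 with a logged warning (conservative:
attributes the whole scale-up effect to new coverage), overridable per
configuration.

## Synthetic worlds

The generator draws latent true parameters per country — prevalences from
scaled Beta(2, 2) over realistic ranges (LBW 0.03–0.30, PTB 0.04–0.18,
anemia 0.10–0.70, underweight 0.02–0.35), IFA coverage uniform 0–0.9,
births log-uniform 10⁴–10⁷, GDP per capita log-uniform $500–$15,000,
returns to schooling 5–15%/year, incomplete secondary 0.2–0.9, survival to
25 in 0.85–0.999 — assigns the six super-region labels with weights
proportional to the real country counts (20/24/14/5/47/22 of 132), and
emits an *observed* table whose prevalences are normal measurements of the
truth with SE = 10% CV, clipped to [0, 1], plus injected missingness
(default 5%) on LBW/PTB. Survival curves use a Gompertz-like adult hazard,
so cumulative survival is monotone by construction.

What the generator does **not** emulate: spatial correlation between
neighbouring countries, correlation among a country's risk factors (e.g.
anemia with underweight), heavier-tailed uncertainty in low-registration
countries, or any specific real country's values. Passing tests therefore
demonstrate internal correctness and calibration of the machinery — not
agreement with any particular real-world extract, which requires supplying
an actual country table in the canonical CSV layout.

A null-world variant forces every intervention RR to 1: all point gains are
exactly zero by construction, and with effect-size SEs retained the
bootstrap UIs straddle zero — the end-to-end null fixture. Parameter
recovery is checked by shrinking all measurement SEs 1000× and requiring
pipeline point outputs to match the truth-ledger chain within 0.1% per
country (the observation noise scales with the SE, so at 100× shrinkage the
worst of ~100 draws can still exceed a 0.1% bar; 1000× tests the same
convergence property with a statistically safe margin).

## Numerical and design choices

- Proportions are validated to [0, 1] at construction; cumulative survival
  must be non-increasing in age (tolerance 1e-12).
- The PAF denominator guard (`1 + p_cur(RR − 1) > 0`) is retained for
  defence in depth, though it cannot trigger for `RR > 0` and coverage in
  [0, 1] — the denominator is bounded below by `1 − p_cur`.
- Degenerate effect CIs (zero width) sample as the point with a warning.
- Per-child income is total income over births to targeted women; it is
  undefined (NaN, flagged) when no births are targeted, e.g. IFA in a
  country already at the target coverage.
- CSV round-trips are bit-exact for decimal inputs (shortest-repr float
  formatting), and pipeline outputs are byte-identical under a fixed seed.

## Limitations

Evidence linking birth outcomes to schooling and income is observational
and may carry confounding; the model covers a single mediation pathway
(birth outcomes → schooling → income), omitting neurodevelopment,
healthcare costs and productivity channels; education quality is not
adjusted; modelling-structure uncertainty is not quantified, so the UIs are
a lower bound on total uncertainty.
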