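# Methods

`ssbtax` models the health consequences of a sugar-sweetened-beverage (SSB)
excise tax for the Indian adult population (25–65) over a ten-year policy
horizon (2014–2023).  The pipeline has three stages: (i) demand-system price
elasticities, (ii) conversion of the tax-induced price change into calorie
and glycemic-load changes under secular consumption trends, and (iii) a
cohort microsimulation mapping intake changes to overweight/obesity
prevalence and type 2 diabetes incidence.  The survey microdata behind the
original elasticity and anthropometry inputs are not publicly deposited, so
the package ships synthetic generators with known ground truth; all
downstream stages are parameterised by packaged transcriptions of the
published input tables.

## Demand system and censoring

Budget shares follow a Quadratic Almost Ideal Demand System over five
beverage classes (milk, SSBs, fresh fruit juice, coffee, tea) plus a
composite outside good:

    w_i = α_i + Σ_j γ_ij ln p_j + β_i ln(x/a(p)) + (λ_i / b(p)) [ln(x/a(p))]²

with the translog index ln a(p) and Cobb–Douglas aggregator b(p) = Π p_i^β_i.
Adding-up (Σα=1, Σβ=Σλ=0, zero γ column sums), homogeneity (zero γ row sums)
and Slutsky symmetry are imposed exactly.  The outside good is not cosmetic:
the published elasticity column (own-price −0.94 with all-positive beverage
cross-elasticities) cannot satisfy Cournot aggregation within a
beverages-only system for any positive budget shares, but it can once
expenditure may leave the purchased-beverage market.  Demand-theory
identities (Cournot, homogeneity) therefore hold over the six-good system
and are tested to 1e-6.

Zero purchases are handled by the standard two-step correction: a probit of
the consumption indicator on household covariates (household size, age of
head, an availability index, residence, income tertile) yields Φ̂ and φ̂ per
record, and the second stage fits w_i = Φ̂_i·w_i*(θ) + δ_i·φ̂_i.  Because
the price aggregators make the system nonlinear only through a(p) and b(p),
estimation iterates constrained linear least squares (free sub-vector of 35
parameters; tolerance 1e-8 on the parameter change, maximum 500 iterations;
typical convergence in 4–6 iterations).  The outside-good equation is
excluded from the objective and recovered by adding-up; on noise-free data
the estimates are invariant to which equation is dropped (tested).  The
translog intercept α₀ is fixed at the log median outlay, the usual
identification convention.  Confidence intervals are a nonparametric
bootstrap over households (both stages re-run per replicate; 200 replicates
by default), with the evaluation point — reference median prices, median log
outlay — held at the full-sample values.

The packaged generator truth is constructed so that its implied elasticities
at that evaluation point reproduce the published overall column exactly
(SSB −0.94; milk +0.049, juice +0.31, coffee +0.004, tea +0.13).  Intercept
shares, expenditure elasticities, the quadratic terms and the non-SSB block
of γ are package choices (documented in `data/generator_truth.json`); the
SSB column of γ is solved from the published elasticities.  Censoring is
generated independently of the share disturbance, so the true density-term
coefficients δ are zero and the corrected estimator's consistency is
directly testable.

## Tax shock and consumption scenarios

A tax at rate τ (default 0.20, full pass-through) changes each beverage's
intake by Δkcal_b = e_{b,SSB} · (100τ) · kcal_b / 100, floored so consumption
cannot go negative.  At the overall baseline intakes this gives −8.65
kcal/day for SSBs, +6.3 kcal/day of substitution, a net −2.4 kcal/day and a
net glycemic-load change of −1.0 g/day — the glycemic-load change is
relatively much larger than the calorie change because SSBs carry 0.1584 g
of glycemic load per kcal, about five times milk's 0.0311.

Baseline SSB consumption grows either (a) linearly — a constant annual
increment of 13% of the 2014 level, the default reading of the fitted
historical trend (the compound-growth reading is available by switch, but it
would overtake the Bass projection and contradict the reported amplification
ordering) — or (b) along a Bass diffusion curve S(t) = m·F(t; p, q).  The
Bass curve is calibrated to interpolate the printed projection endpoints
(12.8 l/person/yr in 2014, 36.3 in 2023) exactly; the remaining degree of
freedom minimises the residual to the 2012 historical anchor (11 l/person/yr).
Exact three-point interpolation is impossible: a Bass cumulative curve has a
monotonically declining relative growth rate, while the printed points imply
slower growth before 2014 (7.9%/yr) than after (12.3%/yr).  The calibrated
curve sits in the pure-imitation limit and reaches 9.9 l/person/yr in 2012.
Non-SSB beverages are flat in the baseline.  Non-beverage calorie intake
follows a configurable linear trend, default +12 kcal/person/day per year
(~0.5%/yr of non-beverage intake, consistent with food-balance trends for
India over the 2000s); it is shared by both arms of a contrast.  The secular
trend is applied as a uniform relative growth across cohorts.

## Body-weight dynamics

Weight responds to intake changes through a two-compartment energy-balance
model.  Fat F and lean L mass carry energy densities ρ_F = 9440 and
ρ_L = 1807 kcal/kg; expenditure is K + γ_F F + γ_L L + δ·activity·W + AT +
0.1·EI with γ_F = 3.2 and γ_L = 22 kcal/kg/day, a physical-activity
coefficient δ = 9 kcal/kg/day at the reference activity level (a moderately
active adult; with the Forbes partition this places the steady-state
response of a 70-kg reference adult to −100 kcal/day at −4.0 kg, inside the
−4 to −5 kg range expected of this model family), and adaptive thermogenesis
AT relaxing toward 0.14·ΔEI with a 14-day time constant (a switch disables
it; the steady-state consistency oracle runs with it off).  An energy
imbalance partitions along the Forbes rule dL/dF = C/F with C = 10.4 kg,
implemented in energy terms as p = C′/(C′+F), C′ = C·ρ_L/ρ_F.  Each
individual is initialised at energy balance at their own composition
(baseline fat mass from a Deurenberg-style BMI/age/sex regression), so only
intake *changes* move weight.  Integration is explicit Euler at 1-day steps,
vectorised over individuals; energy conservation (cumulative imbalance =
ρ_F ΔF + ρ_L ΔL) holds to machine precision by construction and is tested,
and the trajectory endpoint is tested against an independent algebraic
root-find of the steady state along the Forbes path.  Roughly 65% of a step
change's final effect arrives within the first year — the delay that makes a
dynamic model necessary.

## Diabetes hazard

A glycemic-load change ΔGL (g/day, vs the 2014 anchor of the same scenario)
multiplies the hazard by exp[ln(RR)·(ΔGL/100)·(1−e^{−rt})] with RR = 1.45
(95% CI 1.31–1.61) per 100 g/day and r = 1/7.6 yr⁻¹ (CI 1/14.7–1/2.8).
The phase-in-of-log-RR form is mathematically identical to exponential decay
of excess risk after exposure removal.  The multiplier applies to each
cohort's baseline incidence; no separate BMI-mediated diabetes pathway is
added because the glycemic-load RR already incorporates adiposity-mediated
effects.  Yearly events are Bernoulli draws among the at-risk (non-diabetic)
pool with diabetes absorbing; the phase-in clock is evaluated at the end of
each simulated year.  Alongside realised events the simulator reports the
*expected* incidence (mean event probability among the at-risk pool), a
Rao–Blackwellised estimator of the same rate; scenario contrasts use it
because at desk scale the realised difference between paired arms is a
handful of events and would be dominated by Bernoulli noise.

## Microsimulation and uncertainty

The design is the full cross of 2 age bands × 2 sexes × 3 income (SLI)
tertiles × 2 residence strata.  Only margin-level baselines are published,
so cell values are filled by independent margin effects (multiplicative for
intakes and incidence, additive log-odds for prevalence) and raked so
population-weighted cell means reproduce the overall row exactly; the cell
weights default to census-style margins (62% aged 25–44, 51.5% male, 31%
urban, SLI tertiles 28/50.5/21.5).  This margin-product fill is an
approximation the available tables cannot improve on.  Each cohort's
elasticity column averages its income- and residence-margin values.

Per cohort, individuals are drawn with lognormal BMI (log-SD 0.17, a typical
adult BMI coefficient of variation; the log-mean is solved so P(BMI ≥ 25)
equals the cohort's calibrated prevalence), heights normal by sex, lognormal
per-beverage intakes (CV 0.5) tied to BMI through a Gaussian copula (rank
correlation 0.2 — the source states a joint distribution but no dependence
strength), baseline diabetes prevalence scaled from the cohort's incidence
(8% at the overall rate), and an activity multiplier ~N(1, 0.1).  Individual
intake and glycemic-load changes scale each person's own consumption by the
cohort path ratios, so heavy SSB consumers receive proportionally larger
shocks.  Overweight uses the BMI ≥ 25 kg/m² surveillance threshold;
incidence denominators exclude prevalent cases.

Paired scenario runs share all random draws (individuals and event
uniforms), so contrasts are common-random-number paired; a zero tax
reproduces the baseline run bit-for-bit, and paired contrasts have strictly
smaller Monte-Carlo variance than mismatched-seed contrasts (tested).
Parameter uncertainty is propagated by an outer loop that redraws every
input — cohort intakes, prevalences and incidences (from their reported
SDs), elasticities and glycemic-load factors (normal on their 95% CIs),
RR and effect rate (truncated at their sign constraints), and the metabolic
coefficients (5% relative SD; the source publishes no CIs for them) — and
summarises 2.5/97.5 percentiles over draws.  Defaults are desk-scale:
2,000 individuals per cohort and 200 outer draws, with full-scale settings
reachable through configuration.

## Known limitations and reproduction gaps

Faithfully applying the published inputs through the published formulas does
not reproduce all printed headline effects, and the package reports what it
computes rather than the printed values:

* **Diabetes effect size.**  The 20% tax changes glycemic load by −1.0
  (2014) to −2.3 g/day (2023).  With RR = 1.45 per 100 g/day the saturated
  hazard reduction is exp(ln 1.45 × 0.023) − 1 ≈ 0.9%, an upper bound on the
  achievable final-year incidence reduction; the package computes ~0.7%
  against the printed 1.6% (and correspondingly ~1.0% vs 2.5% under the Bass
  baseline).  The printed values are not derivable from the printed inputs
  via the stated hazard; no parameter within the published CIs closes the
  gap.
* **Tax-rate nonlinearity of the diabetes response.**  Because the tax shock
  is linear in τ and the hazard exponent is small, the simulated diabetes
  response is nearly linear in the tax rate (halving the tax removes ~50% of
  the effect; raising it to 30% adds ~50%), not the printed 62%/33%
  asymmetry, which is attributed to demand-side nonlinearities that the
  elasticity-times-price-change shock cannot produce.
* **Overweight effect.**  The simulated overall reduction (~2.6%) sits close
  below the printed 3.0%; it is sensitive to the unpublished BMI dispersion
  and intake–BMI dependence, both fixed here a priori.
* **Bass amplification.**  The Bass baseline amplifies both effects by
  ~35% here, just below the printed 40–60% band.
* The baseline projection reaches ~51% overweight prevalence in 2023
  (printed: 49%) under the default non-beverage trend, and ~314/100,000
  diabetes incidence (printed: 336) — the baseline incidence drift available
  from beverage glycemic load alone is smaller than printed.

Other limitations: no background mortality, remission, migration or
children; no physical-activity feedback after dietary change; constant
elasticities over the horizon; full tax pass-through; synthetic records
emulate marginal and pairwise structure of the real surveys but not their
sampling designs, so passing recovery tests demonstrates estimator
correctness, not survey realism.
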