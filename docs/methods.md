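# Methods

## The design being modeled

Nine histologic cohorts share one adaptive design.  Each cohort *j* has a
historical (null) objective response rate `q_j` — 10% for BTC, GIST, ASI,
LGG, HGG and HCL, 15% for ATC and MM, 25% for NSGCT — and 50% is regarded as
a clinically meaningful rate.  Interim analyses run on a global 12-week
calendar.  At each look the hierarchical model is refit on all evaluable
primary-cohort data and each open cohort's posterior exceedance
`P(p_j > q_j | data)` is gated: stop for futility below 0.30 once ≥ 5
patients are evaluable, stop for efficacy above 0.95 once ≥ 10 are, cap
primary enrollment at 25.  At the final analysis a cohort needs ≥ 2
evaluable patients to be assessable.  Expansion-phase patients never enter
the model.

## Hierarchical model and priors

`x_j ~ Binomial(n_j, p_j)` with `theta_j = logit(p_j) − logit(q_j)` and
`theta_j ~ N(mu, tau²)`.  Centering each cohort on its own null puts
cohorts with unequal historical rates on one exchangeable scale and makes
"exceeding the historical rate" the common event `theta_j > 0`.

The source trial never published its prior specification, link function or
sampler, so the full parameterization here is a documented reference choice:

* `mu ~ N(0, 2²)` — weakly informative on the pooled log-odds lift; the
  prior exceedance probability is ½, favouring neither activity nor its
  absence.
* `tau ~ HalfNormal(0.75)` — between-cohort spread of the log-odds lift.
  The scale was calibrated once, as standard design practice: starting from
  HalfNormal(1), global-null simulations (4,000 replicates per candidate
  scale) showed the maximum per-cohort type I error is dominated by the
  25%-null cohort and is nearly insensitive to the scale (0.040–0.043);
  0.75 was the scale whose measured maximum met the design's 0.04 target.
  Power under a homogeneous 50% alternative exceeds 0.99 at every candidate
  scale, so the choice only affects the null.
* Strict exceedance of `q_j` is used (no margin); the 50% meaningful rate
  enters only as the alternative-hypothesis ORR of simulation scenarios.

An `inverse_gamma` tau-prior family (shape fixed at 2, user scale) and a
`fixed` (point-mass) family are available; the latter exists for
pooling/independence limit checks.

## Posterior computation

**Quadrature (default).**  `mu` and `tau` are placed at the quantiles of
their priors (`grid_resolution` nodes per axis, default 201), giving equal
prior weight per node and automatic adaptation to concentrated priors.  For
each node, the `N(mu, tau)` distribution of `theta` is converted to exact
bin masses by CDF differences over a fixed grid (default 520 bins spanning
±13), which stays exact as `tau → 0`.  Joint `(mu, tau)` nodes are
reweighted by the product of per-cohort marginal likelihoods; per-cohort
marginals over `theta` give posterior means, equal-tailed 95% credible
intervals and exceedance probabilities (zero sits on a bin edge, so the
event `theta > 0` is exact).  Mass outside the span is renormalized and
reported as `truncation_mass` in the diagnostics.  The bin-mass matrix
depends only on the configuration and is cached, so a refit costs two matrix
products — this is what makes whole-trial simulation affordable.  A
101-node / 260-bin configuration used inside simulations agrees with the
default grid to ~1e-4 and with a 301-node / 1040-bin grid to ~2e-5 on
exceedance probabilities.

**MCMC (cross-check).**  Metropolis-within-Gibbs: conjugate Gibbs update
for `mu`, random-walk on `log tau`, componentwise random-walk on `theta`,
plus a joint translation move shifting `mu` and all `theta_j` together to
break location coupling.  Exceedance probabilities are Rao-Blackwellized —
`P(theta_j > 0 | mu, tau, data_j)` is computed by 1-D bin masses and
averaged over thinned hyperparameter draws — which makes their MC error a
function of the well-mixing `(mu, tau)` chain rather than the sticky
indicator.  Diagnostics (acceptance rates, initial-positive-sequence ESS)
attach a warning when acceptance leaves [0.1, 0.6] or ESS drops below 100;
warnings never silently alter results.  Quadrature and MCMC agree within
0.01 on a three-cohort test grid.

## Trial simulation

A replicate generates per-cohort Poisson accrual and Bernoulli responder
status through the synthetic-data generator, then replays the calendar:
patients become evaluable 8 weeks after enrollment (the first scheduled
disease assessment; configurable), a closed cohort's enrollment freezes at
its closing look but already-enrolled patients continue to mature, closed
cohorts keep contributing their frozen data to the joint fit, and a cohort
reaching the cap is decided by the final-analysis rule — the interim
efficacy rule applied to complete data — since the trial specifies only the
minimum-2-patients condition for the final analysis.  The interim calendar
is global rather than per-cohort (the model is joint, so a look refits
everything); the source trial does not say which was used.

Operating characteristics replicate whole trials: with every true ORR at
0.50 the per-cohort efficacy-declaration fraction estimates power, at the
historical rates it estimates type I error.  Binomial MC standard errors
accompany every estimate.  Under the reference model the global-null
maximum (the 25%-null cohort) sits at the 0.04 bound itself, so acceptance
tests compare estimates at two MC standard errors and the acceptance script
uses 4,000 null replicates (MC error ≈ 0.003 on the reported maximum).

## Synthetic data: what it emulates, what it does not

The generator states a trial-like world: homogeneous-Poisson accrual
(default 0.25 patients/week/cohort ≈ one per month, a typical rare-tumor
rate; the trial's per-cohort accrual was unpublished, so the default is
uniform and overridable); Bernoulli responder status at the scenario's true
ORR; best-response categories drawn from responder- and non-responder-
conditional weights defaulting to the published per-cohort proportions
(minor responses therefore appear only where the publication reports them:
LGG and HCL); response onset at the first 8-week assessment; exponential
duration of response, time to progression, and post-progression survival
(medians in weeks; defaults 52 / 30 / 78 ≈ the published 12 / 7 / 18-month
scales).  Death is progression time plus an exponential increment whose
median is `median_os − median_ttp` (floored at 4 weeks), which guarantees
progression ≤ death and hence PFS ≤ OS per patient.  An independent-review
category is generated for solid-tumor/glioma cohorts, matching the
investigator with probability `rater_agreement` (default 0.60; the
published concordances span 46–67%) and otherwise resampled uniformly from
the non-matching categories.  Administrative censoring applies at
`cutoff_weeks` (default 260); a responder whose onset would fall beyond the
cutoff is downgraded to not-evaluable, an unobserved progression downgrades
a PD label to SD.  Time unit is weeks; reports convert at 4.348 weeks per
month.

Not emulated: lesion-level measurements and confirmation rules (responses
enter as categorical labels), response-status evolution between assessments
(a patient's final best response is revealed at their first assessment),
treatment discontinuation for toxicity, non-exponential event times (the
exponential family is the simplest consistent with reported medians; the
scale parameterization is the single swap point for a Weibull variant), and
dependence between response status and survival beyond the onset/progression
construction.  A green simulation test therefore establishes correctness of
the design machinery under this stated world, not reproduction of the
trial's observed survival.

## Frequentist analysis choices

* Clopper–Pearson bounds via beta quantiles (`lower = B(α/2; x, n−x+1)`,
  `upper = B(1−α/2; x+1, n−x)`), validated against direct binomial-tail
  inversion and statsmodels.  Tables print ORR as an integer percent and
  bounds to one decimal, matching the publication's formatting.
* Missing/unknown best responses count as non-responders and stay in the
  denominator; minor responses never count as responses.
* Kaplan–Meier with the standard tie convention (events before censorings at
  equal times), Greenwood variance, and pointwise intervals on the
  complementary log-log scale.
* Brookmeyer–Crowley median intervals invert the cloglog-scale test of
  `S(t) = 0.5`: the lower limit is the first event time whose pointwise band
  contains ½, the upper limit the first event time beyond the qualifying
  set.  (Taking the last *qualifying* time as the upper limit instead
  measurably undercovers: 91.5% vs 94.5% at nominal 95% in a 200-replicate
  exponential check, which is why the standard convention is used.)  Sides
  the follow-up cannot bound report `NOT_REACHED`, as does a median the
  curve never crosses.
* Endpoint derivation uses enrollment week as the first-dose proxy (the
  generator does not model a separate dosing visit); patients who start new
  anti-cancer therapy before progression are censored at last assessment
  (the publication does not state its convention).
* Evaluability follows the protocol's disjunction (progression, new
  anti-cancer therapy, consent withdrawal, death, ≥ 6-week stable disease,
  ≥ 2 post-baseline assessments); the therapy/consent flags are explicit
  input columns, never inferred.

## Known limitations

* The published Bayesian model-based ORR table is out of scope (values
  unpublished in the main text), and the published DoR/PFS/OS medians and
  concordance rates are not reproducible without patient-level data; the
  corresponding machinery is exercised on synthetic data instead.
* Per-cohort type I error is controlled per design, not familywise.
* The reference priors are this package's choice; heterogeneous-effect
  scenarios (the published 55–90% power, 0.03–0.14 type I ranges) depend on
  the unpublished scenario set and are supported but not reproduced.
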