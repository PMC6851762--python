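# fire-extremes

Bayesian spatiotemporal prediction of wildfire size extremes from
finite-sample maxima.

## The problem

How large can the largest wildfire in a region-month plausibly be? A
block-maximum question is usually answered by fitting an asymptotic
extreme-value form (GEV/GPD) above a hand-picked extremeness threshold.
This package takes the finite-sample-maxima route instead: model **how
many** large fires occur in each region and month, model **how big** each
fire is, and combine the two posteriors. If n fires occur with size CDF
F, the maximum Z obeys

    Pr(Z <= z) = F(z)^n ,

so marginalizing n and the parameters of F over their posteriors yields a
full predictive distribution for the extremes — no asymptotics, no
threshold selection, and with parameter uncertainty propagated end to end.

The component models are the ones a monthly, ecoregion-level fire record
calls for:

* counts n_{s,t} ~ Poisson / negative binomial / zero-inflated Poisson /
  zero-inflated negative binomial, with
  `log mu = alpha + X beta + phi + log a` (area offset a) and
  `logit pi = alpha_pi + X beta_pi + phi_pi`;
* burned-area exceedances y_i over a 405-ha threshold ~ lognormal /
  gamma / Weibull / generalized Pareto (via its Lomax form) / tapered
  Pareto, with covariates on one location parameter per family;
* X holds B-spline bases (df 5) of six covariates — humidity, air
  temperature, same-month and prior-12-month precipitation, wind speed,
  log housing density — interacted with a nested L1/L2/L3 region
  hierarchy, under a regularized horseshoe prior (paired across the count
  and zero-inflation components), plus AR(1) x ICAR spatiotemporal random
  effects;
* inference by the package's own No-U-Turn sampler over hand-derived
  analytic gradients, with holdout log likelihood, posterior predictive
  checks, interval-coverage audits and per-covariate contribution
  decompositions for evaluation.

Everything runs on synthetic data with known parameters (the
`synthetic` module generates hierarchy, meteorology, housing and fires
from the same generative model the package fits), so recovery and
calibration are measurable. See `docs/methods.md` for the full model and
its assumptions.

## Worked example

```sh
python analysis/01_simulate_data.py 1
python analysis/02_fit_models.py 1
python analysis/03_predictive_checks.py 1
python analysis/04_extremes.py 1
python analysis/05_contributions.py 1
python analysis/06_calibration_and_recovery.py 1 3
```

`01` prints the study conditions, e.g.

```
regions: 12, modelled months: 120
events simulated: 1030
zero cells: 74.7%, max monthly count: 37
median exceedance: 306 ha, largest: 29541 ha
true nonzero count-model coefficients: 4 of 588
```

— a 12-region, 10-year monthly panel in which ~1,000 fires over the
405-ha threshold occur, with a lognormal long tail (a median fire barely
clears the threshold while the largest burns tens of thousands of
hectares), and only 4 of the 588 design coefficients are truly nonzero.

`02` fits the models and ranks them on the withheld final two years:

```
Model ranking by holdout log likelihood (mean (sd)):
  zinb                   -275.3 (4.6)
  poisson                -333.9 (5.8)
Model ranking by holdout log likelihood (mean (sd)):
  lognormal             -1550.8 (1.7)
  gamma                 -1599.6 (8.2)
```

The zero-inflated negative binomial beats Poisson by ~60 log-likelihood
units and lognormal beats gamma — the fitted models identify the families
that generated the data. `03` reports posterior predictive checks and
test-set interval coverage (95% intervals: counts 0.972, conservative as
discrete-response intervals are, with the few misses all above the upper
bound; sizes 0.933). `04` combines the two posteriors into
99% prediction intervals for the largest fire per region-month (empirical
coverage 0.976 over 85 fire-bearing test cells in this run) and into the
monthly probability that some fire exceeds a 50,000-ha exceedance — the
synthetic analogue of asking for the chance of a million-acre fire. `05`
decomposes the linear predictor by driver (humidity dominates, as built
into the truth) and verifies the partition identity to machine precision.
`06` closes the loop: with the generative parameters known, 95% size and
99% maxima intervals hit their nominal coverage within Monte-Carlo error,
and over seeded replicates the credible intervals cover the true nonzero
coefficients while the 584 true zeros shrink to ~0.

(The numbers above are from seed 1; other seeds give different
realizations of the same behaviour.)

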