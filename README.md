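# whitepox

Bayesian spatio-temporal analysis of white-pox disease on mapped coral
colonies.

White-pox is a tissue-loss disease of the threatened elkhorn coral *Acropora
palmata*. A central epidemiological question is whether it behaves like a
*contagious* disease — spreading to nearby colonies — or like an
environmentally triggered condition of susceptible hosts. `whitepox`
implements the space-time modelling workflow used to ask that question of
multi-year colony survey panels: monthly presence/absence records of disease
on every tagged colony of a reef site, together with colony size, location,
and site-wide environmental series.

## The model

Disease presence $y(s_i, t) \in \{0, 1\}$ on colony $i$ at monthly survey
occasion $t$ follows a Bernoulli-logit latent Gaussian model

$$\mathrm{logit}\,P\!\left(y(s_i,t)=1\right) \;=\; z(s_i,t)\,\beta \;+\; \xi(s_i,t) \;+\; \varepsilon(s_i,t),$$

where

* $z(s_i,t)$ is the standardized design of eight ecological covariates plus
  intercept: northing and easting (UTM m), colony size (cm³, log₁₀),
  the colony's running count of previous disease incidences, distance to the
  nearest neighbouring colony (log₁₀), distance to the nearest colony
  diseased at the previous occasion (log₁₀), trailing 30-day mean water
  temperature (°C), and solar insolation (kW m⁻² day⁻¹);
* $\xi(s_i,t)$ is a zero-mean latent Gaussian field, Matérn-correlated
  across colony sites and evolving in time under stationary AR(1) dynamics
  (separable Kronecker covariance, marginal sd $\sigma_\xi$);
* $\varepsilon(s_i,t) \sim N(0, \sigma_\varepsilon^2)$ is an iid
  observation-level effect absorbing unstructured extra-binomial noise.

Inference is a nested Laplace scheme in the spirit of INLA: an inner damped
Newton pass builds the Gaussian approximation over the stacked latent vector
at fixed hyperparameters, and an outer deterministic quadrature over the
four transformed hyperparameters (spatial range, $\sigma_\xi$, AR
coefficient, $\sigma_\varepsilon$), centred at their posterior mode, mixes
the coefficient marginals. A covariate is declared *significant* when its
2.5%–97.5% posterior quantile range excludes zero. Because the Matérn
covariance is evaluated exactly and densely at the few dozen colony sites
(no mesh), a full 69-colony × 83-occasion fit over an 81-point
hyperparameter grid takes well under a minute on one core.

The package also provides kernel-smoothed intensity surfaces of the colony
point pattern (colony density, and disease reoccurrence with colonies
weighted by their diseased months), and a synthetic-data generator that
draws survey panels from exactly the assumed model — known coefficients,
latent field, seasonal temperature/insolation forcing, sequentially
simulated disease history — so the whole pipeline is testable end to end.

## Worked example

`examples/simulate_and_fit.py` simulates a study-like panel (69 colonies,
83 monthly occasions, effects set to the published posterior means) and
refits it:

```
panel: 69 colonies x 83 occasions, prevalence 10.9%, 124 missing cells
                      mean     sd   q025   q50   q975   mode  significant   true
Intercept           -3.302  0.316 -3.945 ...        ...        True       -3.297
Northing             0.605  0.228  0.152 ...        ...        True        0.290
Easting              0.603  0.159  0.294 ...        ...        True        0.440
Colony size          0.260  0.069  0.124 ...        ...        True        0.300
Previous incidences  0.822  0.089  0.646 ...        ...        True        0.933
Distance            -0.150  0.076 -0.299 ...        ...        True       -0.130
Previous distance   -0.025  0.080 -0.180 ...        ...        False      -0.071
Water temperature    0.561  0.110  0.344 ...        ...        True        0.430
Solar insolation    -0.107  0.106 -0.316 ...        ...        False       0.020
```

Each row is one coefficient of $\beta$ on the standardized scale: `mean`,
`sd`, the central credible quantiles and posterior mode describe its mixed
posterior marginal, `significant` applies the credible-interval rule, and
`true` is the exactly-known generating value mapped onto the fitted scale.
The three strong effects — colony size, previous incidences, water
temperature — are recovered positive and significant, each true value well
inside its interval; a single replicate's location coefficients wander
within their (wide) intervals, which is what the recovery study
(`examples/recovery_study.py`) quantifies across seeds.

Other examples: `read_survey_csv.py` (the CSV dialect and column mapping),
`intensity_maps.py` (density and reoccurrence surfaces). The same stages are
available from a thin CLI:

```bash
whitepox simulate --seed 7 --out panel.csv --truth truth.json
whitepox fit --panel panel.csv --out summary.csv
whitepox map --panel panel.csv --which reoccurrence --out surface.csv --png map.png
whitepox recover --seed 1 --replicates 20 --out report.csv
```

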