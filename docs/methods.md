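# Methods

This note documents the statistical model, the numerical scheme, the
synthetic-data generator and the design decisions behind `whitepox`, at the
level of detail a user needs to judge what the package's results do and do
not establish.

## Model

Monthly presence/absence of white-pox disease on tagged colonies is modelled
as a Bernoulli-logit latent Gaussian model. For colony $i = 1,\dots,d$ at
site $s_i$ (planar UTM metres) and survey occasion $t = 1,\dots,T$:

$$y(s_i,t) \sim \mathrm{Bernoulli}\!\left(\mathrm{logit}^{-1}\eta(s_i,t)\right),
\qquad \eta = z(s_i,t)\beta + \xi(s_i,t) + \varepsilon(s_i,t).$$

*Time index.* $t$ indexes survey occasions (monthly), in date order. Missing
colony-occasion cells are retained and simply contribute no likelihood term
(the Bernoulli likelihood factorises over observed cells); they are never
imputed.

*Latent field.* $\xi$ is zero-mean Gaussian with separable covariance
$R_{\mathrm{AR}}(a) \otimes \sigma_\xi^2 \bar C_\nu(d/r)$: Matérn
correlation $\bar C_\nu$ at the pairwise site distances (smoothness $\nu$,
fixed 1 by default; range convention $\kappa = \sqrt{8\nu}/r$, so the
correlation at distance $r$ is $\approx 0.14$ for $\nu = 1$ — the
conventional "$\approx 0.1$" is only approximate) and stationary AR(1)
month-to-month correlation $a^{|t-t'|}$ (innovation variance
$(1-a^2)\sigma_\xi^2$, so every cell has marginal variance $\sigma_\xi^2$).
At $d \le$ a few hundred sites the Matérn matrix is computed exactly and
densely; no triangulation or finite-element device is involved, and a
relative jitter of $10^{-8}\sigma^2$ on the diagonal guarantees positive
definiteness. Occasion-major stacking makes the joint precision
block-tridiagonal (bandwidth $2d-1$), which every solve exploits.

*Observation-level effect.* The model's Gaussian white-noise term cannot sit
in a Gaussian observation equation when the response is binary; it is
realised as an iid Gaussian random effect $\varepsilon \sim N(0,
\sigma_\varepsilon^2)$ on the linear predictor — the standard translation,
preserving the three-part structure of the predictor.

## Covariates

Eight covariates plus an intercept, each z-scored over observed cells
(recorded means/sds make coefficients transferable to new data):

| covariate | construction | transform |
|---|---|---|
| northing, easting | colony UTM coordinates | linear |
| colony size | cm³, per colony | log₁₀ |
| previous incidences | count of earlier occasions with disease; 0 at study start; missing occasions contribute nothing | linear |
| distance to nearest neighbour | min pairwise distance, all tagged colonies | log₁₀ |
| distance to previously infected | min distance to any *other* colony diseased at $t-1$; fill = max pairwise distance when no source exists (also at $t=1$) | log₁₀ |
| water temperature | trailing 30-day mean before each survey, site-wide | linear |
| solar insolation | site-wide monthly value | linear |

Design choices, made once and exposed as options: z-scoring is on by default
because coefficients across covariates whose raw units differ by orders of
magnitude are only comparable on a common scale; size and distances are
log₁₀-transformed because they span orders of magnitude and would otherwise
be leverage-dominated; "previous incidences" counts presence-months
(episode-based counting available); the self-exclusion in the
previous-infected distance prevents the covariate from trivially re-encoding
the colony's own history, which the incidence count already carries; the
max-pairwise fill encodes "no nearby source" without infinities and without
dropping cells. Distances use all tagged colonies throughout the study.

## Inference

Nested Laplace approximation:

1. **Inner step.** For fixed hyperparameters
   $\theta = (r, \sigma_\xi, a, \sigma_\varepsilon)$, a damped Newton ascent
   maximises the strictly concave log posterior over the stacked latent
   vector $(\xi, \varepsilon, \beta)$, with $\beta_j \sim N(0, 10^2)$ on the
   standardized scale. Each Newton system is solved exactly by eliminating
   $\varepsilon$ (diagonal), then $\xi$ (banded Cholesky, bandwidth $2d-1$),
   then $\beta$ (dense $p \times p$). Step-halving line search; iteration
   cap 100; convergence at gradient $\infty$-norm $< 10^{-6}$ *or* when the
   Newton step falls below $10^{-6}$ / the objective improvement reaches its
   floating-point floor — at $|f| \sim 10^3$ the gradient often stalls near
   $2\times10^{-6}$ with the mode already resolved to machine precision.
   The Laplace evidence $\log p(y\mid\theta)$ follows from the three
   log-determinants the elimination produces.

2. **Outer step.** Priors on transformed hyperparameters: Gaussians on
   $\log r$ (centred at the median pairwise distance, sd 1), $\log
   \sigma_\xi$ and $\log \sigma_\varepsilon$ (centred at 0, sd 1), and on
   the $(-1,1)\to\mathbb R$ logit transform of $a$ (centred at $a = 0.7$,
   sd 1.5). The joint posterior of $\theta$ is maximised by Nelder-Mead over
   warm-started inner solves; finite-difference curvature standardises each
   axis; integration points are then laid out around the mode — by default a
   tensor product of scaled Gauss-Hermite nodes per axis with the matching
   quadrature volumes (for 3 points: $0, \pm\sqrt3$ standardised units — a
   far better 3-point quadrature of a Gaussian-like posterior than a uniform
   $\pm1$ grid), with a central-composite (CCD) option. Point weights are
   proportional to evidence × prior × volume element. A single-point "grid"
   is empirical Bayes at the mode.

3. **Coefficient marginals.** Three accuracy rungs, `strategy=`
   - `gaussian`: mix the conditional Gaussian marginals
     $N(\hat\beta_j(\theta_k), s_j(\theta_k)^2)$ across grid points. Fast,
     but on binary data the conditional means carry the known toward-zero
     Laplace bias (in simulation it cost the intercept ~15 points of CI
     coverage).
   - `gaussian_corrected` (default for large panels): additionally compute
     the profile ("full") Laplace marginal of each coefficient at the modal
     $\theta$ — re-optimising all other latents along an 11-point abscissa
     grid — and apply its mean shift and sd ratio to every component before
     mixing. Restores near-nominal coverage at a small fixed cost.
   - `laplace` (default for panels with ≤ 400 observed cells): profile
     marginals at every grid point; for $p \le 2$ the *entire* coefficient
     vector is profiled on a tensor grid (Laplace over the field only) and
     marginalised numerically, removing the fixed-effect integration error
     altogether.

   Summaries (mean, sd, 2.5/50/97.5% quantiles by trapezoidal CDF
   inversion, mode as the argmax of the mixed density on a 512-point grid)
   are deterministic; the significance flag is the credible-interval rule.

Verification: the inner step reproduces the exact conjugate posterior and
the exact marginal likelihood under a Gaussian likelihood to $10^{-8}$;
with the field switched off it matches 1-D quadrature and a
maximum-likelihood logistic regression; on 3-colony × 2-occasion panels the
`laplace` strategy agrees with dense tensor quadrature over (coefficients ×
latent field) to better than 0.02 in every posterior mean tested.

## Kernel intensity surfaces

Colony density and disease-reoccurrence surfaces are isotropic Gaussian
kernel estimates on a 128 × 128 grid with Diggle-style edge correction
(each point's kernel is renormalised by its kernel mass inside the
rectangular window), so the surface integral equals the total (weighted)
point count exactly up to grid discretisation. Reoccurrence weights count a
colony's diseased survey months (an annualised variant counts its diseased
years). The bandwidth defaults to Silverman's rule averaged over the axes
and is exposed everywhere; the maps are descriptive, and no inferential
output depends on the bandwidth.

## Synthetic-data generator

The generator draws panels from exactly the model above, so recovery
experiments test the estimator against its own assumptions — no more, no
less. The default scenario emulates the motivating survey design: 69
colonies uniformly placed (a clustered parent-offspring option exists) in a
220 m × 560 m coastal strip; 83 monthly occasions from February 2003;
log-normal colony sizes (log-mean 10, log-sd 1.5 — tens of litres in the
median, spanning hand-sized fragments to m³ colonies); sinusoidal
temperature (28 ± 1.5 °C, peak in September) and insolation (5.5 ± 1.3
kW m⁻² day⁻¹, peak in June); 2% of cells missing at random; generating
coefficients equal to the published posterior means (intercept −3.29 …
insolation 0.02) on the standardized scale.

The latent-field truth (range 250 m, σ_ξ = 1.5, a = 0.9, σ_ε = 0.25) was
chosen once, as the regime that reproduces a study-like posterior
uncertainty structure — a long-range field that makes the location
coefficients genuinely hard to separate from spatial confounding (their
posterior sds are several times those of the size/temperature effects, as
in the published table) — while keeping the range below the domain's long
axis so the field stays identifiable, and the overall prevalence in the
low teens of percent.

History-dependent covariates are simulated *sequentially through the same
covariate functions the analysis uses*, so generator and analyser cannot
drift apart. Their standardization constants cannot be known before the
history exists; the generator therefore standardises them against reference
constants calibrated by a damped fixed-point iteration (simulate, measure
the constants the analysis would, geometric-mean damping on the sd — the
map is decreasing, so undamped replacement oscillates; drift tolerance 2%,
default 4 passes). Static covariates use their exact realised constants.
Whatever residual mismatch remains, the recovery harness maps the
generating coefficients onto each replicate's realised analysis scale
*exactly* (an affine reparametrisation of the identical linear predictor),
so bias and coverage are measured against the true values with no
discretisation error.

What the generator does **not** emulate: genuine contagion dynamics (under
the assumed model, proximity enters only through the distance covariates),
colony growth/fragmentation/mortality, genotype structure, observation
error in the disease call, and non-sinusoidal environmental variability.
Passing recovery tests therefore demonstrate that the estimator is
calibrated under the model's own assumptions, not that the model is
adequate for any particular reef.

## Measured calibration and problem sizes

At the default scenario (69 × 83 cells, 3-point-per-axis
hyperparameter grid, `gaussian_corrected` marginals) a 20-replicate
simulate–fit–summarise experiment gives per-coefficient 95%-interval
coverage of 17–20 out of 20 (≈ 92–95% overall), replicate-averaged bias
below 0.06 on every strong effect, detection of the strong effects in
essentially every replicate, and false significance of the near-null
insolation effect in ≤ 1 of 20. The location coefficients sit at the lower
end of the coverage range — their posteriors leaning hardest on the
latent-field approximation. One full fit takes ≈ 20 s on one core; the
acceptance workflow (20 replicates plus the quadrature cross-check) about
ten minutes. These problem sizes (3-point grids, 20 replicates) are the
package defaults for its own validation studies; denser 5-point grids
change the reported posteriors negligibly and are available throughout.

## Known limitations

* Laplace-family accuracy on binary panels is approximate; the corrected
  strategies remove most but not all of the bias, and slight undercoverage
  (a few percent) can persist for coefficients that are nearly confounded
  with the latent field.
* Hyperparameter posteriors are summarised only through the grid weights;
  the package reports the modal hyperparameters but no full hyperparameter
  marginals.
* The separable Matérn × AR(1) covariance excludes non-separable space-time
  interaction and anisotropy by construction.
* The dense-Matérn formulation scales as $O(T d^2)$ memory and roughly
  $O(T d^3)$ per Newton pass within banded solves — comfortable to a few
  hundred colonies, not thousands.
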