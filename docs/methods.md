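# Methods

## The daily spatial model

For each day, at monitoring sites $i = 1,\dots,n$ with collocated gridded
aerosol optical depth (AOD),

$$\mathrm{PM}_{2.5,i} = \beta_0 + \beta_1\,\mathrm{AOD}_i + \omega_i + \varepsilon_i,$$

where $\varepsilon_i \sim N(0,\tau^2)$ iid (the *nugget*) and
$\omega = (\omega_1,\dots,\omega_n)$ is a zero-mean Gaussian process with
covariance $K(h;\theta) = \sigma^2\rho(h;\phi)$ over Euclidean distance $h$
in decimal degrees. $\sigma^2$ is the partial sill and $\phi$ the spatial
decay; $1/\phi$ is the effective range, beyond which correlation is
negligible — exactly zero for the spherical family

$$\rho(h;\phi) = 1 - 1.5h\phi + 0.5(h\phi)^3 \;\; (0<h<1/\phi), \qquad 0
\text{ otherwise},\; 1 \text{ at } h=0.$$

Distances are kept in degrees throughout (no projection); all $\phi$ values
are in 1/degrees. The spherical family is the default because daily
variogram analysis of PM2.5 selects it by smallest equally-weighted OLS
residual among spherical, Matérn, Gaussian and linear candidates; the Matérn
smoothness $\nu$ is profiled over the grid $\{0.5, 1.0, 1.5, 2.5\}$ to avoid
the $\nu$–$\phi$ ridge.

Integrating $\omega$ out, the marginal likelihood is
$y \sim N(X\beta,\ \sigma^2 R(\phi) + \tau^2 I)$, evaluated through a
Cholesky factorization (one retry with a $10^{-8}\sigma^2$ diagonal jitter,
then an error).

## Priors and sampling

- $\beta = (\beta_0,\beta_1) \sim N(0,\,10^6 I)$ — effectively flat on the
  data scale.
- $\tau^2, \sigma^2 \sim \mathrm{InvGamma}(\text{shape}=2,\ \text{scale})$.
  With shape 2 the prior mean equals the scale and the prior variance is
  infinite. The scales default to the nugget and partial sill of a
  spherical variogram fitted to the day's *OLS-detrended* PM2.5 residuals
  (the "prior knowledge from variogram analysis" route). Detrending on AOD
  first matters: a raw-PM2.5 variogram folds the covariate's short-range
  structure into the apparent nugget and drags the nugget posterior well
  above the true noise level. When the fit fails, sample-variance moments
  are used instead.
- $\phi \sim \mathrm{Uniform}(1/(2 d_{\max}),\ 1/(0.05\,d_{\max}))$ with
  $d_{\max}$ the maximum pairwise site distance, i.e. the effective range
  may lie between 5% of the domain diameter and twice it.

Inference is Metropolis-within-Gibbs. $\beta$ has an exact conjugate
normal full conditional given $(\sigma^2,\tau^2,\phi)$ and is
Gibbs-updated — this changes mixing, not the stationary distribution. Each
of $\log\sigma^2$, $\log\tau^2$ and the logit-rescaled $\phi$ takes a
scalar Gaussian random-walk Metropolis–Hastings step with the
corresponding Jacobian term. Proposal standard deviations adapt every 50
iterations toward ~35% acceptance *during burn-in only* and are frozen
afterwards, preserving detailed balance in the retained draws. The default
schedule is 5,000 iterations with a 3,000-iteration burn-in; iterations
numbered 3,000–5,000 inclusive are retained (2,001 draws). Chains are
deterministic given the integer seed.

## Spatial-effect recovery and prediction

For each retained draw, with $S = \sigma^2 R$ and $\Sigma = S + \tau^2 I$,

$$\omega \mid y, \beta, \theta \sim N\!\big(S\Sigma^{-1}(y - X\beta),\;
S - S\Sigma^{-1}S\big),$$

sampled by composition (a $10^{-10}\sigma^2$ jitter stabilizes the
conditional factor in the small-nugget limit). In-sample fitted values use
the per-site posterior mean $\bar\omega_i$.

The posterior-predictive field at new locations uses, per retained draw,
the *exact* conditional moments of $y^*$ with $\omega$ and $\omega^*$
integrated analytically:

$$E[y^*] = \beta_0 + \beta_1\mathrm{AOD}^* + c^\top\Sigma^{-1}(y - X\beta),
\qquad \mathrm{Var}[y^*] = \sigma^2 + \tau^2 - c^\top\Sigma^{-1}c,$$

with $c = \sigma^2\rho(\cdot)$ the cross-covariances to the data sites.
This Rao-Blackwellized form is distributionally identical to chaining
sampled $\omega$ draws through the $\omega^*$ conditional, avoids Monte
Carlo noise in the reported mean surface, and makes the predictor collapse
*exactly* to the classical GLS/simple-kriging closed form when the chain
holds a single fixed draw — which is how the implementation is tested
against an independent dense oracle. Across draws the field mean is the
average conditional mean and the predictive variance follows the law of
total variance; 95% bounds use a normal approximation of the draw mixture.
The nugget is included in the predictive variance (prediction of a new
*observation*); the nugget-free process sd is reported alongside so either
convention is recoverable.

## AOD gap fill

Cloud gaps in the gridded AOD are filled by ordinary kriging constrained
by the day's fitted AOD variogram: a missing cell is filled only when at
least **five** observed cells lie within the effective range $1/\phi$ of
its center (center-to-center distance; a polygonal buffer would differ
only at the rim). Kriging uses at most the 50 nearest donors for cost
control; semivariance is $\gamma(h) = \tau^2 + \sigma^2(1-\rho(h))$ for
$h>0$ with $\gamma(0)=0$, so the fill is exact at donors when the nugget
is zero. Interpolated cells are flagged, are never donors for other cells,
and are used only to enlarge the modeling dataset — prediction maps use
genuinely observed AOD only. If the day's variogram fit fails, the day is
left unfilled.

## Baselines

**GWR.** Per day, locally weighted least squares
$\mathrm{PM}_{2.5,i} = \beta_{0i} + \beta_{1i}\mathrm{AOD}_i$ with Gaussian
kernel $w = \exp(-d^2/2b^2)$ and a *fixed* (not adaptive) bandwidth $b$ in
degrees, selected per day by minimizing leave-one-out cross-validated
squared error over a log-spaced candidate grid with golden-section
refinement. Local systems are solved as batched 2×2 normal equations; a
target with fewer than two effectively weighted points or no local AOD
contrast yields a flagged missing prediction.

**LME.** A single year-long model
$\mathrm{PM}_{2.5,i,t} = (\mu + \mu'_t) + (\beta + \beta'_t)\mathrm{AOD}_{i,t}
+ \varepsilon_{i,t}$ with daily random intercept/slope
$(\mu'_t,\beta'_t) \sim N(0,\Psi_1)$, fitted by maximum likelihood (not
REML) via statsmodels' MixedLM; empirical-Bayes daily effects are used in
prediction, with a flagged fixed-effects fallback for unseen days.

## Validation protocol

10-fold cross validation partitions *records* (site-days) at random —
identically for all three models, so comparisons share folds. Withholding
whole sites instead would change absolute numbers; record-wise folds are
the assumption here. R² is the squared Pearson correlation of observed vs
predicted (the CV-scatterplot convention); 1 − SSE/SST is also available.
Daily prediction fields are averaged per cell into annual and
meteorological-season means (spring MAM, summer JJA, autumn SON, winter =
Jan + Feb + Dec of the single study year), over available days only.

## The synthetic generator

The generator *is* the study condition, not a tuning dial. Defaults:
$\beta_0=20$ µg/m³, $\beta_1=70$ µg/m³ per AOD unit, $\sigma^2=400$
(µg/m³)², $\tau^2=25$ (µg/m³)², $\phi=1/3$ per degree (range 3°),
spherical — magnitudes mimicking a heavily polluted study year with annual
mean PM2.5 near 68 µg/m³ at mean AOD 0.77. Gridded AOD fields are
stationary Gaussian random fields (mean 0.77, variance 0.16, range 1°)
sampled by 2-D circulant embedding (negative embedding eigenvalues clipped;
the sill error is a few percent at these ranges), clipped below at −0.05,
the floor satellite Dark Target retrievals permit. The day-level spatial
sd (0.4) is deliberately below the annual tabulated AOD sd (~0.63), which
also contains day-to-day variation. Cloud decks are emulated by
thresholding a Gaussian-smoothed noise image (clump scale 0.5°) at the
sample quantile of the requested coverage (default 0.3). Sites occupy
distinct cloud-free cells (at most one monitor per cell), jittered within
the cell, which precludes duplicate coordinates; site-level $\omega$ is
drawn by dense Cholesky factorization.

What the generator does *not* emulate: satellite swath geometry and
Thiessen-polygon pixel assignment (synthetic AOD is generated per cell),
the inverse-variance DT/DB retrieval combination, retrieval error in AOD,
meteorology-driven covariates, monitor siting bias toward cities, and
temporal dependence between days. Passing tests therefore demonstrate
correctness of the statistical machinery under the model's own
assumptions, not real-data performance.

## Problem sizes and numerical choices

Desk-scale sizes used by the test suite and the acceptance script, chosen
so a full run stays in the minutes range on one CPU: parameter-recovery
days use 200 sites at the full 5,000/3,000 sampler schedule; the
three-model CV benchmark uses 30 days × 50 sites on a 10°×10° grid with a
shortened 600/300 chain for the 300 per-fold-day refits (the schedule,
priors and blocking are otherwise identical to the full run). Variogram
family selection is tested on lattice-sampled fields: short-lag bins carry
essentially all the spherical-vs-Gaussian discrimination (the spherical
semivariogram rises linearly at the origin, the Gaussian flatly), so
lattice spacing must stay below the first bin edges of interest.

Other numerics: equal-width variogram bins (15 by default) to a max lag of
half the maximum pairwise distance; "equally weighted OLS" read literally
as unit weight per bin (not pair-count weighting); bounded multi-start
least squares (5 deterministic method-of-moments starts); family-selection
ties broken spherical > Matérn > Gaussian > linear; ordinary-kriging
weight sums verified to 1e-10 on every solve and tiny negative kriging
variances (> −1e-9) clipped to zero; grid cells are half-open
[west, east) × [south, north) with an edge snap tolerance of 1e-9 cells;
days with fewer than 10 matchups are skipped by the GP (and fewer than 5
by GWR) and logged.

## Known limitations

- Dense covariance algebra throughout: daily models are comfortable to a
  few hundred sites; no low-rank/predictive-process approximation is
  provided (deliberately — the daily sample sizes targeted here do not
  need one).
- The Bayesian model is fitted per day; no temporal pooling besides the
  LME baseline.
- Credible intervals for the prediction field use a normal approximation
  of the posterior mixture rather than mixture quantiles.
- The LME's record-wise CV advantage (every day seen in training) is
  shared by design with the other models' folds; site-wise CV would be
  harsher on all three.
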