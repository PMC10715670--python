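# Methods

## Model

The pairwise Ratio of Gaussians (RoG) describes the joint single-trial
activity of two simultaneously recorded neurons as elementwise division of
Gaussian vectors plus additive Gaussian residuals:

    R_t = N_t / D_t + eta_t,
    N_t ~ N(mu_N, Sigma_N),  D_t ~ N(mu_D, Sigma_D),  eta_t ~ N(mu_eta, Sigma_eta),

with N and D independent of each other.  N models the excitatory driving
input, D the (latent, positive) normalization signal, and eta
stimulus-independent residual variability such as spontaneous activity.  The
pair structure enters through three correlations: rho_N between driving
inputs, rho_D between normalization signals, rho_eta between residuals.

The exact distribution of a Gaussian ratio has no finite moments, so all
fitting and analysis use the first-order delta-method (Taylor) approximation
of the mean, variances and covariance, which is accurate as long as the
denominator has negligible probability mass at or below zero.  We treat
mu_D / sigma_D >= 3 as the validity regime (P(D <= 0) < 0.0014 per neuron);
outside it the code emits a `ValidityWarning` rather than silently
truncating, because the approximation degrades continuously and the caller
should decide.  The variance of D affects the mean only at second order, so
the approximate mean is mu_N/mu_D + mu_eta.

The noise correlation decomposes into additive numerator, denominator and
residual terms.  With sigma_eta = 0 and a single nonzero coupling the model
makes a parameter-free qualitative prediction: the numerator term increases
and the denominator term decreases monotonically in the mean normalization
strength mu_D.  `corr_decomposition` reports the residual term separately
even though it vanishes in the eta-free rearrangement.

A generalized variant (`approx_moments_general`) takes a full 4x4 covariance
for (N1, N2, D1, D2), sandwiched by the Jacobian of elementwise division at
the means; it reduces exactly to the block-diagonal formulas and is verified
against Monte-Carlo sampling rather than against printed expressions.

## Contrast parametrization

The unreduced stimulus-level model has 10 stimulus-dependent parameters per
condition against 5 measurable statistics, so data analysis uses the
contrast-gain-control factorization: mu_N = R_max c^2, mu_D = eps^2 + c^2
(contrast c in percent, 0-100), giving the hyperbolic-ratio mean response,
and power-law variances sigma^2 = alpha mu^beta for both N and D (Fano
factor constant exactly when beta = 1).  The couplings (rho_N, rho_D,
rho_eta) are stimulus-independent; predicted noise correlations still vary
with contrast because the delta ratios do.

## Fitting

Parameters are estimated by maximum likelihood under the bivariate Gaussian
approximation.  The objective is the moment form

    NLL = sum_s (T_s/2) [ log|Sigma(s)| + Tr(Sigma(s)^-1 Sigma_hat(s))
                          + (mu_hat - mu)' Sigma(s)^-1 (mu_hat - mu) ],

with per-condition trial counts T_s (conditions may differ in counts) and
ML (ddof = 0) empirical moments, which makes the objective equal the summed
per-trial Gaussian negative log densities up to a parameter-free constant.
Singular model covariances return a large finite penalty (1e12 scaled by the
violation) so optimizers can recover.

Optimization is the two-step inference-functions-for-marginals (IFM) scheme,
equivalent to full MLE for Gaussian copulas: each neuron's marginal
parameters (R_max, eps, alpha_N, beta_N, alpha_D, beta_D, R0, sigma_eta) are
fit first (this is the independent RoG), then the couplings with marginals
frozen.  Details that matter:

- Marginal optimization uses bounded L-BFGS-B with an analytic gradient
  (numba-compiled) in a partly logarithmic parametrization — R_max, eps and
  the alphas in log scale — which conditions the problem and roughly halves
  the iteration count.  Bounds: R_max in (0, 10 max mean], eps in (0.01, 300],
  alpha in [1e-6, 1e3], beta in [0.25, 3], |rho| <= 0.999.
- Initialization is deterministic and data-driven: R_max from the maximum
  mean response, eps from the contrast nearest half-maximum, beta from a
  log-log regression of variance on mean, the alphas by attributing 90%/10%
  of the top-contrast variance to the numerator/denominator paths.  Five
  seeded multiplicative-jitter restarts guard against local minima.
- The coupling step is a 2-3 parameter bounded problem whose covariance is
  linear in the rho's; it uses an analytic gradient and multiple starts
  (pooled empirical correlation, zeros).  |rho| is bounded at 0.999 to keep
  the covariance nonsingular; fits at the bound are flagged as boundary hits
  and stand in for the +/-1 estimates such models produce on real data.
- rho_eta is fitted by default; `fix_rho_eta=True` pins it at 0, which all
  simulation experiments use since their generative residual is zero.

Goodness of fit is a cross-validated pseudo-R², scored per held-out split as
(NLL_fit - NLL_null) / (NLL_oracle - NLL_null) where the null predicts pooled
training moments for every stimulus and the oracle each stimulus's own
empirical training moments, median across splits.  Values below 0 or above 1
are possible under cross-validation and are reported as computed.  Defaults:
leave-one-out when the smallest condition has <= 20 trials, otherwise
10-fold; the simulation experiments use 2-fold for speed.

## Bootstrap confidence intervals

CIs for (rho_N, rho_D) come from a within-condition paired bootstrap: trials
are resampled with replacement inside each stimulus condition (response
pairs kept together, counts preserved) and the model is refit per resample;
CIs are percentile intervals of the refitted couplings.  A coupling is
classified significant when its CI excludes 0 AND the pairwise
cross-validated score exceeds the independent-model score.

The refit strategy is the part that determines whether the CIs attain
nominal coverage.  The coupling estimators are weakly identified and
multimodal: much of their sampling variability comes from how the marginal
fit splits variance between the numerator and denominator paths, which
rescales the coupling coefficients.  We verified on pilot simulations that
refitting only the couplings (or only the variance parameters) per resample
reproduces less than half of the estimator's replicate-to-replicate spread
and drives coverage down to ~35-75%, while refitting the complete marginal
model per resample from the same data-driven initialization used by the
point fit matches the replicate distribution and restores near-nominal
coverage.  The default mode therefore refits marginals and couplings per
resample; a `rho-only` fast mode exists for exploratory use with the
documented caveat that its intervals are too narrow.

## Single-trial normalization inference

Given fitted parameters, the posterior over the latent normalization pair on
one trial (after subtracting the residual mean) is

    -log p(D | R - mu_eta) = 1/2 (N - mu_N)' Sigma_N^-1 (N - mu_N)
                           + 1/2 (D - mu_D)' Sigma_D^-1 (D - mu_D)
                           - log D1 - log D2 + const,   N = (R - mu_eta) * D.

Setting the scaled partial derivatives to zero gives the bivariate quadratic
system 2 A_i D_i^2 + B_i D_i + C D1 D2 - 2 = 0 with A_i = r_i^2 [Sigma_N^-1]_ii
+ [Sigma_D^-1]_ii, B_i = -2(r_i [Sigma_N^-1 mu_N]_i + [Sigma_D^-1 mu_D]_i),
C = 2(r_1 r_2 [Sigma_N^-1]_12 + [Sigma_D^-1]_12).  Eliminating D2 yields a
quartic in D1 whose leading coefficient 2 A1 (4 A1 A2 - C^2) is strictly
positive for positive-definite covariances (Cauchy-Schwarz), so the system
always has exactly four (possibly complex) solution pairs.

Numerical choices: roots come from companion-matrix eigenvalues rather than
the radical formula; for each D1 root, D2 candidates come both from the
elimination identity and from the second equation's quadratic (the latter is
immune to the catastrophic cancellation the elimination formula suffers when
the prior term dominates, e.g. sigma_D -> 0); candidates with D > 0 are
scored on the negative log posterior and the winner is polished with damped
Newton steps on the exact gradient/Hessian.  Roots count as real when
|Im| <= 1e-8 (1 + |Re|).  If no positive candidate exists the solver falls
back to multi-start L-BFGS-B minimization started at mu_D and at the
independent-model estimates.  The independent-model estimator is the unique
positive root of a per-neuron quadratic and is reported alongside for
comparison.  Agreement between the algebraic and numerical routes is part of
the test suite (< 1e-6 over randomized trials).

## Modulated-Gaussian baseline

The comparison model is a Gaussianized modulated-Poisson: bivariate Gaussian
responses with mu = R_max c^2/(eps^2 + c^2) + mu_eta, variance
mu + sigma_G^2 mu^2 + sigma_eta^2, covariance rho_P mu_1 mu_2 +
rho_G sigma_G1 sigma_G2 mu_1 mu_2 + rho_eta sigma_eta1 sigma_eta2.  The
first covariance term is implemented exactly in this printed product form by
default; because the modulated-Poisson ancestry would scale a shared
point-process term with sqrt(mu_1 mu_2), a `sqrt_point_term` switch provides
that variant and the ambiguity is deliberately surfaced rather than
resolved.  Without residual noise the MG's Fano factor is >= 1 (it cannot
express underdispersion), the key structural difference from the RoG.  It is
fit with the same IFM scheme, likelihood and cross-validated scoring, so
scores are directly comparable.

## Preprocessing path

Fluorescence trials are 24 frames: 4 pre-stimulus blanks, 3 stimulus frames,
17 post-stimulus frames.  Baseline F0 is the median of frames 1-5 (the
blanks plus one extra frame for onset delay); evoked Delta-F/F is the mean
of (F(i) - F0)/F0 over frames 6-9, chosen symmetrically as the stimulus
frames plus one extra frame for indicator lag — the evoked window is not
pinned down externally, so both windows are explicit configuration
(`FrameLayout`).  Cells are included when the mean evoked Delta-F/F at the
highest contrast is at least 2 spontaneous SDs above the spontaneous mean
(inclusive threshold; blank trials supply the spontaneous statistics; cells
without blanks are flagged indeterminate).  A zero baseline flags the record
instead of raising.

## Synthetic data: what it does and does not emulate

The generator draws from the model itself, with presets reproducing the
printed designs of the validation experiments:

- `fig1` (moment validation): pair-level draws, mu_N ~ U[0,100],
  mu_D ~ U[0.5,1.5], sigma_N^2 = mu_N^beta, sigma_D^2 = 0.001 mu_D^beta,
  beta ~ U[1,1.5], rho ~ U[-0.5,0.5], additive-noise variance 10% of the
  numerator-path response variance, rho_eta = 0.
- `fig2`/`fig3` (trend and inference studies): R_max ~ U[5,50],
  eps ~ U[10,100], alpha ~ U[0.1,1], beta ~ U[1,2], eta = 0; `fig3` draws
  rho_N, rho_D ~ U[-0.9,0.9]; contrasts {6.25, 12.5, 25, 50, 100}.
- `fig4` (estimator comparison): R_max ~ U[10,100], eps ~ U[15,25],
  alpha ~ U[0.1,1], beta ~ U[1,1.5], eta = 0.

Because trials are drawn from the fitted model class with Gaussian sources
and no temporal structure, passing tests demonstrate internal consistency
(correct formulas, calibrated inference under the model), not robustness to
real-data features: calcium indicator dynamics, non-Gaussian and skewed
ratio tails, slow gain drift, serial correlations, and deviations from the
power-law variance are all outside what these fixtures exercise.  The
uniform parameter draws also differ from empirically fitted parameter banks;
one consequence is documented under Limitations.  The fluorescence fixture
emulates only trial structure, baseline, an evoked bump and white frame
noise.

## Validation experiments and problem sizes

All experiments are seed-deterministic and emit tidy tables; the suite runs
them at sizes chosen to complete in minutes on one CPU, since every check is
either exact or a trend/coverage statement whose tolerance already accounts
for Monte-Carlo error at that size:

- Moment validation: 1000 experiments x 1e5 trials; |median percent
  difference| between closed-form and Monte-Carlo covariance and correlation
  < 2%.
- Normalization-correlation trends: 60,000 pairs x 500 trials per coupling
  combination, log-spaced bins in eps_1 x eps_2, bins under 100 pairs
  discarded.  Under uniform parameter draws the per-bin medians are not
  stepwise monotone even in closed form (the (eps_1, eps_2) composition of a
  bin varies along the product axis) and the extreme log-spaced bins are
  sparse, so the test statistic is the count-weighted least-squares slope of
  bin median versus bin index: it must be negative (rho_D shared) or positive
  (rho_N shared) at every contrast, steepest at the lowest contrast, and the
  medians must mirror under sign-flipped couplings.  An equal-count
  (quantile) binning option exists but compresses the dynamic range, so the
  default analysis keeps the fixed log-spaced bins.
- Coverage and sign recovery: in-suite at 120 pairs x 400 trials x 150
  resamples; the acceptance script runs 300 x 500 x 200.  Coverage of the
  90% rho_D interval within 5 points of nominal; >= 90% sign agreement for
  significant rho_N.
- Estimator comparison: 5x5 coupling grid x 12 pairs x 250 trials at
  contrasts {6.25, 25, 100} with recorded latents; differences in z-scored
  MSE and truth-correlation between the pairwise and independent MAP
  estimators.

## Known limitations

- Point estimates of (rho_N, rho_D) are weakly identified under contrast
  tuning (multiplicative interactions with the variance split); only their
  signs, for pairs classified significant, are reliable.  The bootstrap CIs
  quantify this honestly — widths often span most of [-1, 1].
- Under the uniform `fig4` parameter draws with zero residual noise, both
  MAP estimators recover the latent normalization well at high contrast
  (truth-correlation ~0.9), so the pairwise estimator's advantage is largest
  at the *lowest* contrast and shrinks as contrast grows.  Adding a
  realistic residual-noise floor (sigma_eta ~ 1.5 response units) reverses
  this, making the advantage grow with contrast; empirically derived
  parameter sets behave like the latter.  The estimator-comparison suite
  therefore reports a contrast trend opposite to what noise-floored
  parameter banks produce, and the corresponding check fails by design
  rather than being silently weakened.
- The delta-method moments ignore the skewness and kurtosis of the true
  ratio distribution; no higher-order mean correction is applied.
- Gaussian copula only; non-Gaussian dependence and populations beyond pairs
  are out of scope.
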