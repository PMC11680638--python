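# Methods

## Generative models

**Two-session population.** Individual *i*'s true parameter in session
*t* ∈ {T1, T2} is `theta_i^(t) = theta_bar_i + eta^(t) + gamma_i^(t)` with
`theta_bar_i ~ N(mu, sigma_baseline^2)`, a systematic session effect
`eta^(t)` (fixed offsets by default; optionally random,
`eta ~ N(0, sigma_eta^2)` drawn once per simulated study, for designs where
the session effect varies across studies rather than within one), and
`gamma_i^(t) ~ N(0, sigma_gamma^2)` independent across individuals and
sessions. "Case 1" (`eta = 0, sigma_gamma = 0`) keeps true parameters
identical across sessions. The population mean defaults to `mu = 0`:
location drops out of every correlation-based quantity. Group labels
(low/high estimation precision) are Bernoulli(`p_high`) by default; a
deterministic-count mode assigns exactly `round(p_high * n)` individuals to
the high group so that sweeps of `p_high` are exact rather than binomially
jittered. Only two sessions are modeled; slow within-session drift is out
of scope.

**Gaussian response model.** Simulation is at the sufficient-statistic
level: the ML estimate is truth plus `N(0, sigma_eps_g^2)` noise with the
group SE recorded as known. Nothing downstream depends on a trial-level
mechanism, so none is simulated. MAP shrinkage, the empirical-Bayes
marginal likelihood `N(est; mu0, tau^2 + se_i^2)`, and the mixture retest
correlations are closed-form (README). The MAP mixture formula is a derived
expression and is therefore *validated against a Monte-Carlo oracle* in the
test suite: simulated shrunk estimates at n = 50 000, across
`p_high ∈ {0, 0.2, …, 1} × tau ∈ {0.2, 1, 5, ∞}`, agree within ±0.01.
`tau = ∞` is an explicit sentinel meaning "no prior", so one code path
covers ML and MAP.

**Reversal-learning model.** Two options; the chosen option's value moves
toward the binary outcome with learning rate `alpha`; softmax choice with
inverse temperature `beta`. Q values start at (0.5, 0.5) — the unbiased
midpoint for 0/1 outcomes. Task defaults: 200 trials per session, reward
probabilities 0.8/0.2, reversal every 50 trials (trials 51, 101, 151) —
typical of the reversal-learning literature; all config-exposed. Generating
distributions for the precision mixture: `logit(alpha) ~ N(0, 1)`;
`beta ~ LogNormal(log 1, 0.2^2)` (low precision) or `LogNormal(log 8, 0.2^2)`
(high precision). A low `beta` makes choice near-random, which is what
destroys the identifiability of `alpha` and creates the low-precision
group. For Case 2, the intersession decomposition is applied on
`logit(alpha)` with `sigma_baseline = 1` and `sigma_gamma^2 = 0.41`
(intersession correlation `1/1.41 ≈ 0.709`), chosen to mirror the
Gaussian-model Case 2 study; `log(beta)` is session-constant by default
(the learning rate is the parameter of interest) but accepts its own
decomposition via config.

## Estimation

Individual-level fits run on the transformed scale
`(logit alpha, log beta)` with analytic gradients, a BFGS minimizer with
backtracking line search, and 5 restarts (first at the prior mean, the rest
drawn from the prior, or from `N(0, 2^2)` for ML); ties break by lowest
objective then lowest restart index. Transformed parameters are clipped to
±30, beyond which they are numerically at the boundary. SEs come from the
Laplace approximation: the Hessian by central differences (step 1e-4) of
the analytic gradient; a non-positive-definite Hessian is eigenvalue-floored
at 1e-6 and the fit flagged. These kernels are numba-compiled because the
reliability sweeps perform on the order of 10^5 fits.

**Fit failures.** The likelihood is flat in `logit(alpha)` once the
learning rate is numerically at its boundary (with binary outcomes,
`alpha = 0.9` and `alpha = 0.9999` are barely distinguishable), so
unpenalized ML estimates occasionally run away on the transformed scale
with Laplace SEs two to three orders of magnitude above any informative
fit. A fit is flagged failed when it did not converge, sits at the ±30
box bound, or has `SE(logit alpha) > 25` — thresholds that separate the
degenerate cluster (SEs 100+) from healthy fits (SEs below ~2) by orders
of magnitude, so their exact placement is immaterial. Reliability sweeps
correlate the *natural-scale* learning rate (the bounded quantity of
scientific interest) and drop failed fits pairwise, logging the count per
cell; they are never silently included, where a single runaway pair can
dominate a Pearson correlation.

Empirical Bayes is EM with Laplace E-steps. E-step: per-individual MAP and
posterior covariance under the current group prior — warm-started from the
previous iterate after the first iteration (the objective moves only
slightly per EM step, and warm-starting is the standard choice; the first
E-step uses the full multi-restart search). M-step: group mean is the mean
of MAP estimates; group (co)variance is the mean of deviation outer
products *plus* E-step posterior covariances — omitting the posterior term
biases group variances downward. Convergence: max absolute change in group
means and covariances < 1e-4, at most 100 iterations; non-convergence
warns and returns the last iterate. The joint two-session variant gives
each parameter a 2×2 cross-session covariance block (block-diagonal across
parameter types — per-parameter reliability is the target; full coupling
would quadruple the E-step dimension for no benefit here); blocks are kept
positive semidefinite by clamping the implied correlation to |r| ≤ 0.999.
A Laplace approximation of the marginal log-likelihood is recorded each
iteration as an ascent monitor; dips up to ~0.1 nats against objectives in
the thousands are expected Laplace error, and the test suite allows exactly
that.

## Reliability metrics

Pearson retest correlation with Fisher-z 95% CI; ICC(A,1) and ICC(C,1) from
the two-way ANOVA mean squares of the n×2 layout (`MS_R`, `MS_C`, `MS_E`):
`ICC(C,1) = (MS_R − MS_E)/(MS_R + MS_E)` and
`ICC(A,1) = (MS_R − MS_E)/(MS_R + MS_E + (2/n)(MS_C − MS_E))`. The
implementation is cross-validated against pingouin's ANOVA on random tables
to 1e-10. Incomplete pairs are dropped with a warning, never imputed.
`decompose_retest` flags (but still evaluates) ratio inputs above 1, which
are internally inconsistent.

## Bayesian attenuation correction

Model: true pairs `(theta_i^T1, theta_i^T2) ~ N2(mu, Sigma)`; observations
add independent `N(0, se_{i,t}^2)` noise. The latent trues are marginalized
analytically — each observed pair is bivariate normal with covariance
`Sigma + diag(se_i^2)` — so the sampler works in 5 dimensions regardless of
N and handles heterogeneous SEs natively. Priors (weakly informative,
scale-adaptive): `mu_j ~ N(0, (10·SD(data_j))^2)`, session SDs
half-Cauchy with scale `2.5·SD(data_j)`, `rho ~ Uniform(−1, 1)`. Sampler:
4 chains of adaptive random-walk Metropolis on
`(mu1, mu2, log sd1, log sd2, atanh rho)` (Jacobians included), 1000
warmup + 2000 kept draws per chain; during warmup the scalar step size is
nudged toward ~25% acceptance every 100 iterations and the proposal
covariance is re-estimated from the second half of the warmup history.
R-hat and ESS come from arviz; `R-hat(rho) > 1.05` flags the result
non-converged. Setting all SEs to zero reduces the model to a Bayesian
Pearson correlation, which is exactly how the "uncorrected" posterior is
computed — same machinery, SEs forced to zero. With degenerate input
(T2 ≡ T1, zero SEs) the posterior piles up near rho = 1 and R-hat is
meaningless; the flag fires and the result should be read qualitatively.

## Experiment runner and problem sizes

Desk-scale defaults: N = 200 individuals, 10 replications, `p_high` swept
in 0.2 steps; every cell's RNG stream is a deterministic function of
(master seed, experiment, grid index, replication), so each sweep is a pure
function of its config. The acceptance script reports the Case 2 recovery
as the mean corrected posterior mean over 10 replications — the replication
average is the study-level summary of interest, and it halves the
Monte-Carlo scatter of a single draw of 200 individuals. The joint-EB
comparison in the acceptance tests uses 5 replications at
`p_high ∈ {0.6, 0.8, 1.0}`.

## What the simulations do and do not show

The generators implement exactly the assumptions the estimators make:
Gaussian traits, Gaussian session effects, known or well-approximated SEs,
no model misspecification, no outliers, and (for the RL model) the same
Q-learning rule generating and fitting the data. Passing tests therefore
demonstrate internal consistency and correct implementation of the methods,
not robustness on real data — where non-Gaussian parameter distributions,
careless responders, or misspecified learning rules can bias both the
corrected correlation and the model-derived reliability. Robust
(t-distribution) correlation models, >2 sessions, and alternative learning
models (forgetting, dual learning rates) are explicitly out of scope.

## Known limitations

* The attenuation correction treats per-individual SEs as exact; Laplace
  SEs from short RL sessions are coarse, and the correction inherits that
  coarseness (its RL variant is assessed qualitatively, not numerically).
* EM-Laplace empirical Bayes is an approximation to marginal-likelihood
  maximization; with very low-information individuals the group prior can
  pin weakly identified parameters (e.g. `beta`) and reinterpret noise as
  extreme values of the better-identified one.
* The random-walk sampler mixes slowly near |rho| → 1; effective sample
  sizes of a few hundred per run are typical and adequate for posterior
  means and 95% intervals, but tail quantiles are noisy.
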