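# retestkit

Simulation and estimation toolkit for studying the **test–retest
reliability of computational-model parameters** — for cognitive-modeling
and computational-psychiatry researchers who need to know whether a low
retest correlation reflects noisy estimation, genuinely unstable
parameters, or an artifact of the estimator itself.

## What it computes

Classical test theory defines reliability as a variance ratio,

```
reliability = sigma_theta^2 / (sigma_theta^2 + sigma_eps^2),
```

the variance of interest over itself plus unwanted variance, estimated in
practice by the Pearson test–retest correlation or by intraclass
correlations ICC(A,1) / ICC(C,1). `retestkit` provides two simulators and
the estimators needed to probe when those measures mislead:

* **Gaussian response model** — an individual's estimate is the true value
  plus Gaussian error with known SE. Everything is closed-form: with a
  two-group precision mixture (proportion `p_H` of high-precision
  individuals, per-group SEs `sigma_eps,g`, shrinkage weights
  `lambda_g = tau^2/(tau^2 + sigma_eps,g^2)` under a MAP prior of SD `tau`),

  ```
  rho_ML  = sigma_theta^2 / (sigma_theta^2 + sum_g p_g sigma_eps,g^2)
  rho_MAP = sum_g p_g lambda_g^2 sigma_theta^2
            / sum_g p_g lambda_g^2 (sigma_theta^2 + sigma_eps,g^2)
  ```

  so one can see exactly how priors inflate retest correlations in
  heterogeneous populations without improving anyone's estimate.

* **Q-learning on a probabilistic reversal task** — value update
  `Q(c) <- Q(c) + alpha (R - Q(c))`, softmax choice with inverse
  temperature `beta`. Individual-level ML and MAP fitting (Laplace SEs) and
  group-level empirical Bayes, fit per session or **jointly across
  sessions** with a cross-session covariance whose standardized
  off-diagonal is the *model-derived reliability*.

* **Intersession variability** — true parameters may change between
  sessions: `theta_i^(t) = theta_bar_i + eta^(t) + gamma_i^(t)`
  (stable trait + systematic session effect + individual-by-session random
  effect). The observed retest correlation then factors as

  ```
  rho[est1, est2] = rho[theta1, theta2] * rho[theta1, est1] * rho[theta2, est2]
  ```

  and a **Bayesian attenuation correction** (bivariate-Gaussian
  hierarchical model, latent trues marginalized, adaptive Metropolis MCMC)
  infers `rho[theta1, theta2]` from noisy estimates with known or
  Laplace-approximate SEs.

## Worked example

```python
import math
from retestkit import *

mix = PrecisionMixture(0.6, GaussianGroupSpec(2.0), GaussianGroupSpec(0.5))
inter = IntersessionConfig(sigma_baseline=1.0, sigma_gamma=math.sqrt(0.41))
panel = draw_true_panel(mix, inter, 200, seed=1, deterministic_counts=True)
table = simulate_gaussian_estimates(panel, mix, seed=2)

print(pearson_retest(table).pearson_r)                              # 0.221
print(bayesian_correlation_uncorrected(table, MCMCConfig(seed=4)).rho_mean)  # 0.216
print(bayesian_attenuation_correction(table, MCMCConfig(seed=3)).rho_mean)   # 0.774
```

The generating intersession correlation is `1/1.41 = 0.709`. The raw
test–retest correlation (0.221) is crushed by estimation error; the
uncorrected Bayesian correlation agrees with it; the attenuation-corrected
posterior mean (0.774, 95% CrI 0.647–0.875 for this seed) recovers the
truth. The `examples/` directory has one narrative script per capability —
analytic curves, RL fitting, attenuation correction, joint EB — each
printing the numbers above with an explanation.

A thin CLI mirrors the library:
`retestkit simulate|fit|reliability|attenuate|experiment ...`.

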