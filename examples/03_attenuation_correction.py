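"""Separate intersession variability from estimation error.

Case 2 Gaussian-model simulation: each individual's true parameter is a
stable trait (SD 1) plus a session-specific random effect (variance 0.41),
so the true intersession correlation is 1/1.41 ~ 0.709.  Estimates add known
noise (SE 2.0 for 40% of individuals, 0.5 for the rest).  The Bayesian
attenuation correction infers the intersession correlation of the *true*
parameters from the noisy estimates; a plain Bayesian correlation of the
estimates is attenuated far below it.
"""

import math

from retestkit import (
    GaussianGroupSpec,
    IntersessionConfig,
    MCMCConfig,
    PrecisionMixture,
    bayesian_attenuation_correction,
    bayesian_correlation_uncorrected,
    decompose_retest,
    draw_true_panel,
    pearson_retest,
    simulate_gaussian_estimates,
    theoretical_retest_correlation_intersession,
)

mix = PrecisionMixture(0.6, GaussianGroupSpec(2.0), GaussianGroupSpec(0.5))
inter = IntersessionConfig(sigma_baseline=1.0, sigma_gamma=math.sqrt(0.41))
panel = draw_true_panel(mix, inter, 200, seed=1, deterministic_counts=True)
table = simulate_gaussian_estimates(panel, mix, seed=2)

generating = theoretical_retest_correlation_intersession(inter, 0.0)
retest = pearson_retest(table).pearson_r
corrected = bayesian_attenuation_correction(table, MCMCConfig(seed=3))
uncorrected = bayesian_correlation_uncorrected(table, MCMCConfig(seed=4))

print(f"generating intersession correlation : {generating:.3f}")
print(f"raw test-retest correlation         : {retest:.3f}")
print(
    f"uncorrected Bayesian correlation    : {uncorrected.rho_mean:.3f} "
    f"(95% CrI {uncorrected.rho_ci[0]:.3f}..{uncorrected.rho_ci[1]:.3f})"
)
print(
    f"attenuation-corrected posterior     : {corrected.rho_mean:.3f} "
    f"(95% CrI {corrected.rho_ci[0]:.3f}..{corrected.rho_ci[1]:.3f}, "
    f"R-hat {corrected.rhat['rho']:.3f})"
)
rho_est = decompose_retest(retest, corrected.rho_mean)
print(f"implied true-vs-estimate correlation: {rho_est:.3f}")
print(
    "\nThe corrected posterior centers near the generating 0.709 while the\n"
    "uncorrected correlation is dragged down by estimation noise. The last\n"
    "line factors the raw retest correlation into its two causes: if the\n"
    "intrasession factor is the smaller one, better estimation (more trials)\n"
    "helps more than tighter scheduling of sessions."
)
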