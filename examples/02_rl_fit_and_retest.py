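"""Simulate a two-session reversal-learning study and measure reliability.

A 40% high-precision population (inverse temperature around 8 vs around 1)
plays 200 trials per session twice with identical true parameters.  ML and
MAP (prior SD 1 on logit alpha) estimates are fit per individual-session and
the learning rate's test-retest correlation and ICCs are reported.
"""

from retestkit import (
    IntersessionConfig,
    LogNormalBetaSpec,
    PrecisionMixture,
    TaskConfig,
    TransformedPrior,
    fit_map,
    fit_ml,
    pearson_retest,
)
from retestkit.estimators import fit_results_to_frame
from retestkit.experiments import simulate_rl_population

mix = PrecisionMixture(0.4, LogNormalBetaSpec(1.0), LogNormalBetaSpec(8.0))
panel, pairs = simulate_rl_population(mix, IntersessionConfig(), 150, TaskConfig(), seed=0)

prior = TransformedPrior(mean=(0.0, 1.0), sd=(1.0, 1.0))
for label, fit in (("ML", lambda d: fit_ml(d)), ("MAP", lambda d: fit_map(d, prior))):
    fits = [fit(d) for pair in pairs for d in pair]
    table = fit_results_to_frame(fits, label)
    report = pearson_retest(table[table.parameter == "alpha_logit"])
    print(
        f"{label:>4}: learning-rate retest r = {report.pearson_r:.3f} "
        f"(95% CI {report.pearson_ci[0]:.3f}..{report.pearson_ci[1]:.3f}), "
        f"ICC(A,1) = {report.icc_a1:.3f}, ICC(C,1) = {report.icc_c1:.3f}"
    )

print(
    "\nTrue parameters are identical across sessions, so any shortfall from\n"
    "r = 1 is pure estimation error. Shrinking noisy individuals toward the\n"
    "prior mean (MAP) raises the correlation above ML's by muting the\n"
    "low-precision group, not by estimating anyone better."
)
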