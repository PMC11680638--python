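"""Joint two-session empirical Bayes and model-derived reliability.

Case 2 reversal-learning simulation (true logit learning rates correlated
~0.709 across sessions, all individuals high-precision).  Compares three
numbers: the test-retest correlation of independently fitted EB estimates,
the same for jointly fitted estimates, and the model-derived reliability
read off the joint group-level covariance.
"""

import numpy as np

from retestkit import (
    IntersessionConfig,
    LogNormalBetaSpec,
    PrecisionMixture,
    TaskConfig,
    eb_fit_independent,
    eb_fit_joint,
    model_derived_reliability,
)
from retestkit.experiments import simulate_rl_population

mix = PrecisionMixture(1.0, LogNormalBetaSpec(1.0), LogNormalBetaSpec(8.0))
inter = IntersessionConfig(sigma_baseline=1.0, sigma_gamma=np.sqrt(0.41))
panel, pairs = simulate_rl_population(mix, inter, 200, TaskConfig(), seed=5)
truth = np.corrcoef(panel["alpha_logit_t1"], panel["alpha_logit_t2"])[0, 1]

_, ind_t1 = eb_fit_independent([d1 for d1, _ in pairs])
_, ind_t2 = eb_fit_independent([d2 for _, d2 in pairs])
r_ind = np.corrcoef(
    [f.estimate[0] for f in ind_t1], [f.estimate[0] for f in ind_t2]
)[0, 1]

model, joint_fits = eb_fit_joint(pairs)
a1 = [f.estimate[0] for f in joint_fits]
a2 = [f.estimate[2] for f in joint_fits]
r_joint = np.corrcoef(a1, a2)[0, 1]

print(f"true intersession correlation (this sample): {truth:.3f}")
print(f"independent-EB point-estimate retest r     : {r_ind:.3f}")
print(f"joint-EB point-estimate retest r           : {r_joint:.3f}")
print(f"joint-EB model-derived reliability         : "
      f"{model_derived_reliability(model, 'alpha_logit'):.3f}")
print(
    "\nJoint fitting couples the two sessions through a shared prior, so its\n"
    "point estimates correlate *above* the true intersession value - an\n"
    "inflated reliability reading. The model-derived number targets the\n"
    "intersession correlation of the true parameters itself (and ignores\n"
    "estimation error entirely); independent-EB point estimates sit below it,\n"
    "attenuated by per-session noise."
)
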