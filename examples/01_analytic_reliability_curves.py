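"""Closed-form test-retest correlation under heterogeneous precision.

Builds a two-group population (low-precision SE 2.0, high-precision SE 0.5,
trait SD 1) and evaluates the analytic test-retest correlation of ML and MAP
estimates as the high-precision proportion sweeps from 0 to 1.
"""

from retestkit import (
    GaussianGroupSpec,
    GaussianPriorSpec,
    PrecisionMixture,
    analytic_retest_correlation,
    intergroup_average_reliability,
)

print(f"{'p_high':>7} {'ML':>7} {'MAP tau=1':>10} {'MAP tau=0.2':>12} {'group avg':>10}")
for p in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
    mix = PrecisionMixture(p, GaussianGroupSpec(2.0), GaussianGroupSpec(0.5))
    ml = analytic_retest_correlation(mix, 1.0)
    map1 = analytic_retest_correlation(mix, 1.0, GaussianPriorSpec(0.0, 1.0))
    map02 = analytic_retest_correlation(mix, 1.0, GaussianPriorSpec(0.0, 0.2))
    avg = intergroup_average_reliability(mix, 1.0)
    print(f"{p:>7.1f} {ml:>7.3f} {map1:>10.3f} {map02:>12.3f} {avg:>10.3f}")

print(
    "\nAt the pure-population endpoints every column agrees: the prior cannot\n"
    "change a homogeneous population's reliability. In mixtures, a tighter\n"
    "prior (smaller tau) pushes the correlation toward the high-precision\n"
    "group's 0.8 — a higher number without any improvement for the\n"
    "low-precision individuals, while plain ML sits below the group average."
)
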