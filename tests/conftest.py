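import numpy as np
import pandas as pd
import pytest

from retestkit import (
    CASE1,
    GaussianGroupSpec,
    IntersessionConfig,
    PrecisionMixture,
    RLParams,
    TaskConfig,
    draw_true_panel,
    simulate_gaussian_estimates,
    simulate_session,
)


@pytest.fixture(scope="session")
def gaussian_mixture():
    """The reference two-group precision mixture: SEs 2.0 (low) and 0.5 (high)."""

    def make(p_high):
        return PrecisionMixture(p_high, GaussianGroupSpec(2.0), GaussianGroupSpec(0.5))

    return make


@pytest.fixture(scope="session")
def case2_intersession():
    """Intersession variability: trait SD 1, individual-session variance 0.41."""
    return IntersessionConfig(sigma_baseline=1.0, sigma_gamma=float(np.sqrt(0.41)))


@pytest.fixture(scope="session")
def case2_gaussian_table(gaussian_mixture, case2_intersession):
    """A large two-session Gaussian-model estimate table plus its true panel."""
    mix = gaussian_mixture(0.6)
    panel = draw_true_panel(mix, case2_intersession, 20000, seed=101, deterministic_counts=True)
    table = simulate_gaussian_estimates(panel, mix, seed=102)
    return panel, table


@pytest.fixture(scope="session")
def rl_session():
    """One well-identified session: alpha=0.5, beta=8, default reversal task."""
    return simulate_session(RLParams(0.5, 8.0), TaskConfig(), seed=7, individual=0)


def make_estimate_table(t1, t2, se=1.0, method="ML"):
    """Small estimate table from paired values (test helper)."""
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    n = len(t1)
    return pd.DataFrame(
        {
            "id": np.concatenate([np.arange(n), np.arange(n)]),
            "session": ["T1"] * n + ["T2"] * n,
            "method": method,
            "estimate": np.concatenate([t1, t2]),
            "se": se,
        }
    )
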