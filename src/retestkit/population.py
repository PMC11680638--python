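"""Two-session populations of true parameters.

The generative model for an individual *i* and session *t* in {T1, T2} is

    theta_i^(t) = theta_bar_i + eta^(t) + gamma_i^(t)

where ``theta_bar_i ~ Normal(mu, sigma_baseline^2)`` is a stable baseline
(trait), ``eta^(t)`` is a systematic session effect shared by the whole
population (practice, circadian, seasonal effects), and
``gamma_i^(t) ~ Normal(0, sigma_gamma^2)`` is an individual-by-session random
effect (state fluctuations such as mood).  "Case 1" is the degenerate setting
``eta = 0, sigma_gamma = 0`` in which the true parameter is identical across
sessions; "Case 2" has genuine intersession variability.

Each individual additionally belongs to a low- or high-precision group, which
controls the estimation-error variance downstream (a per-session standard
error for the Gaussian response model, or the generating distribution of the
softmax inverse temperature for the reinforcement-learning model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GaussianGroupSpec",
    "LogNormalBetaSpec",
    "PrecisionMixture",
    "IntersessionConfig",
    "CASE1",
    "draw_true_panel",
    "theoretical_reliability",
    "theoretical_retest_correlation_intersession",
]


@dataclass(frozen=True)
class GaussianGroupSpec:
    """Precision descriptor for the Gaussian response model: a per-session SE."""

    sigma_eps: float

    def __post_init__(self) -> None:
        if self.sigma_eps < 0:
            raise ValueError(f"sigma_eps must be >= 0, got {self.sigma_eps}")


@dataclass(frozen=True)
class LogNormalBetaSpec:
    """Precision descriptor for the RL model: log-normal inverse temperature.

    beta ~ LogNormal(log(beta_median), beta_log_sd^2); a low median beta makes
    choices noisy and the learning rate poorly identified (low precision).
    """

    beta_median: float
    beta_log_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.beta_median <= 0:
            raise ValueError("beta_median must be > 0")
        if self.beta_log_sd < 0:
            raise ValueError("beta_log_sd must be >= 0")


@dataclass(frozen=True)
class PrecisionMixture:
    """Two-group mixture of estimation precision.

    Parameters
    ----------
    p_high
        Proportion of high-precision individuals, in [0, 1].
    low_group, high_group
        Per-group precision descriptors (:class:`GaussianGroupSpec` or
        :class:`LogNormalBetaSpec`).
    """

    p_high: float
    low_group: GaussianGroupSpec | LogNormalBetaSpec
    high_group: GaussianGroupSpec | LogNormalBetaSpec

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_high <= 1.0:
            raise ValueError(f"p_high must be in [0, 1], got {self.p_high}")

    def group_spec(self, label: str):
        if label == "high":
            return self.high_group
        if label == "low":
            return self.low_group
        raise KeyError(f"unknown group label {label!r}")


@dataclass(frozen=True)
class IntersessionConfig:
    """Variance decomposition of the true parameter across two sessions.

    Parameters
    ----------
    sigma_baseline
        SD of the stable baseline parameter across individuals (> 0).
    eta
        Fixed systematic session offsets (eta_T1, eta_T2).  Ignored when
        ``sigma_eta`` is set.
    sigma_gamma
        SD of the individual-by-session random effect (>= 0).
    sigma_eta
        If not None, treat the session effect as random: eta^(t) is drawn
        once per simulated study from Normal(0, sigma_eta^2).
    mu
        Population mean of the baseline parameter.  Location is irrelevant
        to every correlation-based metric, so the default is 0.
    """

    sigma_baseline: float = 1.0
    eta: tuple[float, float] = (0.0, 0.0)
    sigma_gamma: float = 0.0
    sigma_eta: float | None = None
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_baseline <= 0:
            raise ValueError("sigma_baseline must be > 0")
        if self.sigma_gamma < 0:
            raise ValueError("sigma_gamma must be >= 0")
        if self.sigma_eta is not None and self.sigma_eta < 0:
            raise ValueError("sigma_eta must be >= 0 when given")


#: Case 1: true parameters identical across sessions.
CASE1 = IntersessionConfig()


def draw_true_panel(
    mix: PrecisionMixture,
    inter: IntersessionConfig,
    n: int,
    seed: int,
    deterministic_counts: bool = False,
) -> pd.DataFrame:
    """Draw true two-session parameters for ``n`` individuals.

    Returns a DataFrame with columns ``id``, ``group`` ("low"/"high"),
    ``theta_t1`` and ``theta_t2``.  Under Case 1 the two theta columns are
    exactly equal.

    Parameters
    ----------
    deterministic_counts
        If True, assign exactly ``round(p_high * n)`` individuals to the
        high-precision group (for exact sweeps of the mixture proportion)
        instead of drawing labels Bernoulli(p_high).
    """
    if n < 2:
        raise ValueError("need at least two individuals")
    rng = np.random.default_rng(seed)

    if deterministic_counts:
        n_high = int(round(mix.p_high * n))
        labels = np.array(["low"] * (n - n_high) + ["high"] * n_high)
        rng.shuffle(labels)
    else:
        labels = np.where(rng.random(n) < mix.p_high, "high", "low")

    baseline = rng.normal(inter.mu, inter.sigma_baseline, size=n)
    if inter.sigma_eta is not None:
        eta = rng.normal(0.0, inter.sigma_eta, size=2)
    else:
        eta = np.asarray(inter.eta, dtype=float)
    gamma = (
        rng.normal(0.0, inter.sigma_gamma, size=(n, 2))
        if inter.sigma_gamma > 0
        else np.zeros((n, 2))
    )

    theta = baseline[:, None] + eta[None, :] + gamma
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "group": labels,
            "theta_t1": theta[:, 0],
            "theta_t2": theta[:, 1],
        }
    )


def theoretical_reliability(var_interest: float, var_components) -> float:
    """Reliability as a variance ratio.

    reliability = var_interest / (var_interest + sum(unwanted variances)).

    ``var_components`` lists the unwanted variance components, e.g. the
    systematic-session, individual-by-session and estimation-error variances.
    """
    if var_interest <= 0:
        raise ValueError("var_interest must be > 0")
    components = [float(v) for v in np.atleast_1d(var_components)]
    if any(v < 0 for v in components):
        raise ValueError("variance components must be >= 0")
    return var_interest / (var_interest + math.fsum(components))


def theoretical_retest_correlation_intersession(
    inter: IntersessionConfig, sigma_eps: float
) -> float:
    """Population test-retest correlation under intersession variability.

    With homogeneous sigma_gamma and sigma_eps,

        rho = sigma_baseline^2 / (sigma_baseline^2 + sigma_gamma^2 + sigma_eps^2).

    The systematic session effect eta does not enter: correlations are
    computed on session-mean-centred quantities, so a population-wide offset
    vanishes.
    """
    if sigma_eps < 0:
        raise ValueError("sigma_eps must be >= 0")
    v = inter.sigma_baseline**2
    return v / (v + inter.sigma_gamma**2 + sigma_eps**2)
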