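"""Reliability metrics and the Bayesian attenuation correction.

Classical metrics on a two-session estimate table: the Pearson test-retest
correlation, and the single-measure intraclass correlations from a two-way
ANOVA — ICC(A,1), which penalizes systematic between-session offsets, and
ICC(C,1), which forgives offsets but not scale changes.

The decomposition layer separates the two causes of imperfect reliability:
the test-retest correlation of estimates factors into the intersession
correlation of the *true* parameters times the two intrasession
true-vs-estimate correlations,

    rho[est1, est2] = rho[theta1, theta2] * rho[theta1, est1] * rho[theta2, est2],

and the square root of an estimator's reliability is the attenuation factor
for any correlation with an external variable.

The Bayesian attenuation correction infers rho[theta1, theta2] directly from
noisy estimates with known (or Laplace-approximate) standard errors: true
pairs are bivariate Gaussian, observations add independent Gaussian noise,
the latent trues are marginalized analytically (each observation pair is
bivariate normal with covariance Sigma + diag(se^2)), and an adaptive
random-walk Metropolis sampler explores (mu1, mu2, log sd1, log sd2,
atanh rho).  Setting every SE to zero reduces the machinery to a plain
Bayesian Pearson correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReliabilityReport",
    "MCMCConfig",
    "PosteriorSummary",
    "pearson_retest",
    "icc",
    "attenuation_factor",
    "decompose_retest",
    "bayesian_attenuation_correction",
    "bayesian_correlation_uncorrected",
]


@dataclass
class ReliabilityReport:
    pearson_r: float
    pearson_ci: tuple[float, float]
    icc_a1: float
    icc_c1: float
    n_pairs: int
    mean_t1: float
    mean_t2: float
    sd_t1: float
    sd_t2: float
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "pearson_ci": list(self.pearson_ci),
            "icc_a1": self.icc_a1,
            "icc_c1": self.icc_c1,
            "n_pairs": self.n_pairs,
            "mean_t1": self.mean_t1,
            "mean_t2": self.mean_t2,
            "sd_t1": self.sd_t1,
            "sd_t2": self.sd_t2,
            "flags": list(self.flags),
        }


def _paired(table: pd.DataFrame):
    """Complete (T1, T2) pairs from an estimate table; drops incomplete ids."""
    wide = table.pivot_table(index="id", columns="session", values="estimate")
    for s in ("T1", "T2"):
        if s not in wide.columns:
            raise ValueError(f"estimate table has no session {s!r}")
    n_total = len(wide)
    wide = wide.dropna(subset=["T1", "T2"])
    dropped = n_total - len(wide)
    if dropped:
        warnings.warn(f"dropped {dropped} ids without both sessions", stacklevel=3)
    return wide["T1"].to_numpy(float), wide["T2"].to_numpy(float)


def pearson_retest(table: pd.DataFrame) -> ReliabilityReport:
    """Pearson test-retest correlation of session T1 vs T2 estimates.

    Requires at least 3 complete pairs; a session with zero variance makes
    the coefficient undefined (NaN, flagged).  The confidence interval is
    the standard Fisher-z 95% interval.
    """
    x, y = _paired(table)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    flags: list[str] = []
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        flags.append("zero_variance")
        r, ci = float("nan"), (float("nan"), float("nan"))
    else:
        r = float(np.corrcoef(x, y)[0, 1])
        if abs(r) < 1.0 and n > 3:
            z = math.atanh(r)
            hw = 1.96 / math.sqrt(n - 3)
            ci = (math.tanh(z - hw), math.tanh(z + hw))
        else:
            ci = (r, r)
    a1, c1 = _icc_pair(x, y)
    return ReliabilityReport(
        pearson_r=r,
        pearson_ci=ci,
        icc_a1=a1,
        icc_c1=c1,
        n_pairs=n,
        mean_t1=float(x.mean()),
        mean_t2=float(y.mean()),
        sd_t1=float(sx),
        sd_t2=float(sy),
        flags=flags,
    )


def _icc_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Single-measure ICCs from the two-way ANOVA of an n x 2 layout."""
    n = len(x)
    k = 2
    data = np.column_stack([x, y])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    c1 = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    a1 = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e))
    return float(a1), float(c1)


def icc(table: pd.DataFrame, variant: str = "A1") -> float:
    """Intraclass correlation of a two-session estimate table.

    variant "A1": absolute agreement, ICC(A,1) — systematic offsets count as
    error.  variant "C1": consistency, ICC(C,1) — offsets are forgiven.
    """
    x, y = _paired(table)
    if len(x) < 2:
        raise ValueError("need at least 2 complete pairs")
    a1, c1 = _icc_pair(x, y)
    if variant.upper() == "A1":
        return a1
    if variant.upper() == "C1":
        return c1
    raise ValueError(f"unknown ICC variant {variant!r} (use 'A1' or 'C1')")


def attenuation_factor(reliability_x: float) -> float:
    """sqrt(reliability): the factor by which estimation error shrinks an
    observed correlation with an external variable below the true one."""
    if not 0.0 <= reliability_x <= 1.0:
        raise ValueError("reliability must be in [0, 1]")
    return math.sqrt(reliability_x)


def decompose_retest(rho_hat_retest: float, rho_true_intersession: float) -> float:
    """Back out the intrasession true-vs-estimate correlation.

    Given the observed test-retest correlation and the intersession
    correlation of the true parameters (equal estimation quality in both
    sessions assumed), returns sqrt(retest / intersession).  A ratio above 1
    is internally inconsistent and is flagged with a warning.
    """
    if not 0.0 < rho_true_intersession <= 1.0:
        raise ValueError("rho_true_intersession must be in (0, 1]")
    if not 0.0 < rho_hat_retest <= 1.0:
        raise ValueError("rho_hat_retest must be in (0, 1]")
    ratio = rho_hat_retest / rho_true_intersession
    if ratio > 1.0:
        warnings.warn(
            "test-retest correlation exceeds the intersession correlation; "
            "inputs are inconsistent with the decomposition",
            stacklevel=2,
        )
    return math.sqrt(ratio)


# ---------------------------------------------------------------------------
# Bayesian attenuation correction


@dataclass(frozen=True)
class MCMCConfig:
    n_chains: int = 4
    n_warmup: int = 1000
    n_draws: int = 2000
    seed: int = 0
    init_scale: float = 0.1
    rhat_limit: float = 1.05


@dataclass
class PosteriorSummary:
    """Posterior draws and summaries for the intersession correlation."""

    draws: pd.DataFrame  # columns: chain, draw, mu1, mu2, sd1, sd2, rho
    mean: dict
    ci95: dict
    rhat: dict
    ess: dict
    converged: bool

    @property
    def rho_mean(self) -> float:
        return self.mean["rho"]

    @property
    def rho_ci(self) -> tuple[float, float]:
        return self.ci95["rho"]


def _log_post(z, x1, x2, s1sq, s2sq, prior_mu_sd, prior_sd_scale):
    """Log posterior on the unconstrained scale (with Jacobians)."""
    mu1, mu2, lsd1, lsd2, zr = z
    if abs(lsd1) > 50 or abs(lsd2) > 50 or abs(zr) > 20:
        return -np.inf
    sd1, sd2 = math.exp(lsd1), math.exp(lsd2)
    rho = math.tanh(zr)

    a = sd1 * sd1 + s1sq
    c = sd2 * sd2 + s2sq
    b = rho * sd1 * sd2
    det = a * c - b * b
    det = np.maximum(det, 1e-300)
    dx1 = x1 - mu1
    dx2 = x2 - mu2
    quad = (c * dx1 * dx1 - 2.0 * b * dx1 * dx2 + a * dx2 * dx2) / det
    loglik = -0.5 * float(np.sum(np.log(det) + quad)) - len(x1) * math.log(2.0 * math.pi)

    # priors: mu ~ N(0, (10 sd_data)^2); sd ~ half-Cauchy(2.5 sd_data); rho ~ U(-1,1)
    lp = -0.5 * (mu1 / prior_mu_sd[0]) ** 2 - 0.5 * (mu2 / prior_mu_sd[1]) ** 2
    lp += -math.log1p((sd1 / prior_sd_scale[0]) ** 2)
    lp += -math.log1p((sd2 / prior_sd_scale[1]) ** 2)
    # Jacobians: log-sd (sd) and atanh-rho (1 - rho^2)
    lp += lsd1 + lsd2 + math.log1p(-rho * rho)
    return loglik + lp


def _run_chain(z0, logp, n_warmup, n_draws, rng, init_scale):
    """Adaptive random-walk Metropolis; proposal covariance adapted in warmup."""
    dim = len(z0)
    z = z0.copy()
    lp = logp(z)
    scale = init_scale
    chol = np.eye(dim)
    warm_hist = np.empty((n_warmup, dim))
    draws = np.empty((n_draws, dim))
    accept_window = []
    for i in range(n_warmup + n_draws):
        prop = z + scale * (chol @ rng.standard_normal(dim))
        lp_prop = logp(prop)
        if math.log(rng.random()) < lp_prop - lp:
            z, lp = prop, lp_prop
            accept_window.append(1.0)
        else:
            accept_window.append(0.0)
        if i < n_warmup:
            warm_hist[i] = z
            if (i + 1) % 100 == 0:
                rate = float(np.mean(accept_window[-100:]))
                # nudge the scalar step toward ~25% acceptance
                scale *= math.exp(rate - 0.25)
                if i + 1 >= 400:
                    cov = np.cov(warm_hist[(i + 1) // 2 : i + 1].T)
                    cov += 1e-8 * np.eye(dim)
                    try:
                        chol = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        pass
        else:
            draws[i - n_warmup] = z
    return draws


def _summarize(chains: np.ndarray, config: MCMCConfig) -> PosteriorSummary:
    """chains: (n_chains, n_draws, 5) on the unconstrained scale."""
    import arviz as az

    names = ["mu1", "mu2", "sd1", "sd2", "rho"]
    nat = np.empty_like(chains)
    nat[..., 0] = chains[..., 0]
    nat[..., 1] = chains[..., 1]
    nat[..., 2] = np.exp(chains[..., 2])
    nat[..., 3] = np.exp(chains[..., 3])
    nat[..., 4] = np.tanh(chains[..., 4])

    ds = az.from_dict({name: nat[..., k] for k, name in enumerate(names)})
    rhat = {name: float(az.rhat(ds)[name].values) for name in names}
    ess = {name: float(az.ess(ds)[name].values) for name in names}
    mean = {name: float(nat[..., k].mean()) for k, name in enumerate(names)}
    ci95 = {
        name: (
            float(np.quantile(nat[..., k], 0.025)),
            float(np.quantile(nat[..., k], 0.975)),
        )
        for k, name in enumerate(names)
    }
    flat = nat.reshape(-1, len(names))
    frame = pd.DataFrame(flat, columns=names)
    frame.insert(0, "draw", np.tile(np.arange(chains.shape[1]), chains.shape[0]))
    frame.insert(0, "chain", np.repeat(np.arange(chains.shape[0]), chains.shape[1]))
    converged = np.isfinite(rhat["rho"]) and rhat["rho"] <= config.rhat_limit
    if not converged:
        warnings.warn(
            f"R-hat for rho is {rhat['rho']:.3f} > {config.rhat_limit}; "
            "posterior flagged as non-converged",
            RuntimeWarning,
            stacklevel=3,
        )
    return PosteriorSummary(frame, mean, ci95, rhat, ess, bool(converged))


def _pairs_with_se(table: pd.DataFrame):
    est = table.pivot_table(index="id", columns="session", values="estimate")
    se = table.pivot_table(index="id", columns="session", values="se")
    keep = est[["T1", "T2"]].notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} ids without both sessions", stacklevel=3)
    est, se = est[keep], se.loc[est[keep].index]
    return (
        est["T1"].to_numpy(float),
        est["T2"].to_numpy(float),
        se["T1"].to_numpy(float),
        se["T2"].to_numpy(float),
    )


def bayesian_attenuation_correction(
    table: pd.DataFrame, config: MCMCConfig = MCMCConfig()
) -> PosteriorSummary:
    """Posterior of the intersession correlation of true parameters.

    Each individual contributes an observed pair with per-session standard
    errors; the marginal likelihood of a pair is bivariate normal with
    covariance Sigma + diag(se^2), so heterogeneous precision is handled
    natively and high-SE individuals are automatically down-weighted.
    """
    x1, x2, se1, se2 = _pairs_with_se(table)
    return _correlation_posterior(x1, x2, se1**2, se2**2, config)


def bayesian_correlation_uncorrected(
    table: pd.DataFrame, config: MCMCConfig = MCMCConfig()
) -> PosteriorSummary:
    """Bayesian Pearson correlation of the estimates (all SEs forced to zero)."""
    x1, x2, _, _ = _pairs_with_se(table)
    zeros = np.zeros_like(x1)
    return _correlation_posterior(x1, x2, zeros, zeros, config)


def _correlation_posterior(x1, x2, s1sq, s2sq, config: MCMCConfig) -> PosteriorSummary:
    if len(x1) < 3:
        raise ValueError("need at least 3 complete pairs")
    sd_data = np.array([max(x1.std(ddof=1), 1e-6), max(x2.std(ddof=1), 1e-6)])
    prior_mu_sd = 10.0 * sd_data
    prior_sd_scale = 2.5 * sd_data

    def logp(z):
        return _log_post(z, x1, x2, s1sq, s2sq, prior_mu_sd, prior_sd_scale)

    r0 = float(np.clip(np.corrcoef(x1, x2)[0, 1], -0.9, 0.9)) if len(x1) > 2 else 0.0
    base = np.array(
        [x1.mean(), x2.mean(), math.log(sd_data[0]), math.log(sd_data[1]), math.atanh(r0)]
    )
    chains = np.empty((config.n_chains, config.n_draws, 5))
    for c in range(config.n_chains):
        rng = np.random.default_rng((config.seed, c))
        z0 = base + 0.1 * rng.standard_normal(5)
        chains[c] = _run_chain(
            z0, logp, config.n_warmup, config.n_draws, rng, config.init_scale
        )
    return _summarize(chains, config)
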