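"""Individual-level ML/MAP fitting and group-level empirical Bayes.

All optimization happens on the transformed scale (logit alpha, log beta),
where Gaussian priors are natural and the parameters are unbounded.  Standard
errors come from the Laplace approximation: the inverse Hessian of the
negative log posterior (or likelihood) at the optimum.

Empirical Bayes is an EM with Laplace-approximate E-steps:

* E-step — each individual's MAP estimate and posterior covariance given the
  current group-level Gaussian prior;
* M-step — group mean is the mean of MAP estimates; group (co)variance is
  the mean of squared deviations *plus* the E-step posterior covariances
  (omitting the latter biases the group variance downward).

The independent variant fits one session at a time with scalar per-parameter
prior variances.  The joint variant models, per parameter, the two sessions'
values as a bivariate Gaussian with a full 2x2 cross-session covariance
block; its off-diagonal, standardized, is the model-derived reliability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .rl import ChoiceData, RLParams

__all__ = [
    "OptConfig",
    "EMConfig",
    "TransformedPrior",
    "FitResult",
    "GroupLevelModel",
    "fit_ml",
    "fit_map",
    "eb_fit_independent",
    "eb_fit_joint",
    "model_derived_reliability",
    "fit_results_to_frame",
]

PARAM_NAMES = ("alpha_logit", "beta_log")
_EMPTY = np.empty(0, dtype=np.int64)


@dataclass(frozen=True)
class OptConfig:
    """Optimizer settings for one individual-level fit."""

    n_restarts: int = 5
    seed: int = 0
    tol: float = 1e-6
    maxiter: int = 200
    hess_step: float = 1e-4
    restart_sd: float = 2.0  # restart spread for ML (no prior to draw from)


@dataclass(frozen=True)
class EMConfig:
    """EM settings for the empirical-Bayes fits."""

    tol: float = 1e-4
    max_iter: int = 100
    opt: OptConfig = field(default_factory=OptConfig)


@dataclass(frozen=True)
class TransformedPrior:
    """Independent Gaussian priors on (alpha_logit, beta_log)."""

    mean: tuple[float, float] = (0.0, 0.0)
    sd: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sd):
            raise ValueError("prior SDs must be > 0")


@dataclass
class FitResult:
    """One individual-session (or individual, for joint fits) optimum."""

    individual: int
    session: str
    estimate: np.ndarray  # transformed scale, aligned with param_names
    se: np.ndarray
    objective: float
    converged: bool
    hessian_pd: bool
    restarts: int
    param_names: tuple[str, ...] = PARAM_NAMES
    posterior_cov: np.ndarray | None = None

    @property
    def params(self) -> RLParams:
        return RLParams.from_transformed(self.estimate[0], self.estimate[1])

    @property
    def failed(self) -> bool:
        """True when the fit carries no usable information about alpha.

        Non-convergence, an estimate pinned at the transformed-scale box
        bound, or a Laplace SE orders of magnitude above any informative
        fit (degenerate flat-likelihood optima show SEs of 100+ against
        <2 for healthy fits) all mark a failure; reliability sweeps drop
        such fits pairwise rather than let them dominate a correlation.
        """
        from . import _kernels

        return (
            not self.converged
            or float(np.abs(self.estimate).max()) >= _kernels.XBOUND - 1.0
            or float(self.se[0]) > 25.0
        )


def _laplace_se(hess: np.ndarray):
    """Invert the Hessian for Laplace SEs; floor eigenvalues if not PD."""
    try:
        cov = np.linalg.inv(hess)
        if np.all(np.diag(cov) > 0):
            return np.sqrt(np.diag(cov)), cov, True
    except np.linalg.LinAlgError:
        pass
    w, v = np.linalg.eigh(0.5 * (hess + hess.T))
    w = np.maximum(w, 1e-6)
    cov = (v / w) @ v.T
    return np.sqrt(np.diag(cov)), cov, False


def _run_fit(
    data1: ChoiceData,
    data2: ChoiceData | None,
    pmu: np.ndarray,
    pprec: np.ndarray,
    x0s: np.ndarray,
    opt: OptConfig,
    session: str,
):
    two = data2 is not None
    ch2 = data2.choices if two else _EMPTY
    out2 = data2.outcomes if two else _EMPTY
    x, f, conv = _kernels.bfgs_fit(
        x0s, data1.choices, data1.outcomes, ch2, out2, two, pmu, pprec,
        opt.tol, opt.maxiter,
    )
    hess = _kernels.hessian_at(
        x, data1.choices, data1.outcomes, ch2, out2, two, pmu, pprec, opt.hess_step
    )
    se, cov, pd_ok = _laplace_se(hess)
    return FitResult(
        individual=data1.individual,
        session=session,
        estimate=x,
        se=se,
        objective=float(f),
        converged=bool(conv),
        hessian_pd=pd_ok,
        restarts=x0s.shape[0],
        param_names=PARAM_NAMES if len(x) == 2 else (
            "alpha_logit_t1", "beta_log_t1", "alpha_logit_t2", "beta_log_t2"
        ),
        posterior_cov=cov,
    )


def _session_code(session: str) -> int:
    # stable across processes (built-in str hash is salted)
    return sum(ord(c) for c in session) % 65536


def _restart_points(mean: np.ndarray, sd: np.ndarray, n: int, rng) -> np.ndarray:
    """First restart at the prior mean, the rest drawn around it."""
    pts = mean + rng.normal(size=(n, len(mean))) * sd
    pts[0] = mean
    return pts


def fit_ml(data: ChoiceData, opt: OptConfig = OptConfig()) -> FitResult:
    """Maximum-likelihood fit of one session (multi-restart BFGS, Laplace SE)."""
    if data.n_trials < 1:
        raise ValueError("need at least one trial")
    rng = np.random.default_rng((opt.seed, data.individual, _session_code(data.session)))
    x0s = _restart_points(
        np.zeros(2), np.full(2, opt.restart_sd), opt.n_restarts, rng
    )
    return _run_fit(
        data, None, np.zeros(2), np.zeros((2, 2)), x0s, opt, data.session
    )


def fit_map(
    data: ChoiceData, prior: TransformedPrior, opt: OptConfig = OptConfig()
) -> FitResult:
    """MAP fit of one session under independent Gaussian priors."""
    mu = np.asarray(prior.mean, dtype=float)
    sd = np.asarray(prior.sd, dtype=float)
    rng = np.random.default_rng((opt.seed, data.individual, _session_code(data.session)))
    x0s = _restart_points(mu, sd, opt.n_restarts, rng)
    return _run_fit(data, None, mu, np.diag(1.0 / sd**2), x0s, opt, data.session)


@dataclass
class GroupLevelModel:
    """Gaussian group-level distribution over transformed parameters.

    Independent variant: per parameter a scalar mean and variance for one
    session.  Joint variant: per parameter a length-2 mean (sessions T1, T2)
    and a 2x2 covariance block whose off-diagonal carries the cross-session
    dependence.  Blocks are symmetric positive semidefinite by construction.
    """

    means: dict
    covs: dict
    joint: bool
    session: str | None = None
    converged: bool = True
    n_iter: int = 0
    history: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "joint": self.joint,
            "session": self.session,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "means": {k: np.asarray(v).tolist() for k, v in self.means.items()},
            "covs": {k: np.asarray(v).tolist() for k, v in self.covs.items()},
        }


def model_derived_reliability(model: GroupLevelModel, param: str = "alpha_logit") -> float:
    """Cross-session correlation read off the group-level covariance block."""
    if not model.joint:
        raise ValueError(
            "model-derived reliability needs a joint fit; the independent "
            "variant has no cross-session covariance"
        )
    block = np.asarray(model.covs[param], dtype=float)
    denom = np.sqrt(block[0, 0] * block[1, 1])
    if denom == 0:
        return 0.0
    return float(block[0, 1] / denom)


def _clamp_corr(block: np.ndarray, limit: float = 0.999) -> np.ndarray:
    """Keep a 2x2 covariance block PSD with |corr| <= limit."""
    v1, v2 = max(block[0, 0], 1e-10), max(block[1, 1], 1e-10)
    c = block[0, 1]
    cmax = limit * np.sqrt(v1 * v2)
    c = float(np.clip(c, -cmax, cmax))
    return np.array([[v1, c], [c, v2]])


def eb_fit_independent(
    all_data: list[ChoiceData], em: EMConfig = EMConfig()
) -> tuple[GroupLevelModel, list[FitResult]]:
    """Empirical-Bayes fit of one session across individuals (EM-Laplace).

    Returns the fitted group-level model (scalar mean/variance per
    parameter) and the final per-individual MAP fits under it.
    """
    if len(all_data) < 2:
        raise ValueError("empirical Bayes needs at least two individuals")
    sessions = {d.session for d in all_data}
    if len(sessions) != 1:
        raise ValueError(f"expected a single session, got {sorted(sessions)}")
    session = next(iter(sessions))

    mu = np.array([0.0, 1.0])  # alpha_logit, beta_log
    var = np.array([2.0, 2.0])
    fits: list[FitResult] = []
    history = []
    converged = False
    it = 0
    for it in range(1, em.max_iter + 1):
        prior = TransformedPrior(mean=tuple(mu), sd=tuple(np.sqrt(var)))
        pprec = np.diag(1.0 / var)
        new_fits = []
        for i, d in enumerate(all_data):
            if fits:  # warm start from the previous E-step optimum
                x0s = fits[i].estimate[None, :].copy()
            else:
                rng = np.random.default_rng((em.opt.seed, d.individual, 0))
                x0s = _restart_points(mu, np.sqrt(var), em.opt.n_restarts, rng)
            new_fits.append(_run_fit(d, None, mu, pprec, x0s, em.opt, session))
        fits = new_fits
        est = np.array([f.estimate for f in fits])
        pvar = np.array([np.diag(f.posterior_cov) for f in fits])
        new_mu = est.mean(axis=0)
        new_var = np.maximum(((est - new_mu) ** 2 + pvar).mean(axis=0), 1e-8)
        history.append(_laplace_marginal(fits, mu, np.diag(var)))
        delta = max(np.abs(new_mu - mu).max(), np.abs(new_var - var).max())
        mu, var = new_mu, new_var
        if delta < em.tol:
            converged = True
            break
    if not converged:
        warnings.warn("EM did not converge within max_iter", RuntimeWarning, stacklevel=2)
    model = GroupLevelModel(
        means={p: float(mu[k]) for k, p in enumerate(PARAM_NAMES)},
        covs={p: float(var[k]) for k, p in enumerate(PARAM_NAMES)},
        joint=False,
        session=session,
        converged=converged,
        n_iter=it,
        history=history,
    )
    return model, fits


def _laplace_marginal(fits, pmu, pcov) -> float:
    """Laplace approximation of the marginal log-likelihood (ascent monitor)."""
    dim = len(pmu)
    sign, logdet_p = np.linalg.slogdet(2.0 * np.pi * np.atleast_2d(pcov))
    total = 0.0
    for f in fits:
        sign_c, logdet_c = np.linalg.slogdet(2.0 * np.pi * f.posterior_cov)
        # f.objective already includes the prior quadratic form
        total += -f.objective - 0.5 * logdet_p + 0.5 * logdet_c
    return float(total)


def eb_fit_joint(
    all_data: list[tuple[ChoiceData, ChoiceData]], em: EMConfig = EMConfig()
) -> tuple[GroupLevelModel, list[FitResult]]:
    """Joint two-session empirical Bayes with cross-session covariance.

    ``all_data`` pairs each individual's (T1, T2) sessions.  The E-step is a
    4-parameter MAP per individual (alpha_logit and beta_log at both
    sessions) against both sessions' likelihoods; the group model keeps, per
    parameter, a 2x2 cross-session covariance block (block-diagonal across
    parameter types).
    """
    if len(all_data) < 2:
        raise ValueError("empirical Bayes needs at least two individuals")
    for d1, d2 in all_data:
        if d1.individual != d2.individual:
            raise ValueError("session pair must belong to one individual")

    # x ordering: (alpha_logit_t1, beta_log_t1, alpha_logit_t2, beta_log_t2)
    a_idx = np.array([0, 2])
    b_idx = np.array([1, 3])
    mu_a = np.zeros(2)
    mu_b = np.ones(2)
    cov_a = np.eye(2) * 2.0
    cov_b = np.eye(2) * 2.0

    fits: list[FitResult] = []
    history = []
    converged = False
    it = 0
    for it in range(1, em.max_iter + 1):
        mu4 = np.empty(4)
        mu4[a_idx] = mu_a
        mu4[b_idx] = mu_b
        prec4 = np.zeros((4, 4))
        prec4[np.ix_(a_idx, a_idx)] = np.linalg.inv(cov_a)
        prec4[np.ix_(b_idx, b_idx)] = np.linalg.inv(cov_b)

        new_fits = []
        for i, (d1, d2) in enumerate(all_data):
            if fits:
                x0s = fits[i].estimate[None, :].copy()
            else:
                rng = np.random.default_rng((em.opt.seed, d1.individual, 1))
                sd4 = np.sqrt(np.concatenate([np.diag(cov_a), np.diag(cov_b)]))[
                    [0, 2, 1, 3]
                ]
                x0s = _restart_points(mu4, sd4, em.opt.n_restarts, rng)
            new_fits.append(_run_fit(d1, d2, mu4, prec4, x0s, em.opt, "joint"))
        fits = new_fits

        est = np.array([f.estimate for f in fits])
        new_mu_a = est[:, a_idx].mean(axis=0)
        new_mu_b = est[:, b_idx].mean(axis=0)
        acc_a = np.zeros((2, 2))
        acc_b = np.zeros((2, 2))
        for f in fits:
            dev_a = f.estimate[a_idx] - new_mu_a
            dev_b = f.estimate[b_idx] - new_mu_b
            acc_a += np.outer(dev_a, dev_a) + f.posterior_cov[np.ix_(a_idx, a_idx)]
            acc_b += np.outer(dev_b, dev_b) + f.posterior_cov[np.ix_(b_idx, b_idx)]
        new_cov_a = _clamp_corr(acc_a / len(fits))
        new_cov_b = _clamp_corr(acc_b / len(fits))

        pcov_full = np.zeros((4, 4))
        pcov_full[np.ix_(a_idx, a_idx)] = cov_a
        pcov_full[np.ix_(b_idx, b_idx)] = cov_b
        history.append(_laplace_marginal(fits, mu4, pcov_full))

        delta = max(
            np.abs(new_mu_a - mu_a).max(),
            np.abs(new_mu_b - mu_b).max(),
            np.abs(new_cov_a - cov_a).max(),
            np.abs(new_cov_b - cov_b).max(),
        )
        mu_a, mu_b, cov_a, cov_b = new_mu_a, new_mu_b, new_cov_a, new_cov_b
        if delta < em.tol:
            converged = True
            break
    if not converged:
        warnings.warn("EM did not converge within max_iter", RuntimeWarning, stacklevel=2)
    model = GroupLevelModel(
        means={"alpha_logit": mu_a.copy(), "beta_log": mu_b.copy()},
        covs={"alpha_logit": cov_a.copy(), "beta_log": cov_b.copy()},
        joint=True,
        converged=converged,
        n_iter=it,
        history=history,
    )
    return model, fits


def fit_results_to_frame(fits: list[FitResult], method: str) -> pd.DataFrame:
    """Serialize fits to a long table: id, session, method, parameter, estimate, se."""
    rows = []
    for f in fits:
        for k, name in enumerate(f.param_names):
            rows.append(
                {
                    "id": f.individual,
                    "session": f.session,
                    "method": method,
                    "parameter": name,
                    "estimate": float(f.estimate[k]),
                    "se": float(f.se[k]),
                    "converged": bool(f.converged),
                }
            )
    return pd.DataFrame(rows)
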