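"""Config-driven simulation experiments at desk scale.

Each runner reproduces one of the study designs end to end with seeded
replications and returns a tidy long table (one row per experiment cell):

* :func:`run_analytic_curves` — closed-form test-retest correlation of
  ML and MAP estimates in the Gaussian response model as a function of the
  high-precision proportion, with an optional Monte-Carlo overlay;
* :func:`run_rl_retest_sweep` — the full RL pipeline under Case 1: simulate
  mixed-precision populations, fit ML/MAP (several prior SDs) and optionally
  empirical Bayes, and record the test-retest correlation of the learning
  rate;
* :func:`run_attenuation_recovery` — Case 2 recovery of the intersession
  correlation by the Bayesian attenuation correction, against the
  uncorrected Bayesian correlation;
* :func:`run_joint_model_comparison` — Case 2 RL comparison of
  independent-session vs joint empirical Bayes: point-estimate test-retest
  correlations and the model-derived reliability.

Every result is a pure function of its config: all RNG streams derive
deterministically from (master seed, experiment, grid point, replication).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import reliability
from .estimators import (
    EMConfig,
    OptConfig,
    TransformedPrior,
    eb_fit_independent,
    eb_fit_joint,
    fit_map,
    fit_ml,
    model_derived_reliability,
)
from .gaussian import (
    ML_PRIOR,
    GaussianPriorSpec,
    analytic_retest_correlation,
    intergroup_average_reliability,
    map_shrink,
    simulate_gaussian_estimates,
)
from .population import (
    CASE1,
    GaussianGroupSpec,
    IntersessionConfig,
    LogNormalBetaSpec,
    PrecisionMixture,
    draw_true_panel,
    theoretical_retest_correlation_intersession,
)
from .reliability import MCMCConfig
from .rl import ChoiceData, RLParams, TaskConfig, simulate_session

__all__ = [
    "ExperimentConfig",
    "simulate_rl_population",
    "run_analytic_curves",
    "run_rl_retest_sweep",
    "run_attenuation_recovery",
    "run_joint_model_comparison",
    "run_experiment",
]

_EXPERIMENT_CODES = {
    "analytic_curves": 1,
    "rl_retest_sweep": 2,
    "attenuation_recovery": 3,
    "joint_model_comparison": 4,
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared settings for all experiment runners (all overridable).

    Defaults: N = 200 individuals, 10 replications, high-precision
    proportion swept in 0.2 increments, Gaussian-model SEs 2.0/0.5 with unit
    trait SD, RL inverse temperatures log-normal around 1 (low precision)
    and 8 (high precision), Case 2 intersession variance 0.41 on the trait
    scale (intersession correlation of about 0.709).
    """

    name: str = "experiment"
    p_grid: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    n_individuals: int = 200
    replications: int = 10
    seed: int = 0
    # Gaussian response model
    sigma_theta: float = 1.0
    se_low: float = 2.0
    se_high: float = 0.5
    tau_grid: tuple[float, ...] = (0.2, 1.0, 5.0)
    mc_overlay_n: int = 0  # 0 disables the Monte-Carlo overlay
    # reinforcement learning model
    task: TaskConfig = field(default_factory=TaskConfig)
    beta_low_median: float = 1.0
    beta_high_median: float = 8.0
    beta_log_sd: float = 0.2
    map_prior_sds: tuple[float, ...] = (0.5, 1.0, 1.5)
    map_prior_beta_sd: float = 1.0
    include_eb: bool = False
    # Case 2 intersession variability (applied on the trait/modeling scale)
    sigma_gamma_sq: float = 0.41
    sigma_gamma_sq_beta: float = 0.0
    # inference settings
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    em: EMConfig = field(default_factory=EMConfig)
    opt: OptConfig = field(default_factory=OptConfig)

    def gaussian_mixture(self, p_high: float) -> PrecisionMixture:
        return PrecisionMixture(
            p_high, GaussianGroupSpec(self.se_low), GaussianGroupSpec(self.se_high)
        )

    def rl_mixture(self, p_high: float) -> PrecisionMixture:
        return PrecisionMixture(
            p_high,
            LogNormalBetaSpec(self.beta_low_median, self.beta_log_sd),
            LogNormalBetaSpec(self.beta_high_median, self.beta_log_sd),
        )

    def intersession(self, case2: bool) -> IntersessionConfig:
        if not case2:
            return CASE1
        return IntersessionConfig(
            sigma_baseline=self.sigma_theta, sigma_gamma=float(np.sqrt(self.sigma_gamma_sq))
        )

    def manifest(self) -> dict:
        d = asdict(self)
        d["task"] = asdict(self.task)
        return d


def _cell_seed(master: int, experiment: str, grid_idx: int, rep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        [int(master), _EXPERIMENT_CODES.get(experiment, 0), grid_idx, rep]
    )


def simulate_rl_population(
    mix: PrecisionMixture,
    inter: IntersessionConfig,
    n: int,
    task: TaskConfig,
    seed,
    inter_beta: IntersessionConfig | None = None,
    deterministic_counts: bool = True,
):
    """Simulate a two-session RL population.

    The intersession decomposition is applied on the transformed scales:
    ``inter`` drives logit(alpha); log(beta) is session-constant unless
    ``inter_beta`` is given.  Returns (truth panel, list of (T1, T2)
    session pairs).  The panel records alpha_logit and beta_log per session
    plus the group label.
    """
    if not isinstance(mix.low_group, LogNormalBetaSpec):
        raise TypeError("simulate_rl_population needs LogNormalBetaSpec groups")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child = ss.spawn(3)
    panel = draw_true_panel(
        mix,
        inter,
        n,
        seed=child[0],
        deterministic_counts=deterministic_counts,
    )
    rng = np.random.default_rng(child[1])
    spec_low, spec_high = mix.low_group, mix.high_group
    med = np.where(
        panel["group"] == "high", spec_high.beta_median, spec_low.beta_median
    )
    lsd = np.where(
        panel["group"] == "high", spec_high.beta_log_sd, spec_low.beta_log_sd
    )
    beta_base = np.log(med) + rng.normal(size=n) * lsd
    if inter_beta is not None:
        gb = rng.normal(0.0, inter_beta.sigma_gamma, size=(n, 2))
        eta_b = np.asarray(inter_beta.eta)
        beta_log = beta_base[:, None] + eta_b[None, :] + gb
    else:
        beta_log = np.repeat(beta_base[:, None], 2, axis=1)
    panel = panel.rename(columns={"theta_t1": "alpha_logit_t1", "theta_t2": "alpha_logit_t2"})
    panel["beta_log_t1"] = beta_log[:, 0]
    panel["beta_log_t2"] = beta_log[:, 1]

    sim_rng = np.random.default_rng(child[2])
    pairs = []
    for i in range(n):
        row = panel.iloc[i]
        d1 = simulate_session(
            RLParams.from_transformed(row["alpha_logit_t1"], row["beta_log_t1"]),
            task,
            seed=int(sim_rng.integers(2**31)),
            session="T1",
            individual=int(row["id"]),
        )
        d2 = simulate_session(
            RLParams.from_transformed(row["alpha_logit_t2"], row["beta_log_t2"]),
            task,
            seed=int(sim_rng.integers(2**31)),
            session="T2",
            individual=int(row["id"]),
        )
        pairs.append((d1, d2))
    return panel, pairs


def run_analytic_curves(config: ExperimentConfig) -> pd.DataFrame:
    """Closed-form ML/MAP test-retest correlation across the precision mixture.

    Emits one row per (p_high, estimator): the ML curve, one MAP curve per
    prior SD in ``tau_grid``, and the intergroup-average line.  With
    ``mc_overlay_n > 0`` a Monte-Carlo estimate at that sample size is added
    for each analytic value (estimator suffix "_mc").
    """
    rows = []
    for gi, p in enumerate(config.p_grid):
        mix = config.gaussian_mixture(p)
        specs = [("ML", ML_PRIOR)] + [
            (f"MAP(tau={tau:g})", GaussianPriorSpec(0.0, tau)) for tau in config.tau_grid
        ]
        for label, prior in specs:
            value = analytic_retest_correlation(mix, config.sigma_theta, prior)
            rows.append(_row(config.name, p, 0, label, "analytic_retest", value))
            if config.mc_overlay_n > 0:
                rng_seed = _cell_seed(config.seed, "analytic_curves", gi, 0)
                s1, s2 = rng_seed.spawn(2)
                panel = draw_true_panel(
                    mix, CASE1, config.mc_overlay_n, s1, deterministic_counts=True
                )
                tab = simulate_gaussian_estimates(panel, mix, s2)
                shrunk = map_shrink(tab, prior) if not prior.is_ml else tab
                r = reliability.pearson_retest(shrunk).pearson_r
                rows.append(_row(config.name, p, 0, label + "_mc", "pearson", r))
        rows.append(
            _row(
                config.name,
                p,
                0,
                "intergroup_average",
                "analytic_retest",
                intergroup_average_reliability(mix, config.sigma_theta),
            )
        )
    return pd.DataFrame(rows)


def _row(name, p, rep, estimator, metric, value):
    return {
        "experiment": name,
        "p_high": p,
        "replication": rep,
        "estimator": estimator,
        "metric": metric,
        "value": float(value),
    }


def _alpha_retest(fits_t1, fits_t2) -> tuple[float, int]:
    """Learning-rate test-retest correlation with pairwise failure exclusion.

    Correlates the natural-scale learning rate (the bounded quantity of
    interest); pairs where either session's fit failed (flat likelihood,
    boundary estimate, non-convergence) are dropped, and the count of
    exclusions is returned alongside.
    """
    from scipy.special import expit

    keep = np.array([not (a.failed or b.failed) for a, b in zip(fits_t1, fits_t2)])
    a1 = expit(np.array([f.estimate[0] for f in fits_t1]))[keep]
    a2 = expit(np.array([f.estimate[0] for f in fits_t2]))[keep]
    n_excluded = int((~keep).sum())
    if len(a1) < 3 or a1.std() == 0 or a2.std() == 0:
        return float("nan"), n_excluded
    return float(np.corrcoef(a1, a2)[0, 1]), n_excluded


def run_rl_retest_sweep(config: ExperimentConfig, case2: bool = False) -> pd.DataFrame:
    """Full RL pipeline: simulate, fit ML/MAP (and optionally EB), correlate.

    For each mixture proportion and replication, simulates a two-session
    population (Case 1 by default), fits every estimator to each
    individual-session, and records the Pearson test-retest correlation of
    the logit learning rate.
    """
    rows = []
    inter = config.intersession(case2)
    for gi, p in enumerate(config.p_grid):
        mix = config.rl_mixture(p)
        for rep in range(config.replications):
            ss = _cell_seed(config.seed, "rl_retest_sweep", gi, rep)
            panel, pairs = simulate_rl_population(
                mix, inter, config.n_individuals, config.task, ss
            )
            sessions = {
                "T1": [d1 for d1, _ in pairs],
                "T2": [d2 for _, d2 in pairs],
            }
            ml_fits = {
                s: [fit_ml(d, config.opt) for d in ds] for s, ds in sessions.items()
            }
            r, n_ex = _alpha_retest(ml_fits["T1"], ml_fits["T2"])
            rows.append(_row(config.name, p, rep, "ML", "pearson", r))
            rows.append(_row(config.name, p, rep, "ML", "excluded_pairs", n_ex))
            for sd in config.map_prior_sds:
                prior = TransformedPrior(mean=(0.0, 1.0), sd=(sd, config.map_prior_beta_sd))
                map_fits = {
                    s: [fit_map(d, prior, config.opt) for d in ds]
                    for s, ds in sessions.items()
                }
                r, n_ex = _alpha_retest(map_fits["T1"], map_fits["T2"])
                label = f"MAP(sd={sd:g})"
                rows.append(_row(config.name, p, rep, label, "pearson", r))
                rows.append(_row(config.name, p, rep, label, "excluded_pairs", n_ex))
            if config.include_eb:
                eb_fits = {}
                for s, ds in sessions.items():
                    _, eb_fits[s] = eb_fit_independent(ds, config.em)
                r, n_ex = _alpha_retest(eb_fits["T1"], eb_fits["T2"])
                rows.append(_row(config.name, p, rep, "EB(independent)", "pearson", r))
                rows.append(
                    _row(config.name, p, rep, "EB(independent)", "excluded_pairs", n_ex)
                )
            true_r = float(
                np.corrcoef(panel["alpha_logit_t1"], panel["alpha_logit_t2"])[0, 1]
            )
            if case2:
                rows.append(_row(config.name, p, rep, "truth", "true_intersession", true_r))
    return pd.DataFrame(rows)


def run_attenuation_recovery(config: ExperimentConfig, model: str = "gaussian") -> pd.DataFrame:
    """Case 2 recovery of the intersession correlation.

    ``model="gaussian"``: estimate-level simulation with known SEs.
    ``model="rl"``: trial-level simulation; inputs to the correction are MAP
    estimates (prior SD 1 on logit alpha) with Laplace-approximate SEs.
    Emits corrected and uncorrected posterior means and 95% CI bounds.
    """
    if model not in ("gaussian", "rl"):
        raise ValueError("model must be 'gaussian' or 'rl'")
    rows = []
    inter = config.intersession(case2=True)
    generating = theoretical_retest_correlation_intersession(inter, 0.0)
    for gi, p in enumerate(config.p_grid):
        for rep in range(config.replications):
            ss = _cell_seed(config.seed, "attenuation_recovery", gi, rep)
            if model == "gaussian":
                mix = config.gaussian_mixture(p)
                s1, s2 = ss.spawn(2)
                panel = draw_true_panel(
                    mix, inter, config.n_individuals, s1, deterministic_counts=True
                )
                table = simulate_gaussian_estimates(panel, mix, s2)
            else:
                mix = config.rl_mixture(p)
                panel, pairs = simulate_rl_population(
                    mix, inter, config.n_individuals, config.task, ss
                )
                prior = TransformedPrior(mean=(0.0, 1.0), sd=(1.0, config.map_prior_beta_sd))
                recs = []
                for d1, d2 in pairs:
                    for d in (d1, d2):
                        f = fit_map(d, prior, config.opt)
                        recs.append(
                            {
                                "id": f.individual,
                                "session": f.session,
                                "method": "MAP",
                                "estimate": f.estimate[0],
                                "se": f.se[0],
                            }
                        )
                table = pd.DataFrame(recs)
            seed_off = int(
                np.random.default_rng(ss).integers(2**31)
            )
            corrected = reliability.bayesian_attenuation_correction(
                table, replace(config.mcmc, seed=seed_off)
            )
            uncorrected = reliability.bayesian_correlation_uncorrected(
                table, replace(config.mcmc, seed=seed_off + 1)
            )
            for label, post in (("corrected", corrected), ("uncorrected", uncorrected)):
                rows.append(_row(config.name, p, rep, label, "posterior_mean", post.rho_mean))
                rows.append(_row(config.name, p, rep, label, "ci_lo", post.rho_ci[0]))
                rows.append(_row(config.name, p, rep, label, "ci_hi", post.rho_ci[1]))
                rows.append(
                    _row(config.name, p, rep, label, "converged", float(post.converged))
                )
            if model == "gaussian":
                emp = float(np.corrcoef(panel["theta_t1"], panel["theta_t2"])[0, 1])
            else:
                emp = float(
                    np.corrcoef(panel["alpha_logit_t1"], panel["alpha_logit_t2"])[0, 1]
                )
            rows.append(_row(config.name, p, rep, "truth", "true_intersession", emp))
            rows.append(
                _row(config.name, p, rep, "truth", "generating_intersession", generating)
            )
    return pd.DataFrame(rows)


def run_joint_model_comparison(config: ExperimentConfig) -> pd.DataFrame:
    """Case 2 RL: independent vs joint empirical Bayes.

    For each cell, emits the point-estimate test-retest correlation of the
    logit learning rate under both EB variants, the joint model's
    model-derived reliability, and the realized intersession correlation of
    the true parameters.
    """
    rows = []
    inter = config.intersession(case2=True)
    generating = theoretical_retest_correlation_intersession(inter, 0.0)
    for gi, p in enumerate(config.p_grid):
        mix = config.rl_mixture(p)
        for rep in range(config.replications):
            ss = _cell_seed(config.seed, "joint_model_comparison", gi, rep)
            panel, pairs = simulate_rl_population(
                mix, inter, config.n_individuals, config.task, ss
            )
            _, ind_t1 = eb_fit_independent([d1 for d1, _ in pairs], config.em)
            _, ind_t2 = eb_fit_independent([d2 for _, d2 in pairs], config.em)
            # all quantities in this comparison live on the logit-alpha scale,
            # matching the generating intersession correlation and the
            # model-derived reliability (EB shrinkage keeps estimates bounded)
            i1 = np.array([f.estimate[0] for f in ind_t1])
            i2 = np.array([f.estimate[0] for f in ind_t2])
            rows.append(
                _row(config.name, p, rep, "EB(independent)", "pearson",
                     float(np.corrcoef(i1, i2)[0, 1]))
            )
            joint_model, joint_fits = eb_fit_joint(pairs, config.em)
            a1 = np.array([f.estimate[0] for f in joint_fits])
            a2 = np.array([f.estimate[2] for f in joint_fits])
            rows.append(
                _row(config.name, p, rep, "EB(joint)", "pearson", float(np.corrcoef(a1, a2)[0, 1]))
            )
            rows.append(
                _row(
                    config.name,
                    p,
                    rep,
                    "EB(joint)",
                    "model_derived",
                    model_derived_reliability(joint_model, "alpha_logit"),
                )
            )
            rows.append(
                _row(
                    config.name,
                    p,
                    rep,
                    "EB(joint)",
                    "converged",
                    float(joint_model.converged),
                )
            )
            emp = float(np.corrcoef(panel["alpha_logit_t1"], panel["alpha_logit_t2"])[0, 1])
            rows.append(_row(config.name, p, rep, "truth", "true_intersession", emp))
            rows.append(
                _row(config.name, p, rep, "truth", "generating_intersession", generating)
            )
    return pd.DataFrame(rows)


_RUNNERS = {
    "analytic_curves": run_analytic_curves,
    "rl_retest_sweep": run_rl_retest_sweep,
    "attenuation_recovery": run_attenuation_recovery,
    "joint_model_comparison": run_joint_model_comparison,
}


def run_experiment(name: str, config: ExperimentConfig, out_dir=None, **kwargs) -> pd.DataFrame:
    """Run a named experiment; optionally write tidy CSV plus a JSON manifest."""
    if name not in _RUNNERS:
        raise KeyError(f"unknown experiment {name!r}; choose from {sorted(_RUNNERS)}")
    config = replace(config, name=name)
    result = _RUNNERS[name](config, **kwargs)
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.to_csv(out / f"{name}.csv", index=False)
        manifest = {"experiment": name, "config": config.manifest(), "kwargs": kwargs}
        (out / f"{name}_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return result
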