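import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from retestkit import (
    MCMCConfig,
    attenuation_factor,
    bayesian_attenuation_correction,
    bayesian_correlation_uncorrected,
    decompose_retest,
    icc,
    pearson_retest,
)
from conftest import make_estimate_table

# full warmup is needed for the step-size/covariance adaptation to settle;
# two chains keep the unit tests quick
FAST_MCMC = MCMCConfig(n_chains=2, n_warmup=1000, n_draws=1000, seed=0)


class TestPearsonRetest:
    def test_identical_sessions_give_one(self):
        tab = make_estimate_table([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert pearson_retest(tab).pearson_r == pytest.approx(1.0)

    def test_affine_invariance(self):
        t1 = [1.0, 2.0, 3.0, 4.0]
        tab = make_estimate_table(t1, [2 * v + 3 for v in t1])
        assert pearson_retest(tab).pearson_r == pytest.approx(1.0)

    def test_matches_independent_oracle_on_small_table(self):
        t1, t2 = [1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 3.0, 4.0]
        report = pearson_retest(make_estimate_table(t1, t2))
        assert report.pearson_r == pytest.approx(stats.pearsonr(t1, t2)[0])
        assert report.pearson_r == pytest.approx(0.8)
        assert report.n_pairs == 4

    def test_zero_variance_flagged(self):
        tab = make_estimate_table([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        report = pearson_retest(tab)
        assert math.isnan(report.pearson_r)
        assert "zero_variance" in report.flags

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            pearson_retest(make_estimate_table([1.0, 2.0], [1.0, 2.0]))

    def test_incomplete_pairs_dropped_with_warning(self):
        tab = make_estimate_table([1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 3.0, 4.0])
        tab = tab.drop(tab[(tab.id == 3) & (tab.session == "T2")].index)
        with pytest.warns(UserWarning, match="dropped 1"):
            report = pearson_retest(tab)
        assert report.n_pairs == 3


class TestICC:
    def test_hand_computed_anova(self):
        # rows (1,2),(2,3),(3,4): MS_R=2, MS_C=1.5, MS_E=0
        tab = make_estimate_table([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert icc(tab, "C1") == pytest.approx(1.0)
        assert icc(tab, "A1") == pytest.approx(2.0 / 3.0)

    def test_perfect_agreement(self):
        tab = make_estimate_table([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert icc(tab, "A1") == pytest.approx(1.0)
        assert icc(tab, "C1") == pytest.approx(1.0)

    def test_against_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(4, 30)
            t1 = rng.normal(0, 1, n)
            t2 = 0.6 * t1 + rng.normal(0, 0.8, n) + rng.normal(0, 0.3)
            tab = make_estimate_table(t1, t2)
            long = pd.DataFrame(
                {
                    "targets": np.tile(np.arange(n), 2),
                    "raters": np.repeat(["T1", "T2"], n),
                    "ratings": np.concatenate([t1, t2]),
                }
            )
            res = pingouin.intraclass_corr(
                long, targets="targets", raters="raters", ratings="ratings"
            ).set_index("Type")
            assert icc(tab, "A1") == pytest.approx(res.loc["ICC(A,1)", "ICC"], abs=1e-10)
            assert icc(tab, "C1") == pytest.approx(res.loc["ICC(C,1)", "ICC"], abs=1e-10)

    def test_consistency_equals_pearson_when_variances_match(self):
        rng = np.random.default_rng(1)
        t1 = rng.normal(0, 1, 200)
        t2 = rng.permutation(t1)  # same sample variance by construction
        tab = make_estimate_table(t1, t2)
        assert icc(tab, "C1") == pytest.approx(pearson_retest(tab).pearson_r, abs=1e-12)

    def test_consistency_below_pearson_when_scales_differ(self):
        rng = np.random.default_rng(2)
        t1 = rng.normal(0, 1, 500)
        t2 = 3.0 * t1 + rng.normal(0, 0.1, 500)  # near-perfect r, scale mismatch
        tab = make_estimate_table(t1, t2)
        assert icc(tab, "C1") < pearson_retest(tab).pearson_r

    def test_large_sample_agreement_with_pearson(self):
        rng = np.random.default_rng(3)
        theta = rng.normal(0, 1, 5000)
        t1 = theta + rng.normal(0, 0.7, 5000)
        t2 = theta + rng.normal(0, 0.7, 5000)
        tab = make_estimate_table(t1, t2)
        r = pearson_retest(tab).pearson_r
        assert icc(tab, "A1") == pytest.approx(r, abs=0.02)
        assert icc(tab, "C1") == pytest.approx(r, abs=0.02)


class TestAttenuation:
    def test_square_root_relation(self):
        assert attenuation_factor(1.0) == 1.0
        assert attenuation_factor(0.64) == pytest.approx(0.8)
        with pytest.raises(ValueError):
            attenuation_factor(1.2)

    def test_observed_correlation_attenuated_by_factor(self):
        # external variable correlated 0.5 with the true parameter; the
        # estimate has reliability 0.64, so observed r should be ~0.4
        rng = np.random.default_rng(4)
        n = 20000
        theta = rng.normal(0, 1, n)
        external = 0.5 * theta + math.sqrt(1 - 0.25) * rng.normal(0, 1, n)
        sigma_eps = math.sqrt(1 / 0.64 - 1)  # reliability 0.64
        est = theta + rng.normal(0, sigma_eps, n)
        observed = np.corrcoef(external, est)[0, 1]
        assert observed == pytest.approx(0.5 * attenuation_factor(0.64), abs=0.03)

    def test_decompose_retest_values(self):
        assert decompose_retest(0.5, 1.0) == pytest.approx(math.sqrt(0.5))
        assert decompose_retest(0.3, 0.74) == pytest.approx(math.sqrt(0.3 / 0.74))

    def test_decompose_inconsistent_inputs_flagged(self):
        with pytest.warns(UserWarning, match="inconsistent"):
            decompose_retest(0.9, 0.5)
        with pytest.raises(ValueError):
            decompose_retest(0.0, 0.5)

    def test_product_identity_on_simulation(self, case2_gaussian_table):
        # retest corr of estimates = intersession corr x the two
        # intrasession true-vs-estimate corrs
        panel, table = case2_gaussian_table
        wide = table.pivot(index="id", columns="session", values="estimate")
        merged = panel.set_index("id").join(wide)
        r_retest = np.corrcoef(merged["T1"], merged["T2"])[0, 1]
        product = (
            np.corrcoef(merged["theta_t1"], merged["theta_t2"])[0, 1]
            * np.corrcoef(merged["theta_t1"], merged["T1"])[0, 1]
            * np.corrcoef(merged["theta_t2"], merged["T2"])[0, 1]
        )
        assert r_retest == pytest.approx(product, abs=0.02)


class TestBayesianCorrection:
    def test_identical_sessions_concentrate_near_one(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, 100)
        tab = make_estimate_table(vals, vals, se=0.0)
        post = bayesian_correlation_uncorrected(tab, FAST_MCMC)
        assert post.rho_mean > 0.9

    def test_recovers_generating_correlation_with_known_ses(self):
        rng = np.random.default_rng(6)
        n = 200
        rho = 0.7
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], n)
        se = np.where(rng.random(n) < 0.5, 1.5, 0.3)
        obs = z + rng.normal(0, 1, (n, 2)) * se[:, None]
        tab = make_estimate_table(obs[:, 0], obs[:, 1], se=np.concatenate([se, se]))
        post = bayesian_attenuation_correction(tab, FAST_MCMC)
        assert post.rho_mean == pytest.approx(rho, abs=0.15)
        assert post.rho_ci[0] < rho < post.rho_ci[1]

    def test_correction_exceeds_uncorrected_on_noisy_data(self):
        rng = np.random.default_rng(7)
        n = 200
        z = rng.multivariate_normal([0, 0], [[1, 0.7], [0.7, 1]], n)
        obs = z + rng.normal(0, 1.2, (n, 2))
        tab = make_estimate_table(obs[:, 0], obs[:, 1], se=1.2)
        corrected = bayesian_attenuation_correction(tab, FAST_MCMC)
        uncorrected = bayesian_correlation_uncorrected(tab, FAST_MCMC)
        assert corrected.rho_mean > uncorrected.rho_mean

    def test_summary_contract(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 1, (50, 2))
        tab = make_estimate_table(vals[:, 0], vals[:, 1], se=0.2)
        post = bayesian_attenuation_correction(tab, FAST_MCMC)
        assert list(post.draws.columns) == ["chain", "draw", "mu1", "mu2", "sd1", "sd2", "rho"]
        assert len(post.draws) == FAST_MCMC.n_chains * FAST_MCMC.n_draws
        assert (post.draws["rho"].abs() < 1).all()
        assert set(post.rhat) == {"mu1", "mu2", "sd1", "sd2", "rho"}
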