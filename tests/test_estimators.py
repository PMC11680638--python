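import numpy as np
import pytest

from retestkit import (
    EMConfig,
    OptConfig,
    RLParams,
    TaskConfig,
    TransformedPrior,
    eb_fit_independent,
    eb_fit_joint,
    fit_map,
    fit_ml,
    model_derived_reliability,
    simulate_session,
)
from retestkit.estimators import GroupLevelModel, fit_results_to_frame
from retestkit.rl import ChoiceData


def _noise_data(n=200, seed=0, individual=0):
    """Choices independent of outcomes: alpha and beta unidentifiable."""
    rng = np.random.default_rng(seed)
    return ChoiceData(
        rng.integers(0, 2, n), rng.integers(0, 2, n), individual=individual
    )


def _population(n, seed, beta_median=8.0, n_trials=200, alpha_sd=1.0, case2_gamma=0.0):
    """Simulated population; returns (alpha_logit truths (n,2), session pairs)."""
    rng = np.random.default_rng(seed)
    task = TaskConfig(n_trials=n_trials, reversal_trials=tuple(range(51, n_trials + 1, 50)))
    pairs, truths = [], []
    for i in range(n):
        al = rng.normal(0.0, alpha_sd)
        al1, al2 = al, al
        if case2_gamma > 0:
            g = rng.normal(0.0, case2_gamma, 2)
            al1, al2 = al + g[0], al + g[1]
        lb = np.log(beta_median) + rng.normal(0.0, 0.2)
        d1 = simulate_session(RLParams.from_transformed(al1, lb), task,
                              seed=int(rng.integers(2**31)), session="T1", individual=i)
        d2 = simulate_session(RLParams.from_transformed(al2, lb), task,
                              seed=int(rng.integers(2**31)), session="T2", individual=i)
        pairs.append((d1, d2))
        truths.append((al1, al2))
    return np.array(truths), pairs


class TestFitML:
    def test_long_horizon_parameter_recovery(self):
        task = TaskConfig(n_trials=2000, reversal_trials=tuple(range(51, 2001, 50)))
        data = simulate_session(RLParams(0.5, 8.0), task, seed=11)
        fit = fit_ml(data)
        assert fit.converged
        assert fit.params.alpha == pytest.approx(0.5, abs=0.05)
        assert fit.params.beta == pytest.approx(8.0, rel=0.15)

    def test_determinism(self):
        data = simulate_session(RLParams(0.3, 2.0), seed=12)
        a, b = fit_ml(data, OptConfig(seed=5)), fit_ml(data, OptConfig(seed=5))
        np.testing.assert_array_equal(a.estimate, b.estimate)
        np.testing.assert_array_equal(a.se, b.se)
        assert a.objective == b.objective

    def test_identifiability_collapse_on_noise(self):
        fit = fit_ml(_noise_data(seed=13))
        assert fit.params.beta < 2.0  # far below the high-precision regime
        assert fit.se[0] > 1.5  # alpha_logit SE blows up without signal

    def test_se_of_alpha_decreases_with_beta(self):
        # low inverse temperature -> noisy choices -> poor alpha precision
        def mean_se(beta, seed0):
            ses = []
            for i in range(10):
                d = simulate_session(RLParams(0.4, beta), seed=seed0 + i, individual=i)
                ses.append(fit_map(d, TransformedPrior((0.0, 1.0), (10.0, 10.0))).se[0])
            return np.mean(ses)

        assert mean_se(1.0, 100) > mean_se(8.0, 200)


class TestFitMAP:
    def test_flat_prior_limit_matches_ml(self):
        data = simulate_session(RLParams(0.5, 6.0), seed=14)
        ml = fit_ml(data)
        flat = fit_map(data, TransformedPrior((0.0, 0.0), (1e6, 1e6)))
        np.testing.assert_allclose(flat.estimate, ml.estimate, atol=1e-3)

    def test_zero_information_returns_prior_mean(self):
        empty = ChoiceData(np.empty(0, dtype=int), np.empty(0, dtype=int))
        prior = TransformedPrior((0.3, 0.8), (1.0, 1.0))
        fit = fit_map(empty, prior)
        np.testing.assert_allclose(fit.estimate, [0.3, 0.8], atol=1e-6)

    def test_shrinkage_toward_prior_mean(self):
        prior = TransformedPrior((0.0, 1.0), (1.0, 1.0))
        for seed in range(5):
            data = simulate_session(RLParams(0.7, 5.0), seed=seed, individual=seed)
            ml = fit_ml(data)
            if not ml.converged:
                continue
            mp = fit_map(data, prior)
            lo, hi = sorted((ml.estimate[0], prior.mean[0]))
            assert lo - 1e-6 <= mp.estimate[0] <= hi + 1e-6

    def test_serialization_round_trip(self):
        data = simulate_session(RLParams(0.4, 3.0), seed=15, individual=3)
        frame = fit_results_to_frame([fit_ml(data)], "ML")
        assert list(frame.columns) == [
            "id", "session", "method", "parameter", "estimate", "se", "converged",
        ]
        assert set(frame["parameter"]) == {"alpha_logit", "beta_log"}


@pytest.fixture(scope="module")
def fitted():
    _, pairs = _population(200, seed=21)
    return eb_fit_independent([d1 for d1, _ in pairs])


class TestEBIndependent:
    def test_group_sd_recovery(self, fitted):
        model, _ = fitted
        assert model.converged
        assert 0.8 <= np.sqrt(model.covs["alpha_logit"]) <= 1.2

    def test_marginal_likelihood_ascends(self, fitted):
        # monotone up to Laplace-approximation error, which is O(0.1) nats
        # against objective values in the thousands
        model, _ = fitted
        h = model.history
        assert all(b >= a - 0.1 for a, b in zip(h, h[1:]))

    def test_zero_information_individual_shrinks_to_group_mean(self):
        _, pairs = _population(30, seed=22)
        empty = ChoiceData(
            np.empty(0, dtype=int), np.empty(0, dtype=int), individual=29
        )
        data = [d1 for d1, _ in pairs[:-1]] + [empty]
        model, fits = eb_fit_independent(data)
        assert fits[-1].estimate[0] == pytest.approx(model.means["alpha_logit"], abs=1e-4)
        assert fits[-1].estimate[1] == pytest.approx(model.means["beta_log"], abs=1e-4)

    def test_mixed_sessions_rejected(self):
        _, pairs = _population(3, seed=24, n_trials=50)
        with pytest.raises(ValueError):
            eb_fit_independent([pairs[0][0], pairs[1][1]])


class TestEBJoint:
    def test_case1_recovers_high_correlation(self):
        _, pairs = _population(200, seed=31)
        model, _ = eb_fit_joint(pairs)
        assert model_derived_reliability(model, "alpha_logit") >= 0.9

    def test_independent_parameters_recover_near_zero(self):
        rng = np.random.default_rng(32)
        task = TaskConfig()
        pairs = []
        for i in range(200):
            lb = np.log(8.0) + rng.normal(0.0, 0.2)
            d1 = simulate_session(
                RLParams.from_transformed(rng.normal(), lb), task,
                seed=int(rng.integers(2**31)), session="T1", individual=i)
            d2 = simulate_session(
                RLParams.from_transformed(rng.normal(), lb), task,
                seed=int(rng.integers(2**31)), session="T2", individual=i)
            pairs.append((d1, d2))
        model, _ = eb_fit_joint(pairs)
        assert abs(model_derived_reliability(model, "alpha_logit")) <= 0.15

    def test_blocks_symmetric_psd(self):
        _, pairs = _population(40, seed=33, n_trials=100)
        model, _ = eb_fit_joint(pairs)
        for name in ("alpha_logit", "beta_log"):
            block = model.covs[name]
            np.testing.assert_allclose(block, block.T)
            assert np.all(np.linalg.eigvalsh(block) >= -1e-10)


class TestModelDerivedReliability:
    @pytest.mark.parametrize(
        "block,expected",
        [
            ([[1.0, 0.76], [0.76, 1.0]], 0.76),
            ([[4.0, 1.52], [1.52, 1.0]], 0.76),
            ([[1.0, 0.0], [0.0, 1.0]], 0.0),
        ],
    )
    def test_read_off_block(self, block, expected):
        model = GroupLevelModel(
            means={"alpha_logit": np.zeros(2)},
            covs={"alpha_logit": np.array(block)},
            joint=True,
        )
        assert model_derived_reliability(model, "alpha_logit") == pytest.approx(expected)

    def test_independent_model_rejected(self):
        model = GroupLevelModel(
            means={"alpha_logit": 0.0}, covs={"alpha_logit": 1.0}, joint=False
        )
        with pytest.raises(ValueError, match="joint"):
            model_derived_reliability(model, "alpha_logit")
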