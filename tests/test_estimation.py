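"""Maximum-likelihood estimation: likelihood, Newton solver, inference."""

import math

import numpy as np
import pytest

import expertchoice as ec
from expertchoice.exceptions import RankDeficiencyError, SeparationError

from conftest import make_spec


def panel_dataset(spec, design, weights, n_experts, seed):
    cfg = ec.SimulationConfig(
        spec=spec, design=design, true_weights=np.asarray(weights, float),
        n_experts=n_experts, seed=seed,
    )
    return ec.simulate_choices(cfg)


@pytest.fixture
def small_fit_setup(mixed_spec):
    design = ec.Design(mixed_spec, tuple(mixed_spec.iter_profiles()))
    truth = np.array([-0.4, 0.8, 1.4, 0.5, 0.9])
    dataset = panel_dataset(mixed_spec, design, truth, n_experts=120, seed=3)
    return mixed_spec, dataset, truth


class TestLogLikelihood:
    def test_null_on_525_binary_observations(self, nec_spec, nec_design, nec_fit):
        cfg = ec.SimulationConfig(
            spec=nec_spec, design=nec_design, true_weights=nec_fit.params,
            n_experts=15, seed=0,
        )
        dataset = ec.simulate_choices(cfg)
        ll0 = ec.log_likelihood(np.zeros(nec_spec.n_params), dataset)
        assert ll0 == pytest.approx(525 * math.log(0.5), abs=1e-9)
        assert round(ll0, 2) == -363.90  # printed as -364
        assert round(ll0) == -364

    def test_single_observation_at_zero_utility(self, binary2_spec):
        p = binary2_spec.reference_profile()
        ds = ec.ChoiceDataset(
            binary2_spec, (ec.ChoiceObservation("e1", p, 1),)
        )
        assert ec.log_likelihood(np.zeros(3), ds) == pytest.approx(math.log(0.5))

    def test_five_observation_hand_oracle(self, binary2_spec):
        profiles = list(binary2_spec.iter_profiles())
        obs = tuple(
            ec.ChoiceObservation("e1", profiles[i % 4], c)
            for i, c in enumerate([1, 0, 1, 1, 0])
        )
        ds = ec.ChoiceDataset(binary2_spec, obs)
        w = np.array([0.2, -1.0, 0.7])
        expected = 0.0
        for o in ds.observations:  # term-by-term probability oracle
            v = float(binary2_spec.encode(o.profile) @ w)
            p_yes = math.exp(v) / (1.0 + math.exp(v))
            expected += math.log(p_yes if o.choice == 1 else 1.0 - p_yes)
        assert ec.log_likelihood(w, ds) == pytest.approx(expected, abs=1e-12)

    def test_stable_at_extreme_utilities(self, binary2_spec):
        p = binary2_spec.best_profile()
        ds = ec.ChoiceDataset(binary2_spec, (ec.ChoiceObservation("e", p, 0),))
        ll = ec.log_likelihood(np.array([700.0, 0.0, 0.0]), ds)
        assert np.isfinite(ll) and ll == pytest.approx(-700.0)


class TestFitLogit:
    def test_saturated_model_closed_form(self, binary2_spec):
        # single varying factor -> cell shares give the MLE in closed form
        spec = make_spec([2])
        p0, p1 = list(spec.iter_profiles())
        obs = []
        for i in range(1000):
            obs.append(ec.ChoiceObservation(f"e{i}", p0, 1 if i % 10 < 6 else 0))
        for i in range(1000):
            obs.append(ec.ChoiceObservation(f"g{i}", p1, 1 if i % 10 < 3 else 0))
        fit = ec.fit_logit(ec.ChoiceDataset(spec, tuple(obs)))
        # intercept = logit of the 60% reference-cell share
        assert fit.params[0] == pytest.approx(math.log(0.6 / 0.4), abs=1e-6)
        assert fit.params[0] + fit.params[1] == pytest.approx(
            math.log(0.3 / 0.7), abs=1e-6
        )
        # predicted == observed shares -> zero mean absolute deviation
        ds = ec.ChoiceDataset(spec, tuple(obs))
        assert ec.predicted_observed_mad(fit, ds) == pytest.approx(0.0, abs=1e-4)

    def test_cross_check_against_statsmodels(self, small_fit_setup):
        sm = pytest.importorskip("statsmodels.api")
        spec, dataset, _ = small_fit_setup
        ours = ec.ChoiceLogit(dataset).fit()
        X = dataset.design_matrix()
        y = dataset.responses()
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(ours.params, ref.params, rtol=1e-5, atol=1e-7)
        np.testing.assert_allclose(ours.bse, ref.bse, rtol=1e-4, atol=1e-7)
        assert ours.llf == pytest.approx(ref.llf, abs=1e-6)

    def test_recovers_truth_within_three_se_at_large_n(self, mixed_spec):
        design = ec.Design(mixed_spec, tuple(mixed_spec.iter_profiles()))
        truth = np.array([-0.5, 0.9, 1.5, 0.4, 0.8])
        dataset = panel_dataset(mixed_spec, design, truth, n_experts=560, seed=9)
        assert len(dataset) >= 10_000
        fit = ec.ChoiceLogit(dataset).fit()
        assert np.all(np.abs(fit.params - truth) < 3.0 * fit.bse)

    def test_gradient_small_at_solution(self, small_fit_setup):
        spec, dataset, _ = small_fit_setup
        model = ec.ChoiceLogit(dataset)
        fit = model.fit(tol=1e-8)
        assert np.max(np.abs(model.score(fit.params))) < 1e-8
        assert fit.converged

    def test_newton_trace_is_monotone(self, small_fit_setup):
        _, dataset, _ = small_fit_setup
        fit = ec.ChoiceLogit(dataset).fit()
        trace = np.asarray(fit.ll_trace)
        assert np.all(np.diff(trace) >= -1e-10)

    def test_all_yes_data_raises_separation(self, binary2_spec):
        obs = tuple(
            ec.ChoiceObservation("e", p, 1) for p in binary2_spec.iter_profiles()
        ) * 10
        with pytest.raises(SeparationError):
            ec.fit_logit(ec.ChoiceDataset(binary2_spec, obs))

    def test_collinear_columns_named(self):
        # two linear factors moving in lockstep are indistinguishable
        spec = make_spec([3, 3], coding=["linear", "linear"])
        profiles = [
            spec.profile({"f1": f"L{i}", "f2": f"L{i}"}) for i in range(3)
        ]
        obs = tuple(
            ec.ChoiceObservation(f"e{j}", p, j % 2)
            for j in range(30)
            for p in profiles
        )
        with pytest.raises(RankDeficiencyError) as err:
            ec.fit_logit(ec.ChoiceDataset(spec, obs))
        assert any(name in str(err.value) for name in ("f1", "f2"))


class TestMcFaddenRho2:
    def test_printed_log_likelihoods(self, nec_spec):
        fit = ec.ChoiceLogitResults.from_estimates(
            nec_spec, np.zeros(nec_spec.n_params), llf=-245.0, llnull=-364.0
        )
        assert ec.mcfadden_rho2(fit) == pytest.approx(1 - 245 / 364, abs=1e-12)

    def test_zero_when_model_equals_null(self, nec_spec):
        fit = ec.ChoiceLogitResults.from_estimates(
            nec_spec, np.zeros(nec_spec.n_params), llf=-364.0, llnull=-364.0
        )
        assert ec.mcfadden_rho2(fit) == 0.0

    def test_approaches_one_for_perfect_fit(self, nec_spec):
        fit = ec.ChoiceLogitResults.from_estimates(
            nec_spec, np.zeros(nec_spec.n_params), llf=-1e-9, llnull=-364.0
        )
        assert ec.mcfadden_rho2(fit) == pytest.approx(1.0, abs=1e-9)

    def test_stored_rho2_reproducible_from_lls(self, small_fit_setup):
        _, dataset, _ = small_fit_setup
        fit = ec.ChoiceLogit(dataset).fit()
        assert fit.prsquared == 1.0 - fit.llf / fit.llnull
        assert 0.0 <= fit.prsquared < 1.0


class TestWaldInference:
    def test_zero_weight_gives_p_one(self, binary2_spec):
        fit = ec.ChoiceLogitResults.from_estimates(
            binary2_spec, np.zeros(3), cov_params=np.eye(3)
        )
        table = ec.wald_inference(fit)
        assert np.all(table["p"].to_numpy() == pytest.approx(1.0))

    def test_z_of_196_gives_p_005(self, binary2_spec):
        fit = ec.ChoiceLogitResults.from_estimates(
            binary2_spec, np.full(3, 1.96), cov_params=np.eye(3)
        )
        table = ec.wald_inference(fit)
        assert table["p"].iloc[0] == pytest.approx(0.05, abs=1e-3)

    def test_type_one_error_rate_under_null(self):
        # true factor weight zero: p<0.05 should reject ~5% of the time
        spec = make_spec([2])
        design = ec.Design(spec, tuple(spec.iter_profiles()))
        truth = np.array([0.0, 0.0])
        rejections = 0
        n_reps = 1000
        for r in range(n_reps):
            ds = panel_dataset(spec, design, truth, n_experts=250, seed=10_000 + r)
            fit = ec.ChoiceLogit(ds).fit()
            p = ec.wald_inference(fit)["p"].loc["f1[L1]"]
            rejections += p < 0.05
        assert 0.03 <= rejections / n_reps <= 0.07

    def test_inference_unavailable_without_covariance(self, nec_fit):
        with pytest.raises(ValueError, match="covariance"):
            ec.wald_inference(nec_fit)


class TestPredictedObservedMad:
    def test_single_scenario_arithmetic(self, binary2_spec):
        profile = binary2_spec.reference_profile()
        obs = tuple(
            ec.ChoiceObservation(f"e{i}", profile, 1 if i < 9 else 0)
            for i in range(15)
        )
        ds = ec.ChoiceDataset(binary2_spec, obs)
        fit = ec.ChoiceLogitResults.from_estimates(binary2_spec, np.zeros(3))
        # predicted 0.5 vs observed 9/15
        assert ec.predicted_observed_mad(fit, ds) == pytest.approx(10.0)

    def test_study_scale_mad_is_single_digit(self, nec_spec, nec_design, nec_fit):
        mads = []
        for seed in range(5):
            ds = panel_dataset(nec_spec, nec_design, nec_fit.params, 15, seed)
            fit = ec.ChoiceLogit(ds).fit()
            mads.append(ec.predicted_observed_mad(fit, ds))
        assert all(0.0 < m < 10.0 for m in mads)


class TestMultinomial:
    def test_two_alternatives_match_binary(self, small_fit_setup):
        _, dataset, _ = small_fit_setup
        binary = ec.ChoiceLogit(dataset).fit()
        multi = ec.MultinomialChoiceLogit(dataset.as_multinomial()).fit()
        np.testing.assert_allclose(multi.params, binary.params, atol=1e-6)
        assert multi.llf == pytest.approx(binary.llf, abs=1e-8)
        np.testing.assert_allclose(multi.bse, binary.bse, rtol=1e-5)

    def test_null_log_likelihood_equal_shares(self, binary2_spec):
        profiles = list(binary2_spec.iter_profiles())
        obs = tuple(
            ec.MultinomialObservation("e", tuple(profiles[:3]), i % 3)
            for i in range(9)
        )
        ds = ec.MultinomialChoiceDataset(binary2_spec, obs)
        assert ec.log_likelihood(np.zeros(3), ds) == pytest.approx(
            9 * math.log(1 / 3)
        )

    def test_three_alternative_gradient_vanishes_at_mle(self, mixed_spec):
        # sets of {opt-out, two profiles}: the opt-out anchors the intercept,
        # which would otherwise cancel in utility differences
        rng = np.random.default_rng(4)
        profiles = list(mixed_spec.iter_profiles())
        truth = np.array([-0.3, 0.6, 1.1, 0.4, 0.7])
        obs = []
        for i in range(400):
            alts = tuple(rng.choice(len(profiles), size=2, replace=False))
            alternatives = (None,) + tuple(profiles[j] for j in alts)
            v = np.array([
                0.0 if p is None else mixed_spec.encode(p) @ truth
                for p in alternatives
            ])
            p = np.exp(v - v.max())
            p /= p.sum()
            choice = int(rng.choice(3, p=p))
            obs.append(ec.MultinomialObservation(f"e{i}", alternatives, choice))
        ds = ec.MultinomialChoiceDataset(mixed_spec, obs)
        model = ec.MultinomialChoiceLogit(ds)
        fit = model.fit()
        assert np.max(np.abs(model.score(fit.params))) < 1e-8
        trace = np.asarray(fit.ll_trace)
        assert np.all(np.diff(trace) >= -1e-10)

    def test_mixed_set_sizes_rejected(self, binary2_spec):
        profiles = list(binary2_spec.iter_profiles())
        obs = (
            ec.MultinomialObservation("a", tuple(profiles[:2]), 0),
            ec.MultinomialObservation("b", tuple(profiles[:3]), 0),
        )
        with pytest.raises(ValueError, match="one size"):
            ec.MultinomialChoiceDataset(binary2_spec, obs)
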