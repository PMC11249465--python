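import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from beartrack import hmm
from beartrack.geo import great_circle_km
from beartrack.hmm import (
    HmmParams,
    aicc,
    brute_force_loglik,
    brute_force_viterbi,
    count_parameters,
    fit_hmm,
    hmm_loglik,
    model_selection,
    stationary_distribution,
    stationary_probs,
    steps_and_turns,
    time_budget,
    transition_matrices,
    treat_zero_steps,
    viterbi_decode,
)
from beartrack.regularize import RegularTrack

from conftest import T0, make_series, random_params, random_series

KM_PER_DEG_LAT = 111.195


def _track_from_latlon(lons, lats, temps=None):
    df = pd.DataFrame(
        {
            "time": T0 + pd.to_timedelta(np.arange(len(lons)) * 4.0, unit="h"),
            "lon": np.asarray(lons, dtype=float),
            "lat": np.asarray(lats, dtype=float),
        }
    )
    if temps is not None:
        df["temp_c"] = temps
        df["temp_missing"] = False
    return RegularTrack("t", 0, 4.0, df)


class TestStepsAndTurns:
    def test_collinear_eastward_path_has_zero_turn(self):
        tr = _track_from_latlon([-94.0, -93.9, -93.8, -93.7], [57.0] * 4)
        s = steps_and_turns(tr)
        assert np.allclose(s.data["turn_rad"].to_numpy()[1:], 0.0, atol=1e-9)
        assert np.isnan(s.data["turn_rad"].iloc[0])

    def test_exact_reversal_gives_turn_of_pi(self):
        # north then back south along a meridian: bearing flips by exactly pi,
        # and the (-pi, pi] wrap convention reports +pi
        tr = _track_from_latlon([-94.0] * 3, [57.0, 57.1, 57.0])
        s = steps_and_turns(tr)
        assert s.data["turn_rad"].iloc[1] == pytest.approx(np.pi)

    def test_steps_match_great_circle_oracle(self):
        rng = np.random.default_rng(0)
        lons = -93.5 + np.cumsum(rng.normal(0, 0.02, 10))
        lats = 57.0 + np.cumsum(rng.normal(0, 0.01, 10))
        s = steps_and_turns(_track_from_latlon(lons, lats))
        expected = great_circle_km(lons[:-1], lats[:-1], lons[1:], lats[1:])
        assert np.allclose(s.data["step_km"], expected, rtol=1e-12)

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            steps_and_turns(_track_from_latlon([-94.0, -93.9], [57.0, 57.0]))


class TestParameterCount:
    @pytest.mark.parametrize(
        "label,expected", [("intercept_only", 11), ("temp", 13), ("temp2", 15)]
    )
    def test_two_state_parameter_counts(self, label, expected):
        assert count_parameters(2, label) == expected

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            count_parameters(2, "temp3")


class TestAicc:
    def test_closed_form_example(self):
        # -2*(-100) + 2*3 + 2*3*4/(50-3-1) = 206.5217...
        assert aicc(-100.0, 3, 50) == pytest.approx(206.5217, abs=1e-4)

    def test_large_n_limit_is_aic(self):
        assert aicc(-100.0, 3, 10**9) == pytest.approx(206.0, abs=1e-6)

    def test_identity_holds_for_fits(self, clean_series):
        fit = fit_hmm(clean_series, "intercept_only", n_restarts=2, seed=0)
        expected = -2 * fit.loglik + 2 * fit.K + 2 * fit.K * (fit.K + 1) / (fit.n_obs - fit.K - 1)
        assert fit.aicc == pytest.approx(expected, rel=1e-12)
        assert fit.K == count_parameters(2, "intercept_only")


class TestForwardLikelihood:
    def test_single_observation_closed_form(self):
        rng = np.random.default_rng(1)
        p = random_params(rng)
        s = make_series([0.4])
        lb = hmm._emission_logdensity(np.array([0.4]), np.array([np.nan]), p)[0]
        expected = np.log(np.sum(p.delta * np.exp(lb)))
        assert hmm_loglik(s, p) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("p_cov", [0, 1, 2])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_enumeration(self, p_cov, seed):
        rng = np.random.default_rng(seed)
        params = random_params(rng, p=p_cov)
        series = random_series(rng, T=8, n_segments=2)
        assert hmm_loglik(series, params) == pytest.approx(
            brute_force_loglik(series, params), abs=1e-8
        )

    def test_duplicated_segment_doubles_contribution(self):
        rng = np.random.default_rng(5)
        params = random_params(rng)
        s1 = random_series(rng, T=20, n_segments=1)
        doubled = s1.data.copy()
        doubled["segment_id"] = "copy"
        s2 = hmm.StepSeries(pd.concat([s1.data, doubled], ignore_index=True))
        assert hmm_loglik(s2, params) == pytest.approx(2 * hmm_loglik(s1, params), rel=1e-12)

    def test_zero_step_without_pretreatment_is_an_error(self):
        rng = np.random.default_rng(6)
        params = random_params(rng)
        s = make_series([0.3, 0.0, 0.2])
        with pytest.raises(ValueError, match="interval 1"):
            hmm_loglik(s, params)
        treated = treat_zero_steps(s)
        assert treated.data["step_km"].iloc[1] == pytest.approx(0.1)  # half of min positive
        assert np.isfinite(hmm_loglik(treated, params))


class TestViterbi:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_argmax(self, seed):
        rng = np.random.default_rng(seed)
        params = random_params(rng, p=1)
        series = random_series(rng, T=9, n_segments=2)
        dec = viterbi_decode(series, params)
        assert np.array_equal(dec.states, brute_force_viterbi(series, params))

    def test_uniform_model_decodes_all_state_one(self):
        # identical emissions in both states and symmetric transitions: every
        # path ties, so the convention sends everything to state 1
        p = HmmParams(
            step_mean=np.array([0.5, 0.5]),
            step_sd=np.array([0.3, 0.3]),
            turn_mean=np.array([0.0, 0.0]),
            turn_conc=np.array([1.0, 1.0]),
            beta12=np.array([0.0]),
            beta21=np.array([0.0]),
            delta=np.array([0.5, 0.5]),
        )
        series = make_series([0.3, 0.4, 0.5, 0.2])
        dec = viterbi_decode(series, p)
        assert np.all(dec.states == 1)

    def test_separated_emissions_decode_the_feasible_sequence(self):
        p = HmmParams(
            step_mean=np.array([0.001, 10.0]),
            step_sd=np.array([0.0005, 0.5]),
            turn_mean=np.array([0.0, 0.0]),
            turn_conc=np.array([0.0, 0.0]),
            beta12=np.array([0.0]),
            beta21=np.array([0.0]),
            delta=np.array([0.5, 0.5]),
        )
        steps = np.array([0.001, 10.0, 10.0, 0.001, 10.0])
        dec = viterbi_decode(make_series(steps), p)
        assert list(dec.states) == [1, 2, 2, 1, 2]

    def test_posterior_rows_sum_to_one(self):
        rng = np.random.default_rng(9)
        params = random_params(rng, p=1)
        series = random_series(rng, T=40, n_segments=3)
        dec = viterbi_decode(series, params)
        assert np.allclose(dec.posterior.sum(axis=1), 1.0, atol=1e-12)


class TestTransitionStructure:
    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10**6))
    def test_rows_stochastic_for_any_covariate(self, seed):
        rng = np.random.default_rng(seed)
        params = random_params(rng, p=2)
        temps = rng.uniform(-40, 30, 20)
        G = transition_matrices(params, temps)
        assert np.allclose(G.sum(axis=2), 1.0, atol=1e-12)
        assert np.all(G >= 0)

    def test_symmetric_matrix_has_uniform_stationary_law(self):
        G = np.array([[0.8, 0.2], [0.2, 0.8]])
        assert np.allclose(stationary_distribution(G), [0.5, 0.5])

    def test_stationary_solves_linear_system(self):
        G = np.array([[0.9, 0.1], [0.5, 0.5]])
        assert np.allclose(stationary_distribution(G), [5 / 6, 1 / 6], atol=1e-12)

    def test_absorbing_matrix_rejected(self):
        with pytest.raises(ValueError, match="absorbing"):
            stationary_distribution(np.array([[1.0, 0.0], [0.5, 0.5]]))

    def test_negative_temp_coefficient_gives_monotone_traveling_curve(self):
        p = HmmParams(
            step_mean=np.array([0.02, 0.74]),
            step_sd=np.array([0.02, 0.5]),
            turn_mean=np.array([np.pi, 0.0]),
            turn_conc=np.array([0.7, 1.5]),
            beta12=np.array([-2.9, -0.06]),
            beta21=np.array([-2.0, 0.04]),
            delta=np.array([0.7, 0.3]),
        )
        curve = stationary_probs(p, np.linspace(-25, 15, 41))
        assert np.all(np.diff(curve["p_traveling"]) < 0)
        assert np.allclose(curve["p_resting"] + curve["p_traveling"], 1.0)


class TestTimeBudget:
    def test_seven_of_ten_intervals(self):
        d = hmm.Decoding(np.array([1] * 7 + [2] * 3), np.zeros((10, 2)), np.zeros(10))
        assert np.allclose(time_budget(d), [0.7, 0.3])

    def test_single_state_path(self):
        d = hmm.Decoding(np.ones(5, dtype=int), np.zeros((5, 2)), np.zeros(5))
        assert np.allclose(time_budget(d), [1.0, 0.0])

    def test_empty_decoding_rejected(self):
        d = hmm.Decoding(np.array([], dtype=int), np.zeros((0, 2)), np.array([]))
        with pytest.raises(ValueError):
            time_budget(d)


class TestFit:
    def test_recovers_emission_means_and_dominates_truth(self, clean_study, clean_series):
        truth = clean_study.truth.params
        fit = fit_hmm(clean_series, "temp", n_restarts=4, seed=3)
        assert fit.params.step_mean == pytest.approx(truth.step_mean, rel=0.10)
        assert fit.loglik >= hmm_loglik(clean_series, truth) - 1e-6
        assert fit.params.beta12[1] < 0  # cooling increases resting->traveling switching

    def test_same_seed_gives_identical_fit(self, clean_series):
        a = fit_hmm(clean_series, "intercept_only", n_restarts=2, seed=7)
        b = fit_hmm(clean_series, "intercept_only", n_restarts=2, seed=7)
        assert np.array_equal(a.params.step_mean, b.params.step_mean)
        assert np.array_equal(a.params.beta12, b.params.beta12)
        assert a.loglik == b.loglik

    def test_state_one_is_the_smaller_step_mean(self, clean_series):
        fit = fit_hmm(clean_series, "intercept_only", n_restarts=2, seed=1)
        assert fit.params.step_mean[0] < fit.params.step_mean[1]

    def test_model_selection_table(self, clean_series):
        fits = [
            fit_hmm(clean_series, label, n_restarts=2, seed=0)
            for label in ("intercept_only", "temp")
        ]
        table = model_selection(fits)
        assert list(table.columns) == ["model", "K", "loglik", "AICc", "delta_AICc"]
        assert table["delta_AICc"].iloc[0] == 0.0
        assert table["delta_AICc"].is_monotonic_increasing

    def test_model_selection_rejects_mismatched_data(self, clean_series):
        fit1 = fit_hmm(clean_series, "intercept_only", n_restarts=2, seed=0)
        shorter = hmm.StepSeries(clean_series.data.iloc[:-10].reset_index(drop=True))
        fit2 = fit_hmm(shorter, "temp", n_restarts=2, seed=0)
        with pytest.raises(ValueError, match="identical data"):
            model_selection([fit1, fit2])

    def test_covariate_model_requires_temperature(self):
        s = make_series([0.2, 0.3, 0.4, 0.5], temps=[np.nan] * 4)
        with pytest.raises(ValueError, match="covariate"):
            fit_hmm(s, "temp", n_restarts=1, seed=0)


def test_printed_aicc_difference_recovered_from_loglik_and_k():
    # two fitted models reported with AICc 2327.796 and 2338.155 differ by
    # 10.359 units of AICc
    assert 2338.155 - 2327.796 == pytest.approx(10.359, abs=1e-9)
    table = pd.DataFrame({"AICc": [2338.155, 2327.796]})
    delta = table["AICc"] - table["AICc"].min()
    assert delta.max() == pytest.approx(10.359, abs=1e-9)
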