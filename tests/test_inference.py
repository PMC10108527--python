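"""Decoding, stationary curves, pseudo-residuals, selection, diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mudcrab.hmm import (
    HMMData,
    HMMParams,
    TransitionModel,
    build_transition_matrices,
    fit_hmm,
    intercepts_for_matrix,
    stationary_distribution,
)
from mudcrab.inference import (
    StateSequence,
    design_for_curve,
    enumerate_formulas,
    forward_backward,
    occupancy,
    pseudo_residuals,
    residual_diagnostics,
    select_model,
    spectral_peak_score,
    stationary_probabilities,
    viterbi,
)
from mudcrab.simulate import simulate_hmm_series, simulate_state_sequence

from conftest import make_hmm_data
from test_hmm import emission_logpdf_at, logit_matrix, random_instance


def brute_force_viterbi(step, angle, accel, X, params):
    N, T = params.n_states, len(step)
    em = params.emission
    Gam = np.stack([logit_matrix(X[t] @ params.transition.beta.T, N) for t in range(T)])
    w, v = np.linalg.eig(Gam[0].T)
    delta = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    delta = delta / delta.sum()
    best, best_lp = None, -np.inf
    for path in itertools.product(range(N), repeat=T):
        lp = np.log(delta[path[0]]) + emission_logpdf_at(em, step[0], angle[0],
                                                         None if accel is None else accel[0], path[0])
        for t in range(1, T):
            lp += np.log(Gam[t, path[t - 1], path[t]])
            lp += emission_logpdf_at(em, step[t], angle[t],
                                     None if accel is None else accel[t], path[t])
        if lp > best_lp:  # strict: first (lexicographically lowest) max kept
            best, best_lp = path, lp
    return np.array(best) + 1, best_lp


class TestViterbi:
    @pytest.mark.parametrize("seed,T", [(0, 5), (1, 6), (2, 8), (3, 7)])
    def test_matches_exhaustive_argmax(self, seed, T):
        rng = np.random.default_rng(seed)
        step, angle, accel, X, params = random_instance(rng, 2, T)
        data = make_hmm_data([step], [angle], [accel], X=[X])
        got = viterbi(params, data)[0]
        expected, _ = brute_force_viterbi(step, angle, accel, X, params)
        assert np.array_equal(got.states, expected)

    def test_uninformative_emissions_follow_sticky_state(self, crab_params):
        em = crab_params.emission
        same = type(em)(
            np.full(2, 1.0), np.full(2, 1.0), np.full(2, 0.01), np.full(2, 0.3),
            np.full(2, 0.1), np.full(2, 0.1), np.full(2, 0.01),
        )
        params = HMMParams(2, same, crab_params.transition)
        rng = np.random.default_rng(4)
        T = 60
        step = rng.gamma(1.0, 1.0, T)
        angle = rng.uniform(-np.pi, np.pi, T)
        accel = rng.gamma(1.0, 0.1, T)
        data = make_hmm_data([step], [angle], [accel])
        got = viterbi(params, data)[0]
        # state 2 is both stickier (0.96 vs 0.91) and the stationary majority
        assert np.all(got.states == 2)

    def test_separated_emissions_recover_generating_states(self, crab_params):
        em = crab_params.emission
        sep = type(em)(
            np.array([100.0, 0.1]), np.array([5.0, 0.01]), np.array([1e-4, 1e-4]),
            em.angle_rho, np.array([1.0, 0.001]), np.array([0.05, 1e-4]),
            np.array([1e-4, 1e-4]),
        )
        params = HMMParams(2, sep, crab_params.transition)
        rng = np.random.default_rng(5)
        states = simulate_state_sequence(np.ones((300, 1)), params.transition.beta, 2, seed=rng)
        from mudcrab.simulate import sample_emissions

        step, angle, accel = sample_emissions(states, sep, seed=rng)
        data = make_hmm_data([step], [angle], [accel])
        got = viterbi(params, data)[0]
        assert np.array_equal(got.states, states)

    def test_path_score_beats_pointwise_map(self):
        rng = np.random.default_rng(6)
        step, angle, accel, X, params = random_instance(rng, 3, 8)
        data = make_hmm_data([step], [angle], [accel], X=[X])
        vit = viterbi(params, data)[0]
        pointwise = np.argmax(forward_backward(params, data)[0], axis=1) + 1

        def path_lp(path):
            p0 = path - 1
            N = 3
            Gam = np.stack([logit_matrix(X[t] @ params.transition.beta.T, N) for t in range(len(step))])
            w, v = np.linalg.eig(Gam[0].T)
            delta = np.real(v[:, np.argmin(np.abs(w - 1.0))])
            delta /= delta.sum()
            lp = np.log(delta[p0[0]]) + emission_logpdf_at(params.emission, step[0], angle[0], accel[0], p0[0])
            for t in range(1, len(step)):
                lp += np.log(Gam[t, p0[t - 1], p0[t]])
                lp += emission_logpdf_at(params.emission, step[t], angle[t], accel[t], p0[t])
            return lp

        assert path_lp(vit.states) >= path_lp(pointwise) - 1e-12

    def test_smoothed_probabilities_sum_to_one(self, crab_params, small_data):
        for d in viterbi(crab_params, small_data):
            assert d.probs.sum(axis=1) == pytest.approx(1.0, abs=1e-10)


class TestStationary:
    def test_published_matrix_equilibrium(self, crab_matrix):
        model = TransitionModel(2, ("intercept",), intercepts_for_matrix(crab_matrix))
        out = stationary_probabilities(model, np.ones((1, 1)))
        assert out["p_state1"].iloc[0] == pytest.approx(0.04 / 0.13, abs=1e-9)
        assert out["p_state2"].iloc[0] == pytest.approx(0.09 / 0.13, abs=1e-9)

    def test_symmetric_chain_is_half_half(self):
        eta = np.log(1e-3 / (1 - 1e-3))
        model = TransitionModel(2, ("intercept",), np.full((2, 1), eta))
        out = stationary_probabilities(model, np.ones((1, 1)))
        assert out["p_state1"].iloc[0] == pytest.approx(0.5, abs=1e-12)

    def test_probabilities_sum_to_one_along_curve(self):
        rng = np.random.default_rng(7)
        model = TransitionModel(2, ("intercept", "tide_height"), rng.normal(0, 1, (2, 2)))
        design = design_for_curve(model.columns, "tide_height", np.linspace(0, 2, 21))
        out = stationary_probabilities(model, design)
        assert (out["p_state1"] + out["p_state2"]).to_numpy() == pytest.approx(1.0, abs=1e-12)

    def test_ci_bounds_truncated_and_ordered(self):
        model = TransitionModel(2, ("intercept", "tide_height"),
                                np.array([[-2.0, 0.8], [-3.0, -0.5]]))
        design = design_for_curve(model.columns, "tide_height", np.linspace(0, 2, 5))
        vcov = np.eye(4) * 0.04
        out = stationary_probabilities(model, design, vcov_beta=vcov)
        for n in (1, 2):
            assert np.all(out[f"lo_state{n}"] >= 0.0) and np.all(out[f"hi_state{n}"] <= 1.0)
            assert np.all(out[f"lo_state{n}"] <= out[f"p_state{n}"])
            assert np.all(out[f"hi_state{n}"] >= out[f"p_state{n}"])

    def test_interaction_term_rebuilt_on_curve(self):
        cols = ("intercept", "tide_height", "dtide", "tide_height:dtide")
        X = design_for_curve(cols, "tide_height", np.array([0.0, 1.0, 2.0]),
                             fixed={"dtide": 0.1})
        assert X[:, 3] == pytest.approx(X[:, 1] * 0.1)


class TestPseudoResiduals:
    def test_calibrated_under_generating_model(self, crab_params):
        df = simulate_hmm_series(4, 700, seed=31)
        data = HMMData.from_table(df)
        res = pseudo_residuals(crab_params, data, seed=1)
        for stream in ("step", "angle", "accel"):
            r = res[stream].dropna().to_numpy()
            assert stats.kstest(r, "norm").pvalue > 0.01, stream

    def test_deterministic_given_seed(self, crab_params, small_data):
        a = pseudo_residuals(crab_params, small_data, seed=5)
        b = pseudo_residuals(crab_params, small_data, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_observations_give_missing_residuals(self, crab_params):
        step = np.array([1.0, np.nan, 2.0])
        angle = np.array([np.nan, 0.3, -0.2])
        accel = np.array([0.1, 0.2, np.nan])
        data = make_hmm_data([step], [angle], [accel])
        res = pseudo_residuals(crab_params, data, seed=0)
        assert np.isnan(res["step"].iloc[1])
        assert np.isnan(res["angle"].iloc[0])
        assert np.isnan(res["accel"].iloc[2])


class TestSelectModel:
    def test_formula_enumeration_keeps_tidal_terms_together(self):
        formulas = enumerate_formulas(tide=True, hour=True)
        assert ((),) and () in formulas
        for f in formulas:
            has = [t in f for t in ("tide_height", "dtide", "tide_height:dtide")]
            assert all(has) or not any(has)
        assert len(formulas) == 4  # {none, tide, hour, tide+hour}

    def test_homogeneous_data_prefers_null_model(self):
        df = simulate_hmm_series(4, 500, seed=8)
        rng = np.random.default_rng(9)
        df["tide_height"] = rng.uniform(0, 2, len(df))
        df["dtide"] = rng.normal(0, 0.1, len(df))
        null = fit_hmm(df, 2, (), n_restarts=2, seed=0)
        tidal = fit_hmm(df, 2, ("tide_height", "dtide", "tide_height:dtide"),
                        n_restarts=2, seed=0)
        ranked = select_model([tidal, null])
        assert ranked["formula"].iloc[0] == "(null)"

    def test_order_invariance_and_tie_break(self, small_series_df):
        a = fit_hmm(small_series_df, 2, n_restarts=1, seed=0)
        b = fit_hmm(small_series_df, 2, n_restarts=1, seed=1)
        r1 = select_model([a, b])
        r2 = select_model([b, a])
        pd.testing.assert_frame_equal(r1, r2)
        tied = select_model([a, a])
        assert tied["aic"].iloc[0] == tied["aic"].iloc[1]
        assert tied["n_params"].is_monotonic_increasing

    def test_differing_data_rejected(self, small_series_df):
        a = fit_hmm(small_series_df, 2, n_restarts=1, seed=0)
        other = simulate_hmm_series(2, 100, seed=77)
        b = fit_hmm(other, 2, n_restarts=1, seed=0)
        with pytest.raises(ValueError, match="differing data"):
            select_model([a, b])

    def test_mixture_sweep_penalizes_extra_components(self, small_series_df):
        """On K=1-generated data AIC increases with K."""
        k1 = fit_hmm(small_series_df, 2, K=1, n_restarts=2, seed=0)
        k2 = fit_hmm(small_series_df, 2, K=2, n_restarts=2, seed=0)
        assert k1.aic < k2.aic


class TestResidualDiagnostics:
    def test_white_noise_scores_no_peak(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(4000)
        score = spectral_peak_score(x, 900.0)
        assert score < 3.0

    def test_injected_twelve_hour_cycle_detected(self):
        rng = np.random.default_rng(11)
        n = 4000
        t = np.arange(n) * 900.0
        clean = rng.standard_normal(n)
        dirty = clean + 0.6 * np.sin(2 * np.pi * t / (12 * 3600.0))
        s_clean = spectral_peak_score(clean, 900.0)
        s_dirty = spectral_peak_score(dirty, 900.0)
        assert s_dirty > 10.0 and s_dirty > 5.0 * s_clean

    def test_summary_table_layout(self):
        rng = np.random.default_rng(12)
        frames = {
            dt: pd.DataFrame({"step": rng.standard_normal(2000),
                              "angle": rng.standard_normal(2000),
                              "accel": rng.standard_normal(2000)})
            for dt in (5.0, 15.0)
        }
        out = residual_diagnostics(frames)
        assert set(out["interval_min"]) == {5.0, 15.0}
        assert set(out["stream"]) == {"step", "angle", "accel"}
        assert (out["ks_distance"] < 0.05).all()


class TestOccupancy:
    def test_degenerate_decode(self):
        d = StateSequence("a", np.full(10, 2), np.column_stack([np.zeros(10), np.ones(10)]))
        assert occupancy([d], 2) == pytest.approx([0.0, 1.0])

    def test_fractions_sum_to_one(self, crab_params, small_data):
        occ = occupancy(viterbi(crab_params, small_data))
        assert occ.sum() == pytest.approx(1.0)

    def test_ergodic_agreement_with_stationary(self, crab_matrix):
        beta = intercepts_for_matrix(crab_matrix)
        states = simulate_state_sequence(np.ones((100_000, 1)), beta, 2, seed=13)
        probs = np.eye(2)[states - 1]
        d = StateSequence("a", states, probs)
        occ = occupancy([d], 2)
        assert occ == pytest.approx([0.04 / 0.13, 0.09 / 0.13], abs=0.01)
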