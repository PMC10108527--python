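"""Likelihood correctness against exhaustive oracles, links, and fitting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mudcrab.distributions import wrapped_cauchy_logpdf, zigamma_logpdf
from mudcrab.hmm import (
    EmissionParams,
    HMMData,
    HMMParams,
    MixtureSpec,
    ParamSpec,
    TransitionModel,
    build_transition_matrices,
    fit_hmm,
    forward_loglik,
    intercepts_for_matrix,
    mixture_loglik,
    pack_params,
    penalized_objective,
    stationary_distribution,
    unpack_params,
)

from conftest import make_hmm_data


# ------------------------------------------------------------------ oracles


def logit_matrix(eta_rows, n):
    """Independent transcription of the multinomial-logit link."""
    P = np.zeros((n, n))
    k = 0
    for i in range(n):
        es = []
        for j in range(n):
            if j != i:
                es.append((j, np.exp(eta_rows[k])))
                k += 1
        denom = 1.0 + sum(e for _, e in es)
        P[i, i] = 1.0 / denom
        for j, e in es:
            P[i, j] = e / denom
    return P


def emission_logpdf_at(em, step, angle, accel, state):
    lp = 0.0
    if np.isfinite(step):
        lp += zigamma_logpdf(step, em.step_mean[state], em.step_sd[state], em.step_zeromass[state])
    if np.isfinite(angle):
        lp += wrapped_cauchy_logpdf(angle, em.angle_rho[state])
    if em.has_accel and accel is not None and np.isfinite(accel):
        lp += zigamma_logpdf(accel, em.accel_mean[state], em.accel_sd[state], em.accel_zeromass[state])
    return float(lp)


def enumerate_loglik(step, angle, accel, X, params):
    """Brute-force sum over all N^T state paths."""
    N = params.n_states
    T = len(step)
    em = params.emission
    Gam = np.stack([logit_matrix(X[t] @ params.transition.beta.T, N) for t in range(T)])
    # initial law: stationary distribution of the first matrix by eigensolve
    w, v = np.linalg.eig(Gam[0].T)
    delta = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    delta = delta / delta.sum()
    logB = np.array(
        [[emission_logpdf_at(em, step[t], angle[t], None if accel is None else accel[t], n)
          for n in range(N)] for t in range(T)]
    )
    total = -np.inf
    for path in itertools.product(range(N), repeat=T):
        lp = np.log(delta[path[0]]) + logB[0, path[0]]
        for t in range(1, T):
            lp += np.log(Gam[t, path[t - 1], path[t]]) + logB[t, path[t]]
        total = np.logaddexp(total, lp)
    return total


def random_instance(rng, N, T, p=1, with_accel=True, with_missing=False):
    em = EmissionParams(
        step_mean=rng.uniform(0.5, 20.0, N),
        step_sd=rng.uniform(0.5, 20.0, N),
        step_zeromass=rng.uniform(0.01, 0.2, N),
        angle_rho=rng.uniform(0.05, 0.9, N),
        accel_mean=rng.uniform(0.02, 1.0, N) if with_accel else None,
        accel_sd=rng.uniform(0.02, 1.0, N) if with_accel else None,
        accel_zeromass=rng.uniform(0.01, 0.2, N) if with_accel else None,
    )
    beta = rng.normal(0.0, 1.0, (N * (N - 1), p))
    X = np.column_stack([np.ones(T)] + [rng.normal(size=T) for _ in range(p - 1)])
    step = rng.gamma(2.0, 3.0, T)
    step[rng.random(T) < 0.1] = 0.0
    angle = rng.uniform(-np.pi, np.pi, T)
    accel = rng.gamma(1.5, 0.2, T) if with_accel else None
    if with_missing:
        step[rng.random(T) < 0.2] = np.nan
        angle[0] = np.nan
        if with_accel:
            accel[rng.random(T) < 0.3] = np.nan
    cols = ("intercept",) + tuple(f"c{j}" for j in range(1, p))
    params = HMMParams(N, em, TransitionModel(N, cols, beta))
    return step, angle, accel, X, params


# ------------------------------------------------------------ forward oracle


class TestForwardLikelihood:
    @pytest.mark.parametrize("seed,N,T,p,miss", [
        (0, 2, 5, 1, False), (1, 2, 8, 2, False), (2, 3, 6, 1, False),
        (3, 3, 5, 2, True), (4, 2, 7, 1, True), (5, 3, 8, 3, True),
    ])
    def test_matches_exhaustive_path_sum(self, seed, N, T, p, miss):
        rng = np.random.default_rng(seed)
        step, angle, accel, X, params = random_instance(rng, N, T, p, with_missing=miss)
        data = make_hmm_data([step], [angle], [accel], X=[X])
        got = forward_loglik(data, params)
        assert got == pytest.approx(enumerate_loglik(step, angle, accel, X, params), abs=1e-10)

    def test_single_interval_is_mixture_density(self):
        rng = np.random.default_rng(9)
        step, angle, accel, X, params = random_instance(rng, 2, 1)
        data = make_hmm_data([step], [angle], [accel], X=[X])
        Gam = build_transition_matrices(params.transition.beta, X, 2)
        delta = stationary_distribution(Gam[0])
        direct = np.logaddexp(
            np.log(delta[0]) + emission_logpdf_at(params.emission, step[0], angle[0], accel[0], 0),
            np.log(delta[1]) + emission_logpdf_at(params.emission, step[0], angle[0], accel[0], 1),
        )
        assert forward_loglik(data, params) == pytest.approx(direct, abs=1e-12)

    def test_duplicated_track_doubles_loglik(self):
        rng = np.random.default_rng(10)
        step, angle, accel, X, params = random_instance(rng, 2, 6)
        single = make_hmm_data([step], [angle], [accel], X=[X])
        double = make_hmm_data([step, step], [angle, angle], [accel, accel], X=[X, X])
        assert forward_loglik(double, params) == pytest.approx(
            2.0 * forward_loglik(single, params), abs=1e-9
        )

    def test_jit_and_numpy_recursions_agree(self):
        from mudcrab.hmm import (
            _emission_logprobs,
            _forward_batched,
            _forward_ll,
            _initial_distributions,
        )

        rng = np.random.default_rng(20)
        step, angle, accel, X, params = random_instance(rng, 2, 40, with_missing=True)
        data = make_hmm_data([step, step[:25]], [angle, angle[:25]],
                             [accel, accel[:25]], X=[X, X[:25]])
        logB = _emission_logprobs(data, params.emission)
        Gam = build_transition_matrices(params.transition.beta, data.X, 2)
        delta = _initial_distributions(Gam[:, 0])
        a = _forward_batched(logB, Gam, delta, data.mask)
        b = _forward_ll(logB, Gam, delta, data.mask, data.lengths)
        assert b == pytest.approx(a, abs=1e-10)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(11)
        step, angle, accel, X, params = random_instance(rng, 3, 7)
        data = make_hmm_data([step], [angle], [accel], X=[X])
        perm = np.array([2, 0, 1])
        permuted = HMMParams(3, params.emission.permuted(perm), params.transition.permuted(perm))
        assert forward_loglik(data, permuted) == pytest.approx(
            forward_loglik(data, params), abs=1e-9
        )


# ------------------------------------------------------------- transitions


class TestTransitionMatrices:
    def test_zero_coefficients_give_uniform_rows(self):
        P = build_transition_matrices(np.zeros((2, 1)), np.ones((4, 1)), 2)
        assert P == pytest.approx(np.full((4, 2, 2), 0.5))

    def test_intercept_inversion_reproduces_matrix(self, crab_matrix):
        beta = intercepts_for_matrix(crab_matrix)
        assert beta[0, 0] == pytest.approx(np.log(0.09 / 0.91))
        assert beta[1, 0] == pytest.approx(np.log(0.04 / 0.96))
        P = build_transition_matrices(beta, np.ones((1, 1)), 2)[0]
        assert P == pytest.approx(crab_matrix, abs=1e-12)

    def test_irrelevant_covariate_changes_nothing(self):
        beta = np.array([[0.3, 0.0], [-1.0, 0.0]])
        X = np.column_stack([np.ones(5), np.linspace(-2, 2, 5)])
        P = build_transition_matrices(beta, X, 2)
        assert np.ptp(P, axis=0) == pytest.approx(0.0, abs=1e-15)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_rows_always_stochastic(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(2, 4))
        p = int(rng.integers(1, 4))
        beta = rng.normal(0, 3, (N * (N - 1), p))
        X = np.column_stack([np.ones(6), rng.normal(0, 2, (6, p - 1))]) if p > 1 else np.ones((6, 1))
        P = build_transition_matrices(beta, X, N)
        assert np.all(P >= 0)
        assert P.sum(axis=2) == pytest.approx(1.0, abs=1e-12)

    def test_stationary_of_published_matrix(self, crab_matrix):
        pi = stationary_distribution(crab_matrix)
        assert pi == pytest.approx([0.04 / 0.13, 0.09 / 0.13], abs=1e-12)


# ---------------------------------------------------------------- mixtures


class TestMixture:
    def test_single_component_collapses_to_forward(self):
        rng = np.random.default_rng(12)
        step, angle, accel, X, params = random_instance(rng, 2, 6)
        data = make_hmm_data([step], [angle], [accel], X=[X])
        mix = MixtureSpec(2, params.transition.columns, np.array([1.0]),
                          params.transition.beta[None])
        mparams = HMMParams(2, params.emission, mix)
        assert mixture_loglik(data, mparams) == pytest.approx(
            forward_loglik(data, params), abs=1e-10
        )

    def test_identical_components_make_weights_irrelevant(self):
        rng = np.random.default_rng(13)
        step, angle, accel, X, params = random_instance(rng, 2, 6)
        data = make_hmm_data([step], [angle], [accel], X=[X])
        b = params.transition.beta
        for w in (0.2, 0.5, 0.9):
            mix = MixtureSpec(2, params.transition.columns, np.array([w, 1 - w]),
                              np.stack([b, b]))
            assert mixture_loglik(data, HMMParams(2, params.emission, mix)) == pytest.approx(
                forward_loglik(data, params), abs=1e-10
            )

    def test_matches_hand_computed_mixture(self):
        rng = np.random.default_rng(14)
        step1, angle1, accel1, X1, params = random_instance(rng, 2, 3)
        step2, angle2, accel2, X2, _ = random_instance(rng, 2, 3)
        beta2 = rng.normal(size=params.transition.beta.shape)
        weights = np.array([0.3, 0.7])
        # two individuals: tracks i1-a, i1-b belong to i1; i2-a to i2
        data = make_hmm_data(
            [step1, step2, step1], [angle1, angle2, angle1], [accel1, accel2, accel1],
            X=[X1, X2, X1], track_ids=["i1-a", "i1-b", "i2-a"],
        )
        mix = MixtureSpec(2, params.transition.columns, weights,
                          np.stack([params.transition.beta, beta2]))
        got = mixture_loglik(data, HMMParams(2, params.emission, mix))

        def ll(step, angle, accel, X, beta):
            p = HMMParams(2, params.emission,
                          TransitionModel(2, params.transition.columns, beta))
            return enumerate_loglik(step, angle, accel, X, p)

        expected = 0.0
        for tracks in ([(step1, angle1, accel1, X1), (step2, angle2, accel2, X2)],
                       [(step1, angle1, accel1, X1)]):
            per_k = []
            for k, beta in enumerate([params.transition.beta, beta2]):
                per_k.append(np.log(weights[k]) + sum(ll(*t, beta) for t in tracks))
            expected += np.logaddexp(*per_k)
        assert got == pytest.approx(expected, abs=1e-10)


# ------------------------------------------------- working-scale transforms


class TestWorkingScale:
    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_pack_unpack_roundtrip(self, seed):
        rng = np.random.default_rng(seed)
        _, _, _, _, params = random_instance(rng, int(rng.integers(2, 4)), 3,
                                             p=int(rng.integers(1, 3)))
        w, spec = pack_params(params)
        back = unpack_params(w, spec, params.transition.columns)
        w2, _ = pack_params(back)
        assert w2 == pytest.approx(w, abs=1e-12)
        assert back.emission.step_mean == pytest.approx(params.emission.step_mean, rel=1e-12)
        assert back.emission.angle_rho == pytest.approx(params.emission.angle_rho, abs=1e-12)

    def test_prior_penalty_magnitude(self, small_data, crab_params):
        """Moving an SD working value from 0 to 1 costs 0.5 / 100^2."""
        w, spec = pack_params(crab_params)
        idx = spec.sd_indices()[0]
        w0 = w.copy(); w0[idx] = 0.0
        w1 = w.copy(); w1[idx] = 1.0
        cols = ("intercept",)
        f0 = penalized_objective(w0, spec, small_data, cols)
        f1 = penalized_objective(w1, spec, small_data, cols)
        nll0 = -forward_loglik(small_data, unpack_params(w0, spec, cols))
        nll1 = -forward_loglik(small_data, unpack_params(w1, spec, cols))
        # the penalty (objective minus nll) grows by 0.5/100^2 from 0 to 1
        assert (f1 - nll1) - (f0 - nll0) == pytest.approx(0.5 / 100**2, abs=1e-9)
        # and is bounded below by its value at the prior mode
        base = penalized_objective(w, spec, small_data, cols)
        assert base - (-forward_loglik(small_data, crab_params)) >= -_penalty_at(w * 0, spec) - 1e-9


def _penalty_at(w, spec, prior_sd=100.0):
    t = w[spec.sd_indices()]
    return float(-0.5 * np.sum(t**2) / prior_sd**2
                 - len(t) * (0.5 * np.log(2 * np.pi) + np.log(prior_sd)))


# ---------------------------------------------------------------- fitting


@pytest.fixture(scope="module")
def fit(small_series_df):
    return fit_hmm(small_series_df, 2, n_restarts=3, seed=0, maxiter=400)


class TestFitHMM:
    def test_states_are_canonically_ordered(self, fit):
        assert fit.params.emission.step_mean[0] > fit.params.emission.step_mean[1]

    def test_best_restart_dominates(self, fit):
        assert fit.penalized <= min(r["objective"] for r in fit.restarts) + 1e-9

    def test_aic_identity(self, fit):
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)

    def test_emissions_recovered_roughly(self, fit, crab_emissions):
        # 6 x 300 intervals: loose recovery check, the full-size experiment
        # lives in the acceptance suite
        assert fit.params.emission.step_mean == pytest.approx(
            crab_emissions.step_mean, rel=0.25
        )
        assert fit.params.emission.accel_mean == pytest.approx(
            crab_emissions.accel_mean, rel=0.25
        )

    def test_deterministic_under_seed(self, small_series_df, fit):
        again = fit_hmm(small_series_df, 2, n_restarts=3, seed=0, maxiter=400)
        assert again.loglik == fit.loglik
        assert again.working == pytest.approx(fit.working, abs=0.0)
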