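import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

import arealrisk as ar
from arealrisk._rng import substream
from arealrisk.bym import BymPriors, _BymSampler
from arealrisk.smr import AreaData


def area_data(y, e):
    y = np.asarray(y)
    return AreaData(
        area_ids=[f"A{i}" for i in range(len(y))],
        y=y,
        populations=np.asarray(e, dtype=float),
        e=np.asarray(e, dtype=float),
    )


class TestLogPosterior:
    def test_single_area_poisson_term(self):
        g = ar.build_adjacency_from_edgelist(["A"], [])
        state = dict(alpha0=0.0, beta=[], u=[0.0], v=[0.0], tau_u=1.0, tau_v=1.0)
        parts = ar.log_posterior(state, area_data([0], [1.0]), g, BymPriors(), parts=True)
        # y=0, e=1, theta=1: 0*log(1) - 1 = -1
        assert parts["poisson"] == pytest.approx(-1.0)

    def test_icar_term_invariant_to_component_level_shift(self, path4):
        # adding a constant within a component (then recentering) leaves
        # the quadratic form, hence the ICAR term, unchanged
        data = area_data([1, 2, 3, 4], [2.0] * 4)
        rng = np.random.default_rng(0)
        u = ar.sample_icar(path4, 0.7, rng)
        state = dict(alpha0=0.1, beta=[], u=u, v=np.zeros(4), tau_u=2.0, tau_v=1.0)
        p1 = ar.log_posterior(state, data, path4, BymPriors(), parts=True)["icar"]
        shifted = u + 5.0
        shifted = shifted - shifted.mean()
        state["u"] = shifted
        p2 = ar.log_posterior(state, data, path4, BymPriors(), parts=True)["icar"]
        assert p1 == pytest.approx(p2, abs=1e-9)

    def test_matches_brute_force_textbook_density(self, path4):
        # assemble the same density from scipy building blocks
        rng = np.random.default_rng(4)
        y = rng.integers(0, 20, 4)
        e = rng.uniform(1, 10, 4)
        X = rng.standard_normal((4, 2))
        data = area_data(y, e)
        u = ar.sample_icar(path4, 0.5, rng)
        state = dict(
            alpha0=0.3, beta=[0.4, -0.2], u=u,
            v=rng.standard_normal(4) * 0.2, tau_u=1.7, tau_v=3.1,
        )
        priors = BymPriors(beta_prior_sd=2.0, alpha0_prior_sd=1.5)
        got = ar.log_posterior(state, data, path4, priors, Xcov=X)

        eta = state["alpha0"] + X @ np.array(state["beta"]) + u + state["v"]
        q0 = ar.icar_structure(path4)
        oracle = (
            float(np.sum(stats.poisson.logpmf(y, e * np.exp(eta)) + gammaln(y + 1)))
            + 0.5 * 3 * math.log(state["tau_u"])
            - 0.5 * state["tau_u"] * float(u @ q0 @ u)
            + float(np.sum(stats.norm.logpdf(state["v"], 0, state["tau_v"] ** -0.5)))
            + stats.gamma.logpdf(state["tau_u"], 0.5, scale=1 / 0.0005)
            + stats.gamma.logpdf(state["tau_v"], 0.5, scale=1 / 0.0005)
            + float(np.sum(stats.norm.logpdf(state["beta"], 0, 2.0)))
            + stats.norm.logpdf(state["alpha0"], 0, 1.5)
        )
        assert got == pytest.approx(oracle, abs=1e-10)

    def test_overflow_returns_neg_inf(self, path4):
        data = area_data([1, 1, 1, 1], [1.0] * 4)
        state = dict(alpha0=800.0, beta=[], u=np.zeros(4), v=np.zeros(4),
                     tau_u=1.0, tau_v=1.0)
        assert ar.log_posterior(state, data, path4, BymPriors()) == -np.inf


class TestCarFullConditional:
    def test_single_neighbor(self):
        g = ar.build_adjacency_from_edgelist(["A", "B"], [("A", "B")])
        mean, var = ar.car_full_conditional(0, np.array([0.0, 2.0]), 1.0, g)
        assert (mean, var) == (2.0, 1.0)

    def test_two_neighbors_higher_precision(self, path3):
        mean, var = ar.car_full_conditional(1, np.array([1.0, 0.0, 3.0]), 2.0, path3)
        assert mean == pytest.approx(2.0)
        assert var == pytest.approx(0.25)  # 1/(tau*degree) = 1/(2*2)

    def test_island_rejected(self):
        g = ar.build_adjacency_from_edgelist(["A", "B"], [])
        with pytest.raises(ValueError, match="neighbour"):
            ar.car_full_conditional(0, np.zeros(2), 1.0, g)

    def test_gibbs_matches_constrained_gaussian_oracle(self, path5):
        # single-site Gibbs from the CAR full conditionals, recentered each
        # sweep, must reproduce the constrained ICAR distribution drawn
        # directly from the spectral decomposition
        tau = 1.0
        rng = substream(9, "car-gibbs")
        m = path5.n_areas
        u = np.zeros(m)
        draws = []
        thin, n_keep, burn = 5, 20_000, 200
        for it in range(burn + n_keep * thin):
            for i in range(m):
                mean, var = ar.car_full_conditional(i, u, tau, path5)
                u[i] = mean + math.sqrt(var) * rng.standard_normal()
            u -= u.mean()
            if it >= burn and (it - burn) % thin == 0:
                draws.append(u.copy())
        draws = np.array(draws)
        oracle = np.array(
            [ar.sample_icar(path5, 1.0, rng) for _ in range(n_keep)]
        )
        for idx in (0, 2):
            p = stats.ks_2samp(draws[:, idx], oracle[:, idx]).pvalue
            assert p > 0.01


@pytest.fixture(scope="module")
def small_fit():
    st = ar.simulate_default_study(2)
    data = ar.expected_counts(st.to_area_data())
    post = ar.bym_fit(
        data, st.truth["scores"], st.graph,
        n_iter=600, n_warmup=300, n_chains=2, seed=4,
    )
    return st, data, post


class TestBymFit:
    def test_same_seed_bit_identical(self):
        st = ar.simulate_default_study(2)
        data = ar.expected_counts(st.to_area_data())
        kw = dict(n_iter=150, n_warmup=50, n_chains=2, seed=7)
        a = ar.bym_fit(data, st.truth["scores"], st.graph, **kw)
        b = ar.bym_fit(data, st.truth["scores"], st.graph, **kw)
        np.testing.assert_array_equal(a.theta_draws, b.theta_draws)
        np.testing.assert_array_equal(a.tau_u_draws, b.tau_u_draws)

    def test_theta_consistency_invariant(self, small_fit):
        # theta = exp(alpha0 + X beta + u + v) recomputable from every draw
        st, _, post = small_fit
        X = st.truth["scores"]
        rng = np.random.default_rng(0)
        for _ in range(100):
            c = rng.integers(post.n_chains)
            s = rng.integers(post.n_draws_per_chain)
            eta = (
                post.alpha0_draws[c, s]
                + X @ post.beta_draws[c, s]
                + post.u_draws[c, s]
                + post.v_draws[c, s]
            )
            np.testing.assert_allclose(post.theta_draws[c, s], np.exp(eta), rtol=1e-10)

    def test_u_draws_satisfy_component_centering(self, small_fit):
        st, _, post = small_fit
        for members in st.graph.components():
            if len(members) > 1:
                means = post.u.T[members].mean(axis=0)
                assert np.abs(means).max() < 1e-10
            else:
                assert np.all(post.u[:, members] == 0.0)

    def test_taus_and_thetas_positive(self, small_fit):
        _, _, post = small_fit
        assert (post.tau_u > 0).all() and (post.tau_v > 0).all()
        assert (post.theta > 0).all()

    def test_no_cases_rejected(self, path4):
        data = area_data([0, 0, 0, 0], [1.0] * 4)
        with pytest.raises(ValueError, match="cases"):
            ar.bym_fit(data, None, path4, n_iter=10, n_warmup=5)

    def test_constant_covariate_rejected(self, path4):
        data = area_data([1, 2, 3, 4], [2.0] * 4)
        with pytest.raises(ValueError, match="constant"):
            ar.bym_fit(data, np.ones((4, 1)), path4, n_iter=10, n_warmup=5)

    def test_adaptation_after_freeze_raises(self, path4):
        data = area_data([1, 2, 3, 4], [2.0] * 4)
        smp = _BymSampler(data, None, path4, BymPriors(), np.random.default_rng(0))
        smp.freeze()
        with pytest.raises(RuntimeError, match="warm-up"):
            smp._adapt()

    def test_prior_validation(self):
        with pytest.raises(ValueError):
            BymPriors(tau_u_prior=(0.0, 1.0))


class TestKernelJointDistribution:
    def test_geweke_successive_vs_marginal_conditional(self, path4):
        # alternating (state -> y -> state) sweeps must preserve the prior
        # marginals of (tau_u, u'Q0u, alpha0, tau_v) when the kernel is
        # exactly invariant; compared against direct prior simulation
        m = 4
        e = np.full(m, 5.0)
        priors = BymPriors(
            tau_u_prior=(2.0, 2.0), tau_v_prior=(2.0, 2.0), alpha0_prior_sd=0.3
        )
        q0 = ar.icar_structure(path4)

        def prior_draw(rng):
            a0 = 0.3 * rng.standard_normal()
            tu, tv = rng.gamma(2.0, 0.5), rng.gamma(2.0, 0.5)
            u = ar.sample_icar(path4, tu**-0.5, rng)
            v = rng.standard_normal(m) * tv**-0.5
            return a0, u, v, tu, tv

        rng = substream(0, "geweke-mc")
        mc = np.array(
            [
                (s[3], s[1] @ q0 @ s[1], s[0], s[4])
                for s in (prior_draw(rng) for _ in range(2500))
            ]
        )

        rng = substream(0, "geweke-sc")
        a0, u, v, tu, tv = prior_draw(rng)
        data = area_data(np.zeros(m, dtype=int), e)
        smp = _BymSampler(data, None, path4, priors, rng)
        smp.set_state(a0, np.zeros(0), u, v, tu, tv)
        smp.draw_y()
        sc = []
        thin = 30
        for it in range(2500 * thin):
            smp.sweep(adapt=False)
            smp.draw_y()
            if it % thin == thin - 1:
                sc.append((smp.tau_u, smp.u @ q0 @ smp.u, smp.alpha0, smp.tau_v))
        sc = np.array(sc)
        for j in range(4):
            assert stats.ks_2samp(mc[:, j], sc[:, j]).pvalue > 0.01


class TestSummaries:
    def test_constant_chain(self):
        post = _flat_posterior(np.full(200, 0.5))
        row = ar.summarize_coefficients(post).iloc[0]
        assert (row["mean"], row["sd"]) == (0.5, 0.0)
        assert (row["q2.5"], row["q97.5"]) == (0.5, 0.5)

    def test_quantiles_by_sort_and_interpolate_oracle(self):
        draws = np.arange(1.0, 1001.0)
        post = _flat_posterior(draws)
        row = ar.summarize_coefficients(post).iloc[0]
        assert row["mean"] == pytest.approx(500.5)
        # linear interpolation: 1 + q*(n-1)
        assert row["q2.5"] == pytest.approx(1 + 0.025 * 999)
        assert row["q97.5"] == pytest.approx(1 + 0.975 * 999)

    def test_symmetric_draws_centered_interval(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal(20_000)
        row = ar.summarize_coefficients(_flat_posterior(draws)).iloc[0]
        assert (row["q2.5"] + row["q97.5"]) / 2 == pytest.approx(row["mean"], abs=0.05)

    def test_exceedance_probability_strict(self):
        post = _flat_posterior(np.full(100, 1.0), as_theta=True)
        rr = ar.relative_risk_summary(post)
        assert rr["p_exceed_1"].iloc[0] == 0.0
        post = _flat_posterior(np.full(100, 1.2), as_theta=True)
        assert ar.relative_risk_summary(post)["p_exceed_1"].iloc[0] == 1.0


def _flat_posterior(draws, as_theta=False):
    S = len(draws)
    arr = np.asarray(draws, dtype=float).reshape(1, S)
    ones = np.ones((1, S))
    return ar.BymPosterior(
        alpha0_draws=arr if not as_theta else np.zeros((1, S)),
        beta_draws=np.zeros((1, S, 0)),
        u_draws=np.zeros((1, S, 1)),
        v_draws=np.zeros((1, S, 1)),
        tau_u_draws=ones,
        tau_v_draws=ones,
        theta_draws=(arr if as_theta else ones)[:, :, None],
        n_chains=1,
        n_iter=S,
        n_warmup=0,
        acceptance_rates={},
        area_ids=["A0"],
        coef_names=[],
    )
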