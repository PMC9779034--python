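import math

import numpy as np
import pytest
from scipy import integrate, stats

import arealrisk as ar
from arealrisk.befa import (
    BefaConfig,
    BefaPosterior,
    allocation_summary,
    befa_fit,
    classify_areas,
    dedicated_marginal_loglik,
    factor_scores,
)

from conftest import RECOVERY_ALLOCATION, RECOVERY_LOADINGS


def canonical_partition(labels):
    """Relabel factors by first appearance so partitions compare directly."""
    mapping, out = {0: 0}, []
    for lab in labels:
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out.append(mapping[lab])
    return out


class TestStandardize:
    def test_three_point_column(self):
        np.testing.assert_allclose(
            ar.standardize(np.array([[1.0], [2.0], [3.0]])).ravel(), [-1, 0, 1]
        )

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        X = ar.standardize(rng.standard_normal((40, 3)))
        np.testing.assert_allclose(ar.standardize(X), X, atol=1e-12)

    def test_column_moments(self):
        X = ar.standardize(np.random.default_rng(2).uniform(0, 100, (25, 4)))
        assert np.abs(X.mean(axis=0)).max() < 1e-12
        np.testing.assert_allclose(X.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_constant_column_named(self):
        with pytest.raises(ValueError, match="stuck"):
            ar.standardize(np.column_stack([np.ones(5), np.arange(5.0)]),
                           names=["stuck", "ok"])


class TestMarginalLikelihoodOracle:
    def test_matches_numerical_quadrature(self):
        # closed-form integrated-loading likelihood vs direct quadrature
        # over lambda, on a 3-variable 5-area toy, in log space
        rng = np.random.default_rng(12)
        f = rng.standard_normal(5)
        s0 = 1.3
        for j in range(3):
            x = rng.standard_normal(5) * 0.8
            sigma2 = 0.5 + 0.5 * rng.random()

            def integrand(lam, x=x, sigma2=sigma2):
                return math.exp(
                    np.sum(stats.norm.logpdf(x, lam * f, np.sqrt(sigma2)))
                    + stats.norm.logpdf(lam, 0, s0)
                )

            val, err = integrate.quad(integrand, -12, 12, limit=200)
            assert dedicated_marginal_loglik(x, f, sigma2, s0**2) == pytest.approx(
                math.log(val), abs=1e-6
            )

    def test_null_model_is_plain_gaussian(self):
        x = np.array([0.3, -1.2, 0.5])
        got = dedicated_marginal_loglik(x, None, 0.7, 1.0)
        assert got == pytest.approx(
            float(np.sum(stats.norm.logpdf(x, 0, math.sqrt(0.7)))), abs=1e-12
        )


class TestBefaFit:
    def test_recovers_generating_partition(self, befa_recovery):
        _, _, post = befa_recovery
        summ = allocation_summary(post)
        got = canonical_partition(summ["modal_factor"].tolist())
        want = canonical_partition(list(RECOVERY_ALLOCATION))
        assert got == want
        assert (summ["posterior_probability"] > 0.9).all()
        assert summ["retained"].all()

    def test_recovered_signs_match_generator_up_to_factor_flip(self, befa_recovery):
        _, _, post = befa_recovery
        summ = allocation_summary(post)
        for k in summ["modal_factor"].unique():
            members = summ["modal_factor"] == k
            got = summ.loc[members, "sign"].to_numpy()
            want = np.sign([RECOVERY_LOADINGS[j] for j in np.flatnonzero(members)])
            assert np.array_equal(got, want) or np.array_equal(got, -want)

    def test_same_seed_identical_draws(self):
        X, _ = ar.simulate_covariates(
            60, (1, 1, 0, 0), (0.8, 0.8, 0, 0), (0.5, 0.5, 1, 1), seed=2
        )
        cfg = BefaConfig(K_max=2, n_iter=400, n_warmup=100, seed=5)
        a = befa_fit(ar.standardize(X), cfg)
        b = befa_fit(ar.standardize(X), cfg)
        np.testing.assert_array_equal(a.allocation_draws, b.allocation_draws)
        np.testing.assert_array_equal(a.loading_draws, b.loading_draws)

    def test_every_draw_respects_min_dedicated(self, befa_recovery):
        _, _, post = befa_recovery
        d = post.config.min_dedicated
        for s in range(0, post.n_draws, 97):
            z = post.allocation_draws[s]
            for k in range(1, post.config.K_max + 1):
                n = int((z == k).sum())
                assert n == 0 or n >= d

    def test_sign_convention_in_every_stored_draw(self, befa_recovery):
        # lowest-index dedicated variable of each active factor loads > 0
        _, _, post = befa_recovery
        for s in range(0, post.n_draws, 53):
            z = post.allocation_draws[s]
            lam = post.loading_draws[s]
            for k in np.unique(z[z > 0]):
                assert lam[np.flatnonzero(z == k)[0]] > 0

    def test_idiosyncratic_variances_positive(self, befa_recovery):
        _, _, post = befa_recovery
        assert (post.idio_var_draws > 0).all()

    def test_infeasible_kmax_rejected(self):
        X = ar.standardize(np.random.default_rng(0).standard_normal((30, 3)))
        with pytest.raises(ValueError, match="feasible"):
            befa_fit(X, BefaConfig(K_max=2, n_iter=10, n_warmup=1))

    def test_unstandardized_input_rejected(self):
        X = np.random.default_rng(0).standard_normal((30, 8)) * 5 + 3
        with pytest.raises(ValueError, match="standardize"):
            befa_fit(X, BefaConfig(n_iter=10, n_warmup=1))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            BefaConfig(n_iter=100, n_warmup=100)
        with pytest.raises(ValueError):
            BefaConfig(retention_threshold=1.5)
        with pytest.raises(ValueError):
            BefaConfig(min_dedicated=1)


def _manual_posterior(alloc, loadings, acc=None, m=10):
    S, M = alloc.shape
    K = int(alloc.max(initial=1))
    rng = np.random.default_rng(0)
    return BefaPosterior(
        allocation_draws=alloc,
        loading_draws=loadings,
        idio_var_draws=np.ones((S, M)),
        score_draws=rng.standard_normal((S, m, max(K, 1))),
        acceptance_rate=acc if acc is not None else np.full(M, 0.4),
        config=BefaConfig(K_max=max(K, 1), n_iter=S + 1, n_warmup=0),
    )


class TestAllocationSummary:
    def test_fully_allocated_variable(self):
        alloc = np.full((50, 2), 2, dtype=int)
        lam = np.full((50, 2), 0.7)
        summ = allocation_summary(_manual_posterior(alloc, lam), ["a", "b"])
        row = summ.iloc[0]
        assert row["modal_factor"] == 2
        assert row["posterior_probability"] == 1.0
        assert row["sign"] == 1
        assert bool(row["retained"])

    def test_mostly_null_variable_not_retained(self):
        alloc = np.zeros((100, 2), dtype=int)
        alloc[:20, 0] = 1
        alloc[:, 1] = 1
        summ = allocation_summary(_manual_posterior(alloc, np.ones((100, 2))))
        assert not bool(summ.iloc[0]["retained"])  # P(null)=0.8 >= 0.5
        assert summ.iloc[0]["modal_factor"] == 0
        assert summ.iloc[0]["sign"] == 0

    def test_negative_mean_loading_reported_negative(self):
        alloc = np.ones((40, 2), dtype=int)
        lam = np.column_stack([np.full(40, 0.5), np.full(40, -0.6)])
        summ = allocation_summary(_manual_posterior(alloc, lam))
        assert summ["sign"].tolist() == [1, -1]


class TestFactorScores:
    def test_scores_track_generating_scores(self, befa_recovery):
        _, true_scores, post = befa_recovery
        est = factor_scores(post)
        assert est.shape == (200, 2)
        # match columns by best absolute correlation (label switching safe)
        cors = np.abs(
            [[np.corrcoef(est[:, a], true_scores[:, b])[0, 1] for b in range(2)]
             for a in range(2)]
        )
        assert cors.max(axis=1).min() > 0.9
        assert {int(c) for c in cors.argmax(axis=1)} == {0, 1}

    def test_columns_standardized(self, befa_recovery):
        est = factor_scores(befa_recovery[2])
        assert np.abs(est.mean(axis=0)).max() < 1e-12
        np.testing.assert_allclose(est.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_sign_convention_aligns_with_lowest_index_variable(self, befa_recovery):
        X, _, post = befa_recovery
        summ = allocation_summary(post)
        est = factor_scores(post)
        Xs = ar.standardize(X)
        for col, k in enumerate(sorted(summ["modal_factor"].unique())):
            j = int(np.flatnonzero(summ["modal_factor"] == k)[0])
            assert np.corrcoef(est[:, col], Xs[:, j])[0, 1] > 0

    def test_no_active_factor_is_an_error(self):
        alloc = np.zeros((30, 4), dtype=int)
        post = _manual_posterior(alloc, np.zeros((30, 4)))
        with pytest.raises(ValueError, match="active"):
            factor_scores(post)


class TestClassifyAreas:
    def test_basic_quadrants_and_tie_rule(self):
        scores = np.array([[2.1, -0.3], [0.0, 0.0], [-1.0, 2.0], [-0.5, -0.5]])
        assert classify_areas(scores) == ["+-", "++", "-+", "--"]

    def test_all_quadrants_occur_for_independent_factors(self):
        rng = np.random.default_rng(3)
        scores = rng.standard_normal((50, 2))
        assert set(classify_areas(scores)) == {"++", "+-", "-+", "--"}

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError):
            classify_areas(np.zeros((5, 1)), 0, 1)
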