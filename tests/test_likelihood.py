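"""Likelihood factors against independent textbook-formula oracles."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from purist.data import CountMatrix, CpeState, ThetaMatrix
from purist.likelihood import (
    Bounds,
    profile_concentration,
    block_loglik_grad,
    complete_loglik,
    dirichlet_loglik,
    mixture_probability,
    multinomial_loglik,
    pinned_logits,
    softmax_pinned,
)


class TestMixtureProbability:
    def test_pure_cancer_returns_cancer_profile(self, rng):
        G, R = 7, 3
        B = rng.dirichlet(np.ones(G), size=R).T
        c = rng.dirichlet(np.ones(G))
        theta = np.zeros(R + 1)
        theta[-1] = 1.0
        out = mixture_probability(theta, B, c)
        np.testing.assert_allclose(out.xhat, c, atol=1e-15)

    def test_pure_normal_returns_reference(self, rng):
        G = 5
        b1 = rng.dirichlet(np.ones(G))
        c = rng.dirichlet(np.ones(G))
        out = mixture_probability(np.array([1.0, 0.0]), b1[:, None], c)
        np.testing.assert_allclose(out.xhat, b1, atol=1e-15)

    def test_matches_elementwise_weighted_sum_oracle(self, rng):
        G, R = 7, 3
        B = rng.dirichlet(np.ones(G), size=R).T
        c = rng.dirichlet(np.ones(G))
        theta = rng.dirichlet(np.ones(R + 1))
        out = mixture_probability(theta, B, c)
        oracle = np.array(
            [
                sum(theta[r] * B[g, r] for r in range(R)) + theta[R] * c[g]
                for g in range(G)
            ]
        )
        np.testing.assert_allclose(out.xhat, oracle, atol=1e-14)

    def test_conservation(self, rng):
        for _ in range(20):
            G, R = int(rng.integers(2, 30)), int(rng.integers(1, 6))
            B = rng.dirichlet(np.ones(G), size=R).T
            c = rng.dirichlet(np.ones(G))
            theta = rng.dirichlet(np.ones(R + 1))
            assert abs(mixture_probability(theta, B, c).xhat.sum() - 1) < 1e-12

    def test_dimension_mismatch_fatal(self, rng):
        B = rng.dirichlet(np.ones(4), size=2).T
        with pytest.raises(Exception, match="theta row length"):
            mixture_probability(np.array([0.5, 0.5]), B, rng.dirichlet(np.ones(4)))


class TestMultinomialLoglik:
    def test_uniform_closed_form(self):
        assert multinomial_loglik(
            np.array([1, 1]), np.array([0.5, 0.5])
        ) == pytest.approx(-2 * np.log(2), abs=1e-14)

    def test_one_sided_closed_form(self):
        eps = 1e-3
        k = 17
        got = multinomial_loglik(np.array([k, 0]), np.array([1 - eps, eps]))
        assert got == pytest.approx(k * np.log(1 - eps), abs=1e-14)

    def test_matches_scipy_up_to_constant(self, rng):
        G = 10
        p = rng.dirichlet(np.ones(G))
        x = rng.multinomial(500, p)
        ours = multinomial_loglik(x, p)
        scipy_ll = stats.multinomial.logpmf(x, n=x.sum(), p=p)
        const = gammaln(x.sum() + 1) - gammaln(x + 1).sum()
        assert ours == pytest.approx(scipy_ll - const, abs=1e-10)

    def test_constant_option_matches_scipy_exactly(self, rng):
        G = 6
        p = rng.dirichlet(np.ones(G))
        x = rng.multinomial(200, p)
        ours = multinomial_loglik(x, p, include_constant=True)
        assert ours == pytest.approx(
            stats.multinomial.logpmf(x, n=x.sum(), p=p), abs=1e-10
        )

    def test_zero_probability_with_counts_fatal(self):
        with pytest.raises(Exception, match="zero mixture probability"):
            multinomial_loglik(np.array([1, 1]), np.array([1.0, 0.0]))


class TestDirichletLoglik:
    def test_flat_two_simplex_is_zero(self, rng):
        p = rng.dirichlet(np.ones(2))
        assert dirichlet_loglik(p, np.ones(2)) == pytest.approx(0.0, abs=1e-14)

    def test_flat_three_simplex_is_log_two(self, rng):
        p = rng.dirichlet(np.ones(3))
        assert dirichlet_loglik(p, np.ones(3)) == pytest.approx(
            np.log(2.0), abs=1e-14
        )

    def test_matches_scipy_oracle(self, rng):
        K = 20
        for _ in range(10):
            a = rng.uniform(0.5, 20.0, K)
            p = rng.dirichlet(a)
            assert dirichlet_loglik(p, a) == pytest.approx(
                stats.dirichlet.logpdf(p, a), abs=1e-10
            )

    def test_non_positive_concentration_fatal(self):
        with pytest.raises(Exception, match="positive"):
            dirichlet_loglik(np.array([0.5, 0.5]), np.array([1.0, 0.0]))


class TestCompleteLoglik:
    def test_cpe_term_by_term_decomposition(self, rng, small_instance):
        X, B, cpe, _ = small_instance
        x1 = X[:, :1]
        theta1 = ThetaMatrix(cpe.theta.weights[:1])
        st1 = CpeState(
            theta=theta1, m=cpe.m, nu=cpe.nu, omega=cpe.omega,
            kappa_prime=cpe.kappa_prime,
        )
        got = complete_loglik(x1, B, st1, "cpe")
        xhat = mixture_probability(theta1.weights[0], B, st1.m).xhat
        expected = (
            dirichlet_loglik(st1.m, profile_concentration(st1.kappa_prime, B @ st1.omega))
            + dirichlet_loglik(theta1.weights[0], st1.nu)
            + multinomial_loglik(x1[:, 0], xhat)
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_ppe_with_shared_profiles_extends_cpe(self, small_instance):
        X, B, cpe, ppe = small_instance
        from dataclasses import replace

        N = X.shape[1]
        tied = replace(
            ppe,
            cancer_profiles=np.tile(cpe.m[:, None], (1, N)),
            theta=cpe.theta, nu=cpe.nu, m=cpe.m, omega=cpe.omega,
            kappa_prime=cpe.kappa_prime,
        )
        got = complete_loglik(X, B, tied, "ppe")
        base = complete_loglik(X, B, cpe, "cpe")
        priors = sum(
            dirichlet_loglik(cpe.m, profile_concentration(float(k), cpe.m))
            for k in tied.kappa_n
        )
        assert got == pytest.approx(base + priors, rel=1e-10)

    def test_grid_search_optimum_is_unimodal_peak(self, rng):
        # single patient, one reference: theta = (theta_1, alpha) on a line
        G = 3
        b = rng.dirichlet(np.ones(G))
        m = rng.dirichlet(np.ones(G))
        x = rng.multinomial(500, 0.3 * b + 0.7 * m)[:, None]
        grid = np.linspace(0.01, 0.99, 99)
        vals = []
        for t1 in grid:
            state = CpeState(
                theta=ThetaMatrix(np.array([[t1, 1 - t1]])), m=m,
                nu=np.array([1.5, 1.5]), omega=np.array([1.0]),
                kappa_prime=10.0,
            )
            vals.append(complete_loglik(x, b[:, None], state, "cpe"))
        vals = np.asarray(vals)
        k = int(np.argmax(vals))
        # moving away from the grid optimum can only decrease the value
        assert np.all(np.diff(vals[: k + 1]) > 0)
        assert np.all(np.diff(vals[k:]) < 0)


class TestBlockGradientSurface:
    def test_reports_negative_terms_and_free_coordinates(self, small_instance):
        X, B, cpe, _ = small_instance
        bg = block_loglik_grad("omega", cpe, X, B, Bounds(), mode="cpe")
        expected = -dirichlet_loglik(
            cpe.m, profile_concentration(cpe.kappa_prime, B @ cpe.omega)
        )
        assert bg.value == pytest.approx(expected, rel=1e-10)
        assert bg.gradient.shape == (B.shape[1] - 1,)

    def test_softmax_logit_round_trip(self, rng):
        p = rng.dirichlet(np.ones(6))
        np.testing.assert_allclose(softmax_pinned(pinned_logits(p)), p, atol=1e-12)
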