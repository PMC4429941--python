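"""Coordinate-descent drivers: monotonicity, freezing, recovery, rescaling."""

import numpy as np
import pytest

from purist.data import CountMatrix, DataError
from purist.estimate import (
    FitOptions,
    initialize_cpe,
    rescale_to_intensity,
    run_cpe,
    run_ppe,
)
from purist.simulate import generate
from purist.data import to_probability_panel


def _small_cohort(seed=3, G=150, N=5, R=2, depth=20_000, **kw):
    tum, healthy, truth = generate(G=G, N=N, R=R, depth=depth, seed=seed, **kw)
    return tum, to_probability_panel(healthy), truth


FAST = FitOptions(seed=3, max_sweeps=8, block_budget=-60)


class TestInitialize:
    def test_same_seed_gives_identical_states(self):
        tum, panel, _ = _small_cohort()
        s1 = initialize_cpe(tum, panel, seed=42)
        s2 = initialize_cpe(tum, panel, seed=42)
        np.testing.assert_array_equal(s1.theta.weights, s2.theta.weights)
        np.testing.assert_array_equal(s1.m, s2.m)
        assert s1.kappa_prime == s2.kappa_prime

    def test_theta_shape_and_simplex(self):
        tum, panel, _ = _small_cohort(R=1)
        s = initialize_cpe(tum, panel, seed=0)
        assert s.theta.weights.shape == (tum.n_samples, 2)
        np.testing.assert_allclose(s.theta.weights.sum(axis=1), 1.0, atol=1e-12)

    def test_theta_rows_sample_flat_dirichlet(self):
        tum, panel, _ = _small_cohort(R=3)
        draws = np.array(
            [
                initialize_cpe(tum, panel, seed=s).theta.weights.mean(axis=0)
                for s in range(1000)
            ]
        )
        K = draws.shape[1]
        mean = draws.mean(axis=0)
        # flat Dirichlet component variance is (K-1)/(K^2 (K+1)); 5 rows/draw
        se = np.sqrt((K - 1) / (K**2 * (K + 1)) / (1000 * tum.n_samples))
        assert np.all(np.abs(mean - 1.0 / K) < 3 * se)


class TestRunCpe:
    def test_trace_is_non_decreasing(self):
        tum, panel, _ = _small_cohort()
        res = run_cpe(tum, panel, FAST)
        bt = res.block_trace
        assert np.all(np.diff(bt) >= -1e-6 * np.maximum(1.0, np.abs(bt[:-1])))
        assert np.all(np.diff(res.loglik_trace) >= -1e-6 * np.abs(res.loglik_trace[:-1]))

    def test_alpha_is_last_theta_column(self):
        tum, panel, _ = _small_cohort()
        res = run_cpe(tum, panel, FAST)
        np.testing.assert_array_equal(res.alphapurities, res.theta.weights[:, -1])

    def test_pure_cancer_detected(self):
        tum, panel, _ = _small_cohort(seed=5, alpha_range=(1.0, 1.0))
        res = run_cpe(tum, panel, FitOptions(seed=5, max_sweeps=12))
        assert res.alphapurities.min() >= 0.95

    def test_pure_normal_detected(self):
        rng = np.random.default_rng(6)
        tum, panel, _ = _small_cohort(seed=6)
        X = np.column_stack(
            [rng.multinomial(20_000, panel.profiles[:, 0]) for _ in range(5)]
        )
        x = CountMatrix(X, tum.gene_ids, tum.sample_ids)
        res = run_cpe(x, panel, FitOptions(seed=6, max_sweeps=12))
        assert res.alphapurities.max() <= 0.1

    def test_deterministic_given_seed(self):
        tum, panel, _ = _small_cohort()
        r1 = run_cpe(tum, panel, FAST)
        r2 = run_cpe(tum, panel, FAST)
        np.testing.assert_array_equal(r1.theta.weights, r2.theta.weights)
        np.testing.assert_array_equal(r1.m, r2.m)
        assert r1.total_loglik == r2.total_loglik

    def test_gene_mismatch_fatal(self):
        tum, panel, _ = _small_cohort()
        tum2, _, _ = _small_cohort(G=151)
        with pytest.raises(DataError):
            run_cpe(tum2, panel, FAST)


class TestRunPpe:
    def test_alpha_bit_identical_to_cpe(self):
        tum, panel, _ = _small_cohort()
        cpe = run_cpe(tum, panel, FAST)
        ppe = run_ppe(tum, panel, cpe, FAST)
        assert np.array_equal(ppe.theta.weights[:, -1], cpe.alphapurities)

    def test_trace_is_non_decreasing(self):
        tum, panel, _ = _small_cohort()
        cpe = run_cpe(tum, panel, FAST)
        ppe = run_ppe(tum, panel, cpe, FAST)
        bt = ppe.block_trace
        assert np.all(np.diff(bt) >= -1e-6 * np.maximum(1.0, np.abs(bt[:-1])))

    def test_intensity_columns_conserve_tumour_totals(self):
        tum, panel, _ = _small_cohort()
        cpe = run_cpe(tum, panel, FAST)
        ppe = run_ppe(tum, panel, cpe, FAST)
        np.testing.assert_allclose(
            ppe.cancerprofiles_intensity.sum(axis=0),
            tum.values.sum(axis=0),
            rtol=1e-6,
        )

    def test_shared_profiles_stay_near_shared_estimate(self):
        """When patients truly share one cancer profile, the fitted
        per-patient profiles sit closer to the shared profile than when
        patients genuinely diverge."""
        opts = FitOptions(seed=9, max_sweeps=8, block_budget=-60)
        tum, panel, _ = _small_cohort(seed=9, patient_divergence=1e10)
        cpe = run_cpe(tum, panel, opts)
        ppe = run_ppe(tum, panel, cpe, opts)
        d_shared = np.abs(ppe.cancerprofiles_probability - cpe.m[:, None]).max(axis=0).mean()

        tum2, panel2, _ = _small_cohort(seed=9, patient_divergence=3e2)
        cpe2 = run_cpe(tum2, panel2, opts)
        ppe2 = run_ppe(tum2, panel2, cpe2, opts)
        d_diverse = np.abs(ppe2.cancerprofiles_probability - cpe2.m[:, None]).max(axis=0).mean()
        assert d_shared < d_diverse

    def test_patient_specific_spike_ranks_first(self):
        """A gene amplified 8x in one patient's true cancer profile shows
        the largest fitted fold-change against the shared profile."""
        rng = np.random.default_rng(17)
        G, N, R, depth = 300, 5, 2, 200_000
        tum, healthy, truth = generate(G=G, N=N, R=R, depth=depth, seed=17)
        panel = to_probability_panel(healthy)
        spike = int(np.argsort(truth.m_true)[-10])  # a solidly expressed gene
        C = truth.c_true.copy()
        c1 = C[:, 0].copy()
        c1[spike] *= 8.0
        C[:, 0] = c1 / c1.sum()
        theta = truth.theta_true.weights
        xhat = panel.profiles @ theta[:, :R].T + C * theta[:, R][None, :]
        X = np.column_stack(
            [rng.multinomial(depth, xhat[:, n] / xhat[:, n].sum()) for n in range(N)]
        )
        x = CountMatrix(X, tum.gene_ids, tum.sample_ids)
        opts = FitOptions(seed=17, max_sweeps=10)
        cpe = run_cpe(x, panel, opts)
        ppe = run_ppe(x, panel, cpe, opts)
        fold = ppe.cancerprofiles_probability[:, 0] / cpe.m
        assert int(np.argmax(fold)) == spike

    def test_mismatched_cpe_fatal(self):
        tum, panel, _ = _small_cohort()
        tum2, panel2, _ = _small_cohort(G=151)
        cpe = run_cpe(tum2, panel2, FAST)
        with pytest.raises(DataError):
            run_ppe(tum, panel, cpe, FAST)


class TestRescale:
    def test_worked_example(self):
        c = np.array([[0.25], [0.75]])
        t = CountMatrix(np.array([[100], [300]]), ("a", "b"), ("s",))
        np.testing.assert_allclose(rescale_to_intensity(c, t), [[100.0], [300.0]])

    def test_conserves_column_sums_and_order(self, rng):
        G, N = 40, 6
        C = rng.dirichlet(np.ones(G), size=N).T
        t = CountMatrix(
            rng.integers(1, 1000, (G, N)),
            tuple(f"g{i}" for i in range(G)),
            tuple(f"s{j}" for j in range(N)),
        )
        out = rescale_to_intensity(C, t)
        np.testing.assert_allclose(out.sum(axis=0), t.values.sum(axis=0), rtol=1e-12)
        for n in range(N):
            np.testing.assert_array_equal(
                np.argsort(out[:, n]), np.argsort(C[:, n])
            )
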