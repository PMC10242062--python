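"""Rare/weak model simulation, chi-square screening, simplified PCA /
IF-PCA, Hamming error, and the phase-transition formulas."""

import itertools

import numpy as np
import pytest
from scipy import stats

from ifpca.rareweak import (
    RareWeakInstance,
    RareWeakParams,
    alpha_star,
    chi2_scores,
    critical_tau,
    eigvec_deviation,
    hamming_error,
    phase_grid,
    simple_ifpca_cluster,
    simple_pca_cluster,
    simulate,
)


def make_instance(n, p, s, tau, seed, noiseless=False):
    """Direct construction with a fixed support size (bypasses the
    (theta, beta, alpha) calibration)."""
    rng = np.random.default_rng(seed)
    Y = rng.choice([-1.0, 1.0], size=n)
    mu = np.zeros(p)
    idx = rng.choice(p, s, replace=False)
    mu[idx] = rng.choice([-1.0, 1.0], size=s) * tau
    Z = 0.0 if noiseless else rng.standard_normal((n, p))
    return RareWeakInstance(
        params=None, Y=Y, mu=mu, support=np.sort(idx),
        X=np.outer(Y, mu) + Z, seed=seed,
    )


class TestSimulate:
    def test_calibration_n_derivation(self):
        params = RareWeakParams(p=10_000, theta=0.6, beta=0.5, alpha=0.2)
        assert params.n == 251  # round(10^2.4)

    def test_support_size_binomial_bound(self):
        p, beta = 2000, 0.4
        params = RareWeakParams(p=p, theta=0.5, beta=beta, alpha=0.2)
        sizes = [len(simulate(params, seed=s).support) for s in range(200)]
        eps = params.eps
        se = np.sqrt(p * eps * (1 - eps) / 200)
        assert abs(np.mean(sizes) - p * eps) <= 3 * np.sqrt(p * eps * (1 - eps))
        assert abs(np.mean(sizes) - p * eps) <= 5 * se  # tighter sanity

    def test_reproducible_and_model_structure(self):
        params = RareWeakParams(p=500, theta=0.6, beta=0.4, alpha=0.3)
        a = simulate(params, seed=3)
        b = simulate(params, seed=3)
        np.testing.assert_array_equal(a.X, b.X)
        nz = a.mu[a.mu != 0]
        np.testing.assert_allclose(np.abs(nz), params.tau)
        resid = a.X - np.outer(a.Y, a.mu)
        assert abs(resid.std() - 1) < 3 / np.sqrt(resid.size)

    def test_vanishing_signal_gives_chance_error(self):
        params = RareWeakParams(p=2000, theta=0.6, beta=0.4, alpha=8.0)
        errs = [
            hamming_error(
                simple_pca_cluster(simulate(params, seed=s).X),
                simulate(params, seed=s).Y,
            )
            for s in range(10)
        ]
        assert np.mean(errs) > 0.35


class TestChi2Scores:
    def test_exact_zero_at_norm_n(self):
        X = np.eye(4) * 2.0  # each column norm^2 = 4 = n
        np.testing.assert_allclose(chi2_scores(X), 0.0)

    def test_null_columns_approximately_standard_normal(self, rng):
        X = rng.standard_normal((100, 10_000))
        psi = chi2_scores(X)
        assert abs(psi.mean()) < 3 / np.sqrt(10_000)
        assert abs(psi.std() - 1) < 0.05

    def test_useful_column_noncentrality(self, rng):
        n, tau, reps = 50, 0.6, 10_000
        Y = rng.choice([-1.0, 1.0], size=n)
        cols = np.outer(Y, tau * np.ones(reps)) + rng.standard_normal(
            (n, reps)
        )
        psi = chi2_scores(cols)
        want = np.sqrt(n / 2) * tau**2
        se = psi.std() / np.sqrt(reps)
        assert abs(psi.mean() - want) <= 3 * se


class TestSimplePCA:
    def test_noiseless_exact_recovery(self):
        inst = make_instance(50, 200, 10, 0.8, seed=0, noiseless=True)
        assert hamming_error(simple_pca_cluster(inst.X), inst.Y) == 0.0

    def test_possibility_point_small_error(self):
        params = RareWeakParams(p=5000, theta=0.6, beta=0.3, alpha=0.15)
        errs = [
            hamming_error(
                simple_pca_cluster(simulate(params, seed=s).X),
                simulate(params, seed=s).Y,
            )
            for s in range(20)
        ]
        assert np.mean(errs) < 0.05

    def test_impossibility_point_chance_error(self):
        params = RareWeakParams(p=5000, theta=0.6, beta=0.3, alpha=0.45)
        errs = [
            hamming_error(
                simple_pca_cluster(simulate(params, seed=s).X),
                simulate(params, seed=s).Y,
            )
            for s in range(20)
        ]
        assert 0.4 <= np.mean(errs) <= 0.5


class TestSimpleIFPCA:
    def test_noiseless_recovery(self):
        # tau < 1: noiseless useful norms n tau^2 < n, screening selects
        # nothing and the full-matrix fallback still recovers exactly
        inst = make_instance(50, 200, 10, 0.8, seed=1, noiseless=True)
        _, labels, fallback = simple_ifpca_cluster(inst.X)
        assert fallback
        assert hamming_error(labels, inst.Y) == 0.0
        # tau large: useful columns clear the threshold outright
        inst = make_instance(50, 200, 10, 2.0, seed=1, noiseless=True)
        S_hat, labels, fallback = simple_ifpca_cluster(inst.X)
        assert not fallback
        np.testing.assert_array_equal(S_hat, inst.support)
        assert hamming_error(labels, inst.Y) == 0.0

    def test_strong_signal_support_recovery_no_misses(self):
        # tau far above the screening boundary: every useful feature is
        # selected; false positives follow the exact chi-square tail
        p, n, s, tau = 5000, 166, 13, 1.3
        t = np.sqrt(2 * np.log(p))
        miss_total, fp_total = 0, 0
        for seed in range(50):
            inst = make_instance(n, p, s, tau, seed=seed)
            S_hat, _, _ = simple_ifpca_cluster(inst.X)
            miss_total += len(set(inst.support) - set(S_hat))
            fp_total += len(set(S_hat) - set(inst.support))
        assert miss_total == 0
        # null column norms are chi-square_n: expected false count uses the
        # exact tail, not the Gaussian approximation
        tail = stats.chi2.sf(n + t * np.sqrt(2 * n), df=n)
        expect = 50 * (p - s) * tail
        assert fp_total <= expect + 3 * np.sqrt(expect)

    def test_empty_selection_falls_back_to_full_pca(self, rng):
        X = rng.standard_normal((30, 50)) * 0.1  # norms far below n
        S_hat, labels, fallback = simple_ifpca_cluster(X)
        assert fallback and S_hat.size == 0
        np.testing.assert_array_equal(labels, simple_pca_cluster(X))

    def test_beats_pca_when_selection_feasible(self):
        # sparse, individually strong signals: screening keeps ~s useful
        # columns and discards the noise that drowns full-matrix PCA
        p, n, s, tau = 5000, 166, 13, 1.0
        e_pca, e_if = [], []
        for seed in range(20):
            inst = make_instance(n, p, s, tau, seed=100 + seed)
            e_pca.append(hamming_error(simple_pca_cluster(inst.X), inst.Y))
            _, labels, _ = simple_ifpca_cluster(inst.X)
            e_if.append(hamming_error(labels, inst.Y))
        assert np.mean(e_if) < np.mean(e_pca)
        assert np.mean(e_if) < 0.05


class TestHammingError:
    def test_flip_and_hand_examples(self):
        Y = np.array([1, 1, -1, -1])
        assert hamming_error(-Y, Y) == 0.0
        assert hamming_error(np.array([1, 1, 1, -1]), Y) == 0.25

    def test_matches_exhaustive_oracle_n8(self):
        n = 8
        Y = np.array([1, 1, 1, 1, -1, -1, -1, -1])
        for bits in itertools.product([-1, 1], repeat=n):
            Y_hat = np.array(bits)
            oracle = min(
                np.mean(Y_hat != Y), np.mean(-Y_hat != Y)
            )
            assert hamming_error(Y_hat, Y) == pytest.approx(oracle)

    def test_flip_invariances(self, rng):
        for _ in range(20):
            Y = rng.choice([-1, 1], size=11)
            Y_hat = rng.choice([-1, 1], size=11)
            e = hamming_error(Y_hat, Y)
            assert hamming_error(-Y_hat, Y) == pytest.approx(e)
            assert hamming_error(Y_hat, -Y) == pytest.approx(e)
            assert 0 <= e <= 0.5

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            hamming_error(np.array([1, -1]), np.array([1, -1, 1]))


class TestBoundaryFormulas:
    def test_alpha_star_printed_values(self):
        assert alpha_star(0.3, 0.6) == pytest.approx(0.25, abs=1e-12)
        assert alpha_star(0.6, 0.6) == pytest.approx(0.15, abs=1e-12)
        assert alpha_star(0.8, 0.6) == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("theta", [0.2, 0.4, 0.6, 0.8])
    def test_alpha_star_continuity(self, theta):
        eps = 1e-9
        assert alpha_star(0.5 - eps, theta) == pytest.approx(
            alpha_star(0.5 + eps, theta), abs=1e-6
        )
        b = 1 - theta / 2
        assert alpha_star(b - eps, theta) == pytest.approx(
            alpha_star(b + eps, theta), abs=1e-6
        )

    def test_critical_tau_middle_piece_arithmetic(self):
        params = RareWeakParams(p=10_000, theta=0.6, beta=0.7, alpha=0.2)
        assert critical_tau(params) == pytest.approx(
            251 ** -0.25, abs=1e-12
        )

    def test_critical_tau_continuity_at_joins(self):
        # continuity is exact under the asymptotic calibration n = p^theta;
        # rounding n to an integer shifts the second join by the rounding
        # error, so the check uses exact powers
        class ExactParams(RareWeakParams):
            @property
            def n(self):
                return self.p ** self.theta

        for theta in (0.4, 0.6):
            for b0 in (0.5, 1 - theta / 2):
                lo = ExactParams(p=4000, theta=theta,
                                 beta=b0 - 1e-9, alpha=0.2)
                hi = ExactParams(p=4000, theta=theta,
                                 beta=b0 + 1e-9, alpha=0.2)
                assert critical_tau(lo) == pytest.approx(
                    critical_tau(hi), rel=1e-5
                )

    def test_consistency_with_alpha_star_exact_powers(self):
        # with n = p^theta taken exactly (no rounding),
        # critical_tau = p^(-alpha_star) identically
        class ExactParams(RareWeakParams):
            @property
            def n(self):
                return self.p ** self.theta

        for beta in (0.2, 0.4, 0.55, 0.75, 0.9):
            params = ExactParams(p=3000, theta=0.6, beta=beta, alpha=0.2)
            want = params.p ** (-alpha_star(beta, 0.6))
            assert critical_tau(params) == pytest.approx(want, rel=1e-12)


class TestEigvecDeviation:
    def test_noiseless_exactly_zero(self):
        inst = make_instance(40, 300, 20, 0.9, seed=2, noiseless=True)
        assert eigvec_deviation(inst) == pytest.approx(0.0, abs=1e-10)

    def test_median_nonincreasing_in_signal_strength(self):
        n, p = 200, 1000
        medians = []
        for mult in (10, 40, 160):
            mu2 = mult * np.log(n + p)
            s = 50
            devs = [
                eigvec_deviation(
                    make_instance(n, p, s, np.sqrt(mu2 / s), seed=seed)
                )
                for seed in range(15)
            ]
            medians.append(np.median(devs))
        assert medians[0] >= medians[1] >= medians[2]


class TestPhaseGrid:
    def test_reps_one_returns_raw_errors(self):
        df = phase_grid(0.6, 500, [0.3], [0.2], reps=1, seed=0)
        assert np.isnan(df["se"]).all()
        assert len(df) == 2

    def test_error_nondecreasing_in_alpha(self):
        df = phase_grid(
            0.6, 2000, [0.3], [0.05, 0.25, 0.45], reps=10, seed=1
        )
        pca = df[df.method == "simple_pca"].sort_values("alpha")
        err, se = pca.mean_error.to_numpy(), pca.se.to_numpy()
        assert err[0] <= err[1] + se[1] and err[1] <= err[2] + se[2]

    def test_reproducible(self):
        a = phase_grid(0.6, 500, [0.3, 0.5], [0.2], reps=3, seed=5)
        b = phase_grid(0.6, 500, [0.3, 0.5], [0.2], reps=3, seed=5)
        np.testing.assert_allclose(
            a.mean_error.to_numpy(), b.mean_error.to_numpy()
        )
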