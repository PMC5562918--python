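import numpy as np
import pytest
from scipy import stats

from neuralpf import (
    DivergenceError,
    ParticleEnsemble,
    empirical_gain,
    model_zoo,
    novelty,
    npf_step,
    posterior_expectation,
    region_certainty,
    riccati_steady_state,
    run_filter,
    run_kalman,
    simulate,
    stationary_density,
)
from conftest import make_custom


def brute_force_gain(z, g, sigma_y_inv):
    """Literal double-sum cross-covariance, the independent oracle."""
    N = len(z)
    gz = np.array([g(zi[None, :])[0] for zi in z])
    term1 = sum(np.outer(z[k], gz[k]) for k in range(N)) / N
    term2 = sum(
        np.outer(z[k], gz[l]) for k in range(N) for l in range(N)
    ) / N**2
    return (term1 - term2) @ sigma_y_inv


class TestEmpiricalGain:
    def test_identical_particles_zero_gain(self, frog):
        ens = ParticleEnsemble(np.full((50, 1), 0.7))
        np.testing.assert_allclose(empirical_gain(ens, frog),
                                   np.zeros((1, 2)), atol=1e-14)

    def test_linear_two_particles(self):
        # particles {-1,+1}, g(x)=x, sigma_y^2=0.1: population var 1 -> W=10
        model = make_custom(sigma_y=np.array([[0.1]]))
        ens = ParticleEnsemble([[-1.0], [1.0]])
        W = empirical_gain(ens, model)
        assert W[0, 0] == pytest.approx(10.0)

    def test_tanh_two_particles(self):
        model = make_custom(g=lambda x: np.tanh(2 * x),
                            sigma_y=np.array([[0.1]]))
        ens = ParticleEnsemble([[0.0], [2.0]])
        W = empirical_gain(ens, model)
        # cov = 0.5*(2 tanh4) - 1*0.5 tanh4 = 0.5 tanh4
        assert W[0, 0] == pytest.approx(0.5 * np.tanh(4.0) / 0.1)
        assert W[0, 0] == pytest.approx(4.9966, abs=1e-3)

    def test_matches_brute_force_double_sum(self, frog, rng):
        z = rng.normal(size=(17, 1))
        ens = ParticleEnsemble(z)
        expected = brute_force_gain(z, frog.g, frog.sigma_y_inv)
        np.testing.assert_allclose(empirical_gain(ens, frog), expected,
                                   atol=1e-12)

    def test_single_particle_gain_zero(self, frog):
        ens = ParticleEnsemble([[0.3]])
        np.testing.assert_array_equal(empirical_gain(ens, frog),
                                      np.zeros((1, 2)))

    def test_population_normalization_not_n_minus_1(self):
        model = make_custom()
        ens = ParticleEnsemble([[0.0], [2.0]])
        # population var of {0,2} is 1 (not 2)
        assert empirical_gain(ens, model)[0, 0] == pytest.approx(1.0)


class TestNovelty:
    def test_perfect_prediction_zero(self, frog, rng):
        z = rng.normal(size=(5, 1))
        ens = ParticleEnsemble(z)
        dy = frog.g(z[0:1])[0] * 0.01
        dn = novelty(ens, dy, frog, 0.01)
        np.testing.assert_allclose(dn[0], 0.0, atol=1e-15)

    def test_linear_residual(self):
        model = make_custom()
        ens = ParticleEnsemble([[0.5]])
        dn = novelty(ens, [0.05], model, 0.1)
        assert dn[0, 0] == pytest.approx(0.0)

    def test_tanh_at_zero(self):
        model = make_custom(g=lambda x: np.tanh(2 * x))
        ens = ParticleEnsemble([[0.0]])
        dn = novelty(ens, [0.2], model, 0.1)
        assert dn[0, 0] == pytest.approx(0.2)

    def test_deterministic(self, frog, rng):
        ens = ParticleEnsemble(rng.normal(size=(8, 1)))
        a = novelty(ens, [0.1, -0.2], frog, 0.01)
        b = novelty(ens, [0.1, -0.2], frog, 0.01)
        np.testing.assert_array_equal(a, b)


class TestNpfStep:
    def test_noop_when_everything_zero(self, rng):
        model = make_custom()
        ens = ParticleEnsemble([[0.4], [-0.2]])
        out = npf_step(ens, [0.1], model, np.zeros((1, 1)), 0.01, rng)
        np.testing.assert_array_equal(out.z, ens.z)

    def test_drift_fixed_point(self, rng):
        model = make_custom(f=lambda x: 3 * x * (1 - x**2))
        ens = ParticleEnsemble([[1.0]])
        out = npf_step(ens, [0.0], model, np.zeros((1, 1)), 0.01, rng)
        assert out.z[0, 0] == pytest.approx(1.0)

    def test_gain_times_novelty(self, rng):
        # f=0, sigma_x=0, z=0, W=10, dn=0.1 -> z' = 1.0
        model = make_custom(g=lambda x: 0.0 * x)
        ens = ParticleEnsemble([[0.0]])
        out = npf_step(ens, [0.1], model, [[10.0]], 0.5, rng)
        assert out.z[0, 0] == pytest.approx(1.0)

    def test_divergence_names_particle(self, rng):
        model = make_custom(f=lambda x: np.where(x > 1, np.inf, 0.0) * x)
        ens = ParticleEnsemble([[0.0], [2.0]])
        with pytest.raises(DivergenceError, match="particle 1"):
            npf_step(ens, [0.0], model, np.zeros((1, 1)), 0.01, rng)

    def test_fresh_noise_per_particle(self, frog, rng):
        ens = ParticleEnsemble(np.zeros((4, 1)))
        out = npf_step(ens, [0.0, 0.0], frog, np.zeros((1, 2)), 0.01, rng)
        assert len(np.unique(out.z)) == 4


class TestPosteriorExpectation:
    def test_symmetric_mean_zero(self):
        ens = ParticleEnsemble([[-1.0], [0.0], [1.0]])
        assert posterior_expectation(ens)[0] == pytest.approx(0.0)

    def test_second_moment(self):
        ens = ParticleEnsemble([[-1.0], [1.0]])
        assert posterior_expectation(ens, lambda z: z**2)[0] == pytest.approx(1.0)

    def test_arithmetic_mean(self):
        ens = ParticleEnsemble([[0.2], [0.4], [0.6]])
        assert posterior_expectation(ens)[0] == pytest.approx(0.4)


class TestRegionCertainty:
    def test_all_inside(self):
        ens = ParticleEnsemble([[0.1], [0.2]])
        assert region_certainty(ens, -1.0, 1.0) == 1.0

    def test_half_inside(self):
        ens = ParticleEnsemble([[-1.1], [-0.9], [1.0], [1.05]])
        assert region_certainty(ens, -1.25, -0.75) == 0.5

    def test_point_interval(self):
        ens = ParticleEnsemble([[0.3], [0.5]])
        assert region_certainty(ens, 0.1, 0.1) == 0.0
        assert region_certainty(ens, 0.5, 0.5) == 0.5

    def test_partition_sums_to_one(self, rng):
        ens = ParticleEnsemble(rng.normal(size=(64, 1)))
        left = region_certainty(ens, -np.inf, -1.0)
        mid = region_certainty(ens, np.nextafter(-1.0, 0), np.nextafter(1.0, 0))
        right = region_certainty(ens, 1.0, np.inf)
        assert left + mid + right == pytest.approx(1.0)

    def test_invalid_interval(self):
        ens = ParticleEnsemble([[0.0]])
        with pytest.raises(ValueError):
            region_certainty(ens, 1.0, -1.0)


class TestRunFilter:
    def test_zero_noise_degenerate_follows_euler(self):
        # identical init, sigma_x = 0: empirical gain stays 0, so the mean
        # follows the deterministic Euler recursion of f
        model = make_custom(f=lambda x: -0.5 * x, sigma_y=np.array([[1.0]]))
        rec = simulate(model, 1.0, 0.01, x0=[1.0], seed=0)
        init = np.full((10, 1), 1.0)
        res = run_filter(model, rec, 10, seed=1, init=init)
        euler = 1.0 * (1 - 0.5 * 0.01) ** np.arange(1, rec.steps + 1)
        np.testing.assert_allclose(res.mean[:, 0], euler, rtol=1e-10)

    def test_frog_tracking_qualitative(self, frog):
        rec = simulate(frog, 30.0, 0.01, seed=6)
        res = run_filter(frog, rec, 1000, seed=7,
                         certainty_boxes=[(-1.25, -0.75), (0.75, 1.25)])
        burn = rec.steps // 10
        corr = np.corrcoef(res.mean[burn:, 0], rec.x[burn:, 0])[0, 1]
        assert corr > 0.7
        # branch occupancy switches with the true state
        right = rec.x[burn:, 0] > 0.5
        left = rec.x[burn:, 0] < -0.5
        if right.any() and left.any():
            assert (res.certainty[burn:, 1][right].mean()
                    > res.certainty[burn:, 1][left].mean())

    def test_linear_mean_converges_to_kalman(self, ou_1d):
        rec = simulate(ou_1d, 50.0, 0.01, seed=8)
        res = run_filter(ou_1d, rec, 10_000, seed=9)
        kal = run_kalman(ou_1d, rec)
        burn = rec.steps // 10
        diff = np.mean(np.abs(res.mean[burn:, 0] - kal.mean[burn:, 0]))
        assert diff < 0.08

    def test_mismatched_dimensions_rejected(self, frog, ou_1d):
        rec = simulate(frog, 1.0, 0.01, seed=0)
        with pytest.raises(ValueError):
            run_filter(ou_1d, rec, 10, seed=0)

    def test_fixed_gain_requires_matrix(self, frog):
        rec = simulate(frog, 1.0, 0.01, seed=0)
        with pytest.raises(ValueError):
            run_filter(frog, rec, 10, gain_mode="fixed", seed=0)

    def test_unknown_modes_rejected(self, frog):
        rec = simulate(frog, 1.0, 0.01, seed=0)
        with pytest.raises(ValueError):
            run_filter(frog, rec, 10, gain_mode="wat", seed=0)
        with pytest.raises(ValueError):
            run_filter(frog, rec, 10, innovation="wat", seed=0)

    def test_determinism(self, frog):
        rec = simulate(frog, 2.0, 0.01, seed=10)
        a = run_filter(frog, rec, 50, seed=11)
        b = run_filter(frog, rec, 50, seed=11)
        np.testing.assert_array_equal(a.mean, b.mean)


class TestLimits:
    def test_zero_gain_limit_recovers_prior(self, frog):
        # W = 0: each particle is an i.i.d. copy of the hidden SDE, so the
        # long-run particle histogram matches the stationary prior density
        rec = simulate(frog, 60.0, 0.01, seed=12)
        res = run_filter(frog, rec, 400, gain_mode="fixed",
                         W_fixed=np.zeros((1, 2)), seed=13,
                         snapshot_every=100)
        dens = stationary_density(frog, np.linspace(-4, 4, 4001))
        samples = np.concatenate(
            [v[:, 0] for k, v in res.snapshots.items() if k > rec.steps // 2]
        )
        ks = stats.kstest(samples, dens.cdf).statistic
        assert ks < 0.05

    @pytest.mark.parametrize("seed", [14])
    def test_deterministic_observation_limit_variance_shrinks(self, seed):
        # inter-particle variance decreases monotonically as sigma_y^2 -> 0
        variances = []
        for s2 in (1.0, 0.1, 0.01):
            m = model_zoo("frog", sigma_v2=s2, sigma_a2=s2)
            rec = simulate(m, 20.0, 0.01, seed=seed)
            res = run_filter(m, rec, 300, seed=seed + 1, track_variance=True)
            variances.append(res.var[rec.steps // 10:, 0].mean())
        assert variances[0] > variances[1] > variances[2]

    def test_auditory_gain_reflects_tanh_slope(self, frog, rng):
        # cov(x, tanh 2x) is larger for mass near 0 (steep sigmoid) than
        # near +-1 (saturated), so W^(a) is larger at the center
        spread = 0.15 * rng.standard_normal((4000, 1))
        W_center = empirical_gain(ParticleEnsemble(spread), frog)
        W_branch = empirical_gain(ParticleEnsemble(1.0 + spread), frog)
        assert W_center[0, 1] > W_branch[0, 1]

    def test_auditory_gain_decreases_with_noise(self):
        avgs = []
        for s2 in (0.01, 0.1, 1.0):
            m = model_zoo("frog", sigma_v2=0.1, sigma_a2=s2)
            rec = simulate(m, 20.0, 0.01, seed=15)
            res = run_filter(m, rec, 300, seed=16)
            avgs.append(res.W_time_avg[0, 1])
        assert avgs[0] > avgs[1] > avgs[2]


class TestNpfGainSelfConsistency:
    def test_stationary_ensemble_variance_root(self, ou_1d):
        # With the per-particle innovation, the stationary inter-particle
        # variance V solves 2 V^2 / R + 2|a| V - Q = 0 (deviations are
        # contracted by the full gain), giving V = (-1.5 + sqrt(10.25))/4
        # for a=-0.75, Q=R=1 -- slightly below the Riccati root 0.5.
        rec = simulate(ou_1d, 50.0, 0.01, seed=17)
        res = run_filter(ou_1d, rec, 10_000, seed=18, track_variance=True)
        burn = rec.steps // 10
        V_expected = (-1.5 + np.sqrt(1.5**2 + 8.0)) / 4.0
        assert res.var[burn:, 0].mean() == pytest.approx(V_expected, rel=0.05)
        assert res.W_time_avg[0, 0] == pytest.approx(V_expected, rel=0.05)

    def test_gain_operator_on_exact_posterior_samples(self, ou_1d, rng):
        # the gain operator itself reproduces the Kalman gain P*/R when fed
        # samples from the exact posterior spread
        P = riccati_steady_state(ou_1d.A, ou_1d.C, ou_1d.sigma_x,
                                 ou_1d.sigma_y)[0, 0]
        z = np.sqrt(P) * rng.standard_normal((10_000, 1))
        W = empirical_gain(ParticleEnsemble(z), ou_1d)
        assert W[0, 0] == pytest.approx(P, rel=0.05)
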