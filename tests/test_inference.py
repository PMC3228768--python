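"""Likelihood, nuisance-parameter marginalization, posterior and entropy."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from glintloc.inference import (
    EchoStrengthPrior,
    EntropySurface,
    average_entropy,
    log_likelihood,
    log_marginal_likelihood,
    marginal_likelihood,
    performance_curve,
    posterior,
    shannon_entropy_bits,
    simulate_entropy_surface,
)
from glintloc.directions import make_direction_grid
from glintloc.noise import NoiseSpec, build_covariance, simulate_measurement
from glintloc.templates import GlintSchedule, SampledTemplate, make_glint_schedule, sample_template_set


def _st(values):
    values = np.asarray(values, dtype=float)
    k = values.size // 2
    sched = GlintSchedule(100.0, 0.050, np.linspace(0.0, 0.04, k), "regular")
    return SampledTemplate(0, values, sched)


def _oracle_logpdf(y, mu, cov):
    """Library-free multivariate-normal log density (inverse + slogdet)."""
    r = y - mu
    sign, logdet = np.linalg.slogdet(cov)
    assert sign > 0
    return -0.5 * (y.size * np.log(2 * np.pi) + logdet + r @ np.linalg.inv(cov) @ r)


class TestLogLikelihood:
    def test_density_is_maximal_at_the_mode(self, rng):
        st_ = _st([2.0, -1.0, 0.5, 1.5])
        cov = build_covariance(2, NoiseSpec(sigma_db=1.5, rho_lr=0.9))
        a = 25.0
        mu = np.maximum(0.0, st_.values_db + a)
        at_mode = log_likelihood(mu, st_, a, cov)
        for _ in range(20):
            y = mu + rng.normal(scale=2.0, size=4)
            assert log_likelihood(y, st_, a, cov) <= at_mode
        normalizer = multivariate_normal(mean=mu, cov=cov).logpdf(mu)
        assert at_mode == pytest.approx(normalizer, abs=1e-12)

    def test_standard_normal_quadratic_form(self):
        st_ = _st([0.0, 0.0])
        cov = build_covariance(1, NoiseSpec(sigma_db=1.0, rho_lr=0.0))
        a = 10.0
        mu = np.array([10.0, 10.0])
        base = log_likelihood(mu, st_, a, cov)
        assert log_likelihood(mu + np.array([1.0, 0.0]), st_, a, cov) == pytest.approx(
            base - 0.5, abs=1e-12
        )

    @pytest.mark.parametrize("k,sigma,rho", [(1, 1.0, 0.0), (2, 2.0, 0.5), (3, 0.7, 0.9)])
    def test_matches_generic_multivariate_normal(self, k, sigma, rho, rng):
        spec = NoiseSpec(sigma_db=sigma, rho_lr=rho)
        cov = build_covariance(k, spec)
        values = rng.normal(scale=5.0, size=2 * k)
        st_ = _st(values)
        a = 15.0
        y = rng.normal(scale=5.0, size=2 * k) + 15.0
        mu = np.maximum(0.0, values + a)
        ours = log_likelihood(y, st_, a, cov)
        assert ours == pytest.approx(_oracle_logpdf(y, mu, cov), abs=1e-10)
        assert ours == pytest.approx(multivariate_normal(mean=mu, cov=cov).logpdf(y), abs=1e-10)

    def test_dimension_mismatch_rejected(self):
        cov = build_covariance(2, NoiseSpec())
        with pytest.raises(ValueError):
            log_likelihood(np.zeros(2), _st(np.zeros(4)), 0.0, cov)


class TestMarginalLikelihood:
    def test_single_point_prior_degenerates(self, rng):
        st_ = _st(rng.normal(size=4))
        cov = build_covariance(2, NoiseSpec(sigma_db=1.0, rho_lr=0.5))
        y = rng.normal(size=4) + 20.0
        prior = EchoStrengthPrior(np.array([20.0]))
        assert marginal_likelihood(y, st_, cov, prior) == pytest.approx(
            np.exp(log_likelihood(y, st_, 20.0, cov)), rel=1e-12
        )

    def test_equals_brute_force_average(self, rng):
        # Riemann-sum oracle: plain average of per-strength densities
        st_ = _st(rng.normal(scale=3.0, size=6))
        cov = build_covariance(3, NoiseSpec(sigma_db=2.0, rho_lr=0.9))
        prior = EchoStrengthPrior.from_range(0.0, 40.0, 10.0)
        y = rng.normal(scale=3.0, size=6) + 20.0
        brute = np.mean(
            [
                np.exp(_oracle_logpdf(y, np.maximum(0.0, st_.values_db + a), cov))
                for a in prior.values_db
            ]
        )
        assert marginal_likelihood(y, st_, cov, prior) == pytest.approx(brute, rel=1e-12)

    def test_peaks_at_true_strength(self, rng):
        st_ = _st([4.0, -4.0, 2.0, -2.0])
        spec = NoiseSpec(sigma_db=0.2, rho_lr=0.0)
        cov = build_covariance(2, spec)
        y = st_.values_db + 30.0
        prior = EchoStrengthPrior.from_range(10.0, 50.0, 5.0)
        lls = [log_likelihood(y, st_, a, cov) for a in prior.values_db]
        assert prior.values_db[int(np.argmax(lls))] == 30.0

    def test_empty_prior_rejected(self):
        with pytest.raises(ValueError):
            EchoStrengthPrior(np.array([]))


class TestPosterior:
    def test_near_noiseless_measurement_pins_the_true_direction(self, micro_templates):
        sched = make_glint_schedule(200.0, 0.050, rng=2)
        sampled = sample_template_set(micro_templates, sched)
        spec = NoiseSpec(sigma_db=1e-3, rho_lr=0.0)
        cov = build_covariance(sched.n_samples, spec)
        true_dir, a = 3, 40.0
        y = sampled[true_dir] + a
        res = posterior(y, sampled, cov, EchoStrengthPrior(np.array([a])))
        assert int(np.argmax(res.probabilities)) == true_dir
        assert res.probabilities[true_dir] == pytest.approx(1.0, abs=1e-9)
        assert res.entropy_bits == pytest.approx(0.0, abs=1e-6)

    def test_identical_templates_give_uniform_posterior(self):
        n = 16
        sampled = np.tile(np.array([1.0, -1.0, 2.0, 0.0]), (n, 1))
        cov = build_covariance(2, NoiseSpec(sigma_db=1.0, rho_lr=0.5))
        res = posterior(
            np.array([5.0, 3.0, 6.0, 4.0]), sampled, cov, EchoStrengthPrior(np.array([4.0]))
        )
        np.testing.assert_allclose(res.probabilities, 1.0 / n, atol=1e-12)
        assert res.entropy_bits == pytest.approx(np.log2(n), abs=1e-9)

    def test_probabilities_normalized_and_entropy_bounded(self, micro_templates, rng):
        sched = make_glint_schedule(60.0, 0.050, rng=4)
        sampled = sample_template_set(micro_templates, sched)
        spec = NoiseSpec(sigma_db=3.0, rho_lr=0.9)
        cov = build_covariance(sched.n_samples, spec)
        prior = EchoStrengthPrior.from_range(0.0, 40.0, 10.0)
        for _ in range(20):
            m = simulate_measurement(
                SampledTemplate(0, sampled[rng.integers(len(micro_templates))], sched),
                float(rng.uniform(0, 40)),
                spec,
                rng,
            )
            res = posterior(m, sampled, cov, prior)
            assert res.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(res.probabilities >= 0)
            assert -1e-9 <= res.entropy_bits <= np.log2(len(micro_templates)) + 1e-9

    def test_chance_level_entropy_on_default_grid(self):
        # uniform posterior over the full 3252-direction hypothesis space
        n = make_direction_grid(3252).count
        h = shannon_entropy_bits(np.full(n, 1.0 / n))
        assert int(h) == 11

    def test_total_underflow_falls_back_to_uniform(self, caplog):
        sampled = np.array([[0.0, 0.0], [5.0, -5.0]])
        cov = build_covariance(1, NoiseSpec(sigma_db=0.01, rho_lr=0.0))
        # measurement absurdly far from every hypothesis: densities underflow
        res = posterior(
            np.array([1e200, -1e200]), sampled, cov, EchoStrengthPrior(np.array([0.0])),
            floor_db=-np.inf,
        )
        np.testing.assert_allclose(res.probabilities, 0.5)
        assert res.entropy_bits == pytest.approx(1.0)


class TestAverageEntropy:
    def test_zero_noise_with_unique_templates_gives_zero_bits(self, micro_templates):
        h = average_entropy(
            micro_templates, 2, 100.0, NoiseSpec(sigma_db=0.0), 40.0, n_realizations=4, rng=0
        )
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_single_realization_is_reproducible(self, micro_templates):
        kwargs = dict(n_realizations=1, rng=42)
        h1 = average_entropy(micro_templates, 1, 60.0, NoiseSpec(sigma_db=2.0), 20.0, **kwargs)
        h2 = average_entropy(micro_templates, 1, 60.0, NoiseSpec(sigma_db=2.0), 20.0, **kwargs)
        assert h1 == h2

    def test_requires_at_least_one_realization(self, micro_templates):
        with pytest.raises(ValueError):
            average_entropy(micro_templates, 0, 60.0, NoiseSpec(), 20.0, n_realizations=0)


def _surface(values, flutters, strengths, n_dir=4):
    grid = make_direction_grid(n_dir)
    arr = np.broadcast_to(
        np.asarray(values, dtype=float)[None, :, :], (n_dir, len(flutters), len(strengths))
    ).copy()
    return EntropySurface(
        grid=grid,
        flutter_rates_hz=np.asarray(flutters, float),
        echo_strengths_db=np.asarray(strengths, float),
        sigma_db=1.5,
        mode="regular",
        n_realizations=1,
        mean_entropy_bits=arr,
    )


class TestPerformanceCurve:
    def test_baseline_is_exactly_100(self):
        surf = _surface([[1.0, 0.5], [0.4, 0.2]], [100.0, 200.0], [0.0, 10.0])
        pc = performance_curve(surf, 200.0)
        assert pc.loc[pc.flutter_hz == 200.0, "performance_pct"].item() == 100.0

    def test_constant_surface_is_flat_100(self):
        surf = _surface([[0.7, 0.7], [0.7, 0.7]], [50.0, 200.0], [0.0, 10.0])
        pc = performance_curve(surf, 200.0)
        np.testing.assert_allclose(pc.performance_pct, 100.0)

    def test_hand_built_two_by_two_surface(self):
        # H_max = log2(4) = 2; P(100) = 100*((2-1)+(2-0.5)) / ((2-0.5)+(2-0.25))
        surf = _surface([[1.0, 0.5], [0.5, 0.25]], [100.0, 200.0], [0.0, 10.0], n_dir=4)
        pc = performance_curve(surf, 200.0)
        expected = 100.0 * 2.5 / 3.25
        assert pc.loc[pc.flutter_hz == 100.0, "performance_pct"].item() == pytest.approx(expected)

    def test_entropy_ratio_variant_also_normalizes_to_100(self):
        surf = _surface([[1.0, 0.5], [0.5, 0.25]], [100.0, 200.0], [0.0, 10.0])
        pc = performance_curve(surf, 200.0, method="entropy-ratio")
        assert pc.loc[pc.flutter_hz == 200.0, "performance_pct"].item() == 100.0

    def test_missing_baseline_rejected(self):
        surf = _surface([[1.0, 0.5]], [100.0], [0.0, 10.0])
        with pytest.raises(ValueError):
            performance_curve(surf, 200.0)

    def test_degenerate_chance_level_surface_rejected(self):
        surf = _surface([[2.0, 2.0], [2.0, 2.0]], [100.0, 200.0], [0.0, 10.0], n_dir=4)
        with pytest.raises(ValueError):
            performance_curve(surf, 200.0)


class TestEntropySurfaceEngine:
    def test_batch_engine_agrees_with_per_measurement_posterior(self, micro_templates):
        # the vectorized whitened-GEMM path and the direct per-measurement
        # path must compute the same entropies
        from glintloc.inference import _entropies_for_measurements

        sched = make_glint_schedule(100.0, 0.050, rng=11)
        sampled = sample_template_set(micro_templates, sched)
        spec = NoiseSpec(sigma_db=2.0, rho_lr=0.9)
        cov = build_covariance(sched.n_samples, spec)
        prior = EchoStrengthPrior.from_range(0.0, 40.0, 20.0)
        rng = np.random.default_rng(5)
        y = sampled + rng.normal(scale=2.0, size=sampled.shape) + 20.0
        batch = _entropies_for_measurements(y, sampled, prior, cov, 0.0, spec.sigma_db)
        for i in range(len(micro_templates)):
            res = posterior(y[i], sampled, cov, prior)
            assert batch[i] == pytest.approx(res.entropy_bits, abs=1e-8)

    def test_surface_shape_and_reproducibility(self, micro_templates):
        kwargs = dict(n_realizations=2, seed=3)
        s1 = simulate_entropy_surface(
            micro_templates, [60.0, 200.0], [20.0, 40.0], NoiseSpec(sigma_db=1.5), **kwargs
        )
        s2 = simulate_entropy_surface(
            micro_templates, [60.0, 200.0], [20.0, 40.0], NoiseSpec(sigma_db=1.5), **kwargs
        )
        assert s1.mean_entropy_bits.shape == (len(micro_templates), 2, 2)
        np.testing.assert_array_equal(s1.mean_entropy_bits, s2.mean_entropy_bits)

    def test_unsampled_surface_is_flutter_independent(self, micro_templates):
        s = simulate_entropy_surface(
            micro_templates, [60.0, 200.0], [20.0], NoiseSpec(sigma_db=6.0),
            n_realizations=2, seed=1, sampled=False,
        )
        np.testing.assert_array_equal(
            s.mean_entropy_bits[:, 0, :], s.mean_entropy_bits[:, 1, :]
        )

    def test_surface_export_schema(self, micro_templates, tmp_path):
        s = simulate_entropy_surface(
            micro_templates, [100.0], [20.0], NoiseSpec(sigma_db=1.5), n_realizations=1, seed=0
        )
        path = tmp_path / "surface.csv"
        s.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == (
            "azimuth_deg,elevation_deg,flutter_hz,echo_strength_db,"
            "sigma_db,mode,mean_entropy_bits,n_realizations"
        )
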