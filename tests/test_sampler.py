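import numpy as np
import pytest

from mifhh.data import DyadReport, ModelSpec, build_design
from mifhh.exceptions import ConfigurationError, DegenerateInputError
from mifhh.priors import default_hyperparameters
from mifhh.sampler import (
    PosteriorDraws,
    SamplerConfig,
    bernoulli_deviance,
    fit,
    fit_null,
)

from _oracles import ks_distance, quadrature_intercept_posterior


def intercept_only_design(y):
    records = [DyadReport("F1", "I1", f"M{k}", s) for k, s in enumerate(y)]
    spec = ModelSpec(name="tiny", cluster_level="none", estimate_sigma2=False)
    return build_design(records, spec)


class TestSamplerConfig:
    def test_default_retained_sample_is_ten_thousand(self):
        config = SamplerConfig()
        assert config.n_iterations == 20_000
        assert config.burn_in == 5_000
        assert config.thin == 2
        assert config.n_retained == 10_000

    @pytest.mark.parametrize(
        "kwargs", [{"burn_in": -1}, {"thin": 0}, {"target_acceptance": 1.5}]
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SamplerConfig(**kwargs)


class TestOracleEquivalence:
    """MCMC must match deterministic quadrature of the exact posterior."""

    @pytest.mark.parametrize("y", [(1, 0, 1, 1, 0), (1, 1, 1, 0, 0, 0, 1, 0), (0, 0, 1)])
    def test_posterior_matches_quadrature(self, y):
        design = intercept_only_design(y)
        hyper = default_hyperparameters(p=1, q=0, prevalence=0.12)
        draws = fit(design, hyper, SamplerConfig(seed=42), estimate_sigma2=False)
        grid, _, cdf, oracle_mean = quadrature_intercept_posterior(
            y, prior_mean=hyper.b[0], prior_var=1.0 / hyper.B[0, 0]
        )
        b0 = draws.beta[:, 0]
        assert abs(b0.mean() - oracle_mean) < 0.05
        assert ks_distance(b0, grid, cdf) < 0.05

    def test_large_sample_intercept_recovers_marginal_prevalence(self):
        rng = np.random.default_rng(9)
        y = (rng.random(2000) < 0.3).astype(int)
        design = intercept_only_design(y)
        hyper = default_hyperparameters(p=1, q=0, prevalence=0.12, intercept_variance=1e6)
        config = SamplerConfig(n_iterations=4000, burn_in=1000, thin=1, seed=3)
        draws = fit(design, hyper, config, estimate_sigma2=False)
        # the Gaussian over-dispersion attenuates the intercept: the marginal
        # report rate satisfies E[expit(b0 + eps)] = 0.3, so b0 sits below
        # logit(0.3); the exact quadrature posterior is the reference
        _, _, _, oracle_mean = quadrature_intercept_posterior(
            y, prior_mean=hyper.b[0], prior_var=1.0 / hyper.B[0, 0]
        )
        assert oracle_mean < np.log(0.3 / 0.7)
        assert draws.beta[:, 0].mean() == pytest.approx(oracle_mean, abs=0.05)


class TestFitContracts:
    def test_identical_seeds_identical_draws(self, faithful_dataset, quick_config):
        records, _, _ = faithful_dataset
        design = build_design(records[:300], ModelSpec(cluster_level="informant"))
        hyper = default_hyperparameters(p=1, q=1)
        a = fit(design, hyper, quick_config)
        b = fit(design, hyper, quick_config)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.b, b.b)
        assert np.array_equal(a.theta, b.theta)
        assert a.acceptance_rate == b.acceptance_rate

    def test_empty_design_raises(self, tiny_design, default_hyper_for, quick_config):
        design = tiny_design
        design.y = np.empty(0)
        with pytest.raises(DegenerateInputError):
            fit(design, default_hyper_for(tiny_design), quick_config)

    def test_dimension_mismatch_rejected(self, tiny_design, quick_config):
        hyper = default_hyperparameters(p=2, q=0)
        with pytest.raises(ConfigurationError):
            fit(tiny_design, hyper, quick_config)

    def test_single_cluster_warns_not_errors(self, four_reports, quick_config):
        design = build_design(four_reports, ModelSpec(cluster_level="family"))
        hyper = default_hyperparameters(p=1, q=1)
        with pytest.warns(UserWarning, match="weakly identified"):
            draws = fit(design, hyper, quick_config)
        assert draws.S == quick_config.n_retained

    def test_theta_strictly_inside_unit_interval_and_D_spd(
        self, faithful_dataset, quick_config
    ):
        records, _, _ = faithful_dataset
        design = build_design(records[:400], ModelSpec(cluster_level="informant"))
        hyper = default_hyperparameters(p=1, q=1)
        draws = fit(design, hyper, quick_config)
        assert np.all(draws.theta > 0.0) and np.all(draws.theta < 1.0)
        for D in draws.D:
            assert np.allclose(D, D.T)
            assert np.all(np.linalg.eigvalsh(D) > 0)

    def test_cluster_relabelling_permutes_b_only(self, faithful_dataset, quick_config):
        records, _, _ = faithful_dataset
        design = build_design(records[:400], ModelSpec(cluster_level="informant"))
        hyper = default_hyperparameters(p=1, q=1)
        base = fit(design, hyper, quick_config)

        rng = np.random.default_rng(1)
        perm = rng.permutation(design.C)
        relabelled = build_design(records[:400], ModelSpec(cluster_level="informant"))
        relabelled.g = perm[design.g]
        other = fit(relabelled, hyper, quick_config)

        assert np.array_equal(base.beta, other.beta)
        assert np.array_equal(base.D, other.D)
        assert np.array_equal(base.theta, other.theta)
        assert np.array_equal(base.b, other.b[:, perm, :])

    def test_input_row_order_is_irrelevant_through_the_sampler(
        self, faithful_dataset, quick_config
    ):
        records, _, _ = faithful_dataset
        subset = records[:300]
        spec = ModelSpec(cluster_level="informant")
        hyper = default_hyperparameters(p=1, q=1)
        base = fit(build_design(subset, spec), hyper, quick_config)
        rng = np.random.default_rng(4)
        shuffled = [subset[i] for i in rng.permutation(len(subset))]
        other = fit(build_design(shuffled, spec), hyper, quick_config)
        assert np.array_equal(base.beta, other.beta)
        assert np.array_equal(base.theta, other.theta)

    def test_adaptive_acceptance_converges_to_target_window(self, faithful_dataset):
        records, _, _ = faithful_dataset
        design = build_design(records[:600], ModelSpec(cluster_level="informant"))
        hyper = default_hyperparameters(p=1, q=1)
        config = SamplerConfig(n_iterations=2000, burn_in=1500, thin=1, seed=8)
        draws = fit(design, hyper, config)
        assert 0.35 <= draws.acceptance_rate <= 0.55

    def test_estimated_sigma2_stays_positive(self, faithful_dataset, quick_config):
        records, _, _ = faithful_dataset
        design = build_design(records[:300], ModelSpec(cluster_level="informant"))
        hyper = default_hyperparameters(p=1, q=1)
        draws = fit(design, hyper, quick_config, estimate_sigma2=True)
        assert np.all(draws.sigma2 > 0)


class TestFitNull:
    def test_all_zero_data_pulls_intercept_below_prior_mean(self, quick_config):
        design = intercept_only_design([0] * 20)
        hyper = default_hyperparameters(p=1, q=0, prevalence=0.12)
        draws = fit_null(design, hyper, quick_config)
        assert draws.beta[:, 0].mean() < hyper.b[0]

    def test_balanced_data_centres_intercept_at_zero(self):
        design = intercept_only_design([1, 0] * 500)
        hyper = default_hyperparameters(p=1, q=0, intercept_variance=1e6)
        config = SamplerConfig(n_iterations=4000, burn_in=1000, thin=1, seed=2)
        draws = fit_null(design, hyper, config)
        assert abs(draws.beta[:, 0].mean()) < 0.1

    def test_theta_constant_within_draw(self, quick_config):
        design = intercept_only_design([1, 0, 1, 0, 1])
        hyper = default_hyperparameters(p=1, q=0)
        draws = fit_null(design, hyper, quick_config)
        assert np.all(draws.theta == draws.theta[:, [0]])

    def test_fixed_seed_bitwise_identical(self, quick_config):
        design = intercept_only_design([1, 0, 1, 1, 0])
        hyper = default_hyperparameters(p=1, q=0)
        a = fit_null(design, hyper, quick_config)
        b = fit_null(design, hyper, quick_config)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.deviance, b.deviance)


class TestBernoulliDeviance:
    @pytest.mark.parametrize(
        "y,theta,expected",
        [
            ([1], [0.5], 1.3863),
            ([1, 0], [0.5, 0.5], 2.7726),
            ([1, 0], [1.0 - 1e-12, 1e-12], 0.0),
        ],
    )
    def test_reference_values(self, y, theta, expected):
        assert bernoulli_deviance(y, theta) == pytest.approx(expected, abs=1e-4)

    def test_boundary_theta_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            value = bernoulli_deviance([1], [1.0])
        assert np.isfinite(value) and value >= 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bernoulli_deviance([1, 0], [0.5])


class TestSerialization:
    def test_npz_round_trip(self, faithful_dataset, quick_config, tmp_path):
        records, _, _ = faithful_dataset
        design = build_design(records[:200], ModelSpec(cluster_level="informant"))
        hyper = default_hyperparameters(p=1, q=1)
        draws = fit(design, hyper, quick_config)
        path = tmp_path / "draws.npz"
        draws.save_npz(path)
        loaded = PosteriorDraws.load_npz(path)
        assert np.array_equal(draws.beta, loaded.beta)
        assert np.array_equal(draws.b, loaded.b)
        assert np.array_equal(draws.theta, loaded.theta)
        assert draws.acceptance_rate == loaded.acceptance_rate

    def test_csv_export_writes_parameter_blocks(
        self, faithful_dataset, quick_config, tmp_path
    ):
        records, _, _ = faithful_dataset
        design = build_design(records[:200], ModelSpec(cluster_level="informant"))
        hyper = default_hyperparameters(p=1, q=1)
        draws = fit(design, hyper, quick_config)
        draws.save_csv(tmp_path / "csv")
        for name in ("beta", "sigma2", "deviance", "b", "D"):
            assert (tmp_path / "csv" / f"{name}.csv").exists()
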