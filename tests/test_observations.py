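"""Observation-model tests: growth/abundance likelihood terms and their sums."""

import math

import numpy as np
import pytest

from humpback_assess import (
    AbundanceObs,
    CatchSeries,
    Dataset,
    GrowthObs,
    ProcessParams,
    Trajectory,
    log_variance_from_cv,
    loglik_abundance,
    loglik_growth,
    model_growth_rate,
    project,
    total_loglik,
)
from humpback_assess._kernels import loglik_kernel
from humpback_assess.observations import pack_observations


def _flat_trajectory(n: float, years: int = 140, start: int = 1901) -> Trajectory:
    return Trajectory(start_year=start, N=np.full(years, n), K=n)


def _doubling_trajectory(start: int = 1901, years: int = 140) -> Trajectory:
    # doubles every 7 years from 1000
    N = 1000.0 * 2 ** (np.arange(years) / 7.0)
    return Trajectory(start_year=start, N=N, K=N[0])


class TestModelGrowthRate:
    def test_constant_population_has_zero_rate(self):
        traj = _flat_trajectory(5000.0)
        assert model_growth_rate(traj, 1950, 1960) == 0.0

    def test_doubling_over_seven_years(self):
        traj = _doubling_trajectory()
        assert model_growth_rate(traj, 1950, 1957) == pytest.approx(
            math.log(2) / 7, rel=1e-12
        )

    def test_invalid_trajectory_raises(self):
        traj = Trajectory(1901, np.full(50, 100.0), 100.0, valid=False)
        with pytest.raises(ValueError):
            model_growth_rate(traj, 1910, 1920)


class TestLoglikGrowth:
    def test_at_the_mean_equals_normal_mode_density(self):
        traj = _doubling_trajectory()
        rate = math.log(2) / 7  # exact model rate over any 7-year interval
        obs = GrowthObs(1950, 1957, rate, 0.446)
        # at the mean the normal logpdf is -0.5*ln(2*pi*sigma^2)
        expected = -0.5 * math.log(2 * math.pi * obs.sd**2)
        assert loglik_growth(obs, traj) == pytest.approx(expected, rel=1e-9)

    def test_study_observation_sigma(self):
        """The 1995-1998 estimate (0.074, CV 0.446) has sd 0.033."""
        obs = GrowthObs(1995, 1998, 0.074, 0.446)
        assert obs.sd == pytest.approx(0.033, abs=5e-4)

    def test_density_integrates_to_one(self):
        """Quadrature over the observed rate recovers unit mass.

        The observation sd is held fixed across the grid (cv = sd/|est|,
        matching the known-variance contract) so the density is a proper
        normal in the observed rate.
        """
        traj = _doubling_trajectory()
        sd = 0.05
        grid = np.linspace(-0.5, 0.7, 20_001)
        grid = grid[grid != 0]
        dens = np.array([
            math.exp(loglik_growth(GrowthObs(1950, 1957, g, sd / abs(g)), traj))
            for g in grid
        ])
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)


class TestLoglikAbundance:
    def test_scale_equivariance(self):
        """Multiplying observation and population by 10 shifts the lognormal
        log-density by exactly -ln(10) (change of variables)."""
        obs1 = AbundanceObs(1950, 8000.0, 0.1)
        obs2 = AbundanceObs(1950, 80000.0, 0.1)
        t1 = _flat_trajectory(9000.0)
        t2 = _flat_trajectory(90000.0)
        assert loglik_abundance(obs2, t2) == pytest.approx(
            loglik_abundance(obs1, t1) - math.log(10), rel=1e-10
        )

    def test_matching_population_beats_mismatch(self):
        obs = AbundanceObs(2012, 20_389.0, 0.071)
        assert loglik_abundance(obs, _flat_trajectory(20_389.0)) > \
            loglik_abundance(obs, _flat_trajectory(10_000.0))

    def test_invalid_trajectory_gives_neg_inf(self):
        traj = Trajectory(1901, np.full(140, 100.0), 100.0, valid=False)
        assert loglik_abundance(AbundanceObs(1950, 100.0, 0.1), traj) == -np.inf

    def test_density_integrates_to_one(self):
        traj = _flat_trajectory(10_000.0)
        grid = np.linspace(1.0, 60_000.0, 60_000)
        dens = np.exp([
            loglik_abundance(AbundanceObs(1950, g, 0.17), traj) for g in grid
        ])
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_cv_to_log_sigma_methods_close_for_small_cv(self):
        exact = log_variance_from_cv(0.17, "exact")
        approx = log_variance_from_cv(0.17, "approx")
        assert abs(math.sqrt(exact) / math.sqrt(approx) - 1) < 0.015
        with pytest.raises(ValueError):
            log_variance_from_cv(0.1, "banana")


class TestTotalLoglik:
    @pytest.fixture()
    def toy(self, zero_catches):
        params = ProcessParams(r_max=0.05, n_ref=10_000.0)
        traj = project(params, 10_000.0, zero_catches, end_year=2040)
        data = Dataset(
            catches=zero_catches,
            abundance_obs=(
                AbundanceObs(2005, 9_000.0, 0.17),
                AbundanceObs(2012, 11_000.0, 0.071),
            ),
            growth_obs=(GrowthObs(1995, 1998, 0.05, 0.446),),
        )
        return data, traj

    def test_empty_dataset_scores_zero(self, zero_catches):
        traj = _flat_trajectory(5000.0)
        assert total_loglik(Dataset(catches=zero_catches), traj) == 0.0

    def test_single_observation_equals_component(self, zero_catches):
        traj = _flat_trajectory(5000.0)
        ob = AbundanceObs(1950, 5500.0, 0.1)
        data = Dataset(catches=zero_catches, abundance_obs=(ob,))
        assert total_loglik(data, traj) == pytest.approx(
            loglik_abundance(ob, traj)
        )

    def test_sum_over_components_and_order_invariance(self, toy):
        data, traj = toy
        expected = sum(
            loglik_abundance(ob, traj) for ob in data.abundance_obs
        ) + sum(loglik_growth(ob, traj) for ob in data.growth_obs)
        assert total_loglik(data, traj) == pytest.approx(expected, rel=1e-12)
        reordered = Dataset(
            catches=data.catches,
            abundance_obs=data.abundance_obs[::-1],
            growth_obs=data.growth_obs,
        )
        assert total_loglik(reordered, traj) == pytest.approx(
            total_loglik(data, traj), rel=1e-12
        )

    def test_compiled_kernel_matches_scipy_route(self, toy):
        """The numba likelihood used inside MCMC must agree with the
        scipy.stats implementation to floating tolerance."""
        data, traj = toy
        packed = pack_observations(data, traj.start_year)
        assert loglik_kernel(traj.N, *packed) == pytest.approx(
            total_loglik(data, traj), rel=1e-10
        )


class TestValidation:
    def test_zero_cv_rejected(self):
        with pytest.raises(ValueError):
            AbundanceObs(2005, 6251.0, 0.0)
        with pytest.raises(ValueError):
            GrowthObs(1995, 1998, 0.074, 0.0)

    def test_zero_growth_estimate_rejected(self):
        with pytest.raises(ValueError):
            GrowthObs(1995, 1998, 0.0, 0.446)

    def test_backwards_interval_rejected(self):
        with pytest.raises(ValueError):
            GrowthObs(1998, 1995, 0.074, 0.446)

    def test_observation_before_catch_series_rejected(self, zero_catches):
        with pytest.raises(ValueError):
            Dataset(
                catches=zero_catches,
                abundance_obs=(AbundanceObs(1890, 100.0, 0.1),),
            )
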