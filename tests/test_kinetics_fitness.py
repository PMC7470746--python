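"""Window statistics: growth rate, death kinetics, fitness, colony screens."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crossfeed import (
    ColonyClassCount,
    CompetitionFitnessEstimator,
    FitnessResult,
    FluorescenceSeries,
    GrowthRateEstimator,
    RatioTrajectory,
    auxotroph_frequency,
    competition_fitness,
    death_metrics,
    frequency_dependence,
    gen_competition,
    gen_fluorescence_series,
    max_growth_rate,
)
from crossfeed import coculture_fixed_point
from crossfeed.errors import EstimationError, InvalidArgumentError
from conftest import lstsq_slope

LN2 = math.log(2)


def brute_force_growth(series, window=4, cutoff=0.25):
    t, intensity = series.time, series.norm_intensity
    threshold = cutoff * intensity.max()
    slopes = [
        lstsq_slope(t[i : i + window], np.log(intensity[i : i + window]))
        for i in range(t.size - window + 1)
        if intensity[i + window - 1] <= threshold
        and np.all(intensity[i : i + window] > 0)
    ]
    return max(slopes) if slopes else None


def brute_force_fitness(traj, window=3):
    best = None
    for i in range(traj.generation.size - window + 1):
        a = traj.count_a[i : i + window]
        b = traj.count_b[i : i + window]
        if np.any(a <= 0) or np.any(b <= 0):
            continue
        slope = lstsq_slope(traj.generation[i : i + window], np.log(a / b))
        if best is None or slope > best[0]:
            best = (slope, i)
    return best


class TestMaxGrowthRate:
    def test_exact_exponential(self):
        series = gen_fluorescence_series(0.2, 0.0, 48.0, 48.0, 1.0)
        assert max_growth_rate(series) == pytest.approx(0.2, rel=1e-6)

    def test_constant_series_is_zero(self):
        series = FluorescenceSeries(np.arange(10.0), np.ones(10))
        with pytest.warns(UserWarning, match="cutoff"):
            assert max_growth_rate(series) == pytest.approx(0.0, abs=1e-12)

    def test_lag_then_exponential_uses_exponential_phase(self):
        t = np.arange(0.0, 40.0)
        intensity = np.where(t < 10, 1.0, np.exp(0.3 * (t - 10)))
        series = FluorescenceSeries(t, intensity)
        assert max_growth_rate(series) == pytest.approx(0.3, rel=1e-9)

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = rng.integers(8, 30)
            t = np.cumsum(rng.uniform(0.5, 2.0, n))
            intensity = np.exp(rng.normal(0.0, 1.0, n).cumsum() * 0.1)
            series = FluorescenceSeries(t, intensity / intensity[0])
            expected = brute_force_growth(series)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = max_growth_rate(series)
            if expected is not None:
                assert got == pytest.approx(expected, rel=1e-12)

    def test_too_few_points(self):
        series = FluorescenceSeries([0.0, 1.0, 2.0], [1.0, 1.1, 1.2])
        with pytest.raises(EstimationError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                max_growth_rate(series)

    def test_estimator_class(self):
        series = gen_fluorescence_series(0.15, 0.0, 48.0, 48.0, 1.0)
        est = GrowthRateEstimator().fit(series)
        assert est.growth_rate_ == pytest.approx(0.15, rel=1e-6)
        assert est.get_params() == {"window": 4, "cutoff_fraction": 0.25}


class TestDeathMetrics:
    def test_constant_series(self):
        metrics = death_metrics(FluorescenceSeries(np.arange(5.0), np.ones(5)))
        assert metrics.endpoint_survival == 1.0
        assert metrics.death_rate == 0.0

    def test_pure_decay(self):
        t = np.arange(0.0, 40.0)
        metrics = death_metrics(FluorescenceSeries(t, np.exp(-0.05 * t)))
        assert metrics.death_rate == pytest.approx(0.05, rel=1e-9)
        assert metrics.endpoint_survival == pytest.approx(math.exp(-0.05 * 39))

    def test_grow_then_decay_round_trip(self):
        series = gen_fluorescence_series(0.2, 0.07, 24.0, 110.0, 1.0)
        metrics = death_metrics(series)
        assert metrics.death_rate == pytest.approx(0.07, rel=0.01)
        assert metrics.flag is None

    def test_monotone_rise_flags_no_decline(self):
        t = np.arange(0.0, 10.0)
        metrics = death_metrics(FluorescenceSeries(t, np.exp(0.1 * t)))
        assert metrics.death_rate == 0.0
        assert metrics.flag == "no_decline"


class TestCompetitionFitness:
    def test_constant_ratio_is_neutral(self):
        traj = RatioTrajectory(np.arange(6.0), np.full(6, 500.0), np.full(6, 500.0))
        result = competition_fitness(traj)
        assert result.relative_fitness == pytest.approx(0.0, abs=1e-12)
        assert result.start_fraction == pytest.approx(0.5)

    def test_doubling_per_generation_is_unit_fitness(self):
        gen = np.arange(6.0)
        traj = RatioTrajectory(gen, 10.0 * 2.0**gen, np.full(6, 10.0))
        assert competition_fitness(traj).relative_fitness == pytest.approx(1.0)

    def test_steep_early_window_chosen(self):
        gen = np.arange(7.0)
        ratio = np.array([1.0, 4.0, 16.0, 17.0, 17.5, 17.8, 18.0])
        traj = RatioTrajectory(gen, ratio * 100, np.full(7, 100.0))
        result = competition_fitness(traj)
        expected_slope, expected_i = brute_force_fitness(traj)
        assert result.window_start_index == expected_i == 0
        assert result.relative_fitness == pytest.approx(expected_slope / LN2)
        assert result.start_fraction == pytest.approx(0.5)

    def test_zero_count_windows_skipped(self):
        gen = np.arange(6.0)
        a = np.array([10.0, 0.0, 10.0, 20.0, 40.0, 80.0])
        b = np.full(6, 100.0)
        result = competition_fitness(RatioTrajectory(gen, a, b))
        assert result.window_start_index >= 2

    def test_all_windows_blocked_raises(self):
        traj = RatioTrajectory(np.arange(4.0), [1.0, 0.0, 1.0, 0.0], np.ones(4))
        with pytest.raises(EstimationError):
            competition_fitness(traj)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        counts=st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=2000),
                st.integers(min_value=1, max_value=2000),
            ),
            min_size=3,
            max_size=15,
        )
    )
    def test_matches_brute_force(self, counts):
        a = np.array([float(x) for x, _ in counts])
        b = np.array([float(y) for _, y in counts])
        traj = RatioTrajectory(np.arange(len(counts), dtype=float), a, b)
        expected = brute_force_fitness(traj)
        if expected is None:
            with pytest.raises(EstimationError):
                competition_fitness(traj)
        else:
            result = competition_fitness(traj)
            assert result.relative_fitness == pytest.approx(
                expected[0] / LN2, rel=1e-12, abs=1e-12
            )
            assert result.window_start_index == expected[1]

    def test_estimator_class(self):
        gen = np.arange(6.0)
        traj = RatioTrajectory(gen, 10.0 * 2.0**gen, np.full(6, 10.0))
        est = CompetitionFitnessEstimator().fit(traj)
        assert est.relative_fitness_ == pytest.approx(1.0)


class TestFrequencyDependence:
    def test_single_result(self):
        table = frequency_dependence([FitnessResult(0.5, 0, 0.1)])
        assert len(table.table) == 1
        assert table.sign is None

    def test_all_equal_fitness_is_undefined(self):
        results = [FitnessResult(0.2, 0, f) for f in (0.1, 0.5, 0.9)]
        assert frequency_dependence(results).sign is None

    def test_model_trajectories_show_negative_dependence(self, paper_params):
        fp = coculture_fixed_point(paper_params, 3e6)
        results = []
        for ratio0 in (fp / 30, fp / 5, fp, 5 * fp, 20 * fp):
            traj = gen_competition(paper_params, ratio0, n_generations=25)
            results.append(competition_fitness(traj))
        dep = frequency_dependence(results)
        assert dep.sign == -1

    def test_fitness_sign_matches_side_of_fixed_point(self, paper_params):
        fp = coculture_fixed_point(paper_params, 3e6)
        below = competition_fitness(
            gen_competition(paper_params, fp / 100, n_generations=20)
        )
        above = competition_fitness(
            gen_competition(paper_params, fp * 10, n_generations=20)
        )
        assert below.relative_fitness > 0
        assert above.relative_fitness < 0


class TestAuxotrophFrequency:
    def test_single_class(self):
        assert auxotroph_frequency([ColonyClassCount(100, 30, 3)]) == pytest.approx(0.1)

    def test_weighted_two_classes(self):
        classes = [ColonyClassCount(90, 20, 10), ColonyClassCount(10, 20, 0)]
        assert auxotroph_frequency(classes) == pytest.approx(0.45)

    def test_zero_auxotrophs(self):
        classes = [ColonyClassCount(50, 10, 0), ColonyClassCount(50, 10, 0)]
        assert auxotroph_frequency(classes) == 0.0

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        counted=st.lists(st.integers(1, 1000), min_size=1, max_size=4),
        scale=st.integers(2, 50),
    )
    def test_invariant_to_rescaling_counts(self, counted, scale):
        classes = [ColonyClassCount(c, 10, min(3, 10)) for c in counted]
        scaled = [ColonyClassCount(c.colonies_counted * scale, 10, 3) for c in classes]
        base = [ColonyClassCount(c.colonies_counted, 10, 3) for c in classes]
        assert auxotroph_frequency(scaled) == pytest.approx(auxotroph_frequency(base))

    def test_validation(self):
        with pytest.raises(InvalidArgumentError):
            ColonyClassCount(10, 5, 6)
        with pytest.raises(EstimationError):
            auxotroph_frequency([ColonyClassCount(10, 0, 0)])
        with pytest.raises(InvalidArgumentError):
            auxotroph_frequency([])
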