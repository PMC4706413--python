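"""Generalized-ensemble machinery: histograms, diffusivity, optimal
distribution, feedback, round trips, PT ladder; plus property tests."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from curlimc.engine import run_sweeps
from curlimc.ensemble import (CanonicalWeight, DegenerateProfileError,
                              EmptyTrajectoryError, EnergyGrid,
                              TabulatedWeight, count_round_trips,
                              diffusion_profile, energy_histogram,
                              feedback_update, geometric_ladder,
                              mean_first_passage, multicanonical_weights,
                              optimal_distribution, parallel_tempering_run,
                              transition_histogram)
from curlimc.fixtures import TwoLevelSystem, make_double_well


class TestEnergyHistogram:
    def test_counts_divided_by_bin_width(self):
        grid = EnergyGrid(0.5, 1.5, 1)
        z, outside = energy_histogram([1.0, 1.0, 1.0], grid)
        assert z[0] == pytest.approx(3.0)  # 3 counts / delta=1
        assert outside == 0

    def test_density_integrates_to_sample_count_at_any_bin_width(self, rng):
        e = rng.uniform(0, 10, 500)
        for nb in (5, 10, 20):
            grid = EnergyGrid(0.0, 10.0, nb)
            z, _ = energy_histogram(e, grid)
            assert (z * grid.delta).sum() == pytest.approx(500)

    def test_uniform_samples_give_uniform_histogram(self, rng):
        grid = EnergyGrid(0.0, 1.0, 10)
        z, _ = energy_histogram(rng.uniform(0, 1, 10_000), grid)
        counts = z * grid.delta
        assert np.all(np.abs(counts - 1000) < 4 * np.sqrt(1000))

    def test_empty_trajectory_rejected(self):
        with pytest.raises(EmptyTrajectoryError):
            energy_histogram([], EnergyGrid(0, 1, 2))


class TestTransitionHistogram:
    def test_alternating_series_half_crossings(self):
        """E = [1,3,1,3] at cut 2: three crossing pairs x 1/2 = 1.5."""
        grid = EnergyGrid(1.5, 2.5, 1)  # single cut at center E=2
        assert transition_histogram([1, 3, 1, 3], grid)[0] == 1.5

    def test_monotone_series_single_crossing(self):
        grid = EnergyGrid(1.0, 2.0, 1)  # cut at 1.5
        assert transition_histogram([0, 1, 2, 3], grid)[0] == 0.5

    def test_constant_series_never_crosses(self):
        grid = EnergyGrid(0.0, 4.0, 8)
        assert transition_histogram([2.0] * 10, grid).sum() == 0.0

    def test_sample_exactly_on_cut_counts_as_non_crossing(self):
        grid = EnergyGrid(1.5, 2.5, 1)  # cut at exactly 2.0
        assert transition_histogram([1.0, 2.0, 3.0], grid)[0] == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=60))
    def test_bounded_by_half_the_pairs(self, series):
        grid = EnergyGrid(-10.0, 10.0, 13)
        z = transition_histogram(series, grid)
        assert np.all(z <= (len(series) - 1) / 2)


class TestDiffusionProfile:
    def test_formula_pi_over_dt_ratio_squared(self):
        d = diffusion_profile([4.0], [2.0], 1.0)
        assert d[0] == pytest.approx(np.pi / 4)

    def test_no_crossings_means_zero_diffusivity(self):
        d = diffusion_profile([5.0, 5.0], [0.0, 1.0], 1.0)
        assert d[0] == 0.0

    def test_doubling_sample_interval_halves_d(self):
        z_h, z_c = [4.0, 2.0], [1.0, 1.0]
        np.testing.assert_allclose(diffusion_profile(z_h, z_c, 2.0),
                                   np.asarray(diffusion_profile(z_h, z_c,
                                                                1.0)) / 2)

    def test_empty_histogram_bins_are_masked(self):
        d = diffusion_profile([0.0, 3.0], [1.0, 1.0], 1.0)
        assert np.isnan(d[0]) and np.isfinite(d[1])


class TestOptimalDistribution:
    def test_inverse_sqrt_diffusivity(self):
        np.testing.assert_allclose(optimal_distribution([1.0, 4.0]),
                                   [2 / 3, 1 / 3])

    def test_constant_d_gives_uniform(self):
        np.testing.assert_allclose(optimal_distribution([2.5] * 4),
                                   [0.25] * 4)

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(1e-3, 1e3), min_size=1, max_size=20),
           st.floats(1e-3, 1e3))
    def test_normalized_and_scale_invariant(self, d, c):
        p = optimal_distribution(d)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(p, optimal_distribution(np.array(d) * c),
                                   rtol=1e-9)

    def test_vanishing_d_everywhere_rejected(self):
        with pytest.raises(DegenerateProfileError):
            optimal_distribution([0.0, 0.0])


class TestMeanFirstPassage:
    def test_single_unit_bin_closed_form(self):
        grid = EnergyGrid(0.0, 1.0, 1)
        assert mean_first_passage([1.0], [1.0], grid) == pytest.approx(1.0)

    def test_halving_d_doubles_tau(self):
        grid = EnergyGrid(0.0, 1.0, 4)
        p = [0.25] * 4
        assert mean_first_passage(np.full(4, 0.5), p, grid) == \
            pytest.approx(2 * mean_first_passage(np.ones(4), p, grid))

    def test_optimal_distribution_never_slower_than_flat(self):
        # diffusivity profile with a bottleneck, as measured on the
        # double-well toy: compare tau under P_opt vs flat (muca-like) P
        d = np.array([0.9, 1.0, 0.8, 0.05, 0.02, 0.05, 0.7, 1.0, 1.1, 0.9])
        grid = EnergyGrid(0.0, 5.0, 10)
        p_flat = np.full(10, 0.1)
        tau_opt = mean_first_passage(d, optimal_distribution(d), grid)
        tau_flat = mean_first_passage(d, p_flat, grid)
        assert tau_opt <= tau_flat

    def test_zero_diffusivity_inside_range_is_infinite(self):
        grid = EnergyGrid(0.0, 1.0, 2)
        assert mean_first_passage([1.0, 0.0], [0.5, 0.5], grid) == np.inf


class TestWeights:
    def test_multicanonical_inverse_density(self):
        grid = EnergyGrid(0.0, 2.0, 2)
        w = multicanonical_weights([2.0, 6.0], grid)
        assert w.ln_w[0] - w.ln_w[1] == pytest.approx(np.log(3.0))

    def test_nearest_edge_extrapolation_outside_grid(self):
        grid = EnergyGrid(0.0, 2.0, 2)
        w = TabulatedWeight(grid, [0.0, -1.0])
        assert w.ln_weight(-5.0) == w.ln_weight(0.1)
        assert w.ln_weight(+9.0) == w.ln_weight(1.9)

    def test_tabulated_weight_requires_finite_values(self):
        with pytest.raises(ValueError):
            TabulatedWeight(EnergyGrid(0, 1, 2), [0.0, np.nan])


class TestFeedback:
    def test_single_update_from_flat(self):
        grid = EnergyGrid(0.0, 2.0, 2)
        w0 = TabulatedWeight(grid, [0.0, 0.0], kind="flat")
        w1 = feedback_update(w0, [2.0, 8.0])
        assert w1.ln_w[0] - w1.ln_w[1] == pytest.approx(np.log(4.0))
        assert w1.iteration == 1
        assert w1.kind == "diffusion-optimized"

    def test_constant_zc_is_a_fixed_point(self):
        grid = EnergyGrid(0.0, 3.0, 3)
        w0 = TabulatedWeight(grid, [0.2, -0.1, 0.4])
        w1 = feedback_update(w0, [7.0, 7.0, 7.0])
        np.testing.assert_allclose(w1.ln_w - w1.ln_w[0],
                                   w0.ln_w - w0.ln_w[0], atol=1e-12)

    def test_all_zero_zc_rejected(self):
        grid = EnergyGrid(0.0, 2.0, 2)
        with pytest.raises(DegenerateProfileError):
            feedback_update(TabulatedWeight(grid, [0.0, 0.0]), [0.0, 0.0])


class TestRoundTrips:
    def test_low_high_low_counts_two_one_way_legs(self):
        assert count_round_trips([0, 5, 10, 5, 0], e_low=1, e_high=9) == 2

    def test_never_reaching_high_counts_zero(self):
        assert count_round_trips([0, 3, 0, 4, 0], e_low=1, e_high=9) == 0

    def test_first_partial_leg_not_counted(self):
        assert count_round_trips([5, 10, 5, 0], e_low=1, e_high=9) == 1

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            count_round_trips([0, 1], e_low=5, e_high=1)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 10), min_size=4, max_size=50))
    def test_self_concatenation_at_least_doubles_minus_one(self, series):
        c1 = count_round_trips(series, e_low=2.0, e_high=8.0)
        c2 = count_round_trips(series + series, e_low=2.0, e_high=8.0)
        assert c2 >= 2 * c1 - 1


class TestGeometricLadder:
    def test_sixteen_rungs_span_279_to_367_exactly(self):
        t = geometric_ladder(279.0, 367.0, 16)
        assert t[0] == pytest.approx(279.0, abs=1e-12)
        assert t[-1] == pytest.approx(367.0, abs=1e-12)

    def test_consecutive_ratio_constant(self):
        t = geometric_ladder(279.0, 367.0, 16)
        r = t[1:] / t[:-1]
        np.testing.assert_allclose(r, r[0], rtol=1e-12)


class TestParallelTempering:
    def test_replica_averages_match_single_temperature_runs(self):
        """Two-level toy: PT per-rung canonical <E> equals the exactly
        enumerated canonical value within 3 sigma."""
        sys_ = TwoLevelSystem(gap=300.0, degeneracy=3)
        res = parallel_tempering_run(sys_, n_replicas=4, t_lo=279.0,
                                     t_hi=367.0, n_sweeps=6000,
                                     sample_interval=1, seed=5,
                                     swap_interval=10, kB=1.0)
        for T, rec in zip(res.temperatures, res.records):
            exact, _ = sys_.canonical_average(T, kB=1.0)
            e = rec.energies[500:]
            se = np.sqrt(e.var() / max(len(e) / 8.0, 4.0))  # batch-ish SE
            assert abs(e.mean() - exact) < 3 * se + 1e-9

    def test_swap_statistics_are_recorded(self):
        sys_ = TwoLevelSystem(gap=300.0)
        res = parallel_tempering_run(sys_, n_replicas=3, t_lo=279, t_hi=367,
                                     n_sweeps=200, sample_interval=10,
                                     seed=1, kB=1.0)
        assert res.swap_attempted.sum() > 0
        assert np.all(res.swap_accepted <= res.swap_attempted)


def test_multicanonical_run_reweights_to_direct_canonical(rng):
    """Cross-validation: <E> at T from a multicanonical double-well run
    equals <E> from a direct canonical run, within 3 sigma."""
    from curlimc.thermo import reweight
    dw = make_double_well(4.0, 41)
    grid = dw.default_grid(16)
    muca = multicanonical_weights(dw.density_of_states(grid), grid)
    T = 1.5
    flat_run = run_sweeps(dw, muca, 30000, 1, seed=8)
    ens = reweight(flat_run, muca, T, kB=1.0)
    direct = run_sweeps(dw, CanonicalWeight(T, kB=1.0), 30000, 1, seed=9)
    e_direct = direct.energies[2000:]
    exact, _ = dw.canonical_average(T)
    se = np.sqrt(e_direct.var() / max(len(e_direct) / 50.0, 4.0))
    assert abs(ens.average("E") - e_direct.mean()) < 3 * se
    assert abs(ens.average("E") - exact) < 3 * se
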