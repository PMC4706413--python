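"""Reweighting, free-energy surfaces, binding thermodynamics, melting
curves and jackknife errors."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from curlimc.constants import KB_KCAL, N_AVOGADRO
from curlimc.engine import run_sweeps
from curlimc.ensemble import CanonicalWeight, FlatWeight
from curlimc.fixtures import TwoLevelSystem, make_synthetic_trajectory, \
    make_two_state_melt
from curlimc.thermo import (TooFewRunsError, binding_free_energy,
                            box_volume_m3, dimer_population,
                            free_energy_surface, jackknife, melting_curve,
                            melting_temperature, reference_concentration,
                            reweight)


class TestReweight:
    def test_already_canonical_weights_give_constant_factors(self):
        tab = pd.DataFrame({"E": [0.0, 1.0, 2.0, 1.5]})
        ens = reweight(tab, CanonicalWeight(300.0), 300.0)
        rw = ens.table["rw"].to_numpy()
        np.testing.assert_allclose(rw, rw[0])

    def test_flat_sampled_two_level_recovers_boltzmann_ratio(self):
        """Degeneracies 1 and 2, gap eps: P(exc)/P(ground) = 2 exp(-b eps)."""
        eps, T = 1.0, 1.0
        sys_ = TwoLevelSystem(gap=eps, degeneracy=2)
        # flat sampling over the three microstates
        rec = run_sweeps(sys_, FlatWeight(), 30000, 1, seed=4)
        # w(E) must be the sampling weight *per energy level*: the flat
        # microstate ensemble samples P(E) ~ g(E), i.e. w = 1
        ens = reweight(rec, FlatWeight(), T, kB=1.0)
        lev = ens.table["level"].to_numpy()
        w = ens.table["rw"].to_numpy()
        p_exc = (w * lev).sum() / w.sum()
        expected = 2 * np.exp(-eps / T) / (1 + 2 * np.exp(-eps / T))
        sigma = np.sqrt(p_exc * (1 - p_exc) / (len(lev) / 4))
        assert abs(p_exc - expected) < 3 * sigma

    def test_infinite_temperature_recovers_density_of_states(self):
        sys_ = TwoLevelSystem(gap=1.0, degeneracy=2)
        rec = run_sweeps(sys_, FlatWeight(), 20000, 1, seed=6)
        ens = reweight(rec, FlatWeight(), 1e12, kB=1.0)
        lev = ens.table["level"].to_numpy()
        w = ens.table["rw"].to_numpy()
        p_exc = (w * lev).sum() / w.sum()   # g ratio 2:1 -> 2/3
        assert abs(p_exc - 2 / 3) < 0.02

    def test_ess_reported_and_low_ess_flagged(self):
        tab = pd.DataFrame({"E": [0.0, 50.0, 100.0]})
        ens = reweight(tab, FlatWeight(), 300.0)
        assert ens.ess < 1.5 and ens.low_ess


class TestFreeEnergySurface:
    def _ensemble(self, x, w=None):
        tab = pd.DataFrame({"E": np.zeros(len(x)), "x": x})
        ens = reweight(tab, FlatWeight(), 300.0)
        if w is not None:
            ens.table["rw"] = w
        return ens

    def test_uniform_probability_is_flat_zero_surface(self):
        ens = self._ensemble([0.5, 1.5, 2.5, 3.5])
        f = free_energy_surface(ens, "x", bins=4, range_x=(0, 4))
        np.testing.assert_allclose(f.F, 0.0, atol=1e-12)

    def test_four_to_one_ratio_gives_ln4(self):
        ens = self._ensemble([0.5] * 8 + [1.5] * 2)
        f = free_energy_surface(ens, "x", bins=2, range_x=(0, 2))
        assert f.F[1] - f.F[0] == pytest.approx(np.log(4.0))
        assert f.F.min() == 0.0

    def test_marginal_of_2d_matches_1d(self, rng):
        x = np.clip(rng.normal(0, 1, 3000), -3.9, 3.9)
        y = np.clip(rng.normal(0, 1, 3000), -3.9, 3.9)
        tab = pd.DataFrame({"E": np.zeros(3000), "x": x, "y": y})
        ens = reweight(tab, FlatWeight(), 300.0)
        f2 = free_energy_surface(ens, "x", "y", bins=8,
                                 range_x=(-4, 4), range_y=(-4, 4))
        f1 = free_energy_surface(ens, "x", bins=8, range_x=(-4, 4))
        m = f2.marginal(axis=0)
        np.testing.assert_allclose(m.F, f1.F, atol=1e-12)


class TestDimerPopulation:
    def test_unweighted_fraction_below_cutoff(self):
        tab = pd.DataFrame({"E": np.zeros(4), "D": [5.0, 20.0, 10.0, 30.0]})
        ens = reweight(tab, FlatWeight(), 300.0)
        assert dimer_population(ens, 15.0) == pytest.approx(0.5)

    def test_all_above_cutoff_gives_zero(self):
        tab = pd.DataFrame({"E": np.zeros(3), "D": [20.0, 16.0, 30.0]})
        ens = reweight(tab, FlatWeight(), 300.0)
        assert dimer_population(ens, 15.0) == 0.0

    def test_recovers_known_mixture_weight(self):
        tab = make_synthetic_trajectory(0.7, 10_000, seed=3)
        ens = reweight(tab, FlatWeight(), 300.0)
        p = dimer_population(ens, 15.0)
        assert abs(p - 0.7) < 3 * np.sqrt(0.7 * 0.3 / 10_000)

    def test_beta_criterion_restricts_population(self):
        tab = make_synthetic_trajectory(0.7, 5000, seed=4)
        ens = reweight(tab, FlatWeight(), 300.0)
        assert dimer_population(ens, 15.0, beta_min=0.5) <= \
            dimer_population(ens, 15.0)


class TestMelting:
    def test_constructed_logistic_curve_crosses_at_310(self):
        T = np.linspace(280, 340, 61)
        curve = pd.DataFrame({"T": T,
                              "population": 1 / (1 + np.exp((T - 310) / 5))})
        assert melting_temperature(curve) == pytest.approx(310.0, abs=0.05)

    def test_no_crossing_gives_nan_sentinel(self):
        curve = pd.DataFrame({"T": [280.0, 300.0],
                              "population": [0.4, 0.3]})
        assert np.isnan(melting_temperature(curve))

    def test_two_state_system_melts_at_designed_temperature(self):
        """Equal-weight point at T* = dE/dS is recovered within 2 K."""
        runs, weight = make_two_state_melt(tm=310.0, n_frames=3000,
                                           n_runs=4, seed=9)
        curve = melting_curve(runs, weight, np.linspace(280, 340, 31), 15.0)
        assert curve.attrs["monotone_decreasing"]
        assert melting_temperature(curve) == pytest.approx(310.0, abs=2.0)


class TestBinding:
    def test_unit_ka_vref_gives_zero(self):
        c0 = reference_concentration(100.0)
        # choose p so that Ka = 1 L/mol: p/((1-p)^2 c0) = 1
        # solve quadratic: p = (1 + 2c0 - sqrt(1 + 4 c0)) / (2 c0)... use
        # direct construction instead: dG = -kBT ln(Ka) must vanish at Ka=1
        p = (2 * c0 + 1 - np.sqrt(4 * c0 + 1)) / (2 * c0)
        res = binding_free_energy(p, 100.0, T=300.0)
        assert res.Ka == pytest.approx(1.0, rel=1e-9)
        assert res.dG == pytest.approx(0.0, abs=1e-9)

    def test_ka_e10_closed_form(self):
        # dG = -kB T ln(Ka Vref) with Ka Vref = e^10 at 300 K
        c0 = reference_concentration(100.0)
        ka_target = np.exp(10.0)
        # invert Ka(p): p/((1-p)^2) = Ka c0
        a = ka_target * c0
        p = (2 * a + 1 - np.sqrt(4 * a + 1)) / (2 * a)
        res = binding_free_energy(p, 100.0, T=300.0)
        assert res.dG == pytest.approx(-10 * KB_KCAL * 300.0, rel=1e-9)
        assert res.dG == pytest.approx(-5.962, abs=2e-3)

    def test_half_population_hand_value(self):
        """p = 0.5 in a 100 A box: Ka = 2/c0 ~ 1200 L/mol."""
        res = binding_free_energy(0.5, 100.0, T=300.0)
        assert res.Ka == pytest.approx(2.0 / res.c0, rel=1e-12)
        assert res.Ka == pytest.approx(1200.0, rel=0.01)

    def test_saturated_population_gives_infinite_sentinel(self):
        res = binding_free_energy(1.0, 100.0)
        assert res.infinite and np.isinf(res.Ka)

    def test_doubling_vref_shifts_dg_by_kbt_ln2(self):
        a = binding_free_energy(0.4, 100.0, T=300.0, c_ref=1.0)
        b = binding_free_energy(0.4, 100.0, T=300.0, c_ref=0.5)
        assert b.dG - a.dG == pytest.approx(-KB_KCAL * 300 * np.log(2.0),
                                            rel=1e-12)


class TestReferenceConcentration:
    def test_hundred_angstrom_box_is_1_over_600_molar(self):
        c = reference_concentration(100.0)
        assert c == pytest.approx(1.0 / (N_AVOGADRO * 1e-21), rel=1e-12)
        assert c == pytest.approx(1.0 / 600.0, rel=5e-3)

    def test_cubic_scaling(self):
        assert reference_concentration(200.0) == pytest.approx(
            reference_concentration(100.0) / 8.0, rel=1e-12)

    def test_box_volume_is_1e_minus_24_m3(self):
        assert box_volume_m3(100.0) == pytest.approx(1e-24, rel=1e-12)


class TestJackknife:
    def test_identical_runs_have_zero_error(self):
        mean, err = jackknife([2.5] * 8)
        assert mean == pytest.approx(2.5)
        assert err == 0.0

    def test_closed_form_delete_one_value(self):
        """[1,2,3,4] with the mean: SE = sqrt(5/12) = s/sqrt(n)."""
        mean, err = jackknife([1.0, 2.0, 3.0, 4.0])
        assert mean == pytest.approx(2.5)
        assert err == pytest.approx(np.sqrt(5.0 / 12.0), rel=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=12))
    def test_linear_statistic_mean_equals_plain_mean(self, vals):
        mean, _ = jackknife(vals)
        assert mean == pytest.approx(np.mean(vals), rel=1e-9, abs=1e-9)

    def test_fewer_than_two_runs_rejected(self):
        with pytest.raises(TooFewRunsError):
            jackknife([1.0])
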