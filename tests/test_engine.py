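"""Metropolis engine: acceptance rule, determinism, canonical ordering,
detailed balance per move kind, and a flat-histogram ergodicity check."""
import numpy as np
import pandas as pd
import pytest

from curlimc.constants import KB_KCAL
from curlimc.energy import LocalOnlyEnergy, SimplifiedImplicitSolvent
from curlimc.engine import (PeptideMCSystem, TorsionOnlyPeptideSystem,
                            acceptance_probability, metropolis_step,
                            run_sweeps)
from curlimc.ensemble import (CanonicalWeight, EnergyGrid, TabulatedWeight)
from curlimc.fixtures import TwoLevelSystem
from curlimc.moves import MoveSet

from conftest import make_state


class TestAcceptanceRule:
    def test_equal_weight_always_accepts(self):
        assert acceptance_probability(-3.2, -3.2, 0.0) == 1.0

    def test_canonical_kbt_step_gives_inverse_e(self):
        """dE = +kB T at 300 K accepts with probability exp(-1)."""
        w = CanonicalWeight(300.0)
        de = KB_KCAL * 300.0
        p = acceptance_probability(w.ln_weight(0.0), w.ln_weight(de))
        assert p == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_nonfinite_energy_is_auto_rejected_and_counted(self, rng):
        class Bad:
            n_dof = 1

            def propose(self, s, r):
                return s, 0.0, "move"

            def energy(self, s):
                return np.inf

        counters = {}
        state, e, acc = metropolis_step(Bad(), 0, 1.0, CanonicalWeight(300),
                                        rng, counters)
        assert not acc and e == 1.0
        assert counters[("rej_nonfinite", "move")] == 1


class TestRunSweeps:
    def test_sample_interval_longer_than_run_gives_empty_table(self):
        rec = run_sweeps(TwoLevelSystem(), CanonicalWeight(1.0, kB=1.0),
                         n_sweeps=5, sample_interval=10, seed=0)
        assert len(rec.table) == 0

    def test_same_seed_gives_bitwise_identical_tables(self):
        sys_ = TwoLevelSystem(gap=0.7, degeneracy=3)
        w = CanonicalWeight(1.0, kB=1.0)
        a = run_sweeps(sys_, w, 500, 2, seed=42)
        b = run_sweeps(sys_, w, 500, 2, seed=42)
        pd.testing.assert_frame_equal(a.table, b.table, check_exact=True)
        assert a.acceptance == b.acceptance

    def test_two_level_occupation_matches_enumeration(self):
        """Occupation odds = degeneracy * exp(-beta gap), within 3 sigma."""
        gap, degen, T = 1.0, 2, 1.0
        sys_ = TwoLevelSystem(gap=gap, degeneracy=degen)
        rec = run_sweeps(sys_, CanonicalWeight(T, kB=1.0), 40000, 1, seed=3)
        lev = rec.table["level"].to_numpy()
        p_exc = lev.mean()
        expected = degen * np.exp(-gap / T) / (1 + degen * np.exp(-gap / T))
        sigma = np.sqrt(expected * (1 - expected) / _n_eff(lev))
        assert abs(p_exc - expected) < 3 * sigma

    def test_canonical_mean_energy_orders_with_temperature(self):
        state = make_state(["GGGGG"])
        model = LocalOnlyEnergy()
        hot = run_sweeps(PeptideMCSystem(state, model, _pivot_only()),
                         CanonicalWeight(2000.0), 400, 1, seed=9)
        cold = run_sweeps(PeptideMCSystem(state, model, _pivot_only()),
                          CanonicalWeight(120.0), 400, 1, seed=9)
        burn = 100
        eh = hot.table["E"].to_numpy()[burn:]
        ec = cold.table["E"].to_numpy()[burn:]
        se = np.sqrt(eh.var() / _n_eff(eh) + ec.var() / _n_eff(ec))
        assert eh.mean() - ec.mean() > -3 * se
        assert eh.mean() > ec.mean()


def _pivot_only():
    return MoveSet(weights={"pivot": 1.0}, pivot_step=40.0)


def _n_eff(x):
    """Crude effective sample size via 10-block batch means."""
    nb = 10
    blocks = np.array_split(np.asarray(x, dtype=float), nb)
    bm = np.array([b.mean() for b in blocks])
    var_full = np.var(x)
    if var_full == 0 or bm.var(ddof=1) == 0:
        return len(x)
    return max(4.0, len(x) * var_full / (bm.var(ddof=1) * len(x) / nb))


class TestDetailedBalance:
    """Empirical flow balance n(i->j) ~ n(j->i) on small systems under a
    tabulated (non-flat) weight, for each move kind separately."""

    GRID = EnergyGrid(-8.0, 6.0, 7)
    LN_W = np.array([0.0, 0.6, -0.4, 0.3, -0.2, 0.5, -0.6])

    def _flow_balance(self, system, state, observable, bins, lo, hi,
                      n_steps=5000, seed=13):
        w = TabulatedWeight(self.GRID, self.LN_W, kind="test")
        rng = np.random.default_rng(seed)
        e = system.energy(state)
        prev_bin = None
        counts = np.zeros((bins, bins))
        for k in range(n_steps):
            state, e, _ = metropolis_step(system, state, e, w, rng)
            if k < 500:  # burn-in
                continue
            b = int(np.clip((observable(state) - lo) / (hi - lo) * bins,
                            0, bins - 1))
            if prev_bin is not None:
                counts[prev_bin, b] += 1
            prev_bin = b
        for i in range(bins):
            for j in range(i + 1, bins):
                tot = counts[i, j] + counts[j, i]
                if tot >= 30:
                    assert abs(counts[i, j] - counts[j, i]) \
                        <= 4.0 * np.sqrt(tot)

    def test_pivot(self):
        state = make_state(["ASA"])
        system = PeptideMCSystem(state, LocalOnlyEnergy(),
                                 MoveSet(weights={"pivot": 1.0},
                                         pivot_step=60.0))
        self._flow_balance(system, state.copy(),
                           lambda s: s.conformation.psi[0][1], 4, -180, 180)

    def test_semilocal(self):
        state = make_state(["ASA"])
        system = PeptideMCSystem(state, LocalOnlyEnergy(),
                                 MoveSet(weights={"semilocal": 1.0},
                                         semilocal_window=3,
                                         semilocal_sigma=40.0))
        self._flow_balance(system, state.copy(),
                           lambda s: s.conformation.psi[0][1], 4, -180, 180,
                           n_steps=4000)

    def test_sidechain(self):
        state = make_state(["ASA"])
        system = PeptideMCSystem(state, SimplifiedImplicitSolvent(),
                                 MoveSet(weights={"sidechain": 1.0},
                                         sidechain_step=80.0))
        self._flow_balance(system, state.copy(),
                           lambda s: s.conformation.chi[0][0], 4, -180, 180)

    def test_rigid_translation(self):
        state = make_state(["GGG", "GGG"], [(-150, 150), (-150, 150)],
                           separation=15.0)
        system = PeptideMCSystem(state, LocalOnlyEnergy(),
                                 MoveSet(weights={"rigid_translation": 1.0},
                                         translation_step=25.0))
        self._flow_balance(system, state.copy(),
                           lambda s: s.conformation.translations[1][0],
                           4, 0, 100, n_steps=4000)


def test_flat_histogram_run_visits_helix_and_strand_rich_states():
    """Ergodicity smoke test: a multicanonical run on a 19-mer (local-only
    separable model, exact weights by per-residue convolution) must visit
    both beta-content > 50% and helix-content > 50% states."""
    n = 19
    model = LocalOnlyEnergy()
    # single-residue energy density on a fine torsion grid
    g1, edges = _single_residue_density(model, bins=240)
    de = edges[1] - edges[0]
    g = g1.copy()
    for _ in range(n - 2):          # residues with both phi and psi: n-1
        g = np.convolve(g, g1)
        g /= g.sum()
    e_min = edges[0] * (n - 1)
    grid = EnergyGrid(e_min, 1e-9, len(g))
    ln_w = np.where(g > 0, -np.log(np.maximum(g, 1e-300)), np.nan)
    from curlimc.ensemble import _fill_nearest
    weights = TabulatedWeight(grid, _fill_nearest(ln_w),
                              kind="multicanonical")
    system = TorsionOnlyPeptideSystem(n, model, step=50.0)
    rec = run_sweeps(system, weights, 1500, 1, seed=2)
    assert rec.table["beta"].max() > 0.5
    assert rec.table["alpha"].max() > 0.5


def _single_residue_density(model, bins):
    t = np.linspace(-180, 180, 181)
    phi, psi = np.meshgrid(t, t)
    e = np.zeros_like(phi)
    from curlimc.energy import _angdiff
    s2 = 2 * model.sigma_loc ** 2
    for (c_phi, c_psi), eps in [(model.HELIX_CENTER, model.eps_helix),
                                (model.STRAND_CENTER, model.eps_strand)]:
        e += -eps * np.exp(-(_angdiff(phi, c_phi) ** 2
                             + _angdiff(psi, c_psi) ** 2) / s2)
    hist, edges = np.histogram(e.ravel(), bins=bins,
                               range=(e.min() - 1e-9, 0.0))
    g = hist.astype(float)
    return g / g.sum(), edges
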