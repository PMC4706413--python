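"""Generalized-ensemble machinery: energy grids and weight functions,
ordinary and transition histograms, the energy-diffusion profile, the
round-trip-optimal sampling distribution, feedback weight learning, and a
parallel-tempering baseline.

The central quantities, for a trajectory E_i sampled every Δt sweeps on a
uniform energy grid:

    Z_H(E) = N(bin) / ΔE                       ordinary histogram (density)
    Z_C(E) = ½ Σ_i Θ[(E_i − E)(E − E_{i+1})]   transition histogram at cut E
    D(E)   = (π/Δt) (Z_C/Z_H)²                 local diffusivity along E
    P_opt(E) ∝ 1/√D(E)                         round-trip-optimal distribution
    τ      = Σ_bins ΔE / (D·P)                 mean first-passage (round-trip)

and the feedback iteration  ln w^n = ln w^{n−1} − ln Z_C, whose fixed point
(Z_C flat) samples P_opt. Samples falling exactly on a cut count as
non-crossing (strict inequalities). D is implemented as (π/Δt)(Z_C/Z_H)² on
dimensional grounds (D must scale as energy²/time).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB_KCAL
from .engine import RunRecord, run_sweeps


class EmptyTrajectoryError(ValueError):
    pass


class DegenerateProfileError(ValueError):
    pass


@dataclass(frozen=True)
class EnergyGrid:
    """Uniform energy bins on [e_min, e_max]."""

    e_min: float
    e_max: float
    n_bins: int

    def __post_init__(self):
        if not (self.e_min < self.e_max and self.n_bins >= 1):
            raise ValueError("need e_min < e_max and n_bins >= 1")

    @property
    def delta(self):
        return (self.e_max - self.e_min) / self.n_bins

    @property
    def edges(self):
        return np.linspace(self.e_min, self.e_max, self.n_bins + 1)

    @property
    def centers(self):
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def bin_index(self, e):
        """Bin index of energies, clipped to the grid (edge extrapolation)."""
        idx = np.floor((np.asarray(e, dtype=float) - self.e_min)
                       / self.delta).astype(int)
        return np.clip(idx, 0, self.n_bins - 1)


class CanonicalWeight:
    """Boltzmann weight ln w(E) = -E / (kB T)."""

    kind = "canonical"

    def __init__(self, T, kB=KB_KCAL):
        self.T = T
        self.kB = kB
        self._beta = 1.0 / (kB * T)

    def ln_weight(self, e):
        if isinstance(e, float) or isinstance(e, int):
            return -e * self._beta
        return -np.asarray(e, dtype=float) * self._beta


class FlatWeight:
    """ln w(E) = 0 everywhere (infinite-temperature / free sampling)."""

    kind = "flat"

    def ln_weight(self, e):
        if isinstance(e, (float, int)):
            return 0.0
        return np.zeros(np.asarray(e).shape)


class TabulatedWeight:
    """Binned ln w(E) table on an EnergyGrid.

    Constant within each bin; energies outside the grid take the nearest
    edge bin's value (documented nearest-edge extrapolation, which avoids
    hard rejections while weights are being learned). Defined up to an
    additive constant; tables are normalized so max ln w = 0.
    """

    def __init__(self, grid: EnergyGrid, ln_w, kind="multicanonical",
                 iteration=0):
        ln_w = np.asarray(ln_w, dtype=float)
        if ln_w.shape != (grid.n_bins,) or not np.all(np.isfinite(ln_w)):
            raise ValueError("ln_w must be finite with one value per bin")
        self.grid = grid
        self.ln_w = ln_w - ln_w.max()
        self.kind = kind
        self.iteration = iteration

    def ln_weight(self, e):
        if isinstance(e, float) or isinstance(e, int):
            g = self.grid
            idx = int((e - g.e_min) / g.delta)
            if idx < 0:
                idx = 0
            elif idx >= g.n_bins:
                idx = g.n_bins - 1
            return self.ln_w[idx]
        return self.ln_w[self.grid.bin_index(e)]


def energy_histogram(energies, grid: EnergyGrid):
    """Z_H per bin (= count/ΔE); also returns the out-of-grid count."""
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise EmptyTrajectoryError("empty trajectory")
    inside = (e >= grid.e_min) & (e < grid.e_max)
    counts, _ = np.histogram(e[inside], bins=grid.edges)
    return counts / grid.delta, int((~inside).sum())


def transition_histogram(energies, grid: EnergyGrid):
    """Z_C(E) at every bin center: half the strict crossings of each cut."""
    e = np.asarray(energies, dtype=float)
    if e.size < 2:
        raise EmptyTrajectoryError("need at least two consecutive samples")
    cuts = grid.centers
    a, b = e[:-1, None], e[1:, None]
    crossing = ((a - cuts[None, :]) * (cuts[None, :] - b)) > 0.0
    return 0.5 * crossing.sum(axis=0)


def diffusion_profile(z_h, z_c, dt):
    """D(E) = (π/Δt)(Z_C/Z_H)²; bins with Z_H = 0 are masked (NaN)."""
    z_h = np.asarray(z_h, dtype=float)
    z_c = np.asarray(z_c, dtype=float)
    d = np.full_like(z_h, np.nan)
    ok = z_h > 0
    if not ok.any():
        raise DegenerateProfileError("all bins have empty histogram")
    d[ok] = (np.pi / dt) * (z_c[ok] / z_h[ok]) ** 2
    return d


def optimal_distribution(d):
    """P_opt(E) ∝ 1/√D(E), normalized over unmasked positive-D bins."""
    d = np.asarray(d, dtype=float)
    ok = np.isfinite(d) & (d > 0)
    if not ok.any():
        raise DegenerateProfileError("diffusivity vanishes on every bin")
    p = np.zeros_like(d)
    p[ok] = 1.0 / np.sqrt(d[ok])
    return p / p.sum()


def mean_first_passage(d, p, grid: EnergyGrid):
    """τ = Σ_bins ΔE/(D·P) over the covered range; inf if D or P vanish."""
    d = np.asarray(d, dtype=float)
    p = np.asarray(p, dtype=float)
    covered = np.isfinite(d)
    if np.any((d[covered] <= 0) | (p[covered] <= 0)):
        return np.inf
    return float((grid.delta / (d[covered] * p[covered])).sum())


def multicanonical_weights(g, grid: EnergyGrid, iteration=0):
    """w(E) = 1/g(E) from a density of states per bin (0 -> nearest)."""
    g = np.asarray(g, dtype=float)
    ln_w = np.full(grid.n_bins, np.nan)
    ok = g > 0
    ln_w[ok] = -np.log(g[ok])
    ln_w = _fill_nearest(ln_w)
    return TabulatedWeight(grid, ln_w, kind="multicanonical",
                           iteration=iteration)


def _fill_nearest(x):
    """Fill NaN entries with the nearest finite value along the grid."""
    x = np.asarray(x, dtype=float).copy()
    ok = np.isfinite(x)
    if not ok.any():
        raise DegenerateProfileError("no finite bins to extrapolate from")
    idx_ok = np.flatnonzero(ok)
    for i in np.flatnonzero(~ok):
        x[i] = x[idx_ok[np.argmin(np.abs(idx_ok - i))]]
    return x


def feedback_update(weights: TabulatedWeight, z_c) -> TabulatedWeight:
    """One diffusion-feedback iteration: ln w^n = ln w^{n−1} − ln Z_C.

    Bins with Z_C = 0 inherit the nearest updated value. Raises if Z_C is
    zero everywhere (the run was too short to cross any cut).
    """
    z_c = np.asarray(z_c, dtype=float)
    if not np.any(z_c > 0):
        raise DegenerateProfileError(
            "Z_C vanishes on every cut; run longer before updating")
    ln_w = np.full(weights.grid.n_bins, np.nan)
    ok = z_c > 0
    ln_w[ok] = weights.ln_w[ok] - np.log(z_c[ok])
    ln_w = _fill_nearest(ln_w)
    return TabulatedWeight(weights.grid, ln_w, kind="diffusion-optimized",
                           iteration=weights.iteration + 1)


def count_round_trips(energies, e_low=None, e_high=None, grid=None,
                      low_frac=0.02, high_frac=0.98):
    """Completed one-way traversals between the low and high energy ends.

    Thresholds default to the ``low_frac``/``high_frac`` quantile positions
    of the sampled (or grid) energy range. Counts alternating one-way legs:
    touching low, then high, then low again counts 2. The first partial leg
    (before the first threshold is reached) is not counted.
    """
    e = np.asarray(energies, dtype=float)
    if e_low is not None and e_high is not None and e_low >= e_high:
        raise ValueError("thresholds inverted: need e_low < e_high")
    if e.size == 0:
        return 0
    if e_low is None or e_high is None:
        if grid is not None:  # restrict to bins the trajectory covered
            idx = grid.bin_index(e)
            centers = grid.centers
            lo, hi = centers[idx.min()], centers[idx.max()]
        else:
            lo, hi = e.min(), e.max()
        span = hi - lo
        e_low = lo + low_frac * span if e_low is None else e_low
        e_high = lo + high_frac * span if e_high is None else e_high
    if e_low >= e_high:
        raise ValueError("thresholds inverted: need e_low < e_high")
    side = 0  # 0: unset, -1 last touched low, +1 last touched high
    trips = 0
    for x in e:
        if x <= e_low:
            if side == +1:
                trips += 1
            side = -1
        elif x >= e_high:
            if side == -1:
                trips += 1
            side = +1
    return trips


def learn_weights(system, grid, n_iterations=4, sweeps_per_iter=2000,
                  sample_interval=1, seed=0, initial_weights=None,
                  min_crossings=1):
    """Diffusion-feedback weight learning (Eq-7-style loop).

    Starts from ``initial_weights`` (default: flat) and applies
    ``feedback_update`` after each seeded run. Returns (weights, history)
    where history holds per-iteration RunRecords.
    """
    weights = initial_weights if initial_weights is not None else \
        TabulatedWeight(grid, np.zeros(grid.n_bins), kind="flat")
    history = []
    state = None
    for it in range(n_iterations):
        rec = run_sweeps(system, weights, sweeps_per_iter, sample_interval,
                         seed + 1000 * it, initial_state=state)
        state = rec.final_state  # warm-start the next iteration
        z_c = transition_histogram(rec.energies, grid)
        history.append(rec)
        if (z_c > 0).sum() < min_crossings:
            break
        weights = feedback_update(weights, z_c)
    return weights, history


def geometric_ladder(t_lo, t_hi, n):
    """T_k = T_lo (T_hi/T_lo)^(k/(n−1)), k = 0..n−1."""
    if n < 2 or t_lo >= t_hi:
        raise ValueError("need n >= 2 and T_lo < T_hi")
    k = np.arange(n)
    return t_lo * (t_hi / t_lo) ** (k / (n - 1))


@dataclass
class PTResult:
    temperatures: np.ndarray
    records: list                     # per-temperature RunRecords
    swap_attempted: np.ndarray        # per neighbor pair
    swap_accepted: np.ndarray


def parallel_tempering_run(system, n_replicas=16, t_lo=279.0, t_hi=367.0,
                           n_sweeps=1000, sample_interval=1, seed=0,
                           swap_interval=10, kB=KB_KCAL) -> PTResult:
    """Replica exchange over a geometric temperature ladder.

    Neighbor swaps are attempted every ``swap_interval`` sweeps (alternating
    even/odd pairs) and accepted with min(1, exp[(β_i−β_j)(E_i−E_j)]).
    Trajectories are recorded per temperature rung.
    """
    temps = geometric_ladder(t_lo, t_hi, n_replicas)
    betas = 1.0 / (kB * temps)
    rng = np.random.default_rng(seed)
    states = [system.initial_state(rng) for _ in range(n_replicas)]
    energies = [system.energy(s) for s in states]
    weights = [CanonicalWeight(t, kB) for t in temps]
    rows = [[] for _ in range(n_replicas)]
    n_pairs = n_replicas - 1
    swap_att = np.zeros(n_pairs)
    swap_acc = np.zeros(n_pairs)
    n_dof = max(1, int(system.n_dof))
    from .engine import metropolis_step
    for sweep in range(1, n_sweeps + 1):
        for k in range(n_replicas):
            for _ in range(n_dof):
                states[k], energies[k], _ = metropolis_step(
                    system, states[k], energies[k], weights[k], rng)
        if sweep % swap_interval == 0:
            parity = (sweep // swap_interval) % 2
            for i in range(parity, n_pairs, 2):
                swap_att[i] += 1
                log_alpha = (betas[i] - betas[i + 1]) \
                    * (energies[i] - energies[i + 1])
                if log_alpha >= 0 or np.log(rng.random()) < log_alpha:
                    states[i], states[i + 1] = states[i + 1], states[i]
                    energies[i], energies[i + 1] = \
                        energies[i + 1], energies[i]
                    swap_acc[i] += 1
        if sweep % sample_interval == 0:
            for k in range(n_replicas):
                rows[k].append({"sweep": sweep, "E": energies[k]})
    import pandas as pd
    records = [RunRecord(seed=seed, n_sweeps=n_sweeps,
                         sample_interval=sample_interval,
                         table=pd.DataFrame(r, columns=["sweep", "E"]),
                         acceptance={}, weight_kind=f"canonical@{t:.2f}K")
               for r, t in zip(rows, temps)]
    return PTResult(temps, records, swap_att, swap_acc)
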