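"""Canonical statistics from generalized-ensemble runs.

Samples drawn under a weight function w(E) are reweighted to the Boltzmann
ensemble at temperature T with per-sample factors

    r_i ∝ exp(-E_i / kB T) / w(E_i),

normalized per independent run and then pooled (each run contributes equal
total weight). Derived observables: free-energy surfaces F = -ln P (in kB T
units, anchored so min F = 0), dimer populations under a center-of-mass
distance cutoff, melting curves and temperatures, standard binding free
energies, and delete-1 jackknife errors over independent runs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import KB_KCAL, N_AVOGADRO

ESS_WARN_THRESHOLD = 10.0


class TooFewRunsError(ValueError):
    pass


@dataclass
class CanonicalEnsemble:
    """Pooled samples with canonical reweighting factors at temperature T."""

    T: float
    table: pd.DataFrame          # pooled samples; column 'rw' holds weights
    ess: float                   # effective sample size (Σr)²/Σr²
    kB: float = KB_KCAL
    low_ess: bool = False

    def average(self, column):
        w = self.table["rw"].to_numpy()
        x = self.table[column].to_numpy()
        return float(np.sum(w * x) / np.sum(w))

    def weighted(self, values):
        w = self.table["rw"].to_numpy()
        return float(np.sum(w * np.asarray(values)) / np.sum(w))


def _as_tables(trajs):
    tables = []
    for t in trajs:
        tables.append(t.table if hasattr(t, "table") else t)
    return tables


def reweight(trajs, weight_fn, T, kB=KB_KCAL) -> CanonicalEnsemble:
    """Reweight one or more runs (RunRecords or DataFrames) to T.

    Multiple runs are pooled with per-run normalization: each run's factors
    are normalized to unit sum before concatenation, so every independent
    run contributes equal statistical weight.
    """
    if hasattr(trajs, "table") or isinstance(trajs, pd.DataFrame):
        trajs = [trajs]
    parts = []
    for tab in _as_tables(trajs):
        e = tab["E"].to_numpy(dtype=float)
        ln_r = -e / (kB * T) - np.asarray(weight_fn.ln_weight(e), dtype=float)
        ln_r -= logsumexp(ln_r)
        part = tab.copy()
        part["rw"] = np.exp(ln_r) / len(trajs)
        parts.append(part)
    pooled = pd.concat(parts, ignore_index=True)
    w = pooled["rw"].to_numpy()
    ess = float(w.sum() ** 2 / np.sum(w ** 2))
    return CanonicalEnsemble(T=T, table=pooled, ess=ess, kB=kB,
                             low_ess=ess < ESS_WARN_THRESHOLD)


@dataclass
class FreeEnergySurface:
    """F = -ln P per bin in kB T units, anchored so min F = 0 over visited
    bins; unvisited bins are masked (NaN). 1-D surfaces have y_edges None."""

    x_edges: np.ndarray
    y_edges: np.ndarray | None
    F: np.ndarray
    x_name: str = "x"
    y_name: str = ""

    def marginal(self, axis=0):
        """1-D surface obtained by marginalizing the 2-D probability."""
        if self.y_edges is None:
            raise ValueError("already one-dimensional")
        P = np.exp(-np.where(np.isfinite(self.F), self.F, np.inf))
        p = P.sum(axis=1 - axis)
        edges = self.x_edges if axis == 0 else self.y_edges
        name = self.x_name if axis == 0 else self.y_name
        with np.errstate(divide="ignore"):
            F = -np.log(p / p.sum())
        F -= np.nanmin(F[np.isfinite(F)])
        F[~np.isfinite(F)] = np.nan
        return FreeEnergySurface(edges, None, F, x_name=name)


def free_energy_surface(ensemble: CanonicalEnsemble, obs_x, obs_y=None,
                        bins=25, range_x=None, range_y=None
                        ) -> FreeEnergySurface:
    """Weighted -ln P over one or two observable axes (column names)."""
    w = ensemble.table["rw"].to_numpy()
    x = ensemble.table[obs_x].to_numpy(dtype=float)
    if obs_y is None:
        hist, xe = np.histogram(x, bins=bins, range=range_x, weights=w)
        ye = None
    else:
        y = ensemble.table[obs_y].to_numpy(dtype=float)
        hist, xe, ye = np.histogram2d(x, y, bins=bins,
                                      range=(range_x, range_y)
                                      if range_x or range_y else None,
                                      weights=w)
    p = hist / hist.sum()
    with np.errstate(divide="ignore"):
        F = -np.log(p)
    F -= F[np.isfinite(F)].min()
    F[~np.isfinite(F)] = np.nan
    return FreeEnergySurface(xe, ye, F, x_name=obs_x, y_name=obs_y or "")


def dimer_population(ensemble: CanonicalEnsemble, d_cut=15.0,
                     beta_min=None) -> float:
    """Weighted fraction of samples with D < d_cut (and beta > beta_min)."""
    sel = ensemble.table["D"].to_numpy(dtype=float) < d_cut
    if beta_min is not None:
        sel &= ensemble.table["beta"].to_numpy(dtype=float) > beta_min
    return ensemble.weighted(sel.astype(float))


def melting_curve(trajs, weight_fn, T_grid, d_cut=15.0, beta_min=None,
                  kB=KB_KCAL) -> pd.DataFrame:
    """Dimer-phase population versus temperature, by reweighting at each T.

    The returned frame has columns T, population, ess and a ``monotone``
    attribute in ``.attrs`` reporting whether the curve is non-increasing.
    """
    rows = []
    for T in np.asarray(T_grid, dtype=float):
        ens = reweight(trajs, weight_fn, T, kB=kB)
        rows.append({"T": T, "population": dimer_population(ens, d_cut,
                                                            beta_min),
                     "ess": ens.ess})
    out = pd.DataFrame(rows)
    pops = out["population"].to_numpy()
    out.attrs["monotone_decreasing"] = bool(np.all(np.diff(pops) <= 1e-9))
    return out


def melting_temperature(curve: pd.DataFrame) -> float:
    """T where the population crosses 0.5 (linear interpolation).

    Returns NaN when the curve never crosses 0.5 inside the grid. If the
    curve crosses more than once, the first crossing (lowest T) is used.
    """
    T = curve["T"].to_numpy(dtype=float)
    p = curve["population"].to_numpy(dtype=float)
    f = p - 0.5
    for i in range(len(T) - 1):
        if f[i] == 0.0:
            return float(T[i])
        if f[i] * f[i + 1] < 0:
            return float(T[i] + (T[i + 1] - T[i]) * f[i] / (f[i] - f[i + 1]))
    if f[-1] == 0.0:
        return float(T[-1])
    return float("nan")


def reference_concentration(box_side: float) -> float:
    """Concentration (mol/L) of one molecule in a cubic box of side Å."""
    if box_side <= 0:
        raise ValueError("box_side must be positive")
    v_liters = (box_side * 1e-10) ** 3 * 1e3  # m^3 -> L
    return 1.0 / (N_AVOGADRO * v_liters)


def box_volume_m3(box_side: float) -> float:
    """Volume of the cubic simulation box in m³."""
    return (box_side * 1e-10) ** 3


@dataclass
class BindingResult:
    Ka: float            # association constant, L/mol
    dG: float            # kcal/mol at temperature T
    T: float
    c_ref: float         # reference concentration, mol/L (Vref = 1/c_ref)
    p_dimer: float
    c0: float            # single-molecule box concentration, mol/L
    infinite: bool = False


def binding_free_energy(p_dimer: float, box_side: float, T=300.0,
                        c_ref=1.0, kB=KB_KCAL) -> BindingResult:
    """Standard binding free energy ΔG = -kB T ln(Ka·Vref).

    With two chains in the box at single-molecule concentration
    c0 = 1/(N_A V_box): [AB] = p·c0, [A] = [B] = (1-p)·c0, so
    Ka = p / ((1-p)² c0). Vref is the reciprocal of the reference
    concentration ``c_ref`` (default 1 mol/L).
    """
    c0 = reference_concentration(box_side)
    if p_dimer >= 1.0:
        return BindingResult(np.inf, -np.inf, T, c_ref, p_dimer, c0,
                             infinite=True)
    Ka = p_dimer / ((1.0 - p_dimer) ** 2 * c0)
    if Ka <= 0.0:
        return BindingResult(0.0, np.inf, T, c_ref, p_dimer, c0,
                             infinite=True)
    dG = -kB * T * np.log(Ka / c_ref)
    return BindingResult(float(Ka), float(dG), T, c_ref, float(p_dimer), c0)


def jackknife(per_run_values, statistic=np.mean):
    """Delete-1 jackknife over independent runs.

    Returns (mean, stderr): the bias-corrected jackknife mean
    n·θ̂ − (n−1)·mean(θ_(i)) and the standard delete-1 error
    sqrt[(n−1)/n · Σ (θ_(i) − mean θ_(i))²]. For linear statistics the
    jackknife mean equals the plain estimate.
    """
    vals = list(per_run_values)
    n = len(vals)
    if n < 2:
        raise TooFewRunsError("jackknife needs at least two runs")
    theta_full = float(statistic(np.asarray(vals)))
    theta_i = np.array([
        float(statistic(np.asarray(vals[:i] + vals[i + 1:])))
        for i in range(n)])
    theta_bar = theta_i.mean()
    mean = n * theta_full - (n - 1) * theta_bar
    err = np.sqrt((n - 1) / n * np.sum((theta_i - theta_bar) ** 2))
    return float(mean), float(err)
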