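"""Metropolis–Hastings engine over arbitrary weight functions w(E).

The engine is generic: any sampling *system* exposing

    n_dof                     -> int, attempts per sweep
    propose(state, rng)       -> (new_state, log_proposal_ratio[, kind])
    energy(state)             -> float
    observables(state)        -> dict (optional, for the trajectory table)

runs here unchanged — the torsional peptide system and the exactly
enumerable toys both satisfy this contract. The acceptance rule is

    P_acc = min(1, [w(E_new)/w(E_old)] * proposal_ratio)

which for the canonical weight w(E) = exp(-E/kB T) is standard Metropolis.
Proposals with non-finite energy are auto-rejected and counted.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chain import SystemState, com_distance, degrees_of_freedom
from .energy import EnergyModel
from .moves import MoveSet
from .structure import ss_content


def acceptance_probability(lnw_old: float, lnw_new: float,
                           log_proposal_ratio: float = 0.0) -> float:
    """min(1, exp(ln w_new - ln w_old + ln q_rev/q_fwd))."""
    return float(min(1.0, np.exp(min(0.0, lnw_new - lnw_old
                                     + log_proposal_ratio))))


@dataclass
class RunRecord:
    """One seeded run: sampled trajectory plus acceptance bookkeeping."""

    seed: int
    n_sweeps: int
    sample_interval: int
    table: pd.DataFrame
    acceptance: dict
    weight_kind: str = ""
    final_state: object = None

    @property
    def energies(self):
        return self.table["E"].to_numpy()


def metropolis_step(system, state, e_old, weight, rng, counters=None):
    """One elementary move attempt; returns (state, energy, accepted)."""
    out = system.propose(state, rng)
    new, log_ratio = out[0], out[1]
    kind = out[2] if len(out) > 2 else "move"
    if counters is not None:
        counters.setdefault(("att", kind), 0)
        counters[("att", kind)] += 1
    e_new = system.energy(new)
    if not np.isfinite(e_new):
        if counters is not None:
            counters.setdefault(("rej_nonfinite", kind), 0)
            counters[("rej_nonfinite", kind)] += 1
        return state, e_old, False
    log_alpha = weight.ln_weight(e_new) - weight.ln_weight(e_old) + log_ratio
    if log_alpha >= 0.0 or np.log(rng.random()) < log_alpha:
        if counters is not None:
            counters.setdefault(("acc", kind), 0)
            counters[("acc", kind)] += 1
        return new, e_new, True
    return state, e_old, False


def run_sweeps(system, weight, n_sweeps: int, sample_interval: int, seed: int,
               initial_state=None, rng=None) -> RunRecord:
    """Run ``n_sweeps`` sweeps (one sweep = n_dof elementary attempts),
    sampling the trajectory table every ``sample_interval`` sweeps.

    Identical (system, weight, seed, initial_state) give bitwise-identical
    tables; the RNG is numpy's portable PCG64 generator.
    """
    if sample_interval <= 0:
        raise ValueError("sample_interval must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    state = system.initial_state(rng) if initial_state is None \
        else initial_state
    e = system.energy(state)
    counters = {}
    rows = []
    n_dof = max(1, int(system.n_dof))
    # hot loop: cache ln w of the current state and inline the accept rule
    propose, energy = system.propose, system.energy
    ln_weight = weight.ln_weight
    random, log, isfinite = rng.random, np.log, np.isfinite
    lnw = float(ln_weight(e))
    for sweep in range(1, n_sweeps + 1):
        for _ in range(n_dof):
            out = propose(state, rng)
            new, log_ratio = out[0], out[1]
            kind = out[2] if len(out) > 2 else "move"
            counters[("att", kind)] = counters.get(("att", kind), 0) + 1
            e_new = energy(new)
            if not isfinite(e_new):
                counters[("rej_nonfinite", kind)] = \
                    counters.get(("rej_nonfinite", kind), 0) + 1
                continue
            lnw_new = float(ln_weight(e_new))
            log_alpha = lnw_new - lnw + log_ratio
            if log_alpha >= 0.0 or log(random()) < log_alpha:
                state, e, lnw = new, e_new, lnw_new
                counters[("acc", kind)] = counters.get(("acc", kind), 0) + 1
        if sweep % sample_interval == 0:
            row = {"sweep": sweep, "E": e}
            obs = system.observables(state) if hasattr(system, "observables") \
                else {}
            row.update(obs)
            # cumulative accepted-move counters per move kind
            for key, v in counters.items():
                if key[0] == "acc":
                    row[f"acc_{key[1]}"] = v
            rows.append(row)
    acc = {k[1]: v for k, v in counters.items() if k[0] == "acc"}
    att = {k[1]: v for k, v in counters.items() if k[0] == "att"}
    table = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["sweep", "E"])
    acc_cols = [c for c in table.columns if c.startswith("acc_")]
    if acc_cols:  # kinds first accepted mid-run start from 0, not NaN
        table[acc_cols] = table[acc_cols].fillna(0).astype(int)
    return RunRecord(seed=seed, n_sweeps=n_sweeps,
                     sample_interval=sample_interval, table=table,
                     acceptance={"accepted": acc, "attempted": att},
                     weight_kind=getattr(weight, "kind", ""),
                     final_state=state)


class PeptideMCSystem:
    """Adapter presenting a torsional peptide system to the engine."""

    def __init__(self, template: SystemState, model: EnergyModel,
                 move_set: MoveSet | None = None):
        self.template = template
        self.model = model
        self.move_set = move_set or MoveSet()
        self.n_dof = degrees_of_freedom(template)

    def initial_state(self, rng):
        return self.template.copy()

    def propose(self, state, rng):
        return self.move_set.propose(state, rng)

    def energy(self, state):
        return self.model.energy(state)

    def observables(self, state):
        bd = self.model.evaluate(state)
        alpha, beta = ss_content(state)
        out = {"E_loc": bd.loc, "E_ev": bd.ev, "E_hb": bd.hb, "E_sc": bd.sc,
               "alpha": alpha, "beta": beta}
        if state.n_chains == 2:
            out["D"] = com_distance(state)
        return out


class TorsionOnlyPeptideSystem:
    """Pivot-only peptide sampling in pure torsion space (no Cartesian
    rebuild): valid for separable local-only energy models, and much
    faster. State is the (phi, psi) array pair of a single chain."""

    def __init__(self, n_residues, model, step=40.0):
        self.n = n_residues
        self.model = model
        self.step = step
        self.n_dof = 2 * n_residues - 1

    def initial_state(self, rng):
        return (np.full(self.n, -150.0), np.full(self.n, 150.0))

    def propose(self, state, rng):
        phi, psi = state[0].copy(), state[1].copy()
        j = int(rng.integers(self.n_dof))
        delta = rng.normal(0.0, self.step)
        if j < self.n - 1:
            phi[j + 1] = (phi[j + 1] + delta + 180.0) % 360.0 - 180.0
        else:
            k = j - (self.n - 1)
            psi[k] = (psi[k] + delta + 180.0) % 360.0 - 180.0
        return (phi, psi), 0.0

    def energy(self, state):
        return self.model._local_chain(state[0], state[1])

    def observables(self, state):
        from .structure import assign_ss

        class _C:  # minimal conformation shim
            phi = [state[0]]
            psi = [state[1]]
        ss = assign_ss(_C(), 0)
        return {"alpha": ss.alpha, "beta": ss.beta}
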