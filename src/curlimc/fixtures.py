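"""Synthetic data standing in for cluster-scale simulations: exactly
solvable toy systems, motif-constrained repeat sequences, ideal
conformations and dimer poses, and stochastic trajectories with known
statistical structure.

Every generator is deterministic under its seed, and every fixture that
claims a label or parameter is designed to be recovered exactly (or within
stated statistical tolerance) by the corresponding analysis operation.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.spatial.transform import Rotation

from .chain import Conformation, PeptideSequence, SystemState
from .constants import KB_KCAL, N_CHI
from .ensemble import EnergyGrid, TabulatedWeight
from .geometry import superpose
from .structure import assign_ss, strand_segments

# ---------------------------------------------------------------------------
# toy systems (exact densities of states by enumeration)
# ---------------------------------------------------------------------------


class DoubleWellSystem:
    """1-D discrete chain of states with two degenerate end wells.

    E(x) = h [G(u) + 4 t u²(1-u²)] with u = 2x/(n-1) - 1 ∈ [-1, 1], where
    G is a narrow Gaussian barrier (width ``barrier_width`` in u)
    normalized so the two end minima sit exactly at E = 0 (degenerate)
    and the barrier top exactly at E = h; the gentle basin tilt
    (amplitude ``t``) vanishes at u ∈ {-1, 0, 1}. The contrast
    between the high-entropy basins and the low-entropy barrier region is
    what makes the toy a meaningful benchmark for round-trip-optimized
    sampling: a flat-in-energy (multicanonical) ensemble over-commits
    sampling time to the few barrier-region states and starves the basin
    interiors, exactly the situation the diffusion-optimized ensemble is
    designed to correct — the discrete analogue of an association/
    dissociation equilibrium with a narrow transition state.

    Moves are ±1 steps (proposals off the ends are rejected; the proposal
    stays symmetric). Reduced units: kB = 1.
    """

    kind = "double_well_1d"

    def __init__(self, barrier_height=5.0, n_states=61, barrier_width=0.3,
                 basin_tilt=0.08):
        if barrier_height < 0:
            raise ValueError("barrier_height must be >= 0")
        self.h = float(barrier_height)
        self.barrier_width = float(barrier_width)
        self.basin_tilt = float(basin_tilt)
        self.n_states = int(n_states)
        u = 2.0 * np.arange(self.n_states) / (self.n_states - 1) - 1.0
        # Gaussian bump rescaled so E(+-1) = 0 exactly and E(0) = h exactly
        tail = np.exp(-(1.0 / self.barrier_width) ** 2)
        bump = (np.exp(-(u / self.barrier_width) ** 2) - tail) / (1.0 - tail)
        self.state_energies = self.h * (
            bump + 4.0 * self.basin_tilt * u * u * (1.0 - u * u))
        self.n_dof = 1

    def initial_state(self, rng):
        return 0

    def propose(self, state, rng):
        step = -1 if rng.random() < 0.5 else 1
        new = state + step
        if new < 0 or new >= self.n_states:
            return state, 0.0
        return new, 0.0

    def energy(self, state):
        return float(self.state_energies[state])

    def observables(self, state):
        return {"x": state}

    def default_grid(self, n_bins=20):
        e = self.state_energies
        if e.max() - e.min() < 1e-12:  # flat landscape (barrier 0)
            return EnergyGrid(e.min() - 0.5, e.min() + 0.5, n_bins)
        return EnergyGrid(e.min() - 1e-9, e.max() + 1e-9, n_bins)

    def density_of_states(self, grid: EnergyGrid):
        """Exact g per bin by enumeration of all states."""
        counts, _ = np.histogram(self.state_energies, bins=grid.edges)
        return counts.astype(float)

    def canonical_average(self, T, kB=1.0):
        """Exact ⟨E⟩ and C_v at temperature T (reduced units)."""
        return _exact_canonical(self.state_energies, T, kB)


class LatticeChainSystem:
    """2-D self-avoiding lattice chain with nearest-neighbor contacts.

    State: (L, 2) integer positions anchored at the origin. Energy: -1 per
    non-bonded nearest-neighbor contact. Moves: pivot (rotate the tail
    about a site by ±90°/180°); self-overlapping proposals are rejected.
    The full state space (all SAWs from the origin, first step free) is
    exactly enumerable for L <= 12. Reduced units: kB = 1.
    """

    kind = "lattice_chain"
    MAX_LENGTH = 12
    _ROTS = [np.array([[0, -1], [1, 0]]), np.array([[-1, 0], [0, -1]]),
             np.array([[0, 1], [-1, 0]])]

    def __init__(self, length=10):
        if length < 3:
            raise ValueError("length must be >= 3")
        if length > self.MAX_LENGTH:
            raise ValueError(
                f"length {length} too large for exact enumeration "
                f"(max {self.MAX_LENGTH})")
        self.length = int(length)
        self.n_dof = self.length - 1
        self._states = None

    def initial_state(self, rng):
        """A random self-avoiding walk (random growth with restarts).

        Dispersed starts decorrelate the initialization bias of
        independent runs, so run-to-run scatter honestly reflects the
        total error.
        """
        dirs = ((1, 0), (-1, 0), (0, 1), (0, -1))
        while True:
            path = [(0, 0)]
            occupied = {(0, 0)}
            ok = True
            for _ in range(self.length - 1):
                x, y = path[-1]
                options = [(x + dx, y + dy) for dx, dy in dirs
                           if (x + dx, y + dy) not in occupied]
                if not options:
                    ok = False
                    break
                nxt = options[int(rng.integers(len(options)))]
                path.append(nxt)
                occupied.add(nxt)
            if ok:
                return np.array(path, dtype=np.int64)

    def propose(self, state, rng):
        i = int(rng.integers(self.length - 1))
        R = self._ROTS[int(rng.integers(3))]
        new = state.copy()
        pivot = state[i]
        new[i + 1:] = (state[i + 1:] - pivot) @ R.T + pivot
        seen = set(map(tuple, new.tolist()))
        if len(seen) < self.length:
            return state, 0.0  # overlap: reject by proposing no change
        return new, 0.0

    def energy(self, state):
        return float(-self._contacts(state))

    @staticmethod
    def _contacts(pos):
        cells = {tuple(p): i for i, p in enumerate(pos.tolist())}
        n = 0
        for (x, y), i in cells.items():
            for dx, dy in ((1, 0), (0, 1)):
                j = cells.get((x + dx, y + dy))
                if j is not None and abs(i - j) > 1:
                    n += 1
        return n

    def observables(self, state):
        return {}

    # -- exact enumeration ---------------------------------------------------
    def enumerate_states(self):
        """Energies of every self-avoiding walk (first step free)."""
        if self._states is not None:
            return self._states
        L = self.length
        energies = []
        path = [(0, 0)]
        occupied = {(0, 0)}

        def extend():
            if len(path) == L:
                pos = np.array(path, dtype=np.int64)
                energies.append(-self._contacts(pos))
                return
            x, y = path[-1]
            for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nxt = (x + dx, y + dy)
                if nxt not in occupied:
                    path.append(nxt)
                    occupied.add(nxt)
                    extend()
                    path.pop()
                    occupied.remove(nxt)

        extend()
        self._states = np.array(energies, dtype=float)
        return self._states

    def default_grid(self):
        e = self.enumerate_states()
        return EnergyGrid(e.min() - 0.5, e.max() + 0.5,
                          int(e.max() - e.min()) + 1)

    def density_of_states(self, grid: EnergyGrid):
        counts, _ = np.histogram(self.enumerate_states(), bins=grid.edges)
        return counts.astype(float)

    def canonical_average(self, T, kB=1.0):
        return _exact_canonical(self.enumerate_states(), T, kB)


class TwoLevelSystem:
    """Ground state (E = 0, degeneracy 1) plus excited level (E = gap,
    degeneracy ``degeneracy``); uniform proposals among all microstates."""

    kind = "two_level"

    def __init__(self, gap=1.0, degeneracy=2):
        self.gap = float(gap)
        self.energies = np.array([0.0] + [self.gap] * degeneracy)
        self.n_states = len(self.energies)
        self.n_dof = 1

    def initial_state(self, rng):
        return 0

    def propose(self, state, rng):
        new = int(rng.integers(self.n_states - 1))
        if new >= state:
            new += 1
        return new, 0.0

    def energy(self, state):
        return float(self.energies[state])

    def observables(self, state):
        return {"level": int(state > 0)}

    def canonical_average(self, T, kB=1.0):
        return _exact_canonical(self.energies, T, kB)


def _exact_canonical(energies, T, kB=1.0):
    """Exact ⟨E⟩ and C_v from an enumerated microstate energy list."""
    beta = 1.0 / (kB * T)
    ln_w = -beta * np.asarray(energies, dtype=float)
    ln_z = logsumexp(ln_w)
    p = np.exp(ln_w - ln_z)
    e_mean = float(np.sum(p * energies))
    e2 = float(np.sum(p * np.asarray(energies) ** 2))
    cv = (e2 - e_mean ** 2) / (kB * T ** 2)
    return e_mean, cv


def make_double_well(barrier_height=5.0, n_states=61) -> DoubleWellSystem:
    return DoubleWellSystem(barrier_height, n_states)


def make_lattice_chain(length=10) -> LatticeChainSystem:
    return LatticeChainSystem(length)


# ---------------------------------------------------------------------------
# motif-constrained repeat sequences
# ---------------------------------------------------------------------------

# Conserved positional motif of curli repeat units (1-based):
# Ser-X5-Gln-X-Gly-X-Gly-Asn-X-Ala-X3-Gln-X
MOTIF = {1: "S", 7: "Q", 9: "G", 11: "G", 12: "N", 14: "A", 18: "Q"}
MOTIF_LENGTH = 19
# residues used at the variable X positions (polar/small-biased, as in
# curli-like repeat sequences)
X_ALPHABET = "ADEFGHIKLMNQRSTVY"


def make_repeat_sequence(seed, length=None, label=None) -> PeptideSequence:
    """A 19-23-mer matching the conserved repeat motif, random X positions.

    Deterministic per seed. ``length`` defaults to a seed-derived choice in
    19..23; positions beyond 19 are unconstrained X residues.
    """
    rng = np.random.default_rng(seed)
    if length is None:
        length = int(rng.integers(MOTIF_LENGTH, 24))
    if not (MOTIF_LENGTH <= length <= 23):
        raise ValueError("repeat peptides are 19-23 residues long")
    letters = []
    for pos in range(1, length + 1):
        letters.append(MOTIF.get(pos) or
                       X_ALPHABET[int(rng.integers(len(X_ALPHABET)))])
    return PeptideSequence(label or f"repeat-seed{seed}", "".join(letters))


# ---------------------------------------------------------------------------
# ideal conformations and dimer poses
# ---------------------------------------------------------------------------

DIMER_CLASSES_ALL = ("NN-parallel", "NC-parallel", "CC-parallel",
                     "NN-antiparallel", "NC-antiparallel",
                     "CC-antiparallel")

HELIX_TORSIONS = (-57.0, -47.0)
STRAND_TORSIONS = (-139.0, 135.0)
TURN_TORSIONS = (60.0, 30.0)  # left-handed region; classified as coil


def _single_chain_conformation(phi, psi, seq, box_side=100.0):
    n = len(seq)
    nchi = sum(N_CHI[aa] for aa in seq.residues)
    return Conformation([np.asarray(phi, dtype=float)],
                        [np.asarray(psi, dtype=float)],
                        [np.full(n, 180.0)], [np.full(nchi, 180.0)],
                        np.array([[box_side / 2] * 3]),
                        np.array([[0.0, 0.0, 0.0, 1.0]]), box_side)


def make_ideal_conformation(kind, n_residues=19, turn=(8, 11), seq=None,
                            box_side=100.0) -> Conformation:
    """Ideal helix, strand, or hairpin torsions for one chain.

    ``turn`` is the 1-based inclusive residue range of the hairpin turn;
    residues before it form the N-proximal strand, residues after it the
    C-proximal strand.
    """
    if seq is None:
        seq = PeptideSequence("ideal", "A" * n_residues)
    n = len(seq)
    if kind == "helix":
        phi = np.full(n, HELIX_TORSIONS[0])
        psi = np.full(n, HELIX_TORSIONS[1])
    elif kind == "strand":
        phi = np.full(n, STRAND_TORSIONS[0])
        psi = np.full(n, STRAND_TORSIONS[1])
    elif kind == "hairpin":
        lo, hi = turn
        if not (2 <= lo <= hi <= n - 1):
            raise ValueError("turn range must lie strictly inside the chain")
        if lo < 4 or hi > n - 3:
            raise ValueError("hairpin needs >= 2 assignable strand residues "
                             "on each side of the turn")
        phi = np.full(n, STRAND_TORSIONS[0])
        psi = np.full(n, STRAND_TORSIONS[1])
        phi[lo - 1:hi] = TURN_TORSIONS[0]
        psi[lo - 1:hi] = TURN_TORSIONS[1]
    else:
        raise ValueError(f"unknown conformation kind {kind!r}")
    return _single_chain_conformation(phi, psi, seq, box_side)


def make_dimer_pose(dimer_class, n_residues=19, turn=(8, 11), seq=None,
                    box_side=100.0, contact_distance=4.8) -> SystemState:
    """Two hairpin chains posed to realize a requested dimer class.

    ``dimer_class`` is one of NN/NC/CC-parallel/antiparallel. The
    designated interface strands are placed facing each other at
    ``contact_distance`` Å (CA-CA), in the designated mutual orientation,
    with each chain's other strand pointing away from the interface. Built
    from ideal torsions plus rigid placement — no energy minimization.
    """
    try:
        letters, orient = dimer_class.split("-")
        assert letters in ("NN", "NC", "CC") and \
            orient in ("parallel", "antiparallel")
    except (ValueError, AssertionError):
        raise ValueError(f"unknown dimer class {dimer_class!r}") from None
    if seq is None:
        seq = PeptideSequence("hairpin", "A" * n_residues)
    conf1 = make_ideal_conformation("hairpin", turn=turn, seq=seq,
                                    box_side=box_side)
    # assemble a two-chain state, both chains initially superposed
    n = len(seq)
    nchi = sum(N_CHI[aa] for aa in seq.residues)
    conf = Conformation(
        [conf1.phi[0].copy(), conf1.phi[0].copy()],
        [conf1.psi[0].copy(), conf1.psi[0].copy()],
        [np.full(n, 180.0), np.full(n, 180.0)],
        [np.full(nchi, 180.0), np.full(nchi, 180.0)],
        np.array([[box_side / 2] * 3, [box_side / 2] * 3]),
        np.array([[0.0, 0.0, 0.0, 1.0], [0.0, 0.0, 0.0, 1.0]]),
        box_side)
    state = SystemState([seq, seq], conf)
    labels = assign_ss(conf, 0).labels
    segs = sorted(strand_segments(labels))
    if len(segs) != 2:
        raise ValueError("hairpin construction did not yield two strands")
    seg_of = {"N": segs[0], "C": segs[1]}
    seg_a = seg_of[letters[0]]
    seg_b = seg_of[letters[1]]

    ca_a = state.ca_coords(0)
    a_pts = ca_a[seg_a[0]:seg_a[1] + 1]
    a_dir = a_pts[-1] - a_pts[0]
    a_dir /= np.linalg.norm(a_dir)
    other_a = seg_of["C" if letters[0] == "N" else "N"]
    v_other = ca_a[other_a[0]:other_a[1] + 1].mean(axis=0) - a_pts.mean(axis=0)
    d = -(v_other - np.dot(v_other, a_dir) * a_dir)
    if np.linalg.norm(d) < 1e-6:
        d = np.cross(a_dir, [0.0, 0.0, 1.0])
        if np.linalg.norm(d) < 1e-6:
            d = np.cross(a_dir, [0.0, 1.0, 0.0])
    d /= np.linalg.norm(d)

    ca_b = state.ca_coords(1)
    b_pts = ca_b[seg_b[0]:seg_b[1] + 1]
    m = min(len(a_pts), len(b_pts))
    targets = a_pts[:m] + contact_distance * d
    if orient == "antiparallel":
        targets = targets[::-1]
    other_b = seg_of["C" if letters[1] == "N" else "N"]
    b_other_centroid = ca_b[other_b[0]:other_b[1] + 1].mean(axis=0)
    s = np.linalg.norm(b_other_centroid - b_pts[:m].mean(axis=0))
    mobile = np.vstack([b_pts[:m], b_other_centroid])
    target = np.vstack([targets, targets.mean(axis=0) + s * d])
    R, t, _ = superpose(mobile, target)
    # fold the rigid transform into chain B's pose
    rot_old = Rotation.from_quat(conf.rotations[1])
    conf.rotations[1] = (Rotation.from_matrix(R) * rot_old).as_quat()
    conf.translations[1] = conf.translations[1] @ R.T + t
    state.rebuild(1)
    return state


# ---------------------------------------------------------------------------
# stochastic trajectories with known structure
# ---------------------------------------------------------------------------


def make_synthetic_trajectory(p_dimer, n_frames, seed, noise=1.0
                              ) -> pd.DataFrame:
    """Two-component (dimer/monomer) trajectory table with known mixture.

    Dimer frames draw D from a truncated normal centred below the 15 Å
    cutoff and high beta-content; monomer frames sit above the cutoff with
    low beta. Columns: sweep, E (flat), D, beta.
    """
    if not 0.0 <= p_dimer <= 1.0:
        raise ValueError("p_dimer must be in [0, 1]")
    rng = np.random.default_rng(seed)
    is_dimer = rng.random(n_frames) < p_dimer
    d = np.where(is_dimer,
                 np.clip(rng.normal(8.0, 2.0 * noise, n_frames), 0.5, 14.5),
                 np.clip(rng.normal(30.0, 5.0 * noise, n_frames), 15.5, 48.0))
    beta = np.where(is_dimer,
                    np.clip(rng.normal(0.70, 0.05 * noise, n_frames), 0, 1),
                    np.clip(rng.normal(0.20, 0.10 * noise, n_frames), 0, 1))
    return pd.DataFrame({"sweep": np.arange(1, n_frames + 1),
                         "E": np.zeros(n_frames), "D": d, "beta": beta})


def make_two_state_melt(tm=310.0, delta_e=25.0, n_frames=4000, n_runs=4,
                        seed=0, kB=KB_KCAL):
    """Two-state dimer/monomer runs with an exactly known melting point.

    The dimer macrostate has energy 0 and degeneracy 1; the monomer
    macrostate has energy ``delta_e`` (kcal/mol) and degeneracy
    g_m = exp(delta_e / kB tm), so the canonical populations are equal
    exactly at ``tm``. Frames are drawn from the multicanonical (flat
    macrostate) ensemble; the matching weight table is returned so that
    reweighting recovers the canonical melting curve.

    Returns (list of DataFrames, TabulatedWeight).
    """
    ln_g_m = delta_e / (kB * tm)
    grid = EnergyGrid(-0.5, delta_e + 0.5, 2)
    ln_w = np.zeros(2)
    ln_w[grid.bin_index(delta_e)] = -ln_g_m
    weight = TabulatedWeight(grid, ln_w, kind="multicanonical")
    rng = np.random.default_rng(seed)
    runs = []
    for _ in range(n_runs):
        is_monomer = rng.random(n_frames) < 0.5
        e = np.where(is_monomer, delta_e, 0.0)
        d = np.where(is_monomer,
                     np.clip(rng.normal(30.0, 5.0, n_frames), 15.5, 48.0),
                     np.clip(rng.normal(8.0, 2.0, n_frames), 0.5, 14.5))
        beta = np.where(is_monomer,
                        np.clip(rng.normal(0.2, 0.1, n_frames), 0, 1),
                        np.clip(rng.normal(0.7, 0.05, n_frames), 0, 1))
        runs.append(pd.DataFrame({"sweep": np.arange(1, n_frames + 1),
                                  "E": e, "D": d, "beta": beta}))
    return runs, weight
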