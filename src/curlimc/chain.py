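"""Multi-chain peptide systems in torsional coordinates with fixed geometry.

Bond lengths and bond angles are held fixed at standard (Engh & Huber-like)
values; the degrees of freedom are the backbone torsions phi/psi (omega is
trans-locked by default), one coarse side-chain torsion chi1 per non-Gly/Ala
residue, and a rigid-body pose per chain inside a periodic cubic box.

Atom model per residue: N, CA, C, O, plus amide H (residues 2..n), CB
(all but Gly), and a single side-chain pseudo-bead SC placed by chi1
(all but Gly/Ala). Phi of residue 1 has no preceding carbonyl and is held
fixed; psi of the last residue still orients its carbonyl O.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from . import constants as K
from .geometry import minimal_image, place_atom


class UnknownResidueError(ValueError):
    """Raised for residues outside the 20-letter canonical alphabet."""


class ChainCountError(ValueError):
    """Raised when an operation requires a different number of chains."""


@dataclass(frozen=True)
class PeptideSequence:
    """A peptide as an id and a string of one-letter residue codes."""

    id: str
    residues: str

    def __post_init__(self):
        if len(self.residues) < 3:
            raise ValueError("peptide sequences must have length >= 3")
        bad = set(self.residues) - K.AMINO_ACIDS
        if bad:
            raise UnknownResidueError(f"unknown residue code(s): {sorted(bad)}")

    def __len__(self):
        return len(self.residues)


class ChainTopology:
    """Static atom layout, bonds and exclusion masks for one sequence."""

    def __init__(self, seq: PeptideSequence):
        self.seq = seq
        n = len(seq)
        names, resid = [], []
        for i, aa in enumerate(seq.residues):
            res_atoms = ["N", "CA", "C", "O"]
            if i > 0:
                res_atoms.append("H")
            if aa != "G":
                res_atoms.append("CB")
            if K.N_CHI[aa] >= 1:
                res_atoms.append("SC")
            names.extend(res_atoms)
            resid.extend([i] * len(res_atoms))
        self.atom_names = names
        self.atom_resid = np.array(resid)
        self.n_atoms = len(names)
        self.index = {}
        for k, (nm, ri) in enumerate(zip(names, resid)):
            self.index[(ri, nm)] = k
        self.ev_sigma = np.array([K.EV_SIGMA[nm] for nm in names])
        self.charges = np.array(
            [K.SC_CHARGE[seq.residues[ri]] if nm == "SC" else 0.0
             for nm, ri in zip(names, resid)]
        )
        # hydrogen-bond donors (N,H) and acceptors (C,O)
        self.donors = [(self.index[(i, "N")], self.index[(i, "H")])
                       for i in range(1, n)]
        self.acceptors = [(self.index[(i, "C")], self.index[(i, "O")])
                          for i in range(n)]
        self._build_exclusions()

    def _build_exclusions(self):
        bonds = []
        n = len(self.seq)
        for i in range(n):
            bonds.append((self.index[(i, "N")], self.index[(i, "CA")]))
            bonds.append((self.index[(i, "CA")], self.index[(i, "C")]))
            bonds.append((self.index[(i, "C")], self.index[(i, "O")]))
            if (i, "H") in self.index:
                bonds.append((self.index[(i, "N")], self.index[(i, "H")]))
            if (i, "CB") in self.index:
                bonds.append((self.index[(i, "CA")], self.index[(i, "CB")]))
            if (i, "SC") in self.index:
                bonds.append((self.index[(i, "CB")], self.index[(i, "SC")]))
            if i + 1 < n:
                bonds.append((self.index[(i, "C")], self.index[(i + 1, "N")]))
        adj = [[] for _ in range(self.n_atoms)]
        for a, b in bonds:
            adj[a].append(b)
            adj[b].append(a)
        # pairs within 3 bonds are excluded from nonbonded terms (1-2 and
        # 1-3 distances are fixed by geometry; 1-4 is governed by E_loc)
        excl = np.zeros((self.n_atoms, self.n_atoms), dtype=bool)
        for start in range(self.n_atoms):
            dist = {start: 0}
            frontier = [start]
            for d in range(1, 4):
                nxt = []
                for u in frontier:
                    for v in adj[u]:
                        if v not in dist:
                            dist[v] = d
                            nxt.append(v)
                frontier = nxt
            for v in dist:
                excl[start, v] = True
        self.excluded = excl
        self.n_chi = sum(K.N_CHI[aa] for aa in self.seq.residues)
        self.chi_residues = [i for i, aa in enumerate(self.seq.residues)
                             if K.N_CHI[aa] >= 1]


@dataclass
class Conformation:
    """Torsional + rigid-body coordinates of a multi-chain system.

    ``phi[c][i]``, ``psi[c][i]``, ``omega[c][i]`` are per-residue backbone
    torsions of chain ``c`` in degrees; ``chi[c]`` holds one chi1 per
    chi-bearing residue (ordered by residue index). ``translations`` and
    ``rotations`` (unit quaternions, scalar-last) give each chain's rigid
    pose; ``box_side`` is the periodic cubic box edge in Å.
    """

    phi: list
    psi: list
    omega: list
    chi: list
    translations: np.ndarray
    rotations: np.ndarray
    box_side: float = 100.0

    def __post_init__(self):
        if self.box_side <= 0:
            raise ValueError("box_side must be positive")

    @property
    def n_chains(self):
        return len(self.phi)

    def copy(self) -> "Conformation":
        return Conformation(
            [p.copy() for p in self.phi],
            [p.copy() for p in self.psi],
            [p.copy() for p in self.omega],
            [p.copy() for p in self.chi],
            self.translations.copy(),
            self.rotations.copy(),
            self.box_side,
        )

    @classmethod
    def extended(cls, seqs, box_side=100.0, separation=30.0):
        """Fully extended (phi=-180 -> use -150/150 strandlike) start."""
        phi, psi, omega, chi = [], [], [], []
        trans, rots = [], []
        for c, seq in enumerate(seqs):
            n = len(seq)
            phi.append(np.full(n, -150.0))
            psi.append(np.full(n, 150.0))
            omega.append(np.full(n, 180.0))
            nchi = sum(K.N_CHI[aa] for aa in seq.residues)
            chi.append(np.full(nchi, 180.0))
            trans.append([box_side / 2 + c * separation % box_side,
                          box_side / 2, box_side / 2])
            rots.append([0.0, 0.0, 0.0, 1.0])
        return cls(phi, psi, omega, chi, np.array(trans, dtype=float),
                   np.array(rots, dtype=float), box_side)


def rebuild_chain(topology: ChainTopology, phi, psi, omega, chi) -> np.ndarray:
    """Cartesian coordinates of one chain in its local frame (NeRF).

    Deterministic; identical torsions always give bitwise-identical output.
    """
    seq = topology.seq.residues
    n = len(seq)
    coords = np.zeros((topology.n_atoms, 3))
    idx = topology.index

    def put(i, name, pos):
        coords[idx[(i, name)]] = pos

    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([K.BOND_N_CA, 0.0, 0.0])
    pseudo = np.array([0.0, 1.0, 0.0])  # reference for phi of residue 1
    put(0, "N", N)
    put(0, "CA", CA)
    prev_C_ref = pseudo
    chi_iter = iter(chi)
    prev = {"N": N, "CA": CA}
    for i in range(n):
        Ni, CAi = prev["N"], prev["CA"]
        Ci = place_atom(prev_C_ref, Ni, CAi, K.BOND_CA_C, K.ANGLE_N_CA_C,
                        phi[i])
        put(i, "C", Ci)
        Oi = place_atom(Ni, CAi, Ci, K.BOND_C_O, K.ANGLE_CA_C_O,
                        psi[i] + 180.0)
        put(i, "O", Oi)
        if seq[i] != "G":
            CBi = place_atom(Ci, Ni, CAi, K.BOND_CA_CB, K.ANGLE_N_CA_CB,
                             K.TORSION_CB_IMPROPER)
            put(i, "CB", CBi)
            if K.N_CHI[seq[i]] >= 1:
                put(i, "SC", place_atom(Ni, CAi, CBi, K.SC_EXTENT[seq[i]],
                                        K.ANGLE_CA_CB_SC, next(chi_iter)))
        if i + 1 < n:
            Nn = place_atom(Ni, CAi, Ci, K.BOND_C_N, K.ANGLE_CA_C_N, psi[i])
            put(i + 1, "N", Nn)
            Hn = place_atom(CAi, Ci, Nn, K.BOND_N_H, K.ANGLE_C_N_H,
                            omega[i + 1] + 180.0)
            put(i + 1, "H", Hn)
            CAn = place_atom(CAi, Ci, Nn, K.BOND_N_CA, K.ANGLE_C_N_CA,
                             omega[i + 1])
            put(i + 1, "CA", CAn)
            prev = {"N": Nn, "CA": CAn}
            prev_C_ref = Ci
    return coords


@dataclass
class SystemState:
    """Sequences + conformation + a consistent Cartesian cache."""

    sequences: list
    conformation: Conformation
    topologies: list = field(default=None)
    coords: list = field(default=None)

    def __post_init__(self):
        if self.topologies is None:
            self.topologies = [ChainTopology(s) for s in self.sequences]
        if self.coords is None:
            self.rebuild()

    @classmethod
    def from_sequences(cls, seqs, box_side=100.0, conformation=None,
                       separation=30.0):
        if conformation is None:
            conformation = Conformation.extended(seqs, box_side,
                                                 separation=separation)
        return cls(list(seqs), conformation)

    @property
    def n_chains(self):
        return len(self.sequences)

    def rebuild(self, chain=None):
        """Refresh the Cartesian cache from torsions (all or one chain)."""
        conf = self.conformation
        chains = range(self.n_chains) if chain is None else [chain]
        if self.coords is None:
            self.coords = [None] * self.n_chains
        for c in chains:
            local = rebuild_chain(self.topologies[c], conf.phi[c],
                                  conf.psi[c], conf.omega[c], conf.chi[c])
            R = Rotation.from_quat(conf.rotations[c]).as_matrix()
            self.coords[c] = local @ R.T + conf.translations[c]
        return self.coords

    def copy(self) -> "SystemState":
        s = SystemState(self.sequences, self.conformation.copy(),
                        topologies=self.topologies,
                        coords=[c.copy() for c in self.coords])
        return s

    def chain_com(self, c: int) -> np.ndarray:
        """Unweighted center of mass (geometric mean of atoms) of chain c."""
        return self.coords[c].mean(axis=0)

    def ca_coords(self, c: int) -> np.ndarray:
        topo = self.topologies[c]
        rows = [topo.index[(i, "CA")] for i in range(len(topo.seq))]
        return self.coords[c][rows]


def rebuild_coordinates(conf: Conformation, seqs) -> list:
    """Per-atom coordinates (Å) for each chain, from torsions + poses."""
    state = SystemState(list(seqs), conf)
    return state.coords


def com_distance(state: SystemState) -> float:
    """Minimal-image distance between the two chains' centers of mass (Å)."""
    if state.n_chains != 2:
        raise ChainCountError("com_distance requires exactly two chains")
    d = state.chain_com(0) - state.chain_com(1)
    return float(np.linalg.norm(minimal_image(d, state.conformation.box_side)))


def degrees_of_freedom(state: SystemState) -> int:
    """Number of sampled coordinates; defines the length of one MC sweep.

    Convention: (n-1) phi + n psi torsions per chain (phi of residue 1 is
    undefined), chi1 per chi-bearing residue, omega locked, and 6 rigid-body
    coordinates for every chain beyond the first (chain 1 is anchored).
    """
    total = 0
    for c, topo in enumerate(state.topologies):
        n = len(topo.seq)
        total += (n - 1) + n + topo.n_chi
        if c > 0:
            total += 6
    return total
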