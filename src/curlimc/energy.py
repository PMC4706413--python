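"""Energy models: the pluggable contract and a simplified four-term potential.

The peptide potential follows the classic implicit-solvent decomposition

    E = E_loc + E_ev + E_hb + E_sc

where E_loc collects local (torsional) interactions, E_ev is excluded
volume, E_hb is backbone hydrogen bonding and E_sc is the signed
charge-charge side-chain term. The functional forms here are deliberately
simple, fully documented reimplementations (see docs/methods.md) — they
preserve the four-term structure and qualitative physics, not any published
parameterization.

All pairwise inter-chain terms use the minimal-image convention in the
periodic cubic box; intra-chain terms use unwrapped chain coordinates.
"""
from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np

from .chain import SystemState
from .geometry import minimal_image

OVERLAP_DISTANCE = 0.1  # Å; closer nonbonded atoms => +inf energy sentinel


@dataclass
class EnergyBreakdown:
    """Total energy and its four-term decomposition (kcal/mol)."""

    total: float
    loc: float
    ev: float
    hb: float
    sc: float

    def as_dict(self):
        return {"E_total": self.total, "E_loc": self.loc, "E_ev": self.ev,
                "E_hb": self.hb, "E_sc": self.sc}


class EnergyModel(ABC):
    """Contract: deterministically map a system state to an EnergyBreakdown.

    Any object with this interface (including the exactly enumerable toy
    systems in :mod:`curlimc.fixtures`) runs unmodified in the sampler.
    """

    name: str = "energy-model"

    @abstractmethod
    def evaluate(self, state) -> EnergyBreakdown:
        ...

    def energy(self, state) -> float:
        return self.evaluate(state).total


class SimplifiedImplicitSolvent(EnergyModel):
    """Documented simplified four-term implicit-solvent peptide potential.

    Parameters (defaults in kcal/mol and Å):

    - ``eps_helix``, ``eps_strand``: depths of two Gaussian wells in
      (phi, psi) space centred on the canonical alpha-helix (-57, -47) and
      beta-strand (-139, 135) regions, width ``sigma_loc`` degrees. This is
      the torsional/neighbour-dipole local term E_loc.
    - ``eps_ev``: prefactor of the pairwise r^-12 repulsion, truncated and
      shifted to zero at the pair contact radius sigma_ij (mean of the two
      atomic radii). E_ev.
    - ``eps_hb``, ``sigma_hb``, ``cut_hb``: backbone NH...OC term
      eps*[5(sigma/r)^12 - 6(sigma/r)^10] on the H...O distance, scaled by
      an alignment factor cos^2(N-H...O) and clamped to <= 0 (the radial
      profile's repulsive core is delegated to E_ev); zero beyond the
      alignment threshold ``hb_align_min`` or beyond ``cut_hb``. E_hb.
    - ``eps_sc``: screened-Coulomb-like signed contact between charged
      side-chain beads, q_i q_j eps_sc (1/r - 1/cut_sc), truncated at
      ``cut_sc``. E_sc.
    - ``eps_hydrophobic``: optional fifth attractive contact term between
      apolar side-chain beads, OFF by default (0.0).
    """

    name = "simplified-implicit-solvent"

    HELIX_CENTER = (-57.0, -47.0)
    STRAND_CENTER = (-139.0, 135.0)
    HYDROPHOBIC = set("VILMFWCY")

    def __init__(self, eps_helix=1.2, eps_strand=1.2, sigma_loc=30.0,
                 eps_ev=0.5, eps_hb=3.0, sigma_hb=2.0, cut_hb=4.5,
                 hb_align_min=0.5, eps_sc=4.15, cut_sc=10.0,
                 eps_hydrophobic=0.0, cut_hp=7.5):
        self.parameters = dict(
            eps_helix=eps_helix, eps_strand=eps_strand, sigma_loc=sigma_loc,
            eps_ev=eps_ev, eps_hb=eps_hb, sigma_hb=sigma_hb, cut_hb=cut_hb,
            hb_align_min=hb_align_min, eps_sc=eps_sc, cut_sc=cut_sc,
            eps_hydrophobic=eps_hydrophobic, cut_hp=cut_hp)
        self.__dict__.update(self.parameters)

    # -- local torsional term ------------------------------------------------
    def _local_chain(self, phi, psi):
        # residues with both phi and psi defined: indices 1..n-1
        dphi_h = _angdiff(phi[1:], self.HELIX_CENTER[0])
        dpsi_h = _angdiff(psi[1:], self.HELIX_CENTER[1])
        dphi_s = _angdiff(phi[1:], self.STRAND_CENTER[0])
        dpsi_s = _angdiff(psi[1:], self.STRAND_CENTER[1])
        s2 = 2.0 * self.sigma_loc ** 2
        e = (-self.eps_helix * np.exp(-(dphi_h ** 2 + dpsi_h ** 2) / s2)
             - self.eps_strand * np.exp(-(dphi_s ** 2 + dpsi_s ** 2) / s2))
        return float(e.sum())

    # -- pairwise helpers ----------------------------------------------------
    @staticmethod
    def _pair_geometry(ti, tj, intra):
        """Cached (mask, sigma_ij) for a chain pair; geometry-only data."""
        key = "_nb_intra" if intra else ("_nb_inter", id(tj))
        cache = getattr(ti, "_nb_cache", None)
        if cache is None:
            cache = ti._nb_cache = {}
        if key not in cache:
            sig = 0.5 * (ti.ev_sigma[:, None] + tj.ev_sigma[None, :])
            if intra:
                mask = ~ti.excluded & np.triu(
                    np.ones_like(ti.excluded, dtype=bool), k=1)
            else:
                mask = np.ones(sig.shape, dtype=bool)
            cache[key] = (mask, sig)
        return cache[key]

    def _pair_terms(self, state: SystemState, ci, cj):
        """(ev, hb, sc, hp, overlap) between chains ci, cj (ci may equal cj)."""
        xi, xj = state.coords[ci], state.coords[cj]
        ti, tj = state.topologies[ci], state.topologies[cj]
        delta = xi[:, None, :] - xj[None, :, :]
        if ci != cj:
            delta = minimal_image(delta, state.conformation.box_side)
        r = np.sqrt((delta ** 2).sum(axis=-1))
        mask, sig = self._pair_geometry(ti, tj, ci == cj)
        if np.any((r < OVERLAP_DISTANCE) & mask):
            return 0.0, 0.0, 0.0, 0.0, True
        # excluded volume: eps * ((sig/r)^12 - 1) for r < sig_ij
        ev_mask = mask & (r < sig)
        rr = r[ev_mask]
        ev = float(self.eps_ev * ((sig[ev_mask] / rr) ** 12 - 1.0).sum())
        # hydrogen bonds: donors of one chain vs acceptors of the other(s)
        hb = self._hb(state, ci, cj, r) + (
            self._hb_cross(state, cj, ci) if ci != cj else 0.0)
        # side-chain charges
        qq = ti.charges[:, None] * tj.charges[None, :]
        sc_mask = mask & (qq != 0.0) & (r < self.cut_sc)
        sc = float((qq[sc_mask] * self.eps_sc
                    * (1.0 / r[sc_mask] - 1.0 / self.cut_sc)).sum())
        hp = 0.0
        if self.eps_hydrophobic > 0.0:
            hyd_i = np.array([nm == "SC" and ti.seq.residues[ri] in self.HYDROPHOBIC
                              for nm, ri in zip(ti.atom_names, ti.atom_resid)])
            hyd_j = np.array([nm == "SC" and tj.seq.residues[ri] in self.HYDROPHOBIC
                              for nm, ri in zip(tj.atom_names, tj.atom_resid)])
            hp_mask = mask & hyd_i[:, None] & hyd_j[None, :] & (r < self.cut_hp)
            hp = -self.eps_hydrophobic * float(hp_mask.sum())
        return ev, hb, sc, hp, False

    def _hb(self, state, ci, cj, r_full=None):
        """Donor(ci) -> acceptor(cj) hydrogen-bond energy."""
        return self._hb_cross(state, ci, cj)

    def _hb_cross(self, state, cd, ca):
        xi, xj = state.coords[cd], state.coords[ca]
        td, ta = state.topologies[cd], state.topologies[ca]
        box = state.conformation.box_side
        e = 0.0
        don = np.array(td.donors)  # (nd, 2): N, H indices
        acc = np.array(ta.acceptors)  # (na, 2): C, O indices
        if len(don) == 0 or len(acc) == 0:
            return 0.0
        H = xi[don[:, 1]]
        N = xi[don[:, 0]]
        O = xj[acc[:, 1]]
        dHO = H[:, None, :] - O[None, :, :]
        if cd != ca:
            dHO = minimal_image(dHO, box)
        r = np.sqrt((dHO ** 2).sum(axis=-1))
        close = r < self.cut_hb
        if cd == ca:
            # skip same-residue and adjacent-residue backbone pairs
            dres = td.atom_resid[don[:, 1]][:, None] - ta.atom_resid[acc[:, 1]][None, :]
            close &= np.abs(dres) >= 2
        di, ai = np.nonzero(close)
        if len(di) == 0:
            return 0.0
        u = H[di] - N[di]
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        v = -dHO[di, ai]  # H -> O
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        align = (u * v).sum(axis=1)
        f = np.where(align > self.hb_align_min, align ** 2, 0.0)
        rr = r[di, ai]
        s = self.sigma_hb / rr
        radial = self.eps_hb * (5.0 * s ** 12 - 6.0 * s ** 10)
        e = float((f * np.minimum(radial, 0.0)).sum())
        return e

    def evaluate(self, state: SystemState) -> EnergyBreakdown:
        conf = state.conformation
        loc = sum(self._local_chain(conf.phi[c], conf.psi[c])
                  for c in range(state.n_chains))
        ev = hb = sc = hp = 0.0
        nc = state.n_chains
        for ci in range(nc):
            for cj in range(ci, nc):
                e, h, s, p, overlap = self._pair_terms(state, ci, cj)
                if overlap:
                    return EnergyBreakdown(np.inf, loc, np.inf, 0.0, 0.0)
                ev += e
                hb += h
                sc += s
                hp += p
        total = loc + ev + hb + sc + hp
        return EnergyBreakdown(total, loc, ev, hb, sc)


def _angdiff(a, b):
    """Wrapped angular difference in degrees."""
    d = np.asarray(a, dtype=float) - b
    return (d + 180.0) % 360.0 - 180.0


class LocalOnlyEnergy(SimplifiedImplicitSolvent):
    """E_loc-only variant: separable over residues, needs no coordinates.

    Its density of states factorizes residue-by-residue, so exact
    multicanonical weights can be computed by convolution — handy for
    engine-level ergodicity checks at negligible cost.
    """

    name = "local-only"

    def __init__(self, **kw):
        kw.setdefault("eps_ev", 0.0)
        kw.setdefault("eps_hb", 0.0)
        kw.setdefault("eps_sc", 0.0)
        super().__init__(**kw)

    def evaluate(self, state: SystemState) -> EnergyBreakdown:
        conf = state.conformation
        loc = sum(self._local_chain(conf.phi[c], conf.psi[c])
                  for c in range(state.n_chains))
        return EnergyBreakdown(loc, loc, 0.0, 0.0, 0.0)
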