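"""Conformational updates: pivot, biased-Gaussian semilocal, side-chain and
rigid-body moves, each returning a proposed state plus the log proposal-ratio
needed for the Metropolis–Hastings correction.

All moves leave bond lengths/angles untouched (torsional moves) or internal
coordinates untouched entirely (rigid-body moves). Proposals never mutate
the input state.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .chain import SystemState
from .geometry import wrap_angle


class WindowError(ValueError):
    """Semilocal window does not fit inside the chain."""


def backbone_torsions(topology):
    """Ordered list of free backbone torsions: ('phi'|'psi', residue)."""
    n = len(topology.seq)
    out = []
    for i in range(n):
        if i > 0:
            out.append(("phi", i))
        out.append(("psi", i))
    return out


def _set_torsion(conf, chain, kind, i, value):
    arr = getattr(conf, kind)[chain]
    arr[i] = wrap_angle(value)


def _get_torsion(conf, chain, kind, i):
    return getattr(conf, kind)[chain][i]


def pivot_move(state: SystemState, rng, step: float, chain=None,
               torsion=None, delta=None):
    """Perturb one backbone torsion; only downstream atoms move.

    Symmetric Gaussian proposal (log-ratio 0). ``torsion`` and ``delta``
    may be fixed explicitly (e.g. to exactly undo a previous move).
    """
    new = state.copy()
    c = int(rng.integers(state.n_chains)) if chain is None else chain
    tors = backbone_torsions(state.topologies[c])
    kind, i = tors[int(rng.integers(len(tors)))] if torsion is None else torsion
    if delta is None:
        delta = rng.normal(0.0, step) if step > 0 else 0.0
    _set_torsion(new.conformation, c, kind, i,
                 _get_torsion(new.conformation, c, kind, i) + delta)
    new.rebuild(c)
    return new, 0.0


def sidechain_move(state: SystemState, rng, step: float):
    """Perturb one chi1 torsion (symmetric)."""
    chains = [c for c in range(state.n_chains)
              if state.topologies[c].n_chi > 0]
    c = chains[int(rng.integers(len(chains)))]
    j = int(rng.integers(state.topologies[c].n_chi))
    new = state.copy()
    arr = new.conformation.chi[c]
    arr[j] = wrap_angle(arr[j] + (rng.normal(0.0, step) if step > 0 else 0.0))
    new.rebuild(c)
    return new, 0.0


def _torsion_axes(state, c, window):
    """Rotation axis (unit) and anchor point for each torsion in window."""
    topo = state.topologies[c]
    X = state.coords[c]
    axes, points = [], []
    for kind, i in window:
        if kind == "phi":
            p0 = X[topo.index[(i, "N")]]
            p1 = X[topo.index[(i, "CA")]]
        else:  # psi
            p0 = X[topo.index[(i, "CA")]]
            p1 = X[topo.index[(i, "C")]]
        ax = p1 - p0
        axes.append(ax / np.linalg.norm(ax))
        points.append(p0)
    return np.array(axes), np.array(points)


def _semilocal_cov(state, c, window, sigma_rad, bias):
    """Covariance of the biased Gaussian step and its Cholesky factor."""
    kdim = len(window)
    if bias <= 0:
        cov_inv = np.eye(kdim) / sigma_rad ** 2
    else:
        topo = state.topologies[c]
        n = len(topo.seq)
        r_end = state.coords[c][topo.index[(n - 1, "CA")]]
        axes, points = _torsion_axes(state, c, window)
        G = np.cross(axes, r_end[None, :] - points)  # (K,3): dr_end/dtheta
        cov_inv = (np.eye(kdim) + bias * (G @ G.T)) / sigma_rad ** 2
    cov = np.linalg.inv(cov_inv)
    L = np.linalg.cholesky(cov)
    return cov_inv, L


def _mvn_logpdf(x, cov_inv, L):
    k = len(x)
    logdet = -2.0 * np.log(np.diag(L)).sum()  # log det cov = -log det cov_inv
    return -0.5 * (k * np.log(2 * np.pi) - logdet + x @ cov_inv @ x)


def semilocal_move(state: SystemState, rng, window_size=4, sigma=8.0,
                   bias=1.0, chain=None, start=None):
    """Biased Gaussian step over a window of consecutive backbone torsions.

    The correlated Gaussian proposal is biased toward small displacement of
    the chain-end CA atom: covariance (I + b G G^T)^-1 sigma^2 with G the
    Jacobian of the end-atom position w.r.t. the window torsions. Forward
    and reverse densities are both evaluated; their log-ratio is returned.
    """
    if window_size > 8:
        raise WindowError("semilocal window is limited to 8 torsions")
    c = int(rng.integers(state.n_chains)) if chain is None else chain
    tors = backbone_torsions(state.topologies[c])
    if window_size > len(tors):
        raise WindowError("window outside chain")
    if start is None:
        start = int(rng.integers(len(tors) - window_size + 1))
    elif start < 0 or start + window_size > len(tors):
        raise WindowError("window outside chain")
    window = tors[start:start + window_size]
    sigma_rad = np.deg2rad(sigma)
    cov_inv_f, Lf = _semilocal_cov(state, c, window, sigma_rad, bias)
    z = rng.standard_normal(len(window))
    dtheta = Lf @ z  # radians
    logq_f = _mvn_logpdf(dtheta, cov_inv_f, Lf)
    new = state.copy()
    for (kind, i), d in zip(window, np.rad2deg(dtheta)):
        _set_torsion(new.conformation, c, kind, i,
                     _get_torsion(new.conformation, c, kind, i) + d)
    new.rebuild(c)
    cov_inv_r, Lr = _semilocal_cov(new, c, window, sigma_rad, bias)
    logq_r = _mvn_logpdf(-dtheta, cov_inv_r, Lr)
    return new, float(logq_r - logq_f)


def rigid_body_move(state: SystemState, rng, which_chain, kind, step):
    """Rigid rotation about the chain COM or translation (wrapped into box).

    Internal torsions are untouched; the proposal is symmetric.
    """
    if kind not in ("rotation", "translation"):
        raise ValueError("kind must be 'rotation' or 'translation'")
    new = state.copy()
    conf = new.conformation
    box = conf.box_side
    if kind == "translation":
        delta = rng.normal(0.0, step, size=3) if step > 0 else np.zeros(3)
        conf.translations[which_chain] = (
            conf.translations[which_chain] + delta) % box
        new.rebuild(which_chain)
    else:
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        angle = rng.normal(0.0, step) if step > 0 else 0.0
        Rd = Rotation.from_rotvec(np.deg2rad(angle) * axis)
        com = state.chain_com(which_chain)
        R_old = Rotation.from_quat(conf.rotations[which_chain])
        conf.rotations[which_chain] = (Rd * R_old).as_quat()
        t = conf.translations[which_chain]
        conf.translations[which_chain] = (Rd.apply(t - com) + com) % box
        new.rebuild(which_chain)
    return new, 0.0


@dataclass
class MoveSet:
    """Move kinds with relative selection weights and step parameters.

    Defaults: pivot 0.25, semilocal 0.25, sidechain 0.30, rigid moves 0.20
    split evenly. Inapplicable kinds (no chi torsions, single chain) are
    dropped and the weights renormalized; applicability depends only on the
    topology, so selection probabilities are state-independent.
    """

    weights: dict = field(default_factory=lambda: {
        "pivot": 0.25, "semilocal": 0.25, "sidechain": 0.30,
        "rigid_rotation": 0.10, "rigid_translation": 0.10})
    pivot_step: float = 25.0
    semilocal_window: int = 4
    semilocal_sigma: float = 8.0
    semilocal_bias: float = 1.0
    sidechain_step: float = 45.0
    rotation_step: float = 30.0
    translation_step: float = 4.0

    def __post_init__(self):
        if any(w < 0 for w in self.weights.values()) or \
                not any(w > 0 for w in self.weights.values()):
            raise ValueError("move weights must be >= 0 and not all zero")

    def applicable(self, state: SystemState):
        kinds = dict(self.weights)
        if all(t.n_chi == 0 for t in state.topologies):
            kinds.pop("sidechain", None)
        if state.n_chains < 2:
            kinds.pop("rigid_rotation", None)
            kinds.pop("rigid_translation", None)
        names = [k for k, w in kinds.items() if w > 0]
        w = np.array([kinds[k] for k in names])
        return names, w / w.sum()

    def propose(self, state: SystemState, rng):
        """Draw a move kind and apply it: (new_state, log_ratio, kind)."""
        names, probs = self.applicable(state)
        kind = names[int(rng.choice(len(names), p=probs))]
        if kind == "pivot":
            new, lr = pivot_move(state, rng, self.pivot_step)
        elif kind == "semilocal":
            new, lr = semilocal_move(state, rng, self.semilocal_window,
                                     self.semilocal_sigma,
                                     self.semilocal_bias)
        elif kind == "sidechain":
            new, lr = sidechain_move(state, rng, self.sidechain_step)
        else:
            which = 1 + int(rng.integers(state.n_chains - 1))
            mv = "rotation" if kind == "rigid_rotation" else "translation"
            step = (self.rotation_step if mv == "rotation"
                    else self.translation_step)
            new, lr = rigid_body_move(state, rng, which, mv, step)
        return new, lr, kind
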