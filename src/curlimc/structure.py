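"""Structural observables: Ramachandran-box secondary structure, contact
maps, dimer topology classification, turn detection and RMSD clustering.

Secondary structure is assigned from backbone torsions alone (a documented
divergence from hydrogen-bond-aware assigners such as STRIDE/DSSP):

    H (helix):  phi in [-100, -30]  and  psi in [-80, -5]
    E (strand): phi in [-180, -80]  and  psi in [80, 180] or [-180, -170]
    C otherwise; singleton E runs are demoted to C.

Terminal residues lacking phi or psi are excluded from all content
denominators. Residue indexing in reports is 1-based inclusive.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import ChainCountError, SystemState
from .geometry import minimal_image, rmsd_kabsch

HELIX_BOX = {"phi": (-100.0, -30.0), "psi": (-80.0, -5.0)}
STRAND_BOX = {"phi": (-180.0, -80.0), "psi_hi": (80.0, 180.0),
              "psi_lo": (-180.0, -170.0)}

DIMER_CLASSES = ("NN-parallel", "NC-parallel", "CC-parallel",
                 "NN-antiparallel", "NC-antiparallel", "CC-antiparallel",
                 "unclassified")


@dataclass
class SSAssignment:
    """Per-residue H/E/C labels plus helix and strand content fractions.

    ``labels[i]`` is '-' for residues lacking phi or psi; those residues do
    not count toward either content denominator.
    """

    labels: list
    alpha: float
    beta: float


def _in(x, lo, hi):
    return lo <= x <= hi


def assign_ss(conformation, chain: int = 0) -> SSAssignment:
    """Ramachandran-box secondary-structure assignment for one chain."""
    phi = conformation.phi[chain]
    psi = conformation.psi[chain]
    n = len(phi)
    if n < 3:
        raise ValueError("secondary structure needs chains of >= 3 residues")
    labels = ["-"] * n
    for i in range(1, n - 1):  # interior residues have both phi and psi
        p, s = phi[i], psi[i]
        if _in(p, *HELIX_BOX["phi"]) and _in(s, *HELIX_BOX["psi"]):
            labels[i] = "H"
        elif _in(p, *STRAND_BOX["phi"]) and (
                _in(s, *STRAND_BOX["psi_hi"]) or _in(s, *STRAND_BOX["psi_lo"])):
            labels[i] = "E"
        else:
            labels[i] = "C"
    # demote singleton E runs
    for i in range(1, n - 1):
        if labels[i] == "E" and labels[i - 1] != "E" and labels[i + 1] != "E":
            labels[i] = "C"
    assignable = [l for l in labels if l != "-"]
    na = len(assignable)
    alpha = assignable.count("H") / na if na else 0.0
    beta = assignable.count("E") / na if na else 0.0
    return SSAssignment(labels, alpha, beta)


def ss_content(state: SystemState, per_chain=False):
    """(alpha, beta) content over all chains (or per chain)."""
    res = [assign_ss(state.conformation, c) for c in range(state.n_chains)]
    if per_chain:
        return [(r.alpha, r.beta) for r in res]
    weights = [len(s) - 2 for s in state.sequences]
    tot = sum(weights)
    alpha = sum(r.alpha * w for r, w in zip(res, weights)) / tot
    beta = sum(r.beta * w for r, w in zip(res, weights)) / tot
    return alpha, beta


def strand_segments(labels):
    """Contiguous runs of 'E' as (start, end) 0-based inclusive tuples."""
    segs, start = [], None
    for i, l in enumerate(labels + ["-"]):
        if l == "E" and start is None:
            start = i
        elif l != "E" and start is not None:
            segs.append((start, i - 1))
            start = None
    return segs


@dataclass
class ContactMap:
    """Residue-pair contact probabilities.

    ``matrix[i, j]`` for i > j holds the intra-chain probability (averaged
    over chains under the relabeling convention), and for i < j the
    inter-chain probability (symmetrized over chain assignment). The
    diagonal is zero.
    """

    matrix: np.ndarray
    cutoff: float
    min_sep: int
    n_frames_used: int
    n_frames_skipped: int = 0


def contact_map(frames, cutoff=8.0, min_sep=5, weights=None,
                box_side=None) -> ContactMap:
    """Contact probabilities from frames of per-chain CA coordinates.

    ``frames`` is a sequence; each frame is a tuple/list of (n_res, 3) CA
    coordinate arrays, one per chain (one or two chains). A contact is a
    CA-CA distance below ``cutoff`` (Å). Intra-chain pairs closer than
    ``min_sep`` in sequence are excluded; inter-chain pairs have no
    separation filter. ``weights`` are per-frame statistical weights.
    """
    frames = list(frames)
    if weights is None:
        w = np.ones(len(frames))
    else:
        w = np.asarray(weights, dtype=float)
    n = len(frames[0][0])
    intra = np.zeros((n, n))
    inter = np.zeros((n, n))
    wtot = 0.0
    skipped = 0
    for frame, wi in zip(frames, w):
        if any(np.any(~np.isfinite(ch)) for ch in frame):
            skipped += 1
            continue
        wtot += wi
        for ch in frame:
            d = np.linalg.norm(ch[:, None, :] - ch[None, :, :], axis=-1)
            intra += wi * (d < cutoff)
        if len(frame) == 2:
            delta = frame[0][:, None, :] - frame[1][None, :, :]
            if box_side:
                delta = minimal_image(delta, box_side)
            d = np.linalg.norm(delta, axis=-1)
            hit = d < cutoff
            inter += wi * (hit + hit.T) / 2.0  # symmetrize chain labels
    if wtot == 0:
        raise ValueError("no usable frames")
    n_chains = len(frames[0])
    intra /= wtot * n_chains
    inter /= wtot
    ii, jj = np.indices((n, n))
    sep_ok = np.abs(ii - jj) >= min_sep
    mat = np.where(ii > jj, intra * sep_ok, np.where(ii < jj, inter, 0.0))
    return ContactMap(mat, cutoff, min_sep, len(frames) - skipped, skipped)


def interchain_contacts(state: SystemState, cutoff=8.0):
    """Boolean (nA, nB) matrix of inter-chain CA contacts for a dimer."""
    if state.n_chains != 2:
        raise ChainCountError("dimer analysis requires two chains")
    a = state.ca_coords(0)
    b = state.ca_coords(1)
    delta = minimal_image(a[:, None, :] - b[None, :, :],
                          state.conformation.box_side)
    return np.linalg.norm(delta, axis=-1) < cutoff


def classify_dimer(state: SystemState, cutoff=8.0, min_contacts=3) -> str:
    """Label a two-chain frame by interface-strand identity and orientation.

    Each chain's interface strand is its strand segment with the most
    inter-chain CA contacts (tie-break toward the longer strand). The label
    letters record whether each interface strand is the N-proximal or
    C-proximal strand of its hairpin (sorted, so NC not CN); orientation is
    the sign of the dot product of the two interface strands' sequence-
    direction end-to-end vectors. Frames without two strand segments per
    chain, or with fewer than ``min_contacts`` interface contacts, are
    'unclassified'.
    """
    contacts = interchain_contacts(state, cutoff)
    segs, letters, vecs = [], [], []
    for c in range(2):
        ss = assign_ss(state.conformation, c)
        s = strand_segments(ss.labels)
        if len(s) < 2:
            return "unclassified"
        counts = []
        for seg in s:
            rows = slice(seg[0], seg[1] + 1)
            ncontact = (contacts[rows, :] if c == 0
                        else contacts[:, rows]).sum()
            counts.append((ncontact, seg[1] - seg[0], seg))
        counts.sort(key=lambda t: (t[0], t[1]), reverse=True)
        best = counts[0]
        if best[0] < min_contacts:
            return "unclassified"
        seg = best[2]
        # N- or C-proximal among this chain's strand segments
        order = sorted(s)
        letters.append("N" if seg == order[0] else "C")
        ca = state.ca_coords(c)
        vecs.append(ca[seg[1]] - ca[seg[0]])
        segs.append(seg)
    pair = "".join(sorted(letters, key=lambda x: x != "N"))  # NN, NC, CC
    orient = "parallel" if float(np.dot(vecs[0], vecs[1])) >= 0 \
        else "antiparallel"
    return f"{pair}-{orient}"


def turn_position(assignment: SSAssignment, contacts=None):
    """1-based inclusive residue range of the hairpin turn, or None.

    The turn is the contiguous non-E segment between the two longest
    strand segments. ``contacts`` is accepted for signature compatibility
    with contact-based refinements but is not required.
    """
    segs = strand_segments(assignment.labels)
    if len(segs) < 2:
        return None
    by_len = sorted(segs, key=lambda s: (s[1] - s[0], -s[0]), reverse=True)
    s1, s2 = sorted(by_len[:2])
    return (s1[1] + 2, s2[0])  # 0-based exclusive gap -> 1-based inclusive


def cluster_representatives(frames, rmsd_cutoff=2.5):
    """Neighbor-count (Daura-style) clustering on CA coordinates.

    ``frames``: sequence of (n_atoms, 3) arrays. Iteratively takes the
    frame with the most neighbors within ``rmsd_cutoff`` (after optimal
    superposition) as a centroid, removes the cluster, and repeats.
    Deterministic; ties break toward the lower frame index.

    Returns (centroid_indices, clusters) where clusters is a list of
    member-index lists (centroid included).
    """
    frames = [np.asarray(f, dtype=float) for f in frames]
    m = len(frames)
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d[i, j] = d[j, i] = rmsd_kabsch(frames[i], frames[j])
    alive = np.ones(m, dtype=bool)
    centroids, clusters = [], []
    while alive.any():
        neigh = (d < rmsd_cutoff) & alive[None, :] & alive[:, None]
        counts = neigh.sum(axis=1)
        counts[~alive] = -1
        c = int(np.argmax(counts))  # argmax takes first on ties
        members = sorted(np.nonzero(neigh[c])[0].tolist())
        centroids.append(c)
        clusters.append(members)
        alive[members] = False
    return centroids, clusters
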