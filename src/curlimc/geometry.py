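"""Low-level 3-D geometry: internal-to-Cartesian placement, dihedrals, RMSD.

All angles at this level are in degrees unless noted; positions are Å.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


_DEG = np.pi / 180.0


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given reference atoms A, B, C (NeRF construction).

    D is bonded to C with bond length ``bond``, bond angle B-C-D
    ``angle_deg`` and torsion A-B-C-D ``torsion_deg``.

    Hot path of the coordinate rebuild: written with scalar 3-vector
    arithmetic (numpy's generic cross/norm dominate the cost otherwise).
    """
    angle = angle_deg * _DEG
    torsion = torsion_deg * _DEG
    bcx = c[0] - b[0]
    bcy = c[1] - b[1]
    bcz = c[2] - b[2]
    inv = 1.0 / np.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx *= inv
    bcy *= inv
    bcz *= inv
    abx = b[0] - a[0]
    aby = b[1] - a[1]
    abz = b[2] - a[2]
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    nn = np.sqrt(nx * nx + ny * ny + nz * nz)
    if nn < 1e-12:
        # colinear reference frame: pick any perpendicular to bc
        nx, ny, nz = 0.0, bcz, -bcy          # bc x (1, 0, 0)
        nn = np.sqrt(ny * ny + nz * nz)
        if nn < 1e-9:
            nx, ny, nz = -bcz, 0.0, bcx      # bc x (0, 1, 0)
            nn = np.sqrt(nx * nx + nz * nz)
    inv = 1.0 / nn
    nx *= inv
    ny *= inv
    nz *= inv
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    sa = np.sin(angle)
    d0 = -bond * np.cos(angle)
    d1 = bond * sa * np.cos(torsion)
    d2 = bond * sa * np.sin(torsion)
    return np.array([c[0] + d0 * bcx + d1 * mx + d2 * nx,
                     c[1] + d0 * bcy + d1 * my + d2 * ny,
                     c[2] + d0 * bcz + d1 * mz + d2 * nz])


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180].

    Standard IUPAC sign convention (agrees with RDKit/mdtraj/biotite).
    """
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = np.rad2deg(np.arctan2(-y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def bond_angle(p0, p1, p2) -> float:
    """Bond angle p0-p1-p2 in degrees."""
    v1 = np.asarray(p0) - np.asarray(p1)
    v2 = np.asarray(p2) - np.asarray(p1)
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))


def wrap_angle(a):
    """Wrap angle(s) in degrees into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    w = -((-a + 180.0) % 360.0 - 180.0)
    return w if w.ndim else float(w)


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """3x3 rotation matrix about ``axis`` (normalized internally)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()


def superpose(mobile: np.ndarray, target: np.ndarray):
    """Optimal rigid superposition of ``mobile`` onto ``target`` (Kabsch).

    Returns ``(R, t, rmsd)`` such that ``mobile @ R.T + t`` best fits
    ``target`` in the least-squares sense.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    import warnings
    with warnings.catch_warnings():
        # collinear point sets leave the rotation under-determined; any
        # optimal rotation gives the same RMSD, which is all we need
        warnings.simplefilter("ignore", UserWarning)
        rot, rssd = Rotation.align_vectors(target - tc, mobile - mc)
    R = rot.as_matrix()
    t = tc - mc @ R.T
    rmsd = rssd / np.sqrt(len(mobile))
    return R, t, float(rmsd)


def rmsd_kabsch(x: np.ndarray, y: np.ndarray) -> float:
    """CA RMSD between two coordinate sets after optimal superposition."""
    return superpose(x, y)[2]


def minimal_image(delta: np.ndarray, box_side: float) -> np.ndarray:
    """Apply the minimal-image convention to displacement vector(s)."""
    delta = np.asarray(delta, dtype=float)
    return delta - box_side * np.round(delta / box_side)
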