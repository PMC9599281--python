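"""Backbone construction from internal coordinates.

Builds N/CA/C/O(/H) polypeptide backbones from (phi, psi) dihedral series
using standard bond lengths and angles, with trans peptide bonds
(omega = 180 deg).  Amide hydrogens are placed in the peptide plane,
1.02 Å from N and trans to the preceding carbonyl oxygen — the same
reconstruction the hydrogen-bond dictionary uses when H is absent.
"""

from __future__ import annotations

import numpy as np

# Bond lengths (Å) and angles (deg) of the idealized backbone.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.02

ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_CA_C_O = 120.8
ANGLE_H_N_CA = 119.0


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """Place atom D given A-B-C with |CD|, angle(BCD) and dihedral(ABCD)."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)

    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)

    d_local = bond * np.array(
        [
            -np.cos(angle),
            np.sin(angle) * np.cos(dihedral),
            np.sin(angle) * np.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi: np.ndarray, psi: np.ndarray, omega: float = 180.0) -> np.ndarray:
    """Backbone coordinates from dihedral series.

    Parameters
    ----------
    phi, psi : arrays of length n_residues, degrees.
        ``phi[0]`` is unused (the first residue has no preceding carbonyl)
        and ``psi[-1]`` orients the final carbonyl oxygen only.

    Returns
    -------
    ndarray, shape (n_residues, 5, 3)
        Atom axis ordered (N, CA, C, O, H), Å.  The first residue's H is
        placed along the bisector convention (it has no preceding
        carbonyl) and takes no part in i -> i+n turn patterns.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n_res = phi.size
    if psi.size != n_res:
        raise ValueError("phi and psi must have equal length")
    if n_res < 1:
        raise ValueError("need at least one residue")

    xyz = np.zeros((n_res, 5, 3))
    N, CA, C, O, H = range(5)

    # First residue in a canonical pose.
    xyz[0, N] = (0.0, 0.0, 0.0)
    xyz[0, CA] = (BOND_N_CA, 0.0, 0.0)
    ang = np.deg2rad(ANGLE_N_CA_C)
    xyz[0, C] = xyz[0, CA] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])

    for i in range(1, n_res):
        xyz[i, N] = place_atom(
            xyz[i - 1, N], xyz[i - 1, CA], xyz[i - 1, C],
            BOND_C_N, ANGLE_CA_C_N, psi[i - 1],
        )
        xyz[i, CA] = place_atom(
            xyz[i - 1, CA], xyz[i - 1, C], xyz[i, N],
            BOND_N_CA, ANGLE_C_N_CA, omega,
        )
        xyz[i, C] = place_atom(
            xyz[i - 1, C], xyz[i, N], xyz[i, CA],
            BOND_CA_C, ANGLE_N_CA_C, phi[i],
        )

    # Carbonyl oxygens: in the peptide plane, anti to the next amide N.
    for i in range(n_res):
        xyz[i, O] = place_atom(
            xyz[i, N], xyz[i, CA], xyz[i, C],
            BOND_C_O, ANGLE_CA_C_O, psi[i] + 180.0,
        )

    # Amide hydrogens: N-H parallel to the preceding C=O, trans geometry.
    for i in range(1, n_res):
        co = xyz[i - 1, C] - xyz[i - 1, O]
        xyz[i, H] = xyz[i, N] + BOND_N_H * co / np.linalg.norm(co)
    bisector = (xyz[0, CA] - xyz[0, N])
    if n_res > 1:
        bisector = bisector + (xyz[1, N] - xyz[0, N]) * 0.0
    xyz[0, H] = xyz[0, N] - BOND_N_H * bisector / np.linalg.norm(bisector)

    return xyz


def measure_dihedral(p0, p1, p2, p3) -> float:
    """Dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))
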