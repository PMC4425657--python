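"""Ideal backbone geometry and coordinate construction helpers.

The coarse-grained backbone keeps near-atomic local geometry: fixed N-Ca,
Ca-C and C-N bond lengths, fixed bond angles at N, Ca and C, and a trans
peptide bond (omega = 180 deg).  Bond angles and omega are enforced during
dynamics by pseudo-bonds whose nominal lengths are *derived* from these
constants, so generated conformations and the constraint network are always
mutually consistent.  The backbone dihedrals phi and psi remain free.
"""

from __future__ import annotations

import numpy as np

# Covalent backbone bond lengths (Angstrom).
BOND_N_CA = 1.460
BOND_CA_C = 1.510
BOND_C_N = 1.330

# Backbone bond angles (degrees).
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.0
ANGLE_C_N_CA = 122.0
OMEGA = 180.0

# Tetrahedral-like angle from backbone neighbours to the side-chain centroid.
ANGLE_N_CA_R = 110.0


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero-length vector")
    return v / n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees (IUPAC convention)."""
    b1 = np.asarray(p1, float) - np.asarray(p0, float)
    b2 = np.asarray(p2, float) - np.asarray(p1, float)
    b3 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, unit(b2))
    return float(np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2))))


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement of atom D bonded to C with angle(B,C,D) and dihedral(A,B,C,D)."""
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    theta = np.radians(angle_deg)
    tau = np.radians(torsion_deg)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(tau), -np.sin(theta) * np.sin(tau)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def side_sphere_direction(n_pos, ca_pos, c_pos, hand: int = 1) -> np.ndarray:
    """Unit vector from Ca toward the side-chain centroid.

    ``hand=+1`` gives the L-isomer arrangement: the scalar triple product
    (N-Ca) . [(C-Ca) x (R-Ca)] is positive, matching real L-amino acids.
    ``hand=-1`` gives the mirror (D) arrangement.
    """
    d1 = unit(np.asarray(n_pos, float) - np.asarray(ca_pos, float))
    d2 = unit(np.asarray(c_pos, float) - np.asarray(ca_pos, float))
    b = unit(d1 + d2)
    nrm = unit(np.cross(d1, d2))
    # choose the in-plane weight so that angle(N, Ca, R) = ANGLE_N_CA_R
    alpha = -np.cos(np.radians(ANGLE_N_CA_R)) / np.dot(b, d1)
    alpha = min(alpha, 1.0)
    beta = np.sqrt(max(0.0, 1.0 - alpha * alpha))
    return unit(-alpha * b + hand * beta * nrm)


def build_backbone(n_res: int, phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Backbone positions for ``n_res`` residues, shape (n_res, 3, 3).

    Axis 1 orders the spheres (NH, CaH, CO).  ``phi[0]`` and ``psi[-1]``
    are unused (undefined at the termini by convention) but must be present.
    """
    phi = np.asarray(phi, float)
    psi = np.asarray(psi, float)
    if len(phi) != n_res or len(psi) != n_res:
        raise ValueError("phi/psi length must equal the residue count")
    xyz = np.zeros((n_res, 3, 3))
    # first residue in a canonical pose
    xyz[0, 0] = (0.0, 0.0, 0.0)
    xyz[0, 1] = (BOND_N_CA, 0.0, 0.0)
    th = np.radians(180.0 - ANGLE_N_CA_C)
    xyz[0, 2] = xyz[0, 1] + BOND_CA_C * np.array([np.cos(th), np.sin(th), 0.0])
    for k in range(1, n_res):
        n_prev, ca_prev, c_prev = xyz[k - 1]
        n_k = place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi[k - 1])
        ca_k = place_atom(ca_prev, c_prev, n_k, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_k = place_atom(c_prev, n_k, ca_k, BOND_CA_C, ANGLE_N_CA_C, phi[k])
        xyz[k] = (n_k, ca_k, c_k)
    return xyz


def _canonical_fragment() -> np.ndarray:
    return build_backbone(2, phi=[0.0, -120.0], psi=[130.0, 0.0])


def backbone_pseudo_lengths() -> dict[str, float]:
    """Nominal pseudo-bond lengths implied by the ideal local geometry.

    These fix the three backbone bond angles and the trans peptide bond:
    ``n_co`` (N_i-C_i, angle at Ca), ``ca_n`` (Ca_i-N_{i+1}, angle at C),
    ``co_ca`` (C_i-Ca_{i+1}, angle at N) and ``ca_ca`` (Ca_i-Ca_{i+1}, omega).
    """
    f = _canonical_fragment()
    (n1, ca1, c1), (n2, ca2, c2) = f
    return {
        "n_co": float(np.linalg.norm(c1 - n1)),
        "ca_n": float(np.linalg.norm(n2 - ca1)),
        "co_ca": float(np.linalg.norm(ca2 - c1)),
        "ca_ca": float(np.linalg.norm(ca2 - ca1)),
    }


def side_pseudo_lengths(dr_ca: float) -> tuple[float, float]:
    """(|R-NH|, |R-CO|) for a side sphere at distance ``dr_ca`` from Ca."""
    f = _canonical_fragment()
    n1, ca1, c1 = f[0]
    r = ca1 + dr_ca * side_sphere_direction(n1, ca1, c1)
    return float(np.linalg.norm(r - n1)), float(np.linalg.norm(r - c1))


def triple_product_sign(n_pos, ca_pos, c_pos, r_pos) -> float:
    """Scalar triple product (N-Ca).[(C-Ca) x (R-Ca)]; > 0 for L residues."""
    ca = np.asarray(ca_pos, float)
    return float(
        np.dot(
            np.asarray(n_pos, float) - ca,
            np.cross(np.asarray(c_pos, float) - ca, np.asarray(r_pos, float) - ca),
        )
    )
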