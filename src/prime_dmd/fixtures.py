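"""Constructed reference systems for testing and demonstrations.

These builders produce small, well-controlled configurations: a two-sphere
square-well pair, extended single chains, and an idealized two-strand
parallel beta arrangement in which backbone hydrogen bonds satisfy the
directional distance constraints.  The parallel pair is found by rigid-body
optimization of the second strand against the hydrogen-bond geometry,
auxiliary cutoffs and hard-core excluded volume.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .forcefield import ForceField, default_forcefield
from .interactions import compile_interactions
from .peptide import SystemTopology, build_chain, chain_coordinates
from .residues import ROLE_CO, ROLE_NH
from .state import SystemState

#: ideal beta-strand backbone dihedrals (degrees)
BETA_PHI, BETA_PSI = -120.0, 135.0


def extended_chain_state(sequence: str, ff: ForceField | None = None,
                         box_length: float = 200.0,
                         phi: float = BETA_PHI, psi: float = BETA_PSI):
    """One chain in an extended (beta-dihedral) conformation, at rest."""
    if ff is None:
        ff = default_forcefield()
    chain = build_chain(sequence, ff.residues)
    top = SystemTopology.replicate(chain, 1)
    n = chain.n_residues
    pos = chain_coordinates(chain, np.full(n, phi), np.full(n, psi), ff.residues)
    pos = pos - pos.min(axis=0) + 0.25 * box_length
    state = SystemState(pos, np.zeros_like(pos), box_length)
    return top, state


def parallel_strand_pair(sequence: str = "AVAVAVA", ff: ForceField | None = None,
                         box_length: float = 200.0, antiparallel: bool = False,
                         margin: float = 0.08, n_bonds: int = 2):
    """Two beta strands placed so inter-chain NH-CO bonds can form.

    Strand B (the donor side) is rigidly positioned against strand A so
    that, for ``n_bonds`` adjacent donor residues i of B, the in-register
    pair (NH_i^B, CO_i^A) sits just inside the hydrogen-bond well with all
    four auxiliary distances inside the active cutoffs, without violating
    any hard core.  Two rigid ideal strands can satisfy two such bonds
    exactly; more requires per-residue relaxation and is not attempted.
    With ``antiparallel=True`` strand B runs the opposite direction (used
    to test orientation classification).

    Returns ``(top, state, inter, candidate_bonds)`` where candidate_bonds
    lists the (nh, co) sphere pairs the construction optimized.
    """
    if ff is None:
        ff = default_forcefield()
    chain = build_chain(sequence, ff.residues)
    top = SystemTopology.replicate(chain, 2)
    inter = compile_interactions(top, ff)
    n = chain.n_residues
    phi = np.full(n, BETA_PHI)
    psi = np.full(n, BETA_PSI)
    coords = chain_coordinates(chain, phi, psi, ff.residues)
    off = top.offsets[1]

    bonds = []
    first = max(1, (n - n_bonds) // 2)
    for i in range(first, min(n - 1, first + n_bonds)):
        nh = off + chain.sphere_id(i, ROLE_NH)
        co = chain.sphere_id(i, ROLE_CO)
        if (nh, co) in inter.hb_aux:
            bonds.append((nh, co))
    if not bonds:
        raise ValueError("sequence too short for a bonded strand pair")

    cut = ff.hbond_cutoffs()
    targets = []          # (sphere_a_on_A_or_global, sphere_b, max distance)
    for nh, co in bonds:
        ca_j, n_j1, ca_i, c_i1 = inter.hb_aux[(nh, co)]
        targets.append((nh, co, cut.well_diameter - margin))
        targets.append((nh, ca_j, cut.n_ca - margin))
        targets.append((nh, n_j1, cut.n_n_next - margin))
        targets.append((co, ca_i, cut.c_ca - margin))
        targets.append((co, c_i1, cut.c_c_prev - margin))

    dmin = inter.min_distance_matrix()
    base = coords.copy()
    if antiparallel:
        # no bond-geometry optimization: simply flip strand B end-for-end
        # and offset it laterally (used for orientation classification)
        flip = Rotation.from_rotvec([0.0, 0.0, np.pi]).as_matrix()
        pb = (coords - coords.mean(axis=0)) @ flip.T + coords.mean(axis=0)
        pb = pb + np.array([0.0, 5.2, 0.0])
        pos = np.vstack([base, pb])
        pos = pos - pos.min(axis=0) + 0.25 * box_length
        state = SystemState(pos, np.zeros_like(pos), box_length)
        return top, state, inter, bonds
    bcoords = coords.copy()
    bcenter = bcoords.mean(axis=0)

    na = chain.n_spheres

    def place(params):
        rot = Rotation.from_rotvec(params[:3]).as_matrix()
        return (bcoords - bcenter) @ rot.T + bcenter + params[3:]

    def loss(params):
        pb = place(params)
        pos = np.vstack([base, pb])
        val = 0.0
        for a, b, dmax in targets:
            d = np.linalg.norm(pos[a] - pos[b])
            val += max(0.0, d - dmax) ** 2
        # excluded volume between the strands
        delta = pos[:na, None, :] - pos[None, na:, :]
        d = np.sqrt(np.sum(delta ** 2, axis=-1))
        pen = np.maximum(0.0, dmin[:na, na:] + 0.05 - d)
        val += float(np.sum(pen ** 2))
        return val

    best = None
    for dy in (4.6, 4.9, 5.2, -4.6, -4.9, -5.2):
        for dz in (-0.8, 0.0, 0.8):
            for dx in (-1.0, 0.0, 1.0):
                x0 = np.array([0.0, 0.0, 0.0, dx, dy, dz])
                r = minimize(loss, x0, method="Nelder-Mead",
                             options={"maxiter": 4000, "fatol": 1e-12, "xatol": 1e-8})
                if best is None or r.fun < best.fun:
                    best = r
                if best.fun < 1e-12:
                    break
            if best.fun < 1e-12:
                break
        if best.fun < 1e-12:
            break
    if best.fun > 1e-8:
        raise RuntimeError(
            f"could not realize the idealized strand pair (residual {best.fun:.3g})")
    pos = np.vstack([base, place(best.x)])
    pos = pos - pos.min(axis=0) + 0.25 * box_length
    state = SystemState(pos, np.zeros_like(pos), box_length)
    return top, state, inter, bonds


#: two-residue turn dihedrals (degrees) producing a strand reversal
TURN_DIHEDRALS = ((60.0, -120.0), (-80.0, 0.0))


def shaped_chain_state(turn_residues=((25, 26),), sequence: str | None = None,
                       ff: ForceField | None = None, numbering_offset: int = 17,
                       box_length: float = 300.0):
    """A single chain with beta strands and turns at chosen residues.

    ``turn_residues`` lists turn regions in reported numbering; each gets
    the two-residue reversal dihedrals.  After the first turn the strand
    dihedrals are biased (-100/110) so the returning strand folds back
    toward the first one, which is what the U-shape contact criterion
    looks for.  Used to exercise turn detection and shape classification.
    """
    from .residues import AB17_42
    if sequence is None:
        sequence = AB17_42
    if ff is None:
        ff = default_forcefield()
    chain = build_chain(sequence, ff.residues, numbering_offset=numbering_offset)
    top = SystemTopology.replicate(chain, 1)
    n = chain.n_residues
    phi = np.full(n, BETA_PHI)
    psi = np.full(n, BETA_PSI)
    if turn_residues:
        first_end = max(turn_residues[0]) - numbering_offset
        phi[first_end + 1:] = -100.0
        psi[first_end + 1:] = 110.0
    for region in turn_residues:
        for m, res in enumerate(region):
            k = res - numbering_offset
            if not 0 <= k < n:
                raise ValueError(f"turn residue {res} outside the chain")
            phi[k], psi[k] = TURN_DIHEDRALS[m % 2]
    pos = chain_coordinates(chain, phi, psi, ff.residues)
    pos = pos - pos.min(axis=0) + 0.25 * box_length
    state = SystemState(pos, np.zeros_like(pos), box_length)
    return top, state


def two_sphere_well_pair(d_core: float = 3.0, d_well: float = 4.5,
                         depth: float = 1.0, masses=(1.0, 1.0),
                         separation: float = 6.0, closing_speed: float = 0.4,
                         box_length: float = 20.0):
    """A single square-well pair on a collision course."""
    from .interactions import K_WELL, make_custom_interactions
    inter = make_custom_interactions(list(masses),
                                     {(0, 1): (K_WELL, d_core, d_well, depth)})
    half = box_length / 2.0
    pos = np.array([[half - separation / 2, half, half],
                    [half + separation / 2, half, half]])
    vel = np.array([[closing_speed / 2, 0.0, 0.0], [-closing_speed / 2, 0.0, 0.0]])
    return inter, SystemState(pos, vel, box_length)
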