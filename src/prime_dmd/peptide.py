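"""Chain topology construction, random-coil generation and geometry checks.

A peptide of ``n`` residues maps to ``4n - n_gly`` spheres: three backbone
united spheres per residue (NH, CaH, CO) plus one side-chain centroid
sphere R for every residue except glycine.  Covalent bonds and the
angle/omega-fixing pseudo-bonds are hard distance windows with a fractional
tolerance; the side sphere is tied to its own backbone by one covalent bond
(Ca-R) and two pseudo-bonds (NH-R, CO-R), and kept out of the neighbouring
backbone by the squeeze distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import geometry
from .forcefield import ForceField, ResidueSpec, default_forcefield
from .residues import (
    MASS_CAH, MASS_CO, MASS_NH, ROLE_CA, ROLE_CO, ROLE_NH, ROLE_R,
    has_side_sphere, validate_sequence,
)
from .state import SystemState


class PlacementError(RuntimeError):
    """Raised when a random-coil configuration cannot be placed."""


@dataclass
class ChainTopology:
    """Sphere/bond graph of a single peptide chain."""

    sequence: str
    role: np.ndarray          # int8, sphere role
    residue: np.ndarray       # int32, 0-based residue index per sphere
    mass: np.ndarray          # float64
    bonds: list               # (i, j, nominal length): covalent + pseudo-bonds
    squeeze: list             # (i, j, minimum distance)
    numbering_offset: int = 1  # reported number of the first residue

    @property
    def n_spheres(self) -> int:
        return len(self.role)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def sphere_id(self, res: int, role: int) -> int:
        """Global (within-chain) sphere id, or -1 if absent (glycine R)."""
        return self._index.get((res, role), -1)

    def __post_init__(self):
        self._index = {
            (int(r), int(ro)): k
            for k, (r, ro) in enumerate(zip(self.residue, self.role))
        }

    def backbone_ids(self, res: int) -> tuple[int, int, int]:
        return (self.sphere_id(res, ROLE_NH), self.sphere_id(res, ROLE_CA),
                self.sphere_id(res, ROLE_CO))


def build_chain(sequence: str, residue_table: dict[str, ResidueSpec] | None = None,
                numbering_offset: int = 1) -> ChainTopology:
    """Build the 4-sphere-per-residue topology for ``sequence``."""
    seq = validate_sequence(sequence)
    if residue_table is None:
        residue_table = _default_residue_table()
    role, residue, mass = [], [], []
    for k, aa in enumerate(seq):
        for ro, m in ((ROLE_NH, MASS_NH), (ROLE_CA, MASS_CAH), (ROLE_CO, MASS_CO)):
            role.append(ro)
            residue.append(k)
            mass.append(m)
        if has_side_sphere(aa):
            role.append(ROLE_R)
            residue.append(k)
            mass.append(residue_table[aa].side_mass)
    top = ChainTopology(
        sequence=seq,
        role=np.array(role, dtype=np.int8),
        residue=np.array(residue, dtype=np.int32),
        mass=np.array(mass, dtype=np.float64),
        bonds=[], squeeze=[],
        numbering_offset=numbering_offset,
    )
    pl = geometry.backbone_pseudo_lengths()
    bonds, squeeze = [], []
    for k, aa in enumerate(seq):
        nh, ca, co = top.backbone_ids(k)
        bonds.append((nh, ca, geometry.BOND_N_CA))
        bonds.append((ca, co, geometry.BOND_CA_C))
        bonds.append((nh, co, pl["n_co"]))
        if k + 1 < len(seq):
            nh1, ca1, _ = top.backbone_ids(k + 1)
            bonds.append((co, nh1, geometry.BOND_C_N))
            bonds.append((ca, nh1, pl["ca_n"]))
            bonds.append((co, ca1, pl["co_ca"]))
            bonds.append((ca, ca1, pl["ca_ca"]))
        if has_side_sphere(aa):
            spec = residue_table[aa]
            r = top.sphere_id(k, ROLE_R)
            bonds.append((ca, r, spec.dr_ca))
            bonds.append((nh, r, spec.dr_nh))
            bonds.append((co, r, spec.dr_co))
            if k - 1 >= 0:
                _, ca_p, co_p = top.backbone_ids(k - 1)
                squeeze.append((r, ca_p, spec.sq_ca_prev))
                squeeze.append((r, co_p, spec.sq_co_prev))
            if k - 2 >= 0:
                co_pp = top.backbone_ids(k - 2)[2]
                squeeze.append((r, co_pp, spec.sq_co_prev2))
            if k + 1 < len(seq):
                nh_n, ca_n, _ = top.backbone_ids(k + 1)
                squeeze.append((r, nh_n, spec.sq_nh_next))
                squeeze.append((r, ca_n, spec.sq_ca_next))
    top.bonds = bonds
    top.squeeze = squeeze
    return top


@lru_cache(maxsize=1)
def _default_residue_table():
    return default_forcefield().residues


@dataclass
class SystemTopology:
    """Topology of the full multi-chain system (identical chains)."""

    chains: list

    def __post_init__(self):
        offsets, n = [], 0
        for c in self.chains:
            offsets.append(n)
            n += c.n_spheres
        self.offsets = offsets
        self.n_spheres = n
        self.role = np.concatenate([c.role for c in self.chains])
        self.residue = np.concatenate([c.residue for c in self.chains])
        self.chain_id = np.concatenate([
            np.full(c.n_spheres, ci, dtype=np.int32)
            for ci, c in enumerate(self.chains)
        ])
        self.mass = np.concatenate([c.mass for c in self.chains])
        self.resletter = np.concatenate([
            np.array([c.sequence[r] for r in c.residue]) for c in self.chains
        ])

    @classmethod
    def replicate(cls, chain: ChainTopology, n_chains: int) -> "SystemTopology":
        if n_chains < 1:
            raise ValueError("need at least one chain")
        return cls(chains=[chain] * n_chains)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def sphere_id(self, chain: int, res: int, role: int) -> int:
        local = self.chains[chain].sphere_id(res, role)
        return -1 if local < 0 else self.offsets[chain] + local

    def bonds_global(self):
        for ci, c in enumerate(self.chains):
            off = self.offsets[ci]
            for i, j, d in c.bonds:
                yield off + i, off + j, d

    def squeeze_global(self):
        for ci, c in enumerate(self.chains):
            off = self.offsets[ci]
            for i, j, d in c.squeeze:
                yield off + i, off + j, d


# ---------------------------------------------------------------------------
# conformation construction
# ---------------------------------------------------------------------------

def chain_coordinates(chain: ChainTopology, phi: np.ndarray, psi: np.ndarray,
                      residue_table: dict[str, ResidueSpec] | None = None,
                      hand: int = 1) -> np.ndarray:
    """Cartesian coordinates (n_spheres, 3) for given backbone dihedrals."""
    if residue_table is None:
        residue_table = _default_residue_table()
    bb = geometry.build_backbone(chain.n_residues, phi, psi)
    pos = np.zeros((chain.n_spheres, 3))
    for k, aa in enumerate(chain.sequence):
        nh, ca, co = chain.backbone_ids(k)
        pos[nh], pos[ca], pos[co] = bb[k]
        if has_side_sphere(aa):
            r = chain.sphere_id(k, ROLE_R)
            direction = geometry.side_sphere_direction(bb[k, 0], bb[k, 1], bb[k, 2], hand)
            pos[r] = bb[k, 1] + residue_table[aa].dr_ca * direction
    return pos


def _chain_min_distances(chain: ChainTopology, ff: ForceField) -> np.ndarray:
    """Required minimum intra-chain distance for every sphere pair.

    Bonded pairs get their lower window edge; squeeze pairs their squeeze
    distance; all other pairs the hard-core contact distance, scaled by the
    local-reduction factor when the spheres are within three bond-graph
    edges of each other.
    """
    from .interactions import hardcore_matrix  # local import: avoids cycle
    return hardcore_matrix(chain, ff)


def grow_random_coil(chain: ChainTopology, ff: ForceField, rng: np.random.Generator,
                     max_residue_attempts: int = 60,
                     failure_budget: list | None = None) -> np.ndarray:
    """Grow one self-avoiding random coil by rejection-sampled dihedrals."""
    dmin = _chain_min_distances(chain, ff)
    n = chain.n_residues
    while True:
        phi = np.zeros(n)
        psi = np.zeros(n)
        pos = None
        ok = True
        for k in range(n):
            placed = False
            for _ in range(max_residue_attempts):
                phi[k] = rng.uniform(-180.0, 180.0)
                if k > 0:
                    psi[k - 1] = rng.uniform(-180.0, 180.0)
                trial = chain_coordinates(chain, phi, psi, residue_table=ff.residues)
                new_ids = [s for s in range(chain.n_spheres) if chain.residue[s] == k]
                old_ids = [s for s in range(chain.n_spheres) if chain.residue[s] < k]
                if _clash_free(trial, new_ids, old_ids, dmin):
                    pos = trial
                    placed = True
                    break
                if failure_budget is not None:
                    failure_budget[0] -= 1
                    if failure_budget[0] <= 0:
                        raise PlacementError(
                            "random-coil growth exhausted its failure budget "
                            f"(steric clash at residue {k})")
            if not placed:
                ok = False
                break
        if ok:
            return pos


def _clash_free(pos, new_ids, old_ids, dmin) -> bool:
    if not old_ids:
        return True
    for s in new_ids:
        d = np.linalg.norm(pos[old_ids] - pos[s], axis=1)
        if np.any(d < dmin[s, old_ids] - 1e-9):
            return False
    return True


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def maxwell_boltzmann_velocities(mass: np.ndarray, temperature: float,
                                 rng: np.random.Generator,
                                 zero_momentum: bool = True) -> np.ndarray:
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    v = rng.normal(size=(len(mass), 3)) * np.sqrt(temperature / mass)[:, None]
    if zero_momentum:
        p = (mass[:, None] * v).sum(axis=0)
        v -= p / mass.sum()
    return v


def generate_initial_configuration(top: SystemTopology, box_length: float,
                                   temperature: float, rng: np.random.Generator,
                                   ff: ForceField | None = None,
                                   max_failures: int = 10_000,
                                   max_chain_placements: int = 2_000,
                                   clearance: float | None = None) -> SystemState:
    """Separated denatured random coils with no inter-peptide contacts.

    Every chain is grown as a self-avoiding random coil, then dropped into
    the box with a random orientation and position such that the smallest
    inter-chain sphere distance exceeds the largest interaction diameter
    (plus a small margin), so no two chains interact at time zero.
    Velocities are Maxwell-Boltzmann at ``temperature``, with zero total
    momentum.  Deterministic for a fixed generator state.
    """
    if ff is None:
        ff = default_forcefield()
    if clearance is None:
        clearance = ff.max_interaction_diameter() + 0.5
    L = float(box_length)
    positions = np.zeros((top.n_spheres, 3))
    placed: list[np.ndarray] = []
    budget = [max_failures]
    for ci, chain in enumerate(top.chains):
        coil = grow_random_coil(chain, ff, rng, failure_budget=budget)
        coil = coil - coil.mean(axis=0)
        for attempt in range(max_chain_placements):
            rot = random_rotation(rng)
            shift = rng.uniform(0.0, L, size=3)
            trial = coil @ rot.T + shift
            if _separated(trial, placed, L, clearance):
                placed.append(trial)
                break
        else:
            raise PlacementError(
                f"could not place chain {ci} with inter-chain clearance "
                f"{clearance:.2f} A in a box of {L:.1f} A")
    for ci, chunk in enumerate(placed):
        off = top.offsets[ci]
        positions[off:off + len(chunk)] = chunk
    vel = maxwell_boltzmann_velocities(top.mass, temperature, rng)
    state = SystemState(positions, vel, L)
    state.wrap()
    return state


def _separated(trial, placed, L, clearance) -> bool:
    for other in placed:
        delta = trial[:, None, :] - other[None, :, :]
        delta -= L * np.round(delta / L)
        if np.min(np.sum(delta ** 2, axis=-1)) < clearance ** 2:
            return False
    return True


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def chirality_sign(state: SystemState, top: SystemTopology, chain: int, res: int) -> str:
    """Handedness of one residue: 'L', 'D', or 'achiral' (glycine)."""
    r = top.sphere_id(chain, res, ROLE_R)
    if r < 0:
        return "achiral"
    nh, ca, co = (top.sphere_id(chain, res, ro) for ro in (ROLE_NH, ROLE_CA, ROLE_CO))
    p = state.positions
    mi = state.minimum_image
    t = geometry.triple_product_sign(
        p[ca] + mi(p[nh] - p[ca]), p[ca], p[ca] + mi(p[co] - p[ca]),
        p[ca] + mi(p[r] - p[ca]))
    return "L" if t > 0 else "D"


@dataclass
class GeometryViolation:
    kind: str          # 'bond', 'squeeze', 'core', 'chirality'
    spheres: tuple
    value: float
    limit: tuple


def validate_geometry(state: SystemState, top: SystemTopology,
                      ff: ForceField | None = None,
                      tol: float = 1e-7) -> list:
    """Report every bond-window, squeeze, hard-core or chirality violation."""
    if ff is None:
        ff = default_forcefield()
    from .interactions import compile_interactions
    inter = compile_interactions(top, ff)
    report = []
    pos = state.positions
    n = top.n_spheres
    # bonds
    for i, j, d0 in top.bonds_global():
        d = state.distance(i, j)
        lo, hi = d0 * (1 - ff.bond_tolerance), d0 * (1 + ff.bond_tolerance)
        if d < lo - tol or d > hi + tol:
            report.append(GeometryViolation("bond", (i, j), d, (lo, hi)))
    # non-bonded minimum distances (includes squeeze values)
    dmin = inter.min_distance_matrix()
    for i in range(n):
        d = np.linalg.norm(state.minimum_image(pos[i + 1:] - pos[i]), axis=1)
        bad = np.nonzero(d < dmin[i, i + 1:] - tol)[0]
        for b in bad:
            j = i + 1 + int(b)
            kind = "squeeze" if inter.is_squeeze(i, j) else "core"
            report.append(GeometryViolation(kind, (i, j), float(d[b]),
                                            (float(dmin[i, j]), np.inf)))
    # chirality
    for ci, chain in enumerate(top.chains):
        for k in range(chain.n_residues):
            if chirality_sign(state, top, ci, k) == "D":
                report.append(GeometryViolation("chirality", (ci, k), -1.0, (0.0, np.inf)))
    return report


def concentration_mM(n_chains: int, box_length: float) -> float:
    """Peptide concentration implied by the chain count and box edge (mM)."""
    avogadro = 6.02214076e23
    litres = (box_length ** 3) * 1e-27
    return n_chains / avogadro / litres * 1e3
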