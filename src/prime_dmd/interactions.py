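"""Compile a topology + force field into flat pair-interaction tables.

Every unordered sphere pair is assigned one discontinuous radial potential:

* ``BOND``   - covalent or pseudo-bond: infinite walls at ``nominal*(1 +/- tol)``
* ``HARD``   - pure hard core (default for non-bonded pairs; squeeze pairs
  use their tabulated minimum distance, and pairs within three bond-graph
  edges get the local reduction factor on the contact distance)
* ``DWELL``  - side-chain double well (deep inner shell, shallow outer shell)
* ``WELL``   - plain single square well (used by constructed test systems)
* ``HBCAND`` - NH donor / CO acceptor pair that may form a hydrogen bond at
  the hydrogen-bond well diameter, subject to the directional constraints

The result is a dense ``n x n`` int16 matrix of row indices into a small
parameter table, which is what the event-prediction kernels operate on.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .forcefield import ForceField, LOCAL_REDUCTION
from .residues import ROLE_CA, ROLE_CO, ROLE_NH, ROLE_R

K_NONE, K_HARD, K_BOND, K_DWELL, K_HBCAND, K_WELL = 0, 1, 2, 3, 4, 5

#: intra-chain donor/acceptor residue separations below this cannot H-bond
MIN_HB_SEQUENCE_SEPARATION = 3

#: bond-graph separation (edges) at or below which hard cores are reduced
LOCAL_GRAPH_DISTANCE = 3


@dataclass
class Interactions:
    """Flat interaction tables for one simulated system."""

    ptype: np.ndarray                    # (n, n) int16 row index
    rows: np.ndarray                     # (k, 5) float64 parameters
    kinds: np.ndarray                    # (k,) int8 kind codes
    mass: np.ndarray                     # (n,) float64
    hb_aux: dict = field(default_factory=dict)   # (nh, co) -> 4 aux sphere ids
    hb_cutoffs: tuple = ()               # active auxiliary cutoffs (4 floats)
    hb_diameter: float = 0.0
    squeeze_pairs: set = field(default_factory=set)
    bond_pairs: dict = field(default_factory=dict)  # (i, j) -> nominal length

    @property
    def n_spheres(self) -> int:
        return len(self.mass)

    def kind(self, i: int, j: int) -> int:
        return int(self.kinds[self.ptype[i, j]])

    def row(self, i: int, j: int) -> np.ndarray:
        return self.rows[self.ptype[i, j]]

    def is_squeeze(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.squeeze_pairs

    def max_range(self) -> float:
        out = 0.0
        for k, row in zip(self.kinds, self.rows):
            if k == K_HARD:
                out = max(out, row[0])
            elif k == K_BOND:
                out = max(out, row[1])
            elif k == K_DWELL:
                out = max(out, row[2])
            elif k in (K_HBCAND, K_WELL):
                out = max(out, row[1])
        return out

    def min_distance_matrix(self) -> np.ndarray:
        """Required minimum separation per pair (0 for bonded pairs)."""
        lower = np.zeros(len(self.rows))
        for r, (k, row) in enumerate(zip(self.kinds, self.rows)):
            lower[r] = row[0] if k in (K_HARD, K_DWELL, K_HBCAND, K_WELL) else 0.0
        return lower[self.ptype]


class _RowTable:
    def __init__(self):
        self._idx = {}
        self.rows = []
        self.kinds = []
        # row 0: no interaction
        self.add(K_NONE, (0.0, 0.0, 0.0, 0.0, 0.0))

    def add(self, kind: int, params) -> int:
        p = tuple(float(x) for x in params) + (0.0,) * (5 - len(params))
        key = (kind, p)
        if key not in self._idx:
            self._idx[key] = len(self.rows)
            self.rows.append(p)
            self.kinds.append(kind)
        return self._idx[key]

    def arrays(self):
        return (np.array(self.rows, dtype=np.float64),
                np.array(self.kinds, dtype=np.int8))


def _graph_distances(chain, cap: int = LOCAL_GRAPH_DISTANCE):
    """Bond-graph distance (edges, covalent + pseudo) up to ``cap``."""
    n = chain.n_spheres
    adj = [[] for _ in range(n)]
    for i, j, _ in chain.bonds:
        adj[i].append(j)
        adj[j].append(i)
    dist = {}
    for s in range(n):
        dq = deque([(s, 0)])
        seen = {s}
        while dq:
            u, d = dq.popleft()
            if d >= cap:
                continue
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    dist[(min(s, v), max(s, v))] = d + 1
                    dq.append((v, d + 1))
    return dist


def _sigma(top_or_chain, ff: ForceField, role, letter) -> float:
    if role == ROLE_R:
        return ff.residue(letter).sigma
    return ff.backbone_sigma[{ROLE_NH: "NH", ROLE_CA: "CaH", ROLE_CO: "CO"}[role]]


def hardcore_matrix(chain, ff: ForceField) -> np.ndarray:
    """Single-chain minimum-distance matrix used during coil growth."""
    top = _SingleChainView(chain)
    inter = compile_interactions(top, ff)
    return inter.min_distance_matrix()


class _SingleChainView:
    """Duck-typed single-chain stand-in for SystemTopology."""

    def __init__(self, chain):
        self.chains = [chain]
        self.offsets = [0]
        self.n_spheres = chain.n_spheres
        self.role = chain.role
        self.residue = chain.residue
        self.chain_id = np.zeros(chain.n_spheres, dtype=np.int32)
        self.mass = chain.mass
        self.resletter = np.array([chain.sequence[r] for r in chain.residue])

    @property
    def n_chains(self):
        return 1

    def sphere_id(self, chain, res, role):
        return self.chains[0].sphere_id(res, role)

    def bonds_global(self):
        yield from self.chains[0].bonds

    def squeeze_global(self):
        yield from self.chains[0].squeeze


def compile_interactions(top, ff: ForceField) -> Interactions:
    n = top.n_spheres
    table = _RowTable()
    ptype = np.zeros((n, n), dtype=np.int16)
    cut = ff.hbond_cutoffs()

    bond_pairs = {}
    for i, j, d0 in top.bonds_global():
        key = (min(i, j), max(i, j))
        bond_pairs[key] = d0
    squeeze = {}
    for i, j, d in top.squeeze_global():
        squeeze[(min(i, j), max(i, j))] = d

    graph = {}
    for ci, chain in enumerate(top.chains):
        off = top.offsets[ci]
        for (a, b), d in _graph_distances(chain).items():
            graph[(off + a, off + b)] = d

    hb_aux = {}
    role = top.role
    letter = top.resletter
    tol = ff.bond_tolerance

    for i in range(n):
        for j in range(i + 1, n):
            key = (i, j)
            if key in bond_pairs:
                d0 = bond_pairs[key]
                r = table.add(K_BOND, (d0 * (1 - tol), d0 * (1 + tol)))
            elif key in squeeze:
                r = table.add(K_HARD, (squeeze[key],))
            else:
                contact = 0.5 * (_sigma(top, ff, role[i], letter[i])
                                 + _sigma(top, ff, role[j], letter[j]))
                local = graph.get(key, 99) <= LOCAL_GRAPH_DISTANCE
                if local:
                    r = table.add(K_HARD, (LOCAL_REDUCTION * contact,))
                elif role[i] == ROLE_R and role[j] == ROLE_R:
                    dw = ff.pair_potential(letter[i], letter[j])
                    if dw.e_base != 0.0:
                        r = table.add(K_DWELL, (dw.d_core, dw.d_inner, dw.d_outer,
                                                dw.e_inner, dw.e_outer))
                    else:
                        r = table.add(K_HARD, (dw.d_core,))
                elif {int(role[i]), int(role[j])} == {ROLE_NH, ROLE_CO}:
                    nh, co = (i, j) if role[i] == ROLE_NH else (j, i)
                    aux = _hb_aux_ids(top, nh, co)
                    if aux is not None:
                        r = table.add(K_HBCAND, (contact, cut.well_diameter))
                        hb_aux[(nh, co)] = aux
                    else:
                        r = table.add(K_HARD, (contact,))
                else:
                    r = table.add(K_HARD, (contact,))
            ptype[i, j] = r
            ptype[j, i] = r

    rows, kinds = table.arrays()
    return Interactions(
        ptype=ptype, rows=rows, kinds=kinds, mass=np.asarray(top.mass, float),
        hb_aux=hb_aux, hb_cutoffs=cut.as_tuple(), hb_diameter=cut.well_diameter,
        squeeze_pairs=set(squeeze), bond_pairs=bond_pairs,
    )


def _hb_aux_ids(top, nh: int, co: int):
    """Auxiliary sphere ids (Ca_j, N_{j+1}, Ca_i, C_{i-1}) or None.

    Donor residue i carries the NH sphere, acceptor residue j the CO
    sphere.  Pairs too close along the same chain, or lacking one of the
    auxiliary spheres (chain termini), can never form a hydrogen bond.
    """
    ci, cj = int(top.chain_id[nh]), int(top.chain_id[co])
    ri, rj = int(top.residue[nh]), int(top.residue[co])
    if ci == cj and abs(ri - rj) < MIN_HB_SEQUENCE_SEPARATION:
        return None
    ca_j = top.sphere_id(cj, rj, ROLE_CA)
    n_j1 = top.sphere_id(cj, rj + 1, ROLE_NH) if rj + 1 < top.chains[cj].n_residues else -1
    ca_i = top.sphere_id(ci, ri, ROLE_CA)
    c_i1 = top.sphere_id(ci, ri - 1, ROLE_CO) if ri - 1 >= 0 else -1
    ids = (ca_j, n_j1, ca_i, c_i1)
    if any(s < 0 for s in ids):
        return None
    return ids


def make_custom_interactions(mass, pairs) -> Interactions:
    """Build interactions for a small ad-hoc system (testing/fixtures).

    ``pairs`` maps ``(i, j)`` to a tuple ``(kind, params...)`` using the
    module kind codes; unlisted pairs do not interact.
    """
    mass = np.asarray(mass, float)
    n = len(mass)
    table = _RowTable()
    ptype = np.zeros((n, n), dtype=np.int16)
    bond_pairs = {}
    for (i, j), spec in pairs.items():
        kind, params = spec[0], spec[1:]
        r = table.add(kind, params)
        ptype[i, j] = ptype[j, i] = r
        if kind == K_BOND:
            bond_pairs[(min(i, j), max(i, j))] = 0.5 * (params[0] + params[1])
    rows, kinds = table.arrays()
    return Interactions(ptype=ptype, rows=rows, kinds=kinds, mass=mass,
                        bond_pairs=bond_pairs)
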