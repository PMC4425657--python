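"""Directional backbone hydrogen bonding.

An NH donor and a CO acceptor associate through a square well at the
hydrogen-bond diameter.  Formation is gated, at the instant the pair
crosses the well surface, by four auxiliary distance constraints between
neighbouring backbone spheres (N_i-Ca_j, N_i-N_{j+1}, C_j-Ca_i, C_j-C_{i-1});
the two shipped cutoff sets differ only in these four distances, and the
tighter "parallel preference" set biases newly formed bonds toward parallel
in-register beta-sheet geometry.  While a bond is active the four auxiliary
pairs are confined below their cutoffs by hard constraint walls, which keep
the bond geometry directional until the bond breaks.
"""

from __future__ import annotations

import numpy as np

from .residues import ROLE_CA

#: width of the per-sphere auxiliary-constraint tables
_AUX_WIDTH = 8


class HBondRegistry:
    """Bookkeeping of active NH-CO bonds and their auxiliary constraints.

    Each NH and each CO sphere participates in at most one bond; the
    forward and inverse maps are kept consistent by construction.
    """

    def __init__(self, n_spheres: int):
        self.partner = np.full(n_spheres, -1, dtype=np.int64)
        self.bonds: dict[tuple, float] = {}      # (nh, co) -> formation time
        self.aux_cnt = np.zeros(n_spheres, dtype=np.int64)
        self.aux_j = np.full((n_spheres, _AUX_WIDTH), -1, dtype=np.int64)
        self.aux_d = np.zeros((n_spheres, _AUX_WIDTH), dtype=np.float64)
        self.aux_owner = np.full((n_spheres, _AUX_WIDTH), -1, dtype=np.int64)
        self._aux_pairs: dict[tuple, list] = {}  # (nh, co) -> [(a, b, cutoff) x 4]

    def __len__(self) -> int:
        return len(self.bonds)

    def is_free(self, sphere: int) -> bool:
        return self.partner[sphere] < 0

    def add(self, nh: int, co: int, time: float, aux_pairs) -> None:
        if not (self.is_free(nh) and self.is_free(co)):
            raise RuntimeError(f"bond ({nh}, {co}): partner already bonded")
        self.partner[nh] = co
        self.partner[co] = nh
        self.bonds[(nh, co)] = time
        self._aux_pairs[(nh, co)] = list(aux_pairs)
        self._rebuild_aux()

    def remove(self, nh: int, co: int) -> None:
        if self.partner[nh] != co:
            raise RuntimeError(f"bond ({nh}, {co}) not registered")
        self.partner[nh] = -1
        self.partner[co] = -1
        del self.bonds[(nh, co)]
        del self._aux_pairs[(nh, co)]
        self._rebuild_aux()

    def aux_spheres(self, nh: int, co: int) -> list:
        return [a for pair in self._aux_pairs[(nh, co)] for a in pair[:2]]

    def _rebuild_aux(self) -> None:
        self.aux_cnt[:] = 0
        self.aux_j[:] = -1
        self.aux_d[:] = 0.0
        self.aux_owner[:] = -1
        for (nh, _co), pairs in self._aux_pairs.items():
            for a, b, d in pairs:
                for s, o in ((a, b), (b, a)):
                    k = self.aux_cnt[s]
                    if k >= _AUX_WIDTH:
                        raise RuntimeError("auxiliary constraint table overflow")
                    self.aux_j[s, k] = o
                    self.aux_d[s, k] = d
                    self.aux_owner[s, k] = nh
                    self.aux_cnt[s] = k + 1

    def check_consistent(self) -> None:
        for (nh, co) in self.bonds:
            assert self.partner[nh] == co and self.partner[co] == nh
        n_bonded = int(np.count_nonzero(self.partner >= 0))
        assert n_bonded == 2 * len(self.bonds)
        assert set(self._aux_pairs) == set(self.bonds)


def aux_constraint_pairs(inter, nh: int, co: int):
    """The four (sphere, sphere, cutoff) auxiliary windows of one bond."""
    ca_j, n_j1, ca_i, c_i1 = inter.hb_aux[(nh, co)]
    c = inter.hb_cutoffs
    return [(nh, ca_j, c[0]), (nh, n_j1, c[1]), (co, ca_i, c[2]), (co, c_i1, c[3])]


_CONSTRAINT_NAMES = ("N_i-Ca_j", "N_i-N_j+1", "C_j-Ca_i", "C_j-C_i-1")


def can_form(state, inter, registry: HBondRegistry, nh: int, co: int):
    """Whether an NH-CO pair at the well surface may bond right now.

    Returns ``(decision, reason)``; on refusal the reason names the first
    failing requirement (occupied partner or the violated constraint).
    """
    if (nh, co) not in inter.hb_aux:
        raise ValueError(f"({nh}, {co}) is not a donor/acceptor candidate pair")
    if not registry.is_free(nh):
        return False, "donor NH already bonded"
    if not registry.is_free(co):
        return False, "acceptor CO already bonded"
    for name, (a, b, cutoff) in zip(_CONSTRAINT_NAMES, aux_constraint_pairs(inter, nh, co)):
        if state.distance(a, b) > cutoff:
            return False, f"{name} exceeds {cutoff:.2f} A"
    return True, None


def classify_bond_orientation(state, top, bond: tuple) -> str | None:
    """'parallel' or 'antiparallel' strand orientation of one bond.

    Compares the local backbone directions Ca_{k-1} -> Ca_{k+1} at the donor
    and acceptor residues; terminal residues lack a neighbour and are
    unclassifiable (returns None).
    """
    nh, co = bond
    out = []
    for s in (nh, co):
        ci, ri = int(top.chain_id[s]), int(top.residue[s])
        prev_ca = top.sphere_id(ci, ri - 1, ROLE_CA) if ri - 1 >= 0 else -1
        next_ca = (top.sphere_id(ci, ri + 1, ROLE_CA)
                   if ri + 1 < top.chains[ci].n_residues else -1)
        if prev_ca < 0 or next_ca < 0:
            return None
        d = state.minimum_image(state.positions[next_ca] - state.positions[prev_ca])
        out.append(d)
    return "parallel" if float(np.dot(out[0], out[1])) > 0 else "antiparallel"
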