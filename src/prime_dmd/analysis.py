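"""Trajectory statistics for coarse-grained aggregation runs.

Implements the observables used to characterize fibril formation:

* backbone dihedrals and a dihedral + hydrogen-bond-ladder secondary
  structure assignment (strand / helix / coil-turn);
* per-residue strand-content profiles over reduced-time windows;
* solvent-accessible surface area on the 4-sphere geometry;
* the max-population statistic P_max of the total-interaction-energy
  series and its free-energy-like transform -k_B T* log(P_max);
* K-D salt-bridge counts (intra- vs inter-chain);
* qualitative chain-shape classes (U, S, triangular, disordered).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry
from .forcefield import ForceField
from .residues import ROLE_CA, ROLE_CO, ROLE_NH, ROLE_R
from .state import SystemState

# STRIDE-like dihedral regions (degrees)
BETA_PHI_RANGE = (-180.0, -45.0)
BETA_PSI_RANGES = ((45.0, 180.0), (-180.0, -150.0))
ALPHA_PHI_RANGE = (-90.0, -30.0)
ALPHA_PSI_RANGE = (-77.0, -17.0)

LABEL_STRAND, LABEL_HELIX, LABEL_COIL = "E", "H", "C"


@dataclass
class EnergySeries:
    """Total interaction energy against reduced time."""

    tstar: np.ndarray
    energy: np.ndarray
    temperature: np.ndarray | None = None

    def __post_init__(self):
        self.tstar = np.asarray(self.tstar, float)
        self.energy = np.asarray(self.energy, float)
        if self.tstar.shape != self.energy.shape:
            raise ValueError("tstar and energy must have equal length")
        if np.any(np.diff(self.tstar) <= 0):
            raise ValueError("tstar must be strictly increasing")
        if self.temperature is not None:
            self.temperature = np.asarray(self.temperature, float)


@dataclass
class PmaxWindow:
    t_lo: float
    t_hi: float
    e_max: float
    p_max: float
    free_energy: float
    n_samples: int


def unwrap_chain(state: SystemState, top, chain: int) -> np.ndarray:
    """Chain coordinates reconstructed continuously across the periodic box.

    Consecutive sphere indices along a chain are always within bonded
    range, far below half the box, so walking the chain and accumulating
    minimum-image steps recovers an unbroken conformation.
    """
    off = top.offsets[chain]
    n = top.chains[chain].n_spheres
    pos = state.positions
    out = np.zeros((n, 3))
    out[0] = pos[off]
    for k in range(1, n):
        out[k] = out[k - 1] + state.minimum_image(pos[off + k] - pos[off + k - 1])
    return out


def phi_psi(state: SystemState, top, chain: int):
    """Backbone dihedrals (phi, psi) in degrees; NaN at the termini."""
    ct = top.chains[chain]
    coords = unwrap_chain(state, top, chain)
    n = ct.n_residues
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    for k in range(n):
        nh, ca, co = ct.backbone_ids(k)
        if k > 0:
            co_prev = ct.backbone_ids(k - 1)[2]
            phi[k] = geometry.dihedral(coords[co_prev], coords[nh],
                                       coords[ca], coords[co])
        if k + 1 < n:
            nh_next = ct.backbone_ids(k + 1)[0]
            psi[k] = geometry.dihedral(coords[nh], coords[ca],
                                       coords[co], coords[nh_next])
    return phi, psi


def _in_beta(phi: float, psi: float) -> bool:
    if np.isnan(phi) or np.isnan(psi):
        return False
    if not BETA_PHI_RANGE[0] <= phi <= BETA_PHI_RANGE[1]:
        return False
    return any(lo <= psi <= hi for lo, hi in BETA_PSI_RANGES)


def _in_alpha(phi: float, psi: float) -> bool:
    if np.isnan(phi) or np.isnan(psi):
        return False
    return (ALPHA_PHI_RANGE[0] <= phi <= ALPHA_PHI_RANGE[1]
            and ALPHA_PSI_RANGE[0] <= psi <= ALPHA_PSI_RANGE[1])


def _residue_partners(top, hbonds):
    """Map (chain, residue) -> set of bonded (chain, residue) partners."""
    partners: dict[tuple, set] = {}
    for bond in hbonds:
        nh, co = int(bond[0]), int(bond[1])
        a = (int(top.chain_id[nh]), int(top.residue[nh]))
        b = (int(top.chain_id[co]), int(top.residue[co]))
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)
    return partners


def assign_secondary_structure(state: SystemState, top, hbonds) -> np.ndarray:
    """Per-residue labels ('E' strand, 'H' helix, 'C' coil/turn).

    A residue is a strand when its dihedrals fall in the beta region *and*
    it belongs to a hydrogen-bond ladder: itself and an adjacent residue
    both bonded to near-consecutive residues of the same partner strand
    (inter-chain, or intra-chain at least three residues away).  A helix
    requires at least four consecutive alpha-region residues supported by
    an intra-chain bond within the run.  Everything else, including the
    termini, is coil/turn.
    """
    partners = _residue_partners(top, hbonds)
    labels = []
    for ci, ct in enumerate(top.chains):
        n = ct.n_residues
        phi, psi = phi_psi(state, top, ci)
        beta = np.array([_in_beta(phi[k], psi[k]) for k in range(n)])
        alpha = np.array([_in_alpha(phi[k], psi[k]) for k in range(n)])
        ladder = np.zeros(n, dtype=bool)
        for k in range(n - 1):
            p1 = partners.get((ci, k), set())
            p2 = partners.get((ci, k + 1), set())
            for (c1, r1) in p1:
                if c1 == ci and abs(r1 - k) < 3:
                    continue
                for (c2, r2) in p2:
                    if c2 == c1 and abs(r2 - r1) <= 2 and not (c2 == ci and abs(r2 - k - 1) < 3):
                        ladder[k] = ladder[k + 1] = True
        lab = np.full(n, LABEL_COIL, dtype="U1")
        lab[beta & ladder] = LABEL_STRAND
        # helix: >= 4 consecutive alpha residues with an intra-chain bond inside
        k = 0
        while k < n:
            if alpha[k]:
                k2 = k
                while k2 + 1 < n and alpha[k2 + 1]:
                    k2 += 1
                if k2 - k + 1 >= 4:
                    supported = False
                    for r in range(k, k2 + 1):
                        for (c1, r1) in partners.get((ci, r), set()):
                            if c1 == ci and k <= r1 <= k2:
                                supported = True
                    if supported:
                        sel = lab[k:k2 + 1]
                        sel[sel == LABEL_COIL] = LABEL_HELIX
                        lab[k:k2 + 1] = sel
                k = k2 + 1
            else:
                k += 1
        labels.append(lab)
    return np.array(labels)


def strand_fraction(labels: np.ndarray) -> float:
    """Fraction of residues labeled strand, over all chains."""
    return float(np.mean(labels == LABEL_STRAND))


def strand_content_profile(assignments) -> np.ndarray:
    """Per-residue strand probability over frames (and chains).

    ``assignments`` is an iterable of per-frame label arrays of shape
    (n_chains, n_residues); the result has shape (n_residues,).
    """
    assignments = list(assignments)
    if not assignments:
        raise ValueError("no frames in the requested window")
    stack = np.stack(assignments)          # (F, n_chains, n_res)
    return np.mean(stack == LABEL_STRAND, axis=(0, 1))


# ---------------------------------------------------------------------------
# solvent accessible surface area
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def sphere_radii(top, ff: ForceField) -> np.ndarray:
    """Per-sphere radii: half the hard-core diameter of each sphere type."""
    out = np.zeros(top.n_spheres)
    for s in range(top.n_spheres):
        role = int(top.role[s])
        if role == ROLE_R:
            out[s] = 0.5 * ff.residue(str(top.resletter[s])).sigma
        else:
            key = {ROLE_NH: "NH", ROLE_CA: "CaH", ROLE_CO: "CO"}[role]
            out[s] = 0.5 * ff.backbone_sigma[key]
    return out


def sasa_profile(state: SystemState, top, ff: ForceField,
                 probe: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Per-residue solvent-accessible area (A^2) on the 4-sphere geometry.

    Shrake-Rupley style: each sphere carries a fixed quasi-uniform point
    set on its probe-expanded surface; points inside any other expanded
    sphere are buried.  Deterministic for a fixed point count.
    """
    radii = sphere_radii(top, ff) + probe
    pts = _sphere_points(n_points)
    pos = state.positions
    n = top.n_spheres
    areas = np.zeros(n)
    for i in range(n):
        delta = state.minimum_image(pos - pos[i])
        d = np.linalg.norm(delta, axis=1)
        neigh = np.nonzero((d < radii[i] + radii) & (np.arange(n) != i))[0]
        surface = pts * radii[i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neigh:
            dd = surface - delta[j]
            exposed &= np.einsum("ij,ij->i", dd, dd) > radii[j] ** 2
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * np.count_nonzero(exposed) / n_points
    per_res = np.zeros((top.n_chains, top.chains[0].n_residues))
    for s in range(n):
        per_res[int(top.chain_id[s]), int(top.residue[s])] += areas[s]
    return per_res


# ---------------------------------------------------------------------------
# P_max
# ---------------------------------------------------------------------------

def pmax_series(series: EnergySeries, window: float = 5000.0,
                halfwidth: float = 4.0, temperature: float | None = None) -> list:
    """Max-population statistic per reduced-time window.

    Within each consecutive window of width ``window`` in t*, E_max is the
    sample energy whose band [E_max - halfwidth, E_max + halfwidth]
    contains the most samples; P_max is that count over the window total.
    The free-energy-like transform is -k_B T* log(P_max), using the
    window's temperature (mean of the recorded schedule unless given).
    """
    if window <= 0 or halfwidth <= 0:
        raise ValueError("window and halfwidth must be > 0")
    t, e = series.tstar, series.energy
    if len(t) == 0:
        raise ValueError("empty energy series")
    out = []
    t0 = t[0]
    n_windows = int(np.ceil((t[-1] - t0) / window)) or 1
    for w in range(n_windows):
        lo, hi = t0 + w * window, t0 + (w + 1) * window
        sel = (t >= lo) & (t < hi) if w < n_windows - 1 else (t >= lo) & (t <= hi)
        ew = np.sort(e[sel])
        m = len(ew)
        if m == 0:
            continue
        # two-pointer band search over sample-centred bands
        best_count, best_e = 0, ew[0]
        left = 0
        for c in range(m):
            while ew[c] - ew[left] > halfwidth:
                left += 1
            right = np.searchsorted(ew, ew[c] + halfwidth, side="right")
            if right - left > best_count:
                best_count, best_e = right - left, ew[c]
        p = best_count / m
        if temperature is not None:
            T = temperature
        elif series.temperature is not None:
            T = float(np.mean(series.temperature[sel]))
        else:
            T = 1.0
        out.append(PmaxWindow(lo, hi, float(best_e), float(p),
                              float(-T * np.log(p)), m))
    return out


# ---------------------------------------------------------------------------
# salt bridges and shapes
# ---------------------------------------------------------------------------

def count_salt_bridges(state: SystemState, top, ff: ForceField):
    """(intra-chain, inter-chain) K-D side-sphere contacts.

    A salt bridge is a lysine/aspartate side-sphere pair within the K-D
    outer well diameter, i.e. a pair engaged by the salt-bridge potential.
    """
    d_out = ff.pair_potential("K", "D").d_outer
    ks = [s for s in range(top.n_spheres)
          if top.role[s] == ROLE_R and top.resletter[s] == "K"]
    ds = [s for s in range(top.n_spheres)
          if top.role[s] == ROLE_R and top.resletter[s] == "D"]
    intra = inter = 0
    for a in ks:
        for b in ds:
            if state.distance(a, b) <= d_out:
                if top.chain_id[a] == top.chain_id[b]:
                    intra += 1
                else:
                    inter += 1
    return intra, inter


#: reported-numbering regions used by the shape classifier (amyloid-beta
#: convention: central turn V24-S26, C-terminal turn G37-G38, extra turn
#: near G33)
CENTRAL_TURN_REGION = (24, 26)
CTERM_TURN_REGION = (37, 38)
G33_TURN_REGION = (32, 34)

TURN_ANGLE_DEG = 120.0


def detect_turns(state: SystemState, top, chain: int,
                 angle_deg: float = TURN_ANGLE_DEG) -> list:
    """Residue numbers (reported numbering) where the Ca trace reverses.

    A turn at residue k means the incoming and outgoing directions over a
    5-residue window (Ca_{k-2}->Ca_k and Ca_k->Ca_{k+2}) differ by more
    than ``angle_deg``.  Consecutive flagged residues merge into one turn
    centred on their middle.
    """
    ct = top.chains[chain]
    coords = unwrap_chain(state, top, chain)
    ca = np.array([coords[ct.backbone_ids(k)[1]] for k in range(ct.n_residues)])
    cos_thr = np.cos(np.radians(angle_deg))
    flagged = []
    for k in range(2, len(ca) - 2):
        a = ca[k] - ca[k - 2]
        b = ca[k + 2] - ca[k]
        c = float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
        if c < cos_thr:
            flagged.append(k)
    turns = []
    for k in flagged:
        if turns and k - turns[-1][-1] == 1:
            turns[-1].append(k)
        else:
            turns.append([k])
    off = ct.numbering_offset
    return [off + grp[len(grp) // 2] for grp in turns]


def _strand_contact(state: SystemState, top, chain: int, ff: ForceField,
                    split: int) -> bool:
    """Any N-side / C-side side-sphere pair of one chain within its outer well."""
    ct = top.chains[chain]
    off = top.offsets[chain]
    numbering = ct.numbering_offset
    n_side = [off + ct.sphere_id(k, ROLE_R) for k in range(ct.n_residues)
              if numbering + k < split and ct.sphere_id(k, ROLE_R) >= 0]
    c_side = [off + ct.sphere_id(k, ROLE_R) for k in range(ct.n_residues)
              if numbering + k > split and ct.sphere_id(k, ROLE_R) >= 0]
    for a in n_side:
        la = str(top.resletter[a])
        for b in c_side:
            if state.distance(a, b) <= ff.pair_potential(la, str(top.resletter[b])).d_outer:
                return True
    return False


def classify_chain_shape(state: SystemState, top, chain: int, ff: ForceField,
                         central=CENTRAL_TURN_REGION, cterm=CTERM_TURN_REGION,
                         near33=G33_TURN_REGION) -> str:
    """Qualitative chain shape: 'U', 'S', 'triangular', 'disordered'.

    U: a single central turn with the C-terminal strand folded back into
    contact with the N-terminal strand.  S: an additional turn in the
    C-terminal turn region directing the tail outward.  Triangular: an
    additional turn near the G33 region.  Chains shorter than 10 residues
    are not classifiable (returns 'unclassified').
    """
    ct = top.chains[chain]
    if ct.n_residues < 10:
        return "unclassified"
    turns = detect_turns(state, top, chain)
    has_central = any(central[0] <= t <= central[1] for t in turns)
    has_cterm = any(cterm[0] <= t <= cterm[1] for t in turns)
    has_g33 = any(near33[0] <= t <= near33[1] for t in turns)
    if not has_central:
        return "disordered"
    if has_g33:
        return "triangular"
    if has_cterm:
        return "S"
    split = (central[0] + central[1]) // 2
    if _strand_contact(state, top, chain, ff, split):
        return "U"
    return "disordered"
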