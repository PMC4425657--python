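"""PRIME20-style interaction parameters in hydrogen-bond-reduced units.

Energy unit: the backbone hydrogen-bond well depth, eps_HB = 1 (k_B = 1, so
the reduced temperature is T* = k_B T / eps_HB).  All well depths are stored
as positive magnitudes; the sign convention (attractive wells lower the
energy) is applied at energy evaluation.

Parameter provenance
--------------------
Backbone sphere masses, the F-F side-chain attraction (0.205 eps_HB), the
K-D salt-bridge strengths (0.136 plain / 0.4 enhanced), the inner/outer
double-well depth multipliers (1.3 / 0.7) and the two directional
hydrogen-bond cutoff sets are fixed model constants.  Per-residue geometry
(sphere diameters, centroid bond lengths, squeeze distances) and the
remaining pair energies ship as editable plain-text tables whose defaults
are synthesized from documented rules (see ``docs/methods.md``): side-chain
diameters from partial molar volumes, well diameters offset 1.5 / 2.5 A
from contact, squeeze distances at 75% of the mean contact distance, and
hydrophobic pair energies from a geometric-mean combining rule anchored at
eps(F,F) = 0.205.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry
from .residues import AMINO_ACIDS, SIDE_MASS, MASS_NH, MASS_CAH, MASS_CO, has_side_sphere

# Backbone united-sphere hard-core diameters (Angstrom).
SIGMA_NH = 3.3
SIGMA_CA = 3.7
SIGMA_CO = 4.0

#: fractional half-width of every covalent/pseudo-bond distance window
BOND_TOLERANCE = 0.02375

#: hard-core scaling for non-bonded pairs separated by <= 3 bond-graph edges
LOCAL_REDUCTION = 0.75

#: NH-CO hydrogen-bond square-well diameter (Angstrom)
HB_WELL_DIAMETER = 4.2

#: double-well depth multipliers: deep inner well, shallow outer well
INNER_MULTIPLIER = 1.3
OUTER_MULTIPLIER = 0.7

#: spacing between contact, inner and outer well surfaces in the default
#: tables, mirroring the 1 A gap between the 4.5 / 5.5 A heavy-atom criteria
INNER_WELL_OFFSET = 1.5
OUTER_WELL_OFFSET = 2.5

# Directional hydrogen-bond auxiliary distance cutoffs (Angstrom), for the
# four pairs (N_i-Ca_j, N_i-N_{j+1}, C_j-Ca_i, C_j-C_{i-1}) between donor
# residue i and acceptor residue j.
HBOND_CUTOFF_SETS = {
    "parallel_preference": (5.10, 4.54, 4.96, 4.58),
    "original": (5.00, 4.74, 4.86, 4.83),
}

SALT_BRIDGE_ORIGINAL = 0.136
SALT_BRIDGE_ENHANCED = 0.4

#: hard-core diameters are closest-approach distances, substantially smaller
#: than the volumetric size of a flexible side chain; the default tables use
#: this fraction of the volume-equivalent contact diameter
CORE_SOFTNESS = 0.70

# Partial molar residue volumes (A^3); the side-chain volume is the excess
# over glycine and sets the default side-sphere diameter.
_RESIDUE_VOLUME = {
    "G": 60.1, "A": 88.6, "S": 89.0, "C": 108.5, "D": 111.1, "P": 112.7,
    "N": 114.1, "T": 116.1, "E": 138.4, "V": 140.0, "Q": 143.8, "H": 153.2,
    "M": 162.9, "I": 166.7, "L": 166.7, "K": 168.6, "R": 173.4, "F": 189.9,
    "Y": 193.6, "W": 227.8,
}

# Ca-to-side-centroid bond distances (A), approximate side-chain centroids.
_DR_CA = {
    "A": 1.53, "S": 1.70, "C": 1.95, "T": 1.95, "V": 1.95, "P": 1.85,
    "D": 2.20, "N": 2.25, "I": 2.30, "L": 2.35, "E": 2.65, "Q": 2.70,
    "H": 2.75, "M": 2.80, "F": 3.00, "Y": 3.20, "K": 3.10, "R": 3.55,
    "W": 3.35,
}

# Per-residue hydrophobic interaction strengths (eps_HB); pair energies use
# the geometric mean, so eps(F,F) = 0.205 exactly.
_HYDRO_EPS = {
    "F": 0.205, "W": 0.210, "Y": 0.180, "L": 0.170, "I": 0.170,
    "M": 0.160, "C": 0.150, "V": 0.140, "P": 0.100, "A": 0.084,
}

# Oppositely charged side-chain pairs attract at the original salt-bridge
# strength; the K-D pair is the one the salt-bridge configuration rescales.
_SALT_PAIRS = {frozenset(p) for p in (("K", "D"), ("K", "E"), ("R", "D"), ("R", "E"))}


@dataclass(frozen=True)
class DoubleWell:
    """Two-shell square well between a pair of side-chain spheres."""

    d_core: float
    d_inner: float
    d_outer: float
    e_base: float

    @property
    def e_inner(self) -> float:
        return INNER_MULTIPLIER * self.e_base

    @property
    def e_outer(self) -> float:
        return OUTER_MULTIPLIER * self.e_base

    def __post_init__(self):
        if not (0 < self.d_core < self.d_inner < self.d_outer):
            raise ValueError(
                f"require 0 < d_core < d_inner < d_outer, got "
                f"({self.d_core}, {self.d_inner}, {self.d_outer})"
            )


@dataclass(frozen=True)
class HBondCutoffSet:
    mode: str
    n_ca: float        # N_i - Ca_j
    n_n_next: float    # N_i - N_{j+1}
    c_ca: float        # C_j - Ca_i
    c_c_prev: float    # C_j - C_{i-1}
    well_diameter: float = HB_WELL_DIAMETER
    energy: float = 1.0

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.n_ca, self.n_n_next, self.c_ca, self.c_c_prev)


@dataclass(frozen=True)
class SaltBridgeConfig:
    enhanced: bool = True

    @property
    def strength(self) -> float:
        return SALT_BRIDGE_ENHANCED if self.enhanced else SALT_BRIDGE_ORIGINAL


@dataclass(frozen=True)
class ResidueSpec:
    """Geometry of one residue's side sphere relative to its backbone."""

    name: str
    has_side_sphere: bool
    side_mass: float = float("nan")
    sigma: float = float("nan")
    dr_ca: float = float("nan")
    dr_nh: float = float("nan")
    dr_co: float = float("nan")
    # squeeze parameters: minimum non-bonded distances to the five
    # neighbouring backbone spheres (keyed by the side sphere's residue i)
    sq_ca_prev: float = float("nan")   # R(i) - Ca(i-1)
    sq_co_prev: float = float("nan")   # R(i) - CO(i-1)
    sq_nh_next: float = float("nan")   # R(i) - NH(i+1)
    sq_ca_next: float = float("nan")   # R(i) - Ca(i+1)
    sq_co_prev2: float = float("nan")  # CO(i-2) - R(i)

    def __post_init__(self):
        if self.has_side_sphere:
            vals = (self.side_mass, self.sigma, self.dr_ca, self.dr_nh, self.dr_co,
                    self.sq_ca_prev, self.sq_co_prev, self.sq_nh_next,
                    self.sq_ca_next, self.sq_co_prev2)
            if any(not (v > 0) for v in vals):
                raise ValueError(f"residue {self.name}: all distances/masses must be > 0")


@dataclass
class ForceField:
    """Complete interaction table set for the 4-sphere peptide model."""

    residues: dict[str, ResidueSpec]
    pair_eps: dict[frozenset, float]
    well_inner: dict[frozenset, float]
    well_outer: dict[frozenset, float]
    hbond_mode: str = "parallel_preference"
    salt_bridge: SaltBridgeConfig = field(default_factory=SaltBridgeConfig)
    hb_well_diameter: float = HB_WELL_DIAMETER
    bond_tolerance: float = BOND_TOLERANCE
    backbone_sigma: dict[str, float] = field(
        default_factory=lambda: {"NH": SIGMA_NH, "CaH": SIGMA_CA, "CO": SIGMA_CO}
    )
    backbone_mass: dict[str, float] = field(
        default_factory=lambda: {"NH": MASS_NH, "CaH": MASS_CAH, "CO": MASS_CO}
    )

    # -- lookups ---------------------------------------------------------

    def residue(self, aa: str) -> ResidueSpec:
        try:
            return self.residues[aa]
        except KeyError:
            raise KeyError(f"unknown residue {aa!r}") from None

    def base_energy(self, a: str, b: str) -> float:
        """Base pair energy eps(a, b), with the active salt-bridge strength
        substituted for the K-D pair."""
        key = frozenset((a, b))
        if key == frozenset(("K", "D")):
            return self.salt_bridge.strength
        return self.pair_eps.get(key, 0.0)

    def pair_potential(self, a: str, b: str) -> DoubleWell:
        for aa in (a, b):
            if not has_side_sphere(aa):
                raise ValueError(f"residue {aa} has no side sphere")
        key = frozenset((a, b))
        ra, rb = self.residue(a), self.residue(b)
        return DoubleWell(
            d_core=0.5 * (ra.sigma + rb.sigma),
            d_inner=self.well_inner[key],
            d_outer=self.well_outer[key],
            e_base=self.base_energy(a, b),
        )

    def hbond_cutoffs(self, mode: str | None = None) -> HBondCutoffSet:
        mode = mode or self.hbond_mode
        try:
            vals = HBOND_CUTOFF_SETS[mode]
        except KeyError:
            raise ValueError(
                f"unknown hydrogen-bond cutoff mode {mode!r}; "
                f"expected one of {sorted(HBOND_CUTOFF_SETS)}"
            ) from None
        return HBondCutoffSet(mode, *vals, well_diameter=self.hb_well_diameter)

    def with_options(self, hbond_mode: str | None = None,
                     salt_bridge_enhanced: bool | None = None) -> "ForceField":
        ff = self
        if hbond_mode is not None:
            ff.hbond_cutoffs(hbond_mode)  # validate
            ff = replace(ff, hbond_mode=hbond_mode)
        if salt_bridge_enhanced is not None:
            ff = replace(ff, salt_bridge=SaltBridgeConfig(salt_bridge_enhanced))
        return ff

    def max_interaction_diameter(self) -> float:
        return max(max(self.well_outer.values()), self.hb_well_diameter,
                   *self.backbone_sigma.values())

    # -- persistence -----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for aa in AMINO_ACIDS:
            r = self.residues[aa]
            rows.append({
                "residue": aa, "side_mass": r.side_mass, "sigma": r.sigma,
                "dr_ca": r.dr_ca, "dr_nh": r.dr_nh, "dr_co": r.dr_co,
                "sq_ca_prev": r.sq_ca_prev, "sq_co_prev": r.sq_co_prev,
                "sq_nh_next": r.sq_nh_next, "sq_ca_next": r.sq_ca_next,
                "sq_co_prev2": r.sq_co_prev2,
            })
        pd.DataFrame(rows).to_csv(directory / "residues.tsv", sep="\t",
                                  index=False, float_format="%.17e")
        pair_rows = []
        for i, a in enumerate(AMINO_ACIDS):
            for b in AMINO_ACIDS[i:]:
                if not (has_side_sphere(a) and has_side_sphere(b)):
                    continue
                key = frozenset((a, b))
                pair_rows.append({
                    "res_a": a, "res_b": b,
                    "eps": self.pair_eps.get(key, 0.0),
                    "d_inner": self.well_inner[key],
                    "d_outer": self.well_outer[key],
                })
        pd.DataFrame(pair_rows).to_csv(directory / "pairs.tsv", sep="\t",
                                       index=False, float_format="%.17e")

    @classmethod
    def load(cls, directory: str | Path, hbond_mode: str = "parallel_preference",
             salt_bridge_enhanced: bool = True) -> "ForceField":
        directory = Path(directory)
        res_df = pd.read_csv(directory / "residues.tsv", sep="\t", float_precision="round_trip")
        required = {"residue", "side_mass", "sigma", "dr_ca", "dr_nh", "dr_co",
                    "sq_ca_prev", "sq_co_prev", "sq_nh_next", "sq_ca_next",
                    "sq_co_prev2"}
        missing = required - set(res_df.columns)
        if missing:
            raise ValueError(f"residues.tsv: missing column(s) {sorted(missing)}")
        residues = {}
        for _, row in res_df.iterrows():
            aa = str(row["residue"])
            if aa not in AMINO_ACIDS:
                raise ValueError(f"residues.tsv: unknown residue {aa!r}")
            residues[aa] = ResidueSpec(
                name=aa, has_side_sphere=has_side_sphere(aa),
                **{k: float(row[k]) for k in required - {"residue"}},
            )
        absent = set(AMINO_ACIDS) - set(residues)
        if absent:
            raise ValueError(f"residues.tsv: missing residue(s) {sorted(absent)}")

        pair_df = pd.read_csv(directory / "pairs.tsv", sep="\t", float_precision="round_trip")
        pair_eps, well_inner, well_outer = {}, {}, {}
        for idx, row in pair_df.iterrows():
            a, b = str(row["res_a"]), str(row["res_b"])
            key = frozenset((a, b))
            if key in well_inner:
                prev = (pair_eps.get(key, 0.0), well_inner[key], well_outer[key])
                cur = (float(row["eps"]), float(row["d_inner"]), float(row["d_outer"]))
                if not np.allclose(prev, cur):
                    raise ValueError(
                        f"pairs.tsv row {idx}: asymmetric duplicate for pair {a}-{b}")
                continue
            if float(row["eps"]) != 0.0:
                pair_eps[key] = float(row["eps"])
            well_inner[key] = float(row["d_inner"])
            well_outer[key] = float(row["d_outer"])
        ff = cls(residues=residues, pair_eps=pair_eps,
                 well_inner=well_inner, well_outer=well_outer,
                 hbond_mode=hbond_mode,
                 salt_bridge=SaltBridgeConfig(salt_bridge_enhanced))
        ff.validate()
        return ff

    def validate(self) -> None:
        side = [a for a in AMINO_ACIDS if has_side_sphere(a)]
        for i, a in enumerate(side):
            for b in side[i:]:
                self.pair_potential(a, b)  # raises if diameters are unordered


def default_forcefield(hbond_mode: str = "parallel_preference",
                       salt_bridge_enhanced: bool = True) -> ForceField:
    """The force field synthesized from the documented default rules."""
    residues = {}
    for aa in AMINO_ACIDS:
        if not has_side_sphere(aa):
            residues[aa] = ResidueSpec(name=aa, has_side_sphere=False)
            continue
        v_side = _RESIDUE_VOLUME[aa] - _RESIDUE_VOLUME["G"]
        sigma = CORE_SOFTNESS * 2.0 * (3.0 * v_side / (4.0 * math.pi)) ** (1.0 / 3.0)
        dr_ca = _DR_CA[aa]
        dr_nh, dr_co = geometry.side_pseudo_lengths(dr_ca)
        residues[aa] = ResidueSpec(
            name=aa, has_side_sphere=True, side_mass=SIDE_MASS[aa],
            sigma=sigma, dr_ca=dr_ca, dr_nh=dr_nh, dr_co=dr_co,
            sq_ca_prev=LOCAL_REDUCTION * 0.5 * (sigma + SIGMA_CA),
            sq_co_prev=LOCAL_REDUCTION * 0.5 * (sigma + SIGMA_CO),
            sq_nh_next=LOCAL_REDUCTION * 0.5 * (sigma + SIGMA_NH),
            sq_ca_next=LOCAL_REDUCTION * 0.5 * (sigma + SIGMA_CA),
            sq_co_prev2=LOCAL_REDUCTION * 0.5 * (sigma + SIGMA_CO),
        )
    pair_eps, well_inner, well_outer = {}, {}, {}
    side = [a for a in AMINO_ACIDS if has_side_sphere(a)]
    for i, a in enumerate(side):
        for b in side[i:]:
            key = frozenset((a, b))
            d_core = 0.5 * (residues[a].sigma + residues[b].sigma)
            well_inner[key] = d_core + INNER_WELL_OFFSET
            well_outer[key] = d_core + OUTER_WELL_OFFSET
            if a in _HYDRO_EPS and b in _HYDRO_EPS:
                pair_eps[key] = math.sqrt(_HYDRO_EPS[a] * _HYDRO_EPS[b])
            elif key in _SALT_PAIRS:
                pair_eps[key] = SALT_BRIDGE_ORIGINAL
    # exact printed anchor
    pair_eps[frozenset(("F",))] = _HYDRO_EPS["F"]
    return ForceField(residues=residues, pair_eps=pair_eps,
                      well_inner=well_inner, well_outer=well_outer,
                      hbond_mode=hbond_mode,
                      salt_bridge=SaltBridgeConfig(salt_bridge_enhanced))


def load_forcefield(directory: str | Path | None = None,
                    hbond_mode: str = "parallel_preference",
                    salt_bridge_enhanced: bool = True) -> ForceField:
    """Load parameter tables from ``directory``, or the packaged defaults."""
    if directory is None:
        directory = resources.files("prime_dmd") / "data"
    return ForceField.load(directory, hbond_mode=hbond_mode,
                           salt_bridge_enhanced=salt_bridge_enhanced)


def derive_well_diameter(centroid_distances, heavy_atom_distance_sets,
                         heavy_atom_cutoff: float, statistic: str | float = "max") -> float:
    """Well diameter from side-chain contact samples.

    A sample (one observed side-chain pair) qualifies when strictly more
    than half of its heavy-atom cross distances fall below
    ``heavy_atom_cutoff``; the returned diameter is a summary statistic of
    the qualifying centroid-centroid distances (default: their maximum, so
    the well encloses every observed contact geometry; a float in (0, 1]
    selects that quantile instead).
    """
    if heavy_atom_cutoff <= 0:
        raise ValueError("heavy_atom_cutoff must be > 0")
    centroid_distances = list(centroid_distances)
    heavy_atom_distance_sets = list(heavy_atom_distance_sets)
    if not centroid_distances or len(centroid_distances) != len(heavy_atom_distance_sets):
        raise ValueError("need one heavy-atom distance set per centroid distance")
    qualifying = []
    for d, heavy in zip(centroid_distances, heavy_atom_distance_sets):
        heavy = np.asarray(heavy, float)
        if heavy.size and np.count_nonzero(heavy < heavy_atom_cutoff) * 2 > heavy.size:
            qualifying.append(d)
    if not qualifying:
        raise ValueError("no sample passes the heavy-atom criterion")
    if statistic == "max":
        return float(np.max(qualifying))
    q = float(statistic)
    if not 0 < q <= 1:
        raise ValueError("quantile statistic must lie in (0, 1]")
    return float(np.quantile(qualifying, q))
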