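# Methods

## Peptide representation

A chain of *n* residues maps onto `4n − n_gly` spheres: backbone united
spheres NH, CαH and CO per residue, plus a single side-chain centroid
sphere R for every residue except glycine. Reduced masses use the CH3
united atom (15.035 amu) as unit — backbone masses 0.999 (NH), 0.866
(CαH), 1.863 (CO); side-chain masses are the side-chain formula mass over
15.035, which reproduces the canonical values (A 1.000, V 2.866, L 3.799,
F 6.061, …) and fixes the three residues absent from that list
(C 3.132, P 2.799, W 8.658).

Local geometry is enforced entirely by hard distance windows
`d₀(1 ± δ)`, δ = 0.02375:

* covalent bonds N–Cα 1.46 Å, Cα–C 1.51 Å, C–N 1.33 Å, Cα–R per residue;
* pseudo-bonds N_i–C_i, Cα_i–N_{i+1}, C_i–Cα_{i+1} and Cα_i–Cα_{i+1},
  whose nominal lengths are *computed* from the ideal bond angles
  (111°, 116°, 122°) and the trans peptide bond (ω = 180°), so the
  constraint network and the coordinate builders can never disagree;
* pseudo-bonds R–NH and R–CO, computed from the L-isomer placement of the
  side sphere (110° from the backbone, positive scalar triple product
  (N−Cα)·[(C−Cα)×(R−Cα)]). Distances alone admit the mirror (D) image,
  but reaching it would require the side sphere to pass through the
  backbone hard cores; an independent triple-product check
  (`chirality_sign`) verifies every sampled frame.

Non-bonded minimum distances: squeeze parameters between R(i) and the five
neighbouring backbone spheres; for all other pairs the mean hard-core
contact distance, reduced by a factor 0.75 when the two spheres are within
three bond-graph edges (without this local reduction, compact conformers
typical of sheets and turns would be sterically excluded).

## Interaction parameters and their provenance

The energy unit is the backbone hydrogen-bond well depth ε_HB ≡ 1
(k_B = 1, T* = k_BT/ε_HB). Model constants fixed by the PRIME20 lineage
and kept exact: the backbone masses above; ε(F,F) = 0.205 ε_HB; the
K–D salt-bridge strengths (0.136 plain, 0.4 enhanced); the double-well
depth multipliers 1.3 (inner) and 0.7 (outer); both directional
hydrogen-bond cutoff sets.

The remaining per-residue geometry is shipped as editable TSV tables whose
defaults are synthesized from documented rules rather than transcribed
digit-for-digit (the published supplementary tables are not redistributed
here):

* backbone hard-core diameters 3.3 / 3.7 / 4.0 Å (NH / CαH / CO);
* side-sphere hard-core diameter = 0.70 × the volume-equivalent diameter
  from partial molar side-chain volumes. The 0.70 factor reflects that
  hard cores encode closest approach of flexible groups, not volumetric
  size; without it, bulky side chains (F–F contact would be 6.3 Å) cannot
  pack at the ≈4.8 Å inter-strand spacing of a β-sheet and hydrogen-bonded
  sheets become sterically impossible;
* double-well diameters: inner = contact + 1.5 Å, outer = contact + 2.5 Å,
  mirroring the 1 Å gap between the 4.5 / 5.5 Å heavy-atom criteria that
  define the two shells;
* squeeze distances: 0.75 × mean contact distance of the pair;
* Cα–centroid bond lengths from approximate side-chain centroid
  geometry (1.53 Å for A up to 3.55 Å for R);
* base pair energies: geometric mean of per-residue hydrophobic strengths
  anchored exactly at ε(F,F) = 0.205; oppositely charged pairs at
  0.136 ε_HB; all other pairs hard-sphere only.

`derive_well_diameter` implements the shell-diameter rule used to build
such tables from structural statistics: a sampled side-chain pair
qualifies when *strictly more than half* of its heavy-atom cross distances
fall below the chosen cutoff (4.5 Å for the inner shell, 5.5 Å for the
outer), and the well diameter is a summary statistic of the qualifying
centroid distances. The summary statistic is not prescribed anywhere, so
the default is the maximum (the well should enclose every observed contact
geometry) with a quantile option; it is a utility, not a reproduction of
the published diameters.

Tables round-trip losslessly (`%.17e` text) and are validated on load
(complete residue coverage, pair symmetry, core < inner < outer).

## Hydrogen bonding

NH–CO pairs interact through a 4.2 Å square well (a PRIME-lineage default;
the diameter is configurable). At the instant an unbonded, eligible pair
crosses the well surface inward, the bond forms if (i) both partners are
free (one bond per NH, one per CO), (ii) the donor and acceptor are at
least 3 residues apart when on the same chain, and (iii) all four
auxiliary distances are inside the active cutoff set. Formation releases
ε_HB into the radial kinetic energy; while the bond lives, the four
auxiliary pairs bounce elastically off their cutoff surfaces (temporary
constraint windows), keeping the geometry directional; breaking requires
ε_HB of radial kinetic energy and releases the windows. Ineligible pairs
pass through the well surface untouched. Orientation of a bond is
classified by the sign of the dot product of the two local backbone
directions Cα_{k−1}→Cα_{k+1}; terminal residues are unclassifiable.

## The event-driven engine

Between events all spheres move ballistically. The time to a radial
discontinuity at distance *d* is the appropriate root of
|r + v·t| = d; a sphere numerically on a surface is classified to the side
it is moving toward (a 10⁻⁹ Å shift along the radial velocity), which
makes post-event re-predictions unambiguous without tracking pair shells.
Each sphere stores its earliest pair event; executing an event re-predicts
only the affected spheres and any sphere whose stored event referenced
them. Impulses act along the line of centres: crossings rescale the
radial relative velocity by energy conservation, insufficient uphill
attempts reflect it. Linear momentum is conserved to machine precision at
every pair event; total energy is exact apart from floating-point
round-off (measured drift ≲10⁻¹³ ε_HB per 10⁶ events).

Neighbour bookkeeping has two modes. *Brute* scans all partners and
schedules per-sphere re-prediction horizons after 0.45·(L/2 − range) of
travel, which guarantees a pair is re-examined before its periodic
minimum image can switch (it requires L > 2·range). *Cells* uses a linked
cell list with cell edge ≥ the interaction range and exact cell-crossing
events; it is enabled automatically at ≥7 cells per side, where a pair
can never change image while both members stay inside one 27-cell
neighbourhood. Both modes execute bit-identical pair-event sequences
(tested).

The thermostat is an Andersen-style ghost-collision process: each sphere
is resampled from the Maxwell–Boltzmann distribution at the scheduled
temperature at Poisson times with a configurable rate (default 0.05 per
sphere per internal time unit, roughly one resampling per ~20 pair events
per sphere at the densities used here). The rate is defined in the time
domain rather than per event because an event-conditioned thermostat is
not ergodic for states with no future collisions (e.g. an unbound pair).
Ghost collisions are excluded from the collision count; schedules,
sampling intervals and the cooling ramp (piecewise linear in T* against
the collision count, default T* 0.5 → production temperature) are all
defined on executed pair events.

Two integrator paths exist: a pure-Python event loop (reference,
feature-complete including cell lists) and a numba-compiled loop
(all-pairs mode only, ~10× faster). They are arithmetically identical —
the test suite asserts bit-identical trajectories over 15 000 events with
the thermostat off; thermostated runs differ only in the RNG stream that
feeds ghost collisions. Checkpoints store positions, velocities, clocks,
counters, the bond registry and the RNG states, and restarting reproduces
the original continuation event-for-event.

Reduced time uses the NH sphere: t* = t/σ·(k_B T/m)^½ with σ = 3.3 Å,
m = 0.999, accumulated piecewise while the temperature schedule varies.

## Analysis

* **Secondary structure**: φ/ψ from the sphere positions (CO_{k−1}, NH_k,
  CαH_k, CO_k, NH_{k+1}); strand = β-region dihedrals
  (φ ∈ [−180°, −45°], ψ ∈ [45°, 180°] ∪ [−180°, −150°]) *and* membership
  in a hydrogen-bond ladder (the residue and a sequence neighbour both
  bonded to near-consecutive residues of the same partner strand); helix =
  ≥4 consecutive α-region residues supported by an intra-chain bond;
  everything else coil/turn, termini coil by convention. A lone extended
  chain therefore scores 0 % strand — strand content measures sheet
  organisation, not local geometry.
* **SASA**: Shrake–Rupley on the 4-sphere geometry — 960 deterministic
  golden-spiral points per sphere, radii = half the hard-core diameters,
  probe 1.4 Å, per-residue sums. Numeric values are tied to these choices
  and are not comparable digit-for-digit with atomistic SASA.
* **P_max**: the energy series is cut into Δt* = 5000 windows; within each
  window the band centre E_max maximising the number of samples within
  ±4 ε_HB is found by an exact sorted two-pointer search over
  sample-centred candidates (verified against exhaustive search);
  P_max = band count / window count, and the free-energy-like value is
  −k_B T*·log P_max with the window's mean scheduled temperature.
* **Salt bridges**: K–D side-sphere pairs within the K–D outer well
  diameter — the force field's own notion of an engaged contact — split
  into intra- and inter-chain counts.
* **Chain shapes**: turns are Cα-trace direction reversals >120° over a
  5-residue window, merged and reported at their centres in Aβ numbering.
  A central turn in 24–26 with the C-terminal strand in side-chain
  contact with the N-terminal strand is **U**; an additional turn at
  37–38 is **S** (outward C-terminal turn); an additional turn near G33
  (32–34) is **triangular**; anything else is disordered, and chains
  under 10 residues are unclassified. The thresholds are heuristics for
  shapes that were originally judged by eye.

## Study conditions, problem sizes and limitations

The production condition the package models is 8 Aβ17–42 chains in a
(160 Å)³ periodic box (the geometry implies ≈3.24 mM), started as
separated denatured random coils without any inter-peptide contacts
(rejection-sampled self-avoiding dihedral growth; placement requires the
smallest inter-chain distance to exceed the largest interaction
diameter), velocities Maxwell–Boltzmann at T* = 0.5 with zero total
momentum, then cooled to a production temperature near the fibrillization
point (T* ≈ 0.19–0.205).

Full protofilament assembly in this model takes on the order of 10¹¹
collisions — far beyond a desktop — so the shipped experiments are
desk-scale by design:

* conservation, kinematics and detailed-balance checks run on 2–8-sphere
  constructed systems (10⁵–10⁶ events);
* the directional hydrogen-bond experiment
  (`experiments.parallel_preference_comparison`) uses two 7-residue
  AVAVAVA fragments in a 30 Å box at T* = 0.20, started from an idealized
  strand pair perturbed by a 20° rotation and 2.5 Å separation (so
  neither cutoff set is satisfied at t = 0), 1.5×10⁶ events per run,
  six matched seeds per cutoff set, bond orientations tallied at 30
  checkpoints. The pre-associated start is what makes first-bond
  formation reachable at this budget: from fully random encounters the
  tight parallel-preference set nucleates its first bond only on ~10⁷+
  event scales. Under these conditions the parallel-preference set
  yields a clearly higher pooled parallel fraction than the original
  set, per the model's design intent.

What passing tests do **not** show: agreement with published supplementary
parameter values (the default tables are rule-synthesized, see above),
quantitative aggregation kinetics or structure populations at production
scale, or any solvent/temperature mapping to experimental conditions
(ε_HB is a potential of mean force; T* has no direct Kelvin equivalent).
Known limitations: tryptophan pairs are too bulky for in-register packing
at i, i+2 within a strand; the fast loop does not implement cell lists
(all-pairs only); and the S/triangular shape classes are geometric
heuristics with no claim of matching visual assignments on borderline
conformations.
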