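# prime-dmd

Event-driven (discontinuous) molecular dynamics for a coarse-grained
4-sphere-per-residue peptide model, built to study the spontaneous
aggregation of amyloid-β fragments — in particular Aβ17–42, the 26-residue
C-terminal fragment whose oligomers and U-shaped protofilaments are central
to models of Alzheimer's disease — together with the trajectory statistics
used to characterize fibril formation.

It is aimed at researchers who want a small, fully tested, pure-Python
(+numba) laboratory for square-well protein aggregation models: every
discontinuity (hard core, well shell, bond window, directional hydrogen
bond, thermostat ghost collision) is an exact analytic event, energy and
momentum are conserved to machine precision between thermostat events, and
the analysis layer computes the observables this class of simulation is
judged by.

## The model

Each residue is three backbone united spheres — NH, CαH, CO — plus one
side-chain sphere R at the side-chain centroid (glycine has none).
Covalent bonds and angle/ω-fixing pseudo-bonds are hard distance windows
`d₀(1 ± δ)` with δ = 2.375 %; "squeeze" minimum distances keep the side
sphere out of the neighbouring backbone, and the geometry admits only the
L-isomer arrangement of every chiral residue.

All energies are in units of the backbone hydrogen-bond well depth ε_HB
(k_B = 1, so the reduced temperature is T* = k_B T/ε_HB; reduced time is
t* = t/σ·(k_B T/m)^½ with σ, m of the NH sphere). Interactions:

* **Side-chain pairs** interact through a *double well*: a deep inner
  shell of depth 1.3·ε(ij) and a shallow outer shell of depth 0.7·ε(ij),
  where ε(ij) is the base pair energy (ε(F,F) = 0.205 ε_HB is the
  strongest hydrophobic anchor).
* **Backbone hydrogen bonds** form when an NH donor and CO acceptor cross
  a 4.2 Å square well *and* four auxiliary distances
  (N_i–Cα_j, N_i–N_{j+1}, C_j–Cα_i, C_j–C_{i−1}) sit inside a directional
  cutoff set. Two sets ship: the *parallel-preference* set
  (5.10, 4.54, 4.96, 4.58 Å), which biases β-sheets toward parallel
  in-register order, and the *original* set (5.00, 4.74, 4.86, 4.83 Å).
  While a bond lives, the four pairs are confined below their cutoffs;
  formation releases ε_HB into kinetic energy, breaking costs it back.
* **The K28–D23 salt bridge** can be enhanced from its plain strength of
  0.136 ε_HB to 0.4 ε_HB, the regime in which U-shaped protofilaments
  assemble most readily.

The analysis layer provides φ/ψ dihedrals, a dihedral + hydrogen-bond-ladder
secondary-structure assignment, per-residue β-strand profiles, a
Shrake–Rupley-style SASA tailored to the 4-sphere geometry, intra/inter
chain salt-bridge counts, U/S/triangular chain-shape classification, and
P_max — the per-window fraction of configurations whose total interaction
energy lies within ±4 ε_HB of the most populated energy, with its
free-energy-like transform −k_B T* log P_max.

## Worked example

```sh
$ prime-dmd init --sequence AAAAAAA --nc 2 --box 24 --seed 1 \
      --config run.yaml
configuration -> run.yaml (2 chains, 24 A box, 240.24 mM, hash 81908b843d10a4bf)

$ prime-dmd run --config run.yaml --events 50000 --out traj.h5 \
      --energy-out energy.tsv
{
  "config_hash": "e445b6aa09d08b6f",
  "collisions": 50000,
  "ghosts": 185,
  "final_tstar": 8.434441091431909,
  "final_potential": -2.1763999999999997,
  ...
}

$ prime-dmd analyze --traj traj.h5
P_max (1 windows) -> analysis/pmax.tsv
strand profile -> analysis/strand_profile.tsv (mean strand content 3.6%)
salt bridges -> analysis/salt_bridges.tsv
chain shapes -> analysis/shapes.tsv
```

The run executes 50 000 pair events (collisions) of two 7-residue chains
in a dense 24 Å box; `final_potential` is the total interaction energy in
ε_HB (−2.18 here: a couple of occupied side-chain wells and/or hydrogen
bonds), `final_tstar` the elapsed reduced time. The analysis tables give
the per-residue strand probability (3.6 % of residue observations were in
β-strand ladders by the end of this short run), the per-frame salt-bridge
counts, and a P_max of the energy series per Δt* window.

`prime-dmd export --traj traj.h5 --out traj.pdb` writes coarse-grained
PDB models (spheres mapped to N, CA, C and CBX atoms, Aβ numbering
preserved) for visualization.

The default production setup — `prime-dmd init` with no options — is the
8-chain Aβ17–42 system in a (160 Å)³ box (the geometry implies ≈3.24 mM),
cooled from T* = 0.5 toward a production temperature near the
fibrillization point (T* ≈ 0.19–0.205). Reaching actual protofilament
assembly takes event counts far beyond a desktop budget; the package is
tuned for exactness and testability at fragment scale, not for cluster
production runs.

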