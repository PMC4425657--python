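"""Trajectory persistence, energy-series text output and PDB export.

The trajectory container is a versioned HDF5 file holding per-frame
positions, clocks, temperatures, potentials and the active hydrogen-bond
list, together with the run configuration needed to rebuild the topology.
The energy series is written as tab-separated text (t*, E/eps_HB, T*).
PDB export maps the four spheres to atom records N, CA, C and CBX with the
reported residue numbering, one MODEL per frame.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .engine import Frame, RunResult
from .peptide import SystemTopology, build_chain
from .residues import ROLE_CA, ROLE_CO, ROLE_NH, ROLE_R, THREE_LETTER

FORMAT_VERSION = 1


def write_trajectory(path, top: SystemTopology, result: RunResult,
                     box_length: float, metadata: dict | None = None) -> None:
    path = Path(path)
    frames = result.frames
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["sequence"] = top.chains[0].sequence
        f.attrs["n_chains"] = top.n_chains
        f.attrs["numbering_offset"] = top.chains[0].numbering_offset
        f.attrs["box_length"] = float(box_length)
        f.attrs["metadata"] = json.dumps(metadata or {})
        g = f.create_group("frames")
        g.create_dataset("positions",
                         data=np.stack([fr.positions for fr in frames])
                         if frames else np.zeros((0, top.n_spheres, 3)))
        for name in ("time", "tstar", "temperature", "potential"):
            g.create_dataset(name, data=np.array([getattr(fr, name) for fr in frames]))
        bonds = []
        for k, fr in enumerate(frames):
            for nh, co, t0 in fr.hbonds:
                bonds.append((k, nh, co, t0))
        g.create_dataset("hbonds", data=np.array(bonds, dtype=np.float64)
                         if bonds else np.zeros((0, 4)))
        e = f.create_group("energy")
        e.create_dataset("tstar", data=result.energy_tstar)
        e.create_dataset("energy", data=result.energy)
        e.create_dataset("temperature", data=result.energy_temperature)
        f.attrs["collisions"] = result.collisions
        f.attrs["ghosts"] = result.ghosts


def read_trajectory(path, residue_table=None):
    """Returns (top, result, box_length, metadata)."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise ValueError(
                f"unsupported trajectory format version {version} "
                f"(expected {FORMAT_VERSION})")
        chain = build_chain(str(f.attrs["sequence"]), residue_table,
                            numbering_offset=int(f.attrs["numbering_offset"]))
        top = SystemTopology.replicate(chain, int(f.attrs["n_chains"]))
        g = f["frames"]
        pos = g["positions"][...]
        times = g["time"][...]
        tstars = g["tstar"][...]
        temps = g["temperature"][...]
        pots = g["potential"][...]
        braw = g["hbonds"][...]
        per_frame_bonds: dict[int, list] = {}
        for k, nh, co, t0 in braw:
            per_frame_bonds.setdefault(int(k), []).append((int(nh), int(co), float(t0)))
        frames = [Frame(positions=pos[k], time=float(times[k]), tstar=float(tstars[k]),
                        temperature=float(temps[k]), potential=float(pots[k]),
                        hbonds=per_frame_bonds.get(k, []))
                  for k in range(len(times))]
        result = RunResult(frames=frames,
                           energy_tstar=f["energy"]["tstar"][...],
                           energy=f["energy"]["energy"][...],
                           energy_temperature=f["energy"]["temperature"][...],
                           collisions=int(f.attrs["collisions"]),
                           ghosts=int(f.attrs["ghosts"]))
        return top, result, float(f.attrs["box_length"]), json.loads(str(f.attrs["metadata"]))


def write_energy_series(path, result: RunResult) -> None:
    """Tab-separated (t*, E/eps_HB, T*) text file."""
    with open(path, "w") as f:
        f.write("tstar\tenergy\ttemperature\n")
        for t, e, T in zip(result.energy_tstar, result.energy,
                           result.energy_temperature):
            f.write(f"{t:.8g}\t{e:.8g}\t{T:.8g}\n")


def read_energy_series(path):
    data = np.loadtxt(path, skiprows=1)
    data = np.atleast_2d(data)
    return data[:, 0], data[:, 1], data[:, 2]


_ATOM_NAMES = {ROLE_NH: "N", ROLE_CA: "CA", ROLE_CO: "C", ROLE_R: "CBX"}
_ELEMENTS = {ROLE_NH: "N", ROLE_CA: "C", ROLE_CO: "C", ROLE_R: "C"}
_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def export_pdb(path, top: SystemTopology, frames, box_length: float,
               unwrap: bool = True) -> None:
    """Write frames as PDB MODELs with the coarse-grained atom mapping."""
    from .analysis import unwrap_chain
    path = Path(path)
    with open(path, "w") as f:
        f.write("REMARK   coarse-grained 4-sphere peptide model\n")
        f.write("REMARK   spheres: NH->N, CaH->CA, CO->C, side chain->CBX\n")
        for m, fr in enumerate(frames, start=1):
            f.write(f"MODEL     {m:4d}\n")
            serial = 1
            for ci, chain in enumerate(top.chains):
                if unwrap:
                    coords = unwrap_chain(frame_state(fr, box_length), top, ci)
                else:
                    off = top.offsets[ci]
                    coords = fr.positions[off:off + chain.n_spheres]
                for s in range(chain.n_spheres):
                    res = int(chain.residue[s])
                    aa = chain.sequence[res]
                    name = _ATOM_NAMES[int(chain.role[s])]
                    x, y, z = coords[s]
                    f.write(
                        "ATOM  {serial:5d} {name:<4s}{res3:>4s}{chain:>2s}{resnum:4d}    "
                        "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n"
                        .format(serial=serial, name=name, res3=THREE_LETTER[aa],
                                chain=_CHAIN_IDS[ci % 26],
                                resnum=res + chain.numbering_offset,
                                x=x, y=y, z=z, occ=1.0, b=0.0,
                                el=_ELEMENTS[int(chain.role[s])]))
                    serial += 1
                f.write("TER\n")
            f.write("ENDMDL\n")
        f.write("END\n")


def frame_state(frame: Frame, box_length: float):
    """A SystemState (zero velocities) for one stored frame."""
    from .state import SystemState
    return SystemState(frame.positions.copy(),
                       np.zeros_like(frame.positions), box_length,
                       time=frame.time)
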