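"""Structured run configuration with lossless YAML round-trip."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
import yaml

from .peptide import concentration_mM
from .residues import AB17_42, AB17_42_FIRST_RESIDUE, validate_sequence


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation run."""

    sequence: str = AB17_42
    n_chains: int = 8
    box_length: float = 160.0           # Angstrom
    hbond_mode: str = "parallel_preference"
    salt_bridge_enhanced: bool = True
    t_start: float = 0.5                # reduced temperature at start
    t_final: float = 0.2                # production temperature
    cooling_events: int = 0             # collisions spent cooling linearly
    max_events: int = 1_000_000         # pair-event budget
    sample_every: int = 100_000         # frames
    energy_every: int = 1_000           # energy series samples
    thermostat_rate: float = 0.05       # ghost collisions per sphere per time
    seed: int = 0
    numbering_offset: int = AB17_42_FIRST_RESIDUE
    clearance: float | None = None      # initial inter-chain separation

    def __post_init__(self):
        self.sequence = validate_sequence(self.sequence)
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.box_length <= 0:
            raise ValueError("box_length must be > 0")
        if not (self.t_start >= self.t_final > 0):
            raise ValueError("require t_start >= t_final > 0")
        for name in ("max_events", "sample_every", "energy_every"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def concentration_mM(self) -> float:
        return concentration_mM(self.n_chains, self.box_length)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def save(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**data)
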