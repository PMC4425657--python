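"""System state: sphere coordinates and velocities in a periodic cubic box."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SystemState:
    """Positions (Angstrom) and velocities (reduced) of all spheres.

    Velocities are in internal reduced units (Angstrom per internal time,
    with masses in CH3 units and energies in eps_HB, k_B = 1).  Positions
    are kept wrapped into [0, L); all distance computations use the
    minimum-image convention.
    """

    positions: np.ndarray
    velocities: np.ndarray
    box_length: float
    time: float = 0.0

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        if self.positions.shape != self.velocities.shape or self.positions.ndim != 2 \
                or self.positions.shape[1] != 3:
            raise ValueError("positions and velocities must both have shape (n, 3)")
        if not np.all(np.isfinite(self.velocities)):
            raise ValueError("non-finite velocities")

    @property
    def n_spheres(self) -> int:
        return self.positions.shape[0]

    def minimum_image(self, delta: np.ndarray) -> np.ndarray:
        L = self.box_length
        return delta - L * np.round(delta / L)

    def distance(self, i: int, j: int) -> float:
        d = self.minimum_image(self.positions[i] - self.positions[j])
        return float(np.linalg.norm(d))

    def wrap(self) -> None:
        L = self.box_length
        self.positions -= L * np.floor(self.positions / L)

    def copy(self) -> "SystemState":
        return SystemState(self.positions.copy(), self.velocities.copy(),
                           self.box_length, self.time)

    def kinetic_energy(self, mass: np.ndarray) -> float:
        return float(0.5 * np.sum(mass * np.sum(self.velocities ** 2, axis=1)))
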