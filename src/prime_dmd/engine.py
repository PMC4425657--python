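"""Exact event-driven dynamics for discontinuous (square-well) potentials.

Between events every sphere moves ballistically; the engine predicts, for
each sphere, its earliest discontinuity (hard-core collision, well-shell
crossing, bond-window wall, hydrogen-bond attempt, auxiliary-constraint
wall), executes events in strict time order, and re-predicts only the
spheres whose trajectories changed.  Impulses act along the line of
centres, so linear momentum is conserved exactly at every pair event, and
kinetic + potential energy is conserved exactly outside of thermostat
(ghost) collisions, which resample a single sphere's velocity from the
Maxwell-Boltzmann distribution at the scheduled temperature.

Collision counting for schedules and sampling follows executed pair events;
ghost and neighbour-bookkeeping events are excluded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import hbond as hb
from ._kernels import (
    K_DWELL, K_NONE, K_WELL,
    S_AUX, S_BHI, S_BLO, S_CORE, S_HB, S_INNER, S_NONE, S_OUTER, S_WELL,
    pair_surfaces, predict_sphere,
)
from .forcefield import MASS_NH, SIGMA_NH
from .interactions import Interactions
from .state import SystemState

_INF = math.inf


@dataclass(frozen=True)
class ReducedUnits:
    """Reduced time uses the NH united sphere: t* = t/sigma * (k_B T/m)^1/2."""

    sigma: float = SIGMA_NH
    m: float = MASS_NH

    def tstar_rate(self, temperature: float) -> float:
        if temperature <= 0:
            raise ValueError("temperature must be > 0")
        return math.sqrt(temperature / self.m) / self.sigma


def reduced_time(t_internal: float, temperature: float,
                 units: ReducedUnits = ReducedUnits()) -> float:
    return t_internal * units.tstar_rate(temperature)


@dataclass(frozen=True)
class CoolingSchedule:
    """Piecewise-linear cooling in T* against the executed collision count,
    then a constant-temperature production phase."""

    t_start: float = 0.5
    t_final: float = 0.2
    cooling_events: int = 0

    def __post_init__(self):
        if not (self.t_start >= self.t_final > 0):
            raise ValueError("require t_start >= t_final > 0")

    @classmethod
    def constant(cls, temperature: float) -> "CoolingSchedule":
        return cls(t_start=temperature, t_final=temperature, cooling_events=0)

    def temperature(self, collisions: int) -> float:
        if self.cooling_events <= 0 or collisions >= self.cooling_events:
            return self.t_final
        f = collisions / self.cooling_events
        return self.t_start + (self.t_final - self.t_start) * f


@dataclass
class Frame:
    positions: np.ndarray
    time: float
    tstar: float
    temperature: float
    potential: float
    hbonds: list  # (nh, co, formation time)


@dataclass
class RunResult:
    frames: list
    energy_tstar: np.ndarray
    energy: np.ndarray
    energy_temperature: np.ndarray
    collisions: int
    ghosts: int


@dataclass(frozen=True)
class Event:
    time: float
    kind: str          # 'pair', 'ghost', 'neighbor'
    spheres: tuple
    surface: int = S_NONE


def total_energy(state: SystemState, inter: Interactions,
                 registry: hb.HBondRegistry | None = None) -> float:
    """Total interaction (potential) energy in eps_HB.

    Sum of the occupied well depths: side-chain pairs contribute the depth
    of the shell they sit in, each active hydrogen bond contributes -1.
    Pairs exactly on a shell surface are classified to the side they are
    moving toward.
    """
    pos, vel, L = state.positions, state.velocities, state.box_length
    u = 0.0
    n = inter.n_spheres
    kinds, rows, ptype = inter.kinds, inter.rows, inter.ptype
    well_rows = {r for r in range(len(kinds)) if kinds[r] in (K_DWELL, K_WELL)}
    for i in range(n):
        prow = ptype[i, i + 1:]
        js = np.nonzero(np.isin(prow, list(well_rows)))[0] + i + 1
        for j in js:
            row = rows[ptype[i, j]]
            d = pos[i] - pos[j]
            d -= L * np.round(d / L)
            r = float(np.linalg.norm(d))
            b = float(np.dot(d, vel[i] - vel[j]))
            r_eff = r + (1e-9 if b > 0 else -1e-9)
            if kinds[ptype[i, j]] == K_DWELL:
                if r_eff < row[1]:
                    u -= row[3]
                elif r_eff < row[2]:
                    u -= row[4]
            else:  # single square well
                if r_eff < row[1]:
                    u -= row[2]
    if registry is not None:
        u -= len(registry)
    return u


class DMDEngine:
    """Event-driven integrator for one compiled system."""

    def __init__(self, inter: Interactions, state: SystemState,
                 schedule: CoolingSchedule | None = None,
                 thermostat_rate: float = 0.05,
                 seed: int | np.random.SeedSequence | None = 0,
                 neighbor_mode: str = "auto",
                 units: ReducedUnits = ReducedUnits()):
        self.inter = inter
        self.state = state
        self.schedule = schedule
        self.units = units
        self.thermostat_rate = float(thermostat_rate)
        state.wrap()
        n = inter.n_spheres
        if isinstance(seed, np.random.SeedSequence):
            ss = seed
        else:
            ss = np.random.SeedSequence(seed)
        self._rng_thermo, self._rng_misc = (np.random.default_rng(s)
                                            for s in ss.spawn(2))
        self.registry = hb.HBondRegistry(n)
        self.collisions = 0
        self.ghosts = 0
        self.tstar = 0.0
        self.temperature = schedule.temperature(0) if schedule else None
        self.potential = total_energy(state, inter, self.registry)
        #: time integral of the potential energy (exact, event-resolved);
        #: divides by elapsed time to give the time-averaged potential
        self.potential_time_integral = 0.0

        # neighbour bookkeeping
        self._range = inter.max_range() + 1e-9
        L = state.box_length
        nc = int(L / self._range)
        # With >= 7 cells per side a pair can never change periodic image
        # while both spheres remain within one 27-cell neighbourhood, so
        # linear-motion predictions stay exact between crossing events.
        self._use_cells = neighbor_mode == "cells" or (
            neighbor_mode == "auto" and nc >= 7)
        if neighbor_mode == "cells" and nc < 3:
            raise ValueError("box too small for cell lists at this range")
        if not self._use_cells:
            if L <= 2.0 * self._range:
                raise ValueError(
                    "box must exceed twice the interaction range for "
                    "minimum-image event prediction")
            # re-predict each sphere before the pair image can switch
            self._h_dist = 0.45 * (0.5 * L - self._range)
        if self._use_cells:
            self._nc = nc
            self._cellw = L / nc
            self._cell = np.zeros((n, 3), dtype=np.int64)
            self._cell[:] = np.clip((state.positions / self._cellw).astype(np.int64),
                                    0, nc - 1)
        # per-sphere earliest pair event
        self.ev_time = np.full(n, _INF)
        self.ev_j = np.full(n, -1, dtype=np.int64)
        self.ev_surf = np.zeros(n, dtype=np.int64)
        # neighbour events: cell crossings (cells) or re-prediction horizons
        self.nb_time = np.full(n, _INF)
        self._nb_dimdir = np.zeros((n, 2), dtype=np.int64)
        # thermostat events
        self.ghost_time = np.full(n, _INF)
        if self.schedule is not None and self.thermostat_rate > 0:
            self.ghost_time[:] = state.time + self._rng_thermo.exponential(
                1.0 / self.thermostat_rate, size=n)
        self._predict_all()

    # -- prediction ------------------------------------------------------

    def _candidates(self, i: int) -> np.ndarray:
        n = self.inter.n_spheres
        if not self._use_cells:
            return np.arange(n, dtype=np.int64)
        nc = self._nc
        ci = self._cell[i]
        out = []
        members = self._cell_members
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    key = ((ci[0] + dx) % nc, (ci[1] + dy) % nc, (ci[2] + dz) % nc)
                    out.extend(members.get(key, ()))
        return np.array(sorted(set(out)), dtype=np.int64)

    @property
    def _cell_members(self):
        cache = getattr(self, "_cell_members_cache", None)
        if cache is None:
            cache = {}
            for s in range(self.inter.n_spheres):
                cache.setdefault(tuple(self._cell[s]), set()).add(s)
            self._cell_members_cache = cache
        return cache

    def _move_cell(self, i: int, new: np.ndarray) -> None:
        cache = self._cell_members
        cache[tuple(self._cell[i])].discard(i)
        self._cell[i] = new
        cache.setdefault(tuple(new), set()).add(i)

    def _predict_slot(self, i: int) -> None:
        reg = self.registry
        dt, j, s = predict_sphere(
            i, self.state.positions, self.state.velocities, self.state.box_length,
            self.inter.ptype, self.inter.rows, self.inter.kinds,
            self._candidates(i), reg.partner, reg.aux_cnt, reg.aux_j, reg.aux_d)
        self.ev_time[i] = self.state.time + dt
        self.ev_j[i] = j
        self.ev_surf[i] = s

    def _predict_neighbor(self, i: int) -> None:
        v = self.state.velocities[i]
        x = self.state.positions[i]
        if self._use_cells:
            # distances to the next boundary are taken modulo the box so a
            # sphere exactly on (or marginally past) a boundary after
            # wrapping schedules the *next* crossing, not a zero-time loop
            L = self.state.box_length
            best, dim, dr = _INF, 0, 1
            for d in range(3):
                if v[d] > 1e-14:
                    dist = ((self._cell[i, d] + 1) * self._cellw - x[d]) % L
                    t = dist / v[d]
                    if t < best:
                        best, dim, dr = t, d, 1
                elif v[d] < -1e-14:
                    dist = (x[d] - self._cell[i, d] * self._cellw) % L
                    t = dist / -v[d]
                    if t < best:
                        best, dim, dr = t, d, -1
            self.nb_time[i] = self.state.time + best
            self._nb_dimdir[i] = (dim, dr)
        else:
            speed = float(np.linalg.norm(v))
            horizon = self._h_dist / speed if speed > 1e-14 else _INF
            self.nb_time[i] = self.state.time + horizon

    def _predict_all(self) -> None:
        self._cell_members_cache = None
        for i in range(self.inter.n_spheres):
            self._predict_slot(i)
            self._predict_neighbor(i)

    def _repredict(self, spheres) -> None:
        """Re-predict slots for ``spheres`` and every slot referencing them."""
        affected = set(int(s) for s in spheres)
        dependent = np.nonzero(np.isin(self.ev_j, list(affected)))[0]
        for s in sorted(affected | set(int(d) for d in dependent)):
            self._predict_slot(s)
        for s in sorted(affected):
            self._predict_neighbor(s)

    # -- execution -------------------------------------------------------

    def _advance(self, t: float) -> None:
        dt = t - self.state.time
        if dt < 0:
            raise RuntimeError("event time before current clock")
        if dt > 0:
            self.state.positions += self.state.velocities * dt
            self.state.wrap()
            self.potential_time_integral += self.potential * dt
            if self.temperature is not None:
                self.tstar += dt * self.units.tstar_rate(self.temperature)
            self.state.time = t

    def next_event(self) -> Event:
        i_pair = int(np.argmin(self.ev_time))
        i_nb = int(np.argmin(self.nb_time))
        i_gh = int(np.argmin(self.ghost_time))
        t_pair, t_nb, t_gh = (self.ev_time[i_pair], self.nb_time[i_nb],
                              self.ghost_time[i_gh])
        t = min(t_pair, t_nb, t_gh)
        if t == _INF:
            return Event(_INF, "none", ())
        if t_pair <= t:
            return Event(t_pair, "pair", (i_pair, int(self.ev_j[i_pair])),
                         int(self.ev_surf[i_pair]))
        if t_gh <= t:
            return Event(t_gh, "ghost", (i_gh,))
        return Event(t_nb, "neighbor", (i_nb,))

    def step(self) -> Event:
        """Execute the single earliest event; returns it."""
        ev = self.next_event()
        if not math.isfinite(ev.time):
            raise RuntimeError("no future events (empty system?)")
        self._advance(ev.time)
        if ev.kind == "pair":
            self._execute_pair(*ev.spheres, ev.surface)
        elif ev.kind == "ghost":
            self._execute_ghost(ev.spheres[0])
        else:
            self._execute_neighbor(ev.spheres[0])
        return ev

    def _execute_pair(self, i: int, j: int, surf: int) -> None:
        pos, vel, L = self.state.positions, self.state.velocities, self.state.box_length
        mass = self.inter.mass
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= L * math.floor(dx / L + 0.5)
        dy -= L * math.floor(dy / L + 0.5)
        dz -= L * math.floor(dz / L + 0.5)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        rx, ry, rz = dx / r, dy / r, dz / r
        rhat = np.array([rx, ry, rz])
        s = ((vel[i, 0] - vel[j, 0]) * rx + (vel[i, 1] - vel[j, 1]) * ry
             + (vel[i, 2] - vel[j, 2]) * rz)
        mu = mass[i] * mass[j] / (mass[i] + mass[j])
        row = self.inter.row(i, j)
        kind = self.inter.kind(i, j)
        affected = [i, j]
        s_new = s

        def cross(delta_u: float) -> bool:
            """Attempt to cross a step of height delta_u; False -> reflect."""
            nonlocal s_new
            radial_ke = 0.5 * mu * s * s
            if delta_u > 0 and radial_ke <= delta_u:
                s_new = -s
                return False
            s_new = math.copysign(math.sqrt(s * s - 2.0 * delta_u / mu), s)
            self.potential += delta_u
            return True

        if surf in (S_CORE, S_BLO, S_BHI, S_AUX):
            s_new = -s
        elif surf == S_INNER:
            step_h = row[3] - row[4]          # e_inner - e_outer
            cross(step_h if s > 0 else -step_h)
        elif surf == S_OUTER:
            cross(row[4] if s > 0 else -row[4])
        elif surf == S_WELL:
            cross(row[2] if s > 0 else -row[2])
        elif surf == S_HB:
            nh, co = (i, j) if (i, j) in self.inter.hb_aux else (j, i)
            if self.registry.partner[nh] == co:
                if s > 0 and cross(1.0):
                    aux = self.registry.aux_spheres(nh, co)
                    self.registry.remove(nh, co)
                    affected.extend(aux)
            elif s < 0:
                ok, _reason = hb.can_form(self.state, self.inter, self.registry, nh, co)
                if ok:
                    cross(-1.0)
                    self.registry.add(nh, co, self.state.time,
                                      hb.aux_constraint_pairs(self.inter, nh, co))
                    affected.extend(self.registry.aux_spheres(nh, co))
                # ineligible pairs pass through the surface freely
            # outward crossing of an unbonded pair: bookkeeping only
        else:
            raise RuntimeError(f"unexpected surface code {surf}")

        if s_new != s:
            dv = mu * (s_new - s)
            vel[i, 0] += dv / mass[i] * rx
            vel[i, 1] += dv / mass[i] * ry
            vel[i, 2] += dv / mass[i] * rz
            vel[j, 0] -= dv / mass[j] * rx
            vel[j, 1] -= dv / mass[j] * ry
            vel[j, 2] -= dv / mass[j] * rz
        self.collisions += 1
        if self.schedule is not None:
            self.temperature = self.schedule.temperature(self.collisions)
        self._repredict(affected)

    def _execute_ghost(self, i: int) -> None:
        self.ghost_collision(i)
        self.ghost_time[i] = self.state.time + self._rng_thermo.exponential(
            1.0 / self.thermostat_rate)

    def ghost_collision(self, i: int, temperature: float | None = None) -> None:
        """Resample sphere ``i`` from the Maxwell-Boltzmann distribution."""
        T = self.temperature if temperature is None else temperature
        if T is None or T <= 0:
            raise ValueError("ghost collision requires a positive temperature")
        m = self.inter.mass[i]
        self.state.velocities[i] = self._rng_thermo.normal(
            0.0, math.sqrt(T / m), size=3)
        self.ghosts += 1
        self._repredict([i])

    def _execute_neighbor(self, i: int) -> None:
        if self._use_cells:
            dim, dr = self._nb_dimdir[i]
            new = self._cell[i].copy()
            new[dim] = (new[dim] + dr) % self._nc
            self._move_cell(i, new)
        self._predict_slot(i)
        self._predict_neighbor(i)

    # -- driver ----------------------------------------------------------

    def run(self, max_events: int | None = None, max_tstar: float | None = None,
            sample_every: int = 5000, energy_every: int = 500,
            collect_frames: bool = True, validate_every: int | None = None,
            progress: bool = False) -> RunResult:
        if max_events is None and max_tstar is None:
            raise ValueError("need an event budget or a t* limit")
        frames: list[Frame] = []
        e_t, e_u, e_T = [], [], []

        def sample_energy():
            e_t.append(self.tstar)
            e_u.append(self.potential)
            e_T.append(self.temperature if self.temperature is not None else np.nan)

        def sample_frame():
            frames.append(Frame(
                positions=self.state.positions.copy(), time=self.state.time,
                tstar=self.tstar,
                temperature=self.temperature if self.temperature is not None else np.nan,
                potential=self.potential,
                hbonds=[(nh, co, t0) for (nh, co), t0 in self.registry.bonds.items()]))

        sample_energy()
        if collect_frames:
            sample_frame()
        start = self.collisions
        while True:
            if max_events is not None and self.collisions - start >= max_events:
                break
            if max_tstar is not None and self.tstar >= max_tstar:
                break
            ev = self.step()
            if ev.kind != "pair":
                continue
            done = self.collisions - start
            if done % energy_every == 0:
                sample_energy()
            if collect_frames and done % sample_every == 0:
                sample_frame()
            if validate_every and done % validate_every == 0:
                self._check_invariants()
        if collect_frames and (not frames or frames[-1].time != self.state.time):
            sample_frame()
        return RunResult(frames=frames,
                         energy_tstar=np.array(e_t), energy=np.array(e_u),
                         energy_temperature=np.array(e_T),
                         collisions=self.collisions, ghosts=self.ghosts)

    # -- compiled fast path ---------------------------------------------

    def _hb_meta(self):
        cache = getattr(self, "_hb_meta_cache", None)
        if cache is None:
            n = self.inter.n_spheres
            pairs = sorted(self.inter.hb_aux.items())
            hbidx = np.full((n, n), -1, dtype=np.int64)
            hbmeta = np.zeros((max(len(pairs), 1), 6), dtype=np.int64)
            for m, ((nh, co), aux) in enumerate(pairs):
                hbidx[nh, co] = hbidx[co, nh] = m
                hbmeta[m] = (nh, co) + tuple(aux)
            cache = (hbidx, hbmeta)
            self._hb_meta_cache = cache
        return cache

    def run_fast(self, max_events: int, sample_every: int = 100_000,
                 energy_every: int = 1000, collect_frames: bool = True) -> RunResult:
        """Run ``max_events`` pair events through the compiled loop.

        Equivalent to :meth:`run` (identical event sequences when the
        thermostat is off); thermostated runs use an internally seeded RNG
        for ghost collisions.  Requires the all-pairs neighbour mode.
        """
        if self._use_cells:
            raise RuntimeError("compiled loop supports the all-pairs mode only")
        from . import _fastloop
        inter = self.inter
        reg = self.registry
        hbidx, hbmeta = self._hb_meta()
        n = inter.n_spheres
        bond_time = np.full(n, -1.0)
        for (nh, _co), t0 in reg.bonds.items():
            bond_time[nh] = t0
        clock = np.array([self.state.time])
        tstar = np.array([self.tstar])
        potential = np.array([self.potential])
        u_integral = np.array([self.potential_time_integral])
        counters = np.array([self.collisions, self.ghosts], dtype=np.int64)
        if self.schedule is not None:
            t_start, t_final = self.schedule.t_start, self.schedule.t_final
            cooling_events = self.schedule.cooling_events
        else:
            t_start = t_final = 1.0
            cooling_events = 0
        cut4 = np.array(inter.hb_cutoffs if inter.hb_cutoffs else (0.0,) * 4)

        frames: list[Frame] = []
        e_t, e_u, e_T = [], [], []

        def sync_registry():
            reg.bonds = {}
            reg._aux_pairs = {}
            for s in np.nonzero(reg.partner >= 0)[0]:
                p = int(reg.partner[s])
                if (int(s), p) in inter.hb_aux:
                    reg.bonds[(int(s), p)] = float(bond_time[s])
                    reg._aux_pairs[(int(s), p)] = hb.aux_constraint_pairs(
                        inter, int(s), p)
            reg._rebuild_aux()

        def sample_frame():
            frames.append(Frame(
                positions=self.state.positions.copy(), time=self.state.time,
                tstar=self.tstar,
                temperature=self.temperature if self.temperature is not None else np.nan,
                potential=self.potential,
                hbonds=[(nh, co, t0) for (nh, co), t0 in reg.bonds.items()]))

        def sample_energy():
            e_t.append(self.tstar)
            e_u.append(self.potential)
            e_T.append(self.temperature if self.temperature is not None else np.nan)

        sample_energy()
        if collect_frames:
            sample_frame()
        remaining = max_events
        while remaining > 0:
            chunk = int(min(remaining, sample_every))
            n_es = chunk // max(energy_every, 1) + 2
            es_t = np.zeros(n_es)
            es_u = np.zeros(n_es)
            es_T = np.zeros(n_es)
            es_n = np.zeros(1, dtype=np.int64)
            seed = int(self._rng_misc.integers(2 ** 31 - 1))
            status = _fastloop.run_chunk(
                self.state.positions, self.state.velocities, inter.mass,
                self.state.box_length, clock, tstar, potential, u_integral,
                inter.ptype, inter.rows, inter.kinds,
                reg.partner, bond_time,
                reg.aux_cnt, reg.aux_j, reg.aux_d, reg.aux_owner,
                hbidx, hbmeta, cut4,
                self.ev_time, self.ev_j, self.ev_surf, self.nb_time,
                self.ghost_time,
                t_start, t_final, cooling_events, counters,
                max(self.thermostat_rate, 1e-300), self.units.sigma, self.units.m,
                self._h_dist, chunk, seed,
                energy_every, es_t, es_u, es_T, es_n)
            self.state.time = float(clock[0])
            if self.schedule is not None:
                self.tstar = float(tstar[0])
                self.temperature = self.schedule.temperature(int(counters[0]))
            self.potential = float(potential[0])
            self.potential_time_integral = float(u_integral[0])
            self.collisions = int(counters[0])
            self.ghosts = int(counters[1])
            sync_registry()
            k = int(es_n[0])
            e_t.extend(es_t[:k])
            e_u.extend(es_u[:k])
            e_T.extend(es_T[:k])
            if status == _fastloop.OVERFLOW:
                raise RuntimeError("compiled loop overflow (stuck system?)")
            if status == _fastloop.NO_EVENTS:
                raise RuntimeError("no future events (empty system?)")
            remaining -= chunk
            if collect_frames:
                sample_frame()
        return RunResult(frames=frames,
                         energy_tstar=np.array(e_t), energy=np.array(e_u),
                         energy_temperature=np.array(e_T),
                         collisions=self.collisions, ghosts=self.ghosts)

    def _check_invariants(self) -> None:
        dmin = self.inter.min_distance_matrix()
        pos = self.state.positions
        n = self.inter.n_spheres
        for i in range(n):
            d = np.linalg.norm(self.state.minimum_image(pos[i + 1:] - pos[i]), axis=1)
            if np.any(d < dmin[i, i + 1:] - 1e-6):
                j = int(np.argmax(d < dmin[i, i + 1:] - 1e-6)) + i + 1
                raise RuntimeError(
                    f"geometry violation at t={self.state.time:.6g}: "
                    f"spheres ({i}, {j}) at {d.min():.4f} A")

    def total_energy(self) -> float:
        """Tracked kinetic + potential energy (eps_HB)."""
        return self.state.kinetic_energy(self.inter.mass) + self.potential

    # -- checkpointing ---------------------------------------------------

    def checkpoint(self, path) -> None:
        bonds = np.array([(nh, co) for (nh, co) in self.registry.bonds],
                         dtype=np.int64).reshape(-1, 2)
        btimes = np.array(list(self.registry.bonds.values()))
        np.savez(
            path,
            positions=self.state.positions, velocities=self.state.velocities,
            box_length=self.state.box_length, time=self.state.time,
            collisions=self.collisions, ghosts=self.ghosts, tstar=self.tstar,
            potential=self.potential, bonds=bonds, bond_times=btimes,
            ghost_time=self.ghost_time,
            # the scheduled event queues are part of the state: re-predicting
            # them from coordinates reproduces the times only to round-off,
            # not bit-exactly
            ev_time=self.ev_time, ev_j=self.ev_j, ev_surf=self.ev_surf,
            nb_time=self.nb_time, nb_dimdir=self._nb_dimdir,
            cell=self._cell if self._use_cells else np.zeros(0, dtype=np.int64),
            rng_thermo=json.dumps(self._rng_thermo.bit_generator.state),
            rng_misc=json.dumps(self._rng_misc.bit_generator.state),
        )

    @classmethod
    def resume(cls, path, inter: Interactions,
               schedule: CoolingSchedule | None = None,
               thermostat_rate: float = 0.05,
               neighbor_mode: str = "auto",
               units: ReducedUnits = ReducedUnits()) -> "DMDEngine":
        z = np.load(path, allow_pickle=False)
        state = SystemState(z["positions"], z["velocities"],
                            float(z["box_length"]), float(z["time"]))
        eng = cls(inter, state, schedule=schedule, thermostat_rate=thermostat_rate,
                  seed=0, neighbor_mode=neighbor_mode, units=units)
        eng.collisions = int(z["collisions"])
        eng.ghosts = int(z["ghosts"])
        eng.tstar = float(z["tstar"])
        if schedule is not None:
            eng.temperature = schedule.temperature(eng.collisions)
        for (nh, co), t0 in zip(z["bonds"], z["bond_times"]):
            eng.registry.add(int(nh), int(co), float(t0),
                             hb.aux_constraint_pairs(inter, int(nh), int(co)))
        eng.potential = float(z["potential"])
        eng.ghost_time = z["ghost_time"].copy()
        eng.ev_time = z["ev_time"].copy()
        eng.ev_j = z["ev_j"].copy()
        eng.ev_surf = z["ev_surf"].copy()
        eng.nb_time = z["nb_time"].copy()
        eng._nb_dimdir = z["nb_dimdir"].copy()
        if eng._use_cells and z["cell"].size:
            eng._cell = z["cell"].copy()
            eng._cell_members_cache = None
        eng._rng_thermo.bit_generator.state = json.loads(str(z["rng_thermo"]))
        eng._rng_misc.bit_generator.state = json.loads(str(z["rng_misc"]))
        return eng


def predict_pair_event(state: SystemState, inter: Interactions, i: int, j: int,
                       registry: hb.HBondRegistry | None = None):
    """Earliest discontinuity for one pair: (dt, surface code) or None."""
    if i == j:
        raise ValueError("need two distinct spheres")
    d = state.minimum_image(state.positions[i] - state.positions[j])
    v = state.velocities[i] - state.velocities[j]
    bonded = registry is not None and registry.partner[i] == j
    kind = inter.kind(i, j)
    if kind == K_NONE:
        return None
    t, s = pair_surfaces(kind, inter.row(i, j),
                         float(np.dot(d, d)), float(np.dot(d, v)),
                         float(np.dot(v, v)), bonded)
    if not math.isfinite(t):
        return None
    return t, s
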