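"""Independent reference implementations used as test oracles.

A brute-force time-driven integrator for small discontinuous systems (the
engine's event predictions and impulses are checked against it), an
exhaustive band search for the max-population statistic, and closed-form
sphere-overlap areas.  Deliberately simple and slow.
"""

from __future__ import annotations

import math

import numpy as np

# kind codes mirrored from the package (kept literal so the oracle does not
# share code paths with the implementation under test)
K_HARD, K_BOND, K_DWELL, K_WELL = 1, 2, 3, 5


def _surfaces(kind, row):
    """(distance, delta_u_outward) per surface, innermost first.

    ``delta_u_outward`` is the potential change when crossing the surface
    moving outward; infinite walls use math.inf.
    """
    if kind == K_HARD:
        return [(row[0], -math.inf)]          # hard core: impenetrable
    if kind == K_BOND:
        return [(row[0], -math.inf), (row[1], math.inf)]
    if kind == K_WELL:
        return [(row[0], -math.inf), (row[1], row[2])]
    if kind == K_DWELL:
        return [(row[0], -math.inf), (row[1], row[3] - row[4]), (row[2], row[4])]
    raise ValueError(kind)


class TimeDrivenIntegrator:
    """Step-and-bisect integrator for a handful of spheres (no periodicity)."""

    def __init__(self, positions, velocities, masses, pair_spec, dt=1e-3):
        self.pos = np.array(positions, dtype=float)
        self.vel = np.array(velocities, dtype=float)
        self.mass = np.array(masses, dtype=float)
        self.pairs = {tuple(sorted(k)): (v[0], list(v[1:])) for k, v in pair_spec.items()}
        self.dt = dt
        self.time = 0.0
        self.events = []  # (time, i, j, surface_distance)

    def _gap(self, pos, i, j, d):
        return np.linalg.norm(pos[i] - pos[j]) - d

    def _all_keys(self):
        for (i, j), (kind, row) in self.pairs.items():
            for d, du in _surfaces(kind, row):
                yield (i, j, d), du

    def run_until(self, t_end, max_events=10 ** 6):
        # track which side of each surface the pair is on; a sphere landing
        # exactly on a surface is assigned the side it departs toward, so an
        # executed event can never re-trigger at time zero
        sides = {key: self._gap(self.pos, key[0], key[1], key[2]) > 0
                 for key, _du in self._all_keys()}
        while self.time < t_end and len(self.events) < max_events:
            step = min(self.dt, t_end - self.time)
            crossing = None
            for key, du in self._all_keys():
                i, j, d = key
                g1 = self._gap(self.pos + self.vel * step, i, j, d)
                if (g1 > 0) == sides[key]:
                    continue
                lo, hi = 0.0, step
                for _ in range(80):
                    mid = 0.5 * (lo + hi)
                    gm = self._gap(self.pos + self.vel * mid, i, j, d)
                    if (gm > 0) == sides[key]:
                        lo = mid
                    else:
                        hi = mid
                tc = 0.5 * (lo + hi)
                if crossing is None or tc < crossing[0]:
                    crossing = (tc, key, du)
            if crossing is None:
                self.pos += self.vel * step
                self.time += step
                continue
            tc, key, du = crossing
            i, j, d = key
            self.pos += self.vel * tc
            self.time += tc
            s_new = self._impulse(i, j, du)
            # refresh every side from the new positions, then pin the event
            # surface to the side the pair is now moving toward
            for other, _du in self._all_keys():
                sides[other] = self._gap(self.pos, other[0], other[1], other[2]) > 0
            sides[key] = s_new > 0
            self.events.append((self.time, i, j, d))

    def _impulse(self, i, j, du_outward):
        r = self.pos[i] - self.pos[j]
        rhat = r / np.linalg.norm(r)
        s = float(np.dot(self.vel[i] - self.vel[j], rhat))
        mu = self.mass[i] * self.mass[j] / (self.mass[i] + self.mass[j])
        du = du_outward if s > 0 else (-du_outward if np.isfinite(du_outward) else math.inf)
        if not np.isfinite(du) or (du > 0 and 0.5 * mu * s * s <= du):
            s_new = -s
        else:
            s_new = math.copysign(math.sqrt(s * s - 2.0 * du / mu), s)
        dv = mu * (s_new - s)
        self.vel[i] += dv / self.mass[i] * rhat
        self.vel[j] -= dv / self.mass[j] * rhat
        return s_new


def brute_force_pmax(energies, halfwidth):
    """Exhaustive band search: best (count, centre) over sample centres."""
    e = np.asarray(energies, float)
    best_count, best_e = 0, None
    for c in sorted(e):
        count = int(np.count_nonzero(np.abs(e - c) <= halfwidth))
        if count > best_count:
            best_count, best_e = count, c
    return best_count / len(e), best_e


def equal_spheres_exposed_area(radius, distance):
    """Exposed area per sphere for two equal spheres of ``radius`` whose
    centres are ``distance`` apart (spherical-cap overlap)."""
    if distance >= 2 * radius:
        return 4 * math.pi * radius ** 2
    cap_height = radius - distance / 2.0
    return 4 * math.pi * radius ** 2 - 2 * math.pi * radius * cap_height
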