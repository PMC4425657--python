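"""Compiled main loop: executes many events per call without Python overhead.

Semantically identical to the pure-Python event loop in ``engine.py``
(same predictions, same impulse rules, same tie-breaks) for thermostat-free
dynamics; thermostated runs draw their ghost-collision randomness from
numba's internal RNG (seeded per chunk) instead of the engine's Generator
streams, so the two paths agree exactly only when the thermostat is off.
Only the all-pairs (brute) neighbour mode is supported here; the engine
falls back to the Python loop for cell-list runs.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ._kernels import (S_AUX, S_BHI, S_BLO, S_CORE, S_HB, S_INNER,
                       S_OUTER, S_WELL, predict_sphere)

_INF = math.inf

# status codes
OK, NO_EVENTS, OVERFLOW = 0, 1, 2


@njit(cache=True)
def _min_image(d, L):
    return d - L * math.floor(d / L + 0.5)


@njit(cache=True)
def _predict_nb(i, vel, h_dist):
    vx, vy, vz = vel[i, 0], vel[i, 1], vel[i, 2]
    speed = math.sqrt(vx * vx + vy * vy + vz * vz)
    if speed < 1e-14:
        return _INF
    return h_dist / speed


@njit(cache=True)
def _schedule_T(collisions, t_start, t_final, cooling_events):
    if cooling_events <= 0 or collisions >= cooling_events:
        return t_final
    f = collisions / cooling_events
    return t_start + (t_final - t_start) * f


@njit(cache=True)
def _remove_aux(sphere, owner, aux_cnt, aux_j, aux_d, aux_owner):
    k = 0
    while k < aux_cnt[sphere]:
        if aux_owner[sphere, k] == owner:
            last = aux_cnt[sphere] - 1
            aux_j[sphere, k] = aux_j[sphere, last]
            aux_d[sphere, k] = aux_d[sphere, last]
            aux_owner[sphere, k] = aux_owner[sphere, last]
            aux_cnt[sphere] = last
        else:
            k += 1


@njit(cache=True)
def _add_aux(a, b, d, owner, aux_cnt, aux_j, aux_d, aux_owner):
    for s, o in ((a, b), (b, a)):
        k = aux_cnt[s]
        if k >= aux_j.shape[1]:
            return False
        aux_j[s, k] = o
        aux_d[s, k] = d
        aux_owner[s, k] = owner
        aux_cnt[s] = k + 1
    return True


@njit(cache=True)
def run_chunk(pos, vel, mass, L,
              clock, tstar, potential, u_integral,  # 1-element float64 arrays
              ptype, rows, kinds,
              partner, bond_time,
              aux_cnt, aux_j, aux_d, aux_owner,
              hbidx, hbmeta, cut4,
              ev_time, ev_j, ev_surf, nb_time, ghost_time,
              t_start, t_final, cooling_events, counters,  # counters: [collisions, ghosts]
              ghost_rate, sigma_nh, m_nh, h_dist,
              n_target, seed,
              es_every, es_t, es_u, es_T, es_n):
    """Execute pair events until ``n_target`` more collisions have run."""
    np.random.seed(seed)
    n = pos.shape[0]
    cand = np.arange(n)
    done = 0
    guard = 0
    max_steps = 1000 * n_target + 1000
    T = _schedule_T(counters[0], t_start, t_final, cooling_events)
    while done < n_target:
        guard += 1
        if guard > max_steps:
            return OVERFLOW
        # earliest event over the three queues; pair wins ties, then ghost
        best_t = _INF
        which = -1
        ib = -1
        for i in range(n):
            if ev_time[i] < best_t:
                best_t = ev_time[i]
                which = 0
                ib = i
        for i in range(n):
            if ghost_time[i] < best_t:
                best_t = ghost_time[i]
                which = 1
                ib = i
        for i in range(n):
            if nb_time[i] < best_t:
                best_t = nb_time[i]
                which = 2
                ib = i
        if which < 0:
            return NO_EVENTS
        # advance everyone ballistically
        dt = best_t - clock[0]
        if dt > 0.0:
            for s in range(n):
                for d in range(3):
                    x = pos[s, d] + vel[s, d] * dt
                    x -= L * math.floor(x / L)
                    pos[s, d] = x
            u_integral[0] += potential[0] * dt
            tstar[0] += dt * math.sqrt(T / m_nh) / sigma_nh
            clock[0] = best_t

        if which == 1:
            # ghost collision: Maxwell-Boltzmann resample of one sphere
            std = math.sqrt(T / mass[ib])
            vel[ib, 0] = np.random.normal(0.0, std)
            vel[ib, 1] = np.random.normal(0.0, std)
            vel[ib, 2] = np.random.normal(0.0, std)
            counters[1] += 1
            ghost_time[ib] = clock[0] + np.random.exponential(1.0 / ghost_rate)
            t0, j0, s0 = predict_sphere(ib, pos, vel, L, ptype, rows, kinds,
                                        cand, partner, aux_cnt, aux_j, aux_d)
            ev_time[ib] = clock[0] + t0
            ev_j[ib] = j0
            ev_surf[ib] = s0
            for s in range(n):
                if s != ib and ev_j[s] == ib:
                    t0, j0, s0 = predict_sphere(s, pos, vel, L, ptype, rows, kinds,
                                                cand, partner, aux_cnt, aux_j, aux_d)
                    ev_time[s] = clock[0] + t0
                    ev_j[s] = j0
                    ev_surf[s] = s0
            nb_time[ib] = clock[0] + _predict_nb(ib, vel, h_dist)
            continue
        if which == 2:
            # re-prediction horizon (minimum-image guard)
            t0, j0, s0 = predict_sphere(ib, pos, vel, L, ptype, rows, kinds,
                                        cand, partner, aux_cnt, aux_j, aux_d)
            ev_time[ib] = clock[0] + t0
            ev_j[ib] = j0
            ev_surf[ib] = s0
            nb_time[ib] = clock[0] + _predict_nb(ib, vel, h_dist)
            continue

        # pair event
        i = ib
        j = ev_j[i]
        surf = ev_surf[i]
        dx = _min_image(pos[i, 0] - pos[j, 0], L)
        dy = _min_image(pos[i, 1] - pos[j, 1], L)
        dz = _min_image(pos[i, 2] - pos[j, 2], L)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        rx, ry, rz = dx / r, dy / r, dz / r
        svel = ((vel[i, 0] - vel[j, 0]) * rx + (vel[i, 1] - vel[j, 1]) * ry
                + (vel[i, 2] - vel[j, 2]) * rz)
        mu = mass[i] * mass[j] / (mass[i] + mass[j])
        row = rows[ptype[i, j]]
        s_new = svel
        n_aff = 2
        aff = np.empty(8, dtype=np.int64)
        aff[0] = i
        aff[1] = j

        if surf == S_CORE or surf == S_BLO or surf == S_BHI or surf == S_AUX:
            s_new = -svel
        elif surf == S_INNER or surf == S_OUTER or surf == S_WELL:
            if surf == S_INNER:
                du = row[3] - row[4]
            elif surf == S_OUTER:
                du = row[4]
            else:
                du = row[2]
            if svel <= 0.0:
                s_new = -math.sqrt(svel * svel + 2.0 * du / mu)
                potential[0] -= du
            else:
                if 0.5 * mu * svel * svel > du:
                    s_new = math.sqrt(svel * svel - 2.0 * du / mu)
                    potential[0] += du
                else:
                    s_new = -svel
        elif surf == S_HB:
            m = hbidx[i, j]
            nh = hbmeta[m, 0]
            co = hbmeta[m, 1]
            ca_j = hbmeta[m, 2]
            n_j1 = hbmeta[m, 3]
            ca_i = hbmeta[m, 4]
            c_i1 = hbmeta[m, 5]
            if partner[nh] == co:
                if svel > 0.0:
                    if 0.5 * mu * svel * svel > 1.0:
                        s_new = math.sqrt(svel * svel - 2.0 / mu)
                        potential[0] += 1.0
                        partner[nh] = -1
                        partner[co] = -1
                        bond_time[nh] = -1.0
                        for s in (nh, co, ca_j, n_j1, ca_i, c_i1):
                            _remove_aux(s, nh, aux_cnt, aux_j, aux_d, aux_owner)
                        aff[2] = ca_j
                        aff[3] = n_j1
                        aff[4] = ca_i
                        aff[5] = c_i1
                        n_aff = 6
                    else:
                        s_new = -svel
            elif svel < 0.0:
                if partner[nh] < 0 and partner[co] < 0:
                    ok = True
                    aux4 = ((nh, ca_j), (nh, n_j1), (co, ca_i), (co, c_i1))
                    for k in range(4):
                        a, b = aux4[k]
                        ax = _min_image(pos[a, 0] - pos[b, 0], L)
                        ay = _min_image(pos[a, 1] - pos[b, 1], L)
                        az = _min_image(pos[a, 2] - pos[b, 2], L)
                        if math.sqrt(ax * ax + ay * ay + az * az) > cut4[k]:
                            ok = False
                            break
                    if ok:
                        s_new = -math.sqrt(svel * svel + 2.0 / mu)
                        potential[0] -= 1.0
                        partner[nh] = co
                        partner[co] = nh
                        bond_time[nh] = clock[0]
                        for k in range(4):
                            a, b = aux4[k]
                            if not _add_aux(a, b, cut4[k], nh,
                                            aux_cnt, aux_j, aux_d, aux_owner):
                                return OVERFLOW
                        aff[2] = ca_j
                        aff[3] = n_j1
                        aff[4] = ca_i
                        aff[5] = c_i1
                        n_aff = 6

        if s_new != svel:
            dv = mu * (s_new - svel)
            vel[i, 0] += dv / mass[i] * rx
            vel[i, 1] += dv / mass[i] * ry
            vel[i, 2] += dv / mass[i] * rz
            vel[j, 0] -= dv / mass[j] * rx
            vel[j, 1] -= dv / mass[j] * ry
            vel[j, 2] -= dv / mass[j] * rz

        counters[0] += 1
        done += 1
        T = _schedule_T(counters[0], t_start, t_final, cooling_events)

        # re-predict affected spheres and every slot referencing them
        for s in range(n):
            redo = False
            for a in range(n_aff):
                if s == aff[a] or ev_j[s] == aff[a]:
                    redo = True
                    break
            if redo:
                t0, j0, s0 = predict_sphere(s, pos, vel, L, ptype, rows, kinds,
                                            cand, partner, aux_cnt, aux_j, aux_d)
                ev_time[s] = clock[0] + t0
                ev_j[s] = j0
                ev_surf[s] = s0
        for a in range(n_aff):
            nb_time[aff[a]] = clock[0] + _predict_nb(aff[a], vel, h_dist)

        if es_every > 0 and done % es_every == 0:
            k = es_n[0]
            if k < es_t.shape[0]:
                es_t[k] = tstar[0]
                es_u[k] = potential[0]
                es_T[k] = T
                es_n[0] = k + 1
    return OK
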