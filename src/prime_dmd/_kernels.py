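"""Numba kernels for event prediction.

Motion between events is ballistic, so the time to a radial discontinuity
surface at distance ``d`` is a root of ``|r + v t| = d``:

    t = (-b -/+ sqrt(b^2 - v^2 (r^2 - d^2))) / v^2,   b = r . v

The '-' root is the approach from outside, the '+' root the outward
crossing from inside.  A sphere sitting numerically on a surface is
classified to the side it is moving toward (a 1e-9 A shift along the sign
of the radial velocity), which makes re-predictions immediately after an
executed event unambiguous.
"""

from __future__ import annotations

import math

from numba import njit

# surface codes
S_NONE, S_CORE, S_INNER, S_OUTER, S_BLO, S_BHI, S_HB, S_AUX, S_WELL = range(9)

# kind codes (mirror interactions.py)
K_NONE, K_HARD, K_BOND, K_DWELL, K_HBCAND, K_WELL = 0, 1, 2, 3, 4, 5

_EPS = 1e-9
_INF = math.inf


@njit(cache=True, inline="always")
def _approach(r2, b, v2, d):
    """Time to reach |r| = d from outside (requires closing motion)."""
    if b >= 0.0 or d <= 0.0:
        return _INF
    disc = b * b - v2 * (r2 - d * d)
    if disc <= 0.0:
        return _INF
    t = (-b - math.sqrt(disc)) / v2
    return t if t >= 0.0 else _INF

@njit(cache=True, inline="always")
def _outward(r2, b, v2, d):
    """Time to reach |r| = d from inside (always reached if v != 0)."""
    disc = b * b - v2 * (r2 - d * d)
    if disc < 0.0:
        return _INF
    t = (-b + math.sqrt(disc)) / v2
    return t if t > 0.0 else _INF


@njit(cache=True)
def pair_surfaces(kind, row, r2, b, v2, bonded):
    """Earliest surface crossing (dt, surface) for one pair."""
    if v2 <= 0.0:
        return _INF, S_NONE
    r = math.sqrt(r2)
    # side-of-surface tie break: nudge along the radial motion
    r_eff = r + (_EPS if b > 0.0 else -_EPS)
    best_t, best_s = _INF, S_NONE
    if kind == K_HARD:
        d = row[0]
        if r_eff > d:
            best_t, best_s = _approach(r2, b, v2, d), S_CORE
    elif kind == K_BOND:
        lo, hi = row[0], row[1]
        if r_eff > lo:
            t = _approach(r2, b, v2, lo)
            if t < best_t:
                best_t, best_s = t, S_BLO
        if r_eff < hi:
            t = _outward(r2, b, v2, hi)
            if t < best_t:
                best_t, best_s = t, S_BHI
    elif kind == K_DWELL:
        core, din, dout = row[0], row[1], row[2]
        if r_eff > dout:
            best_t, best_s = _approach(r2, b, v2, dout), S_OUTER
        elif r_eff > din:
            t1 = _approach(r2, b, v2, din)
            t2 = _outward(r2, b, v2, dout)
            if t1 <= t2:
                best_t, best_s = t1, S_INNER
            else:
                best_t, best_s = t2, S_OUTER
        else:
            t1 = _approach(r2, b, v2, core)
            t2 = _outward(r2, b, v2, din)
            if t1 <= t2:
                best_t, best_s = t1, S_CORE
            else:
                best_t, best_s = t2, S_INNER
    elif kind == K_HBCAND:
        core, dhb = row[0], row[1]
        if not bonded and r_eff > dhb:
            best_t, best_s = _approach(r2, b, v2, dhb), S_HB
        elif r_eff <= dhb:
            t1 = _approach(r2, b, v2, core)
            t2 = _outward(r2, b, v2, dhb)
            if t1 <= t2:
                best_t, best_s = t1, S_CORE
            else:
                best_t, best_s = t2, S_HB
    elif kind == K_WELL:
        core, d = row[0], row[1]
        if r_eff > d:
            best_t, best_s = _approach(r2, b, v2, d), S_WELL
        else:
            t1 = _approach(r2, b, v2, core)
            t2 = _outward(r2, b, v2, d)
            if t1 <= t2:
                best_t, best_s = t1, S_CORE
            else:
                best_t, best_s = t2, S_WELL
    return best_t, best_s


@njit(cache=True)
def predict_sphere(i, pos, vel, L, ptype, rows, kinds,
                   cand, hb_partner, aux_cnt, aux_j, aux_d):
    """Earliest pair event for sphere ``i`` over candidate partners.

    Returns (dt, partner, surface); candidates must be sorted ascending so
    that exact ties resolve to the lowest partner id deterministically.
    """
    best_t, best_j, best_s = _INF, -1, S_NONE
    for idx in range(cand.shape[0]):
        j = cand[idx]
        if j == i:
            continue
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= L * math.floor(dx / L + 0.5)
        dy -= L * math.floor(dy / L + 0.5)
        dz -= L * math.floor(dz / L + 0.5)
        vx = vel[i, 0] - vel[j, 0]
        vy = vel[i, 1] - vel[j, 1]
        vz = vel[i, 2] - vel[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        v2 = vx * vx + vy * vy + vz * vz
        b = dx * vx + dy * vy + dz * vz
        p = ptype[i, j]
        kind = kinds[p]
        t, s = _INF, S_NONE
        if kind != K_NONE:
            t, s = pair_surfaces(kind, rows[p], r2, b, v2, hb_partner[i] == j)
        # active auxiliary constraint wall (outer window from a hydrogen bond)
        for k in range(aux_cnt[i]):
            if aux_j[i, k] == j and v2 > 0.0:
                d = aux_d[i, k]
                r = math.sqrt(r2)
                if r + (_EPS if b > 0.0 else -_EPS) < d:
                    t2 = _outward(r2, b, v2, d)
                    if t2 < t:
                        t, s = t2, S_AUX
        if t < best_t:
            best_t, best_j, best_s = t, j, s
    return best_t, best_j, best_s
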