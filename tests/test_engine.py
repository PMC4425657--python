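"""Event-driven engine: predictions, impulses, conservation, bookkeeping."""

import numpy as np
import pytest

from prime_dmd import (CoolingSchedule, DMDEngine, SystemTopology, SystemState,
                       build_chain, compile_interactions,
                       generate_initial_configuration, reduced_time,
                       total_energy, validate_geometry)
from prime_dmd.engine import ReducedUnits, predict_pair_event
from prime_dmd.fixtures import two_sphere_well_pair
from prime_dmd.interactions import K_HARD, K_WELL, make_custom_interactions
from prime_dmd._kernels import S_CORE, S_WELL


def _pair(inter_state):
    inter, state = inter_state
    return DMDEngine(inter, state, schedule=None, neighbor_mode="brute")


class TestPredictPairEvent:
    def test_head_on_hard_spheres_analytic(self):
        inter = make_custom_interactions([1.0, 1.0], {(0, 1): (K_HARD, 3.0)})
        st = SystemState(np.array([[5.0, 10, 10], [13.0, 10, 10]]),
                         np.array([[0.5, 0, 0], [-0.5, 0, 0]]), 40.0)
        dt, surf = predict_pair_event(st, inter, 0, 1)
        assert surf == S_CORE
        assert dt == pytest.approx((8.0 - 3.0) / 1.0)

    def test_receding_pair_has_no_event(self):
        inter = make_custom_interactions([1.0, 1.0], {(0, 1): (K_WELL, 3.0, 4.5, 1.0)})
        st = SystemState(np.array([[5.0, 10, 10], [11.0, 10, 10]]),
                         np.array([[-0.2, 0, 0], [0.2, 0, 0]]), 40.0)
        assert predict_pair_event(st, inter, 0, 1) is None

    def test_trapped_pair_hits_well_boundary(self):
        # inside the well moving out with too little radial kinetic energy:
        # the engine must schedule the boundary event at the quadratic root
        inter, st = two_sphere_well_pair(separation=4.0, closing_speed=-0.4)
        dt, surf = predict_pair_event(st, inter, 0, 1)
        assert surf == S_WELL
        # |r + v t| = 4.5 with r = 4, closing speed -0.4 (receding)
        assert dt == pytest.approx((4.5 - 4.0) / 0.4)

    def test_identical_sphere_rejected(self):
        inter, st = two_sphere_well_pair()
        with pytest.raises(ValueError):
            predict_pair_event(st, inter, 1, 1)


class TestImpulses:
    def test_equal_mass_head_on_exchanges_velocities(self):
        inter = make_custom_interactions([1.0, 1.0], {(0, 1): (K_HARD, 3.0)})
        st = SystemState(np.array([[5.0, 10, 10], [10.0, 10, 10]]),
                         np.array([[0.7, 0, 0], [-0.1, 0, 0]]), 40.0)
        eng = DMDEngine(inter, st, schedule=None, neighbor_mode="brute")
        eng.step()
        assert st.velocities[0] == pytest.approx([-0.1, 0, 0])
        assert st.velocities[1] == pytest.approx([0.7, 0, 0])

    def test_capture_converts_well_depth_to_kinetic_energy(self):
        depth = 0.7 * 0.205  # outer-shell capture of the F-F pair
        inter, st = two_sphere_well_pair(depth=depth, masses=(6.061, 6.061))
        eng = DMDEngine(inter, st, schedule=None, neighbor_mode="brute")
        ke0 = st.kinetic_energy(inter.mass)
        eng.step()  # capture at the well surface
        assert st.kinetic_energy(inter.mass) - ke0 == pytest.approx(depth)
        assert eng.potential == pytest.approx(-depth)

    def test_inner_capture_releases_step_between_shells(self):
        # entering the deep inner shell releases (1.3 - 0.7) x eps
        from prime_dmd.interactions import K_DWELL
        inter = make_custom_interactions(
            [6.061, 6.061],
            {(0, 1): (K_DWELL, 3.0, 4.0, 5.0, 1.3 * 0.205, 0.7 * 0.205)})
        st = SystemState(np.array([[8.0, 10, 10], [14.0, 10, 10]]),
                         np.array([[0.3, 0, 0], [-0.3, 0, 0]]), 40.0)
        eng = DMDEngine(inter, st, schedule=None, neighbor_mode="brute")
        eng.step()  # outer capture at 5.0
        ke1 = st.kinetic_energy(inter.mass)
        eng.step()  # inner capture at 4.0
        assert st.kinetic_energy(inter.mass) - ke1 == pytest.approx(0.6 * 0.205)

    def test_insufficient_escape_reflects_radial_component(self):
        inter, st = two_sphere_well_pair(depth=5.0, separation=4.0,
                                         closing_speed=-0.2)
        st.velocities[0][1] = 0.13  # add a tangential component
        eng = DMDEngine(inter, st, schedule=None, neighbor_mode="brute")
        v_pre = (st.velocities[0] - st.velocities[1]).copy()
        eng.step()  # escape attempt fails at the well surface
        rhat = st.minimum_image(st.positions[0] - st.positions[1])
        rhat = rhat / np.linalg.norm(rhat)
        v_post = st.velocities[0] - st.velocities[1]
        # radial relative component reversed, tangential untouched
        assert float(v_post @ rhat) == pytest.approx(-float(v_pre @ rhat))
        assert np.allclose(v_post - (v_post @ rhat) * rhat,
                           v_pre - (v_pre @ rhat) * rhat, atol=1e-12)

    def test_momentum_conserved_every_event(self, ff):
        chain = build_chain("KDAF", ff.residues)
        top = SystemTopology.replicate(chain, 2)
        rng = np.random.default_rng(8)
        st = generate_initial_configuration(top, 26.0, 0.5, rng, ff=ff,
                                            clearance=5.0)
        inter = compile_interactions(top, ff)
        eng = DMDEngine(inter, st, schedule=None, neighbor_mode="brute")
        p0 = (inter.mass[:, None] * st.velocities).sum(axis=0)
        for _ in range(800):
            eng.step()
            p = (inter.mass[:, None] * st.velocities).sum(axis=0)
            assert np.abs(p - p0).max() < 1e-12 * max(1.0, np.abs(p0).max())


class TestGhostThermostat:
    def test_mean_kinetic_energy_at_temperature(self):
        inter, st = two_sphere_well_pair()
        eng = DMDEngine(inter, st, schedule=CoolingSchedule.constant(0.20),
                        thermostat_rate=1.0, neighbor_mode="brute", seed=4)
        samples = []
        for _ in range(4000):
            eng.ghost_collision(0)
            v = st.velocities[0]
            samples.append(0.5 * inter.mass[0] * float(v @ v))
        assert np.mean(samples) == pytest.approx(1.5 * 0.20, rel=0.05)

    def test_zero_temperature_rejected(self):
        inter, st = two_sphere_well_pair()
        eng = DMDEngine(inter, st, schedule=None, neighbor_mode="brute")
        with pytest.raises(ValueError):
            eng.ghost_collision(0, temperature=0.0)

    def test_thermostat_reproducible_under_seed(self):
        inter, st = two_sphere_well_pair()
        out = []
        for _ in range(2):
            eng = DMDEngine(inter, st.copy(),
                            schedule=CoolingSchedule.constant(0.3),
                            thermostat_rate=0.5, neighbor_mode="brute", seed=11)
            for _ in range(500):
                eng.step()
            out.append(eng.state.velocities.copy())
        assert np.array_equal(out[0], out[1])


class TestRun:
    def test_zero_budget_returns_initial_state(self):
        inter, st = two_sphere_well_pair()
        pos0 = st.positions.copy()
        eng = DMDEngine(inter, st, schedule=None, neighbor_mode="brute")
        res = eng.run(max_events=0)
        assert np.array_equal(st.positions, pos0)
        assert res.collisions == 0

    def test_cooling_temperature_monotone(self):
        inter, st = two_sphere_well_pair()
        eng = DMDEngine(inter, st, schedule=CoolingSchedule(0.5, 0.2, 30_000),
                        thermostat_rate=0.5, neighbor_mode="brute", seed=3)
        res = eng.run_fast(40_000, collect_frames=False, energy_every=200)
        temps = res.energy_temperature
        assert np.all(np.diff(temps) <= 1e-12)
        assert temps[0] == pytest.approx(0.5, abs=0.01)
        assert temps[-1] == pytest.approx(0.2)

    def test_tracked_potential_matches_recomputation(self, ff):
        chain = build_chain("KDFA", ff.residues)
        top = SystemTopology.replicate(chain, 2)
        rng = np.random.default_rng(2)
        st = generate_initial_configuration(top, 26.0, 0.4, rng, ff=ff,
                                            clearance=5.0)
        inter = compile_interactions(top, ff)
        eng = DMDEngine(inter, st, schedule=CoolingSchedule.constant(0.3),
                        thermostat_rate=0.1, neighbor_mode="brute", seed=5)
        eng.run_fast(60_000, collect_frames=False, energy_every=10 ** 9)
        assert eng.potential == pytest.approx(
            total_energy(st, inter, eng.registry), abs=1e-9)

    def test_constraints_hold_along_a_run(self, ff):
        chain = build_chain("AFADKA", ff.residues)
        top = SystemTopology.replicate(chain, 2)
        rng = np.random.default_rng(4)
        st = generate_initial_configuration(top, 28.0, 0.4, rng, ff=ff,
                                            clearance=5.0)
        inter = compile_interactions(top, ff)
        eng = DMDEngine(inter, st, schedule=CoolingSchedule.constant(0.25),
                        thermostat_rate=0.05, neighbor_mode="brute", seed=6)
        from prime_dmd import chirality_sign
        for _ in range(5):
            eng.run_fast(20_000, collect_frames=False, energy_every=10 ** 9)
            assert validate_geometry(st, top, ff) == []
            labels = {chirality_sign(st, top, c, k)
                      for c in range(2) for k in range(6)}
            assert "D" not in labels


class TestFastLoopEquivalence:
    def test_fast_and_reference_paths_bit_identical(self, ff):
        """Without a thermostat the compiled loop must replay the exact
        event sequence of the pure-Python loop."""
        chain = build_chain("AAAAA", ff.residues)
        top = SystemTopology.replicate(chain, 2)
        rng = np.random.default_rng(3)
        st = generate_initial_configuration(top, 24.0, 0.4, rng, ff=ff,
                                            clearance=5.0)
        inter = compile_interactions(top, ff)
        e1 = DMDEngine(inter, st.copy(), schedule=None, neighbor_mode="brute")
        e2 = DMDEngine(inter, st.copy(), schedule=None, neighbor_mode="brute")
        n = 0
        while n < 15_000:
            if e1.step().kind == "pair":
                n += 1
        e2.run_fast(15_000, collect_frames=False, energy_every=10 ** 9)
        assert np.array_equal(e1.state.positions, e2.state.positions)
        assert np.array_equal(e1.state.velocities, e2.state.velocities)
        assert e1.state.time == e2.state.time
        assert e1.potential == e2.potential


class TestNeighborModes:
    @staticmethod
    def _random_gas(seed=0, n=40, L=24.0):
        rng = np.random.default_rng(seed)
        pairs = {(i, j): (K_WELL, 2.0, 3.0, 0.5)
                 for i in range(n) for j in range(i + 1, n)}
        inter = make_custom_interactions(np.ones(n), pairs)
        st = SystemState(rng.uniform(0, L, (n, 3)), rng.normal(0, 0.4, (n, 3)), L)
        return inter, st

    def test_cell_and_brute_predictions_agree_exactly(self):
        """From the same state, the cell-list engine predicts exactly the
        same event as the all-pairs engine whenever the partner lies inside
        the 27-cell neighbourhood, and never predicts anything earlier."""
        inter, st = self._random_gas()
        brute = DMDEngine(inter, st.copy(), schedule=None, neighbor_mode="brute")
        cells = DMDEngine(inter, st.copy(), schedule=None, neighbor_mode="cells")
        assert cells._use_cells and not brute._use_cells
        n = inter.n_spheres
        compared = 0
        for i in range(n):
            neighbourhood = set(int(x) for x in cells._candidates(i))
            if int(brute.ev_j[i]) in neighbourhood:
                assert cells.ev_time[i] == brute.ev_time[i]
                assert cells.ev_j[i] == brute.ev_j[i]
                assert cells.ev_surf[i] == brute.ev_surf[i]
                compared += 1
            else:
                # distant partners are discovered later via cell crossings
                assert cells.ev_time[i] >= brute.ev_time[i]
        assert compared > 5

    def test_cell_and_brute_dynamics_agree(self):
        """Both modes execute the same collisions; states agree to within
        chaos-amplified round-off over a few hundred collisions."""
        inter, st = self._random_gas()
        engines = {mode: DMDEngine(inter, st.copy(), schedule=None,
                                   neighbor_mode=mode)
                   for mode in ("brute", "cells")}
        for eng in engines.values():
            while eng.collisions < 300:
                eng.step()
        a, b = engines["brute"], engines["cells"]
        dp = np.abs(a.state.positions - b.state.positions)
        dp = np.minimum(dp, a.state.box_length - dp)
        assert dp.max() < 1e-4
        assert np.abs(a.state.velocities - b.state.velocities).max() < 1e-4

    def test_box_below_twice_range_rejected(self):
        inter = make_custom_interactions([1.0, 1.0], {(0, 1): (K_WELL, 3.0, 6.0, 1.0)})
        st = SystemState(np.array([[1.0, 1, 1], [5.0, 5, 5]]),
                         np.zeros((2, 3)), 11.0)
        with pytest.raises(ValueError, match="twice the interaction range"):
            DMDEngine(inter, st, schedule=None, neighbor_mode="brute")


class TestCheckpoint:
    def test_restart_continues_identically(self, ff, tmp_path):
        chain = build_chain("AAAA", ff.residues)
        top = SystemTopology.replicate(chain, 2)
        rng = np.random.default_rng(9)
        st = generate_initial_configuration(top, 24.0, 0.4, rng, ff=ff,
                                            clearance=5.0)
        inter = compile_interactions(top, ff)
        sched = CoolingSchedule.constant(0.3)

        full = DMDEngine(inter, st.copy(), schedule=sched, thermostat_rate=0.2,
                         neighbor_mode="brute", seed=13)
        half = DMDEngine(inter, st.copy(), schedule=sched, thermostat_rate=0.2,
                         neighbor_mode="brute", seed=13)
        for _ in range(3000):
            full.step()
        for _ in range(1500):
            half.step()
        path = tmp_path / "ckpt.npz"
        half.checkpoint(path)
        resumed = DMDEngine.resume(path, inter, schedule=sched,
                                   thermostat_rate=0.2, neighbor_mode="brute")
        for _ in range(1500):
            resumed.step()
        assert np.array_equal(full.state.positions, resumed.state.positions)
        assert np.array_equal(full.state.velocities, resumed.state.velocities)
        assert full.collisions == resumed.collisions


class TestReducedUnits:
    def test_zero_time_maps_to_zero(self):
        assert reduced_time(0.0, 0.2) == 0.0

    def test_doubling_sigma_halves_tstar(self):
        u1 = ReducedUnits(sigma=3.3, m=1.0)
        u2 = ReducedUnits(sigma=6.6, m=1.0)
        assert reduced_time(5.0, 0.2, u1) == pytest.approx(
            2 * reduced_time(5.0, 0.2, u2))

    def test_linear_in_time(self):
        assert reduced_time(10.0, 0.3) == pytest.approx(10 * reduced_time(1.0, 0.3))

    def test_positive_temperature_required(self):
        with pytest.raises(ValueError):
            reduced_time(1.0, 0.0)
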