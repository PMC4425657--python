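"""Directional hydrogen bonding: gating, registry, orientation, energetics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prime_dmd import (DMDEngine, HBondRegistry, build_chain, can_form,
                       classify_bond_orientation, compile_interactions,
                       total_energy)
from prime_dmd.fixtures import parallel_strand_pair
from prime_dmd.hbond import aux_constraint_pairs
from prime_dmd.peptide import SystemTopology


class TestCanForm:
    def test_idealized_parallel_geometry_accepted(self, strand_pair):
        top, state, inter, bonds = strand_pair
        registry = HBondRegistry(top.n_spheres)
        for nh, co in bonds:
            ok, reason = can_form(state, inter, registry, nh, co)
            assert ok, reason

    def test_inflated_auxiliary_distance_refused_with_name(self, strand_pair):
        top, state, inter, bonds = strand_pair
        registry = HBondRegistry(top.n_spheres)
        nh, co = bonds[0]
        (a, b, cutoff) = aux_constraint_pairs(inter, nh, co)[0]
        bad = state.copy()
        delta = bad.minimum_image(bad.positions[b] - bad.positions[a])
        d = np.linalg.norm(delta)
        # push the first auxiliary pair 0.1 A beyond its cutoff
        bad.positions[b] = bad.positions[a] + delta / d * (cutoff + 0.1)
        ok, reason = can_form(bad, inter, registry, nh, co)
        assert not ok
        assert "N_i-Ca_j" in reason

    def test_busy_donor_refused(self, strand_pair):
        top, state, inter, bonds = strand_pair
        registry = HBondRegistry(top.n_spheres)
        (nh, co), (nh2, co2) = bonds[0], bonds[1]
        registry.add(nh, co2, 0.0, aux_constraint_pairs(inter, nh, co2))
        ok, reason = can_form(state, inter, registry, nh, co)
        assert not ok and "donor" in reason
        ok, reason = can_form(state, inter, registry, nh2, co2)
        assert not ok and "acceptor" in reason

    def test_non_candidate_pair_rejected(self, strand_pair):
        top, state, inter, _bonds = strand_pair
        registry = HBondRegistry(top.n_spheres)
        with pytest.raises(ValueError):
            can_form(state, inter, registry, 0, 1)


class TestWellEventOutcomes:
    @pytest.fixture()
    def approaching(self, strand_pair):
        """Strand pair rigidly separated, donor strand drifting back in."""
        top, state, inter, bonds = strand_pair
        nh, co = bonds[0]
        st = state.copy()
        delta = st.minimum_image(st.positions[nh] - st.positions[co])
        d = float(np.linalg.norm(delta))
        rhat = delta / d
        na = top.chains[0].n_spheres
        # move the donor strand out of the well, then drift it back
        st.positions[na:] += (inter.hb_diameter + 0.05 - d) * rhat
        st.velocities[:na] = 0.0
        st.velocities[na:] = -0.02 * rhat
        eng = DMDEngine(inter, st, schedule=None, neighbor_mode="brute")
        return eng, nh, co

    def _step_until_bond(self, eng, max_steps=5000):
        for _ in range(max_steps):
            ke = eng.state.kinetic_energy(eng.inter.mass)
            u = eng.potential
            eng.step()
            if eng.registry.bonds:
                return ke, u
        raise AssertionError("no bond formed")

    def test_formation_releases_one_eps(self, approaching):
        eng, nh, co = approaching
        e0 = eng.total_energy()
        ke_before, u_before = self._step_until_bond(eng)
        # the formation event converts exactly one eps_HB of well depth
        # into kinetic energy
        assert eng.state.kinetic_energy(eng.inter.mass) - ke_before == \
            pytest.approx(1.0, abs=1e-9)
        assert eng.potential - u_before == pytest.approx(-1.0, abs=1e-12)
        assert eng.total_energy() == pytest.approx(e0, abs=1e-9)

    def test_energy_conserved_through_bounce_and_escape_attempts(self, approaching):
        eng, nh, co = approaching
        self._step_until_bond(eng)
        e_formed = eng.total_energy()
        for _ in range(200):
            eng.step()
            assert eng.total_energy() == pytest.approx(e_formed, abs=1e-9)

    def test_registry_energy_term_matches_total_energy(self, approaching):
        eng, nh, co = approaching
        self._step_until_bond(eng)
        u = total_energy(eng.state, eng.inter, eng.registry)
        u_no_hb = total_energy(eng.state, eng.inter, None)
        assert u - u_no_hb == pytest.approx(-len(eng.registry))


class TestRegistry:
    @given(ops=st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)),
                        max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_consistency_under_random_add_remove(self, ops):
        """The forward and inverse maps stay mutually consistent under any
        interleaving of bond formation and breaking."""
        n = 20
        donors = [0, 1, 2, 3]
        acceptors = [10, 11, 12, 13]
        reg = HBondRegistry(n)
        for di, ai in ops:
            nh, co = donors[di], acceptors[ai]
            if reg.partner[nh] == co:
                reg.remove(nh, co)
            elif reg.is_free(nh) and reg.is_free(co):
                reg.add(nh, co, 0.0, [(nh, co + 4, 5.0)] * 4)
            reg.check_consistent()

    def test_double_booking_raises(self):
        reg = HBondRegistry(10)
        reg.add(0, 5, 0.0, [(0, 6, 5.0)] * 4)
        with pytest.raises(RuntimeError):
            reg.add(0, 7, 0.0, [(0, 6, 5.0)] * 4)

    def test_removing_absent_bond_raises(self):
        reg = HBondRegistry(10)
        with pytest.raises(RuntimeError):
            reg.remove(0, 5)


class TestOrientation:
    def test_parallel_construction(self, strand_pair):
        top, state, _inter, bonds = strand_pair
        for bond in bonds:
            assert classify_bond_orientation(state, top, bond) == "parallel"

    def test_reversed_strand_is_antiparallel(self, ff):
        top, state, _inter, bonds = parallel_strand_pair(
            "AVAVAVA", ff, antiparallel=True)
        for bond in bonds:
            assert classify_bond_orientation(state, top, bond) == "antiparallel"

    def test_terminal_residues_unclassified(self, ff):
        chain = build_chain("AVA", ff.residues)
        top = SystemTopology.replicate(chain, 2)
        inter = compile_interactions(top, ff)
        # donor NH of residue 1 (chain B) with acceptor CO of residue 1
        # (chain A) is a candidate, but residue 0/2 neighbours are termini
        from prime_dmd.fixtures import extended_chain_state
        _t, state1 = extended_chain_state("AVA", ff)
        pos = np.vstack([state1.positions, state1.positions + [0, 5.2, 0]])
        from prime_dmd.state import SystemState
        st = SystemState(pos, np.zeros_like(pos), 200.0)
        nh = top.sphere_id(1, 0, 0)
        co = top.sphere_id(0, 0, 2)
        assert classify_bond_orientation(st, top, (nh, co)) is None
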