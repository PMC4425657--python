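"""Trajectory statistics: dihedrals, secondary structure, SASA, P_max,
salt bridges and chain shapes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prime_dmd import SystemTopology, build_chain
from prime_dmd.analysis import (EnergySeries, assign_secondary_structure,
                                classify_chain_shape, count_salt_bridges,
                                detect_turns, phi_psi, pmax_series,
                                sasa_profile, sphere_radii, strand_content_profile,
                                strand_fraction)
from prime_dmd.fixtures import shaped_chain_state
from prime_dmd.peptide import chain_coordinates
from prime_dmd.residues import ROLE_NH, ROLE_CO, ROLE_R
from prime_dmd.state import SystemState

from oracle import brute_force_pmax, equal_spheres_exposed_area


def _single_chain_state(chain, phi, psi, ff, box=300.0):
    pos = chain_coordinates(chain, phi, psi, ff.residues)
    pos = pos - pos.min(axis=0) + 0.25 * box
    return SystemState(pos, np.zeros_like(pos), box)


class TestPhiPsi:
    def test_constructed_dihedrals_recovered(self, ff):
        chain = build_chain("AAAAAA", ff.residues)
        top = SystemTopology.replicate(chain, 1)
        phis = np.array([0.0, -120, -60, 57.5, -139, 0])
        psis = np.array([130.0, 140, -40, 120, -35, 0])
        state = _single_chain_state(chain, phis, psis, ff)
        phi, psi = phi_psi(state, top, 0)
        assert np.allclose(phi[1:], phis[1:], atol=1e-9)
        assert np.allclose(psi[:-1], psis[:-1], atol=1e-9)

    def test_termini_undefined(self, ff):
        chain = build_chain("AAAA", ff.residues)
        top = SystemTopology.replicate(chain, 1)
        state = _single_chain_state(chain, [0, -120, -120, 0], [130, 130, 130, 0], ff)
        phi, psi = phi_psi(state, top, 0)
        assert np.isnan(phi[0]) and np.isnan(psi[-1])

    def test_mirror_negates_dihedrals(self, ff):
        chain = build_chain("AAAAA", ff.residues)
        top = SystemTopology.replicate(chain, 1)
        state = _single_chain_state(chain, [0, -120, -70, -110, 0],
                                    [130, 150, -30, 120, 0], ff)
        mirrored = state.copy()
        mirrored.positions = -mirrored.positions
        mirrored.wrap()
        phi, psi = phi_psi(state, top, 0)
        phi_m, psi_m = phi_psi(mirrored, top, 0)
        assert np.allclose(phi_m[1:], -phi[1:], atol=1e-9)
        assert np.allclose(psi_m[:-1], -psi[:-1], atol=1e-9)


class TestSecondaryStructure:
    def test_fresh_random_coils_have_zero_strand(self, ab_top8, fresh_coils):
        labels = assign_secondary_structure(fresh_coils, ab_top8, [])
        assert strand_fraction(labels) == 0.0

    def test_parallel_sheet_interior_is_strand(self, ff):
        from prime_dmd.fixtures import parallel_strand_pair
        top, state, _inter, _b = parallel_strand_pair("AVAVAVAV", ff)
        chain = top.chains[0]
        off = top.offsets[1]
        ladder = [(off + chain.sphere_id(i, ROLE_NH), chain.sphere_id(i, ROLE_CO))
                  for i in range(1, 7)]
        labels = assign_secondary_structure(state, top, ladder)
        for lab in labels:
            assert "".join(lab) == "CEEEEEEC"

    def test_beta_dihedrals_without_bonds_are_coil(self, ff):
        chain = build_chain("AVAVAVAV", ff.residues)
        top = SystemTopology.replicate(chain, 1)
        state = _single_chain_state(chain, np.full(8, -120.0), np.full(8, 135.0), ff)
        labels = assign_secondary_structure(state, top, [])
        assert strand_fraction(labels) == 0.0

    def test_mirror_cannot_create_strand(self, ab_top8, fresh_coils):
        mirrored = fresh_coils.copy()
        mirrored.positions = -mirrored.positions
        mirrored.wrap()
        labels = assign_secondary_structure(mirrored, ab_top8, [])
        assert strand_fraction(labels) == 0.0


class TestStrandProfile:
    def test_all_coil_gives_zeros(self):
        a = np.full((2, 10), "C")
        prof = strand_content_profile([a, a, a])
        assert np.all(prof == 0.0)

    def test_alternating_labels_give_half(self):
        a = np.full((1, 5), "C")
        b = a.copy()
        b[0, 2] = "E"
        prof = strand_content_profile([a, b])
        assert prof[2] == pytest.approx(0.5)
        assert prof[0] == 0.0

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            strand_content_profile([])

    def test_probabilities_bounded(self, ab_top8, fresh_coils):
        labels = assign_secondary_structure(fresh_coils, ab_top8, [])
        prof = strand_content_profile([labels])
        assert np.all((prof >= 0) & (prof <= 1))


class TestSasa:
    def test_isolated_sphere_closed_form(self, ff):
        chain = build_chain("G", ff.residues)  # 3 spheres, no side sphere
        top = SystemTopology.replicate(chain, 1)
        # pull the spheres far apart so each is isolated
        pos = np.array([[50.0, 50, 50], [150.0, 50, 50], [100.0, 150, 50]])
        state = SystemState(pos, np.zeros_like(pos), 400.0)
        per_res = sasa_profile(state, top, ff, probe=1.4, n_points=2000)
        radii = sphere_radii(top, ff) + 1.4
        expect = float(np.sum(4 * np.pi * radii ** 2))
        assert per_res[0, 0] == pytest.approx(expect, rel=2e-3)

    def test_enclosed_sphere_has_zero_area(self, ff):
        chain = build_chain("G", ff.residues)
        top = SystemTopology.replicate(chain, 1)
        # NH sphere caged by the two others placed on top of it
        pos = np.array([[50.0, 50, 50], [50.0, 50, 50], [50.0, 50, 50]])
        state = SystemState(pos, np.zeros_like(pos), 200.0)
        per_res = sasa_profile(state, top, ff)
        # the smaller concentric spheres are fully buried: only the largest
        # (CO) surface survives
        r_co = 0.5 * ff.backbone_sigma["CO"] + 1.4
        assert per_res[0, 0] == pytest.approx(4 * np.pi * r_co ** 2, rel=1e-9)

    def test_two_overlapping_equal_spheres_match_cap_formula(self, ff):
        chain = build_chain("G", ff.residues)
        top = SystemTopology.replicate(chain, 2)
        r_nh = 0.5 * ff.backbone_sigma["NH"] + 1.4
        d = 1.5 * r_nh
        pos = np.array([[50.0, 50, 50], [250.0, 50, 50], [150.0, 250, 50],
                        [50.0 + d, 50, 50], [250.0, 150, 50], [150.0, 250, 150]])
        state = SystemState(pos, np.zeros_like(pos), 400.0)
        per = sasa_profile(state, top, ff, n_points=4000)
        # the two NH spheres overlap; compare their summed exposed area
        # against the spherical-cap closed form
        iso = {"CaH": 4 * np.pi * (0.5 * ff.backbone_sigma["CaH"] + 1.4) ** 2,
               "CO": 4 * np.pi * (0.5 * ff.backbone_sigma["CO"] + 1.4) ** 2}
        nh_area_each = per[0, 0] - iso["CaH"] - iso["CO"]
        expect = equal_spheres_exposed_area(r_nh, d)
        assert nh_area_each == pytest.approx(expect, rel=5e-3)
        # symmetric up to the finite surface-point resolution
        assert per[0, 0] == pytest.approx(per[1, 0], rel=2e-3)


class TestPmax:
    def test_constant_series_is_one(self):
        s = EnergySeries(np.arange(1.0, 100.0), np.zeros(99))
        windows = pmax_series(s, window=50.0, halfwidth=4.0, temperature=0.2)
        assert all(w.p_max == 1.0 for w in windows)
        assert all(w.free_energy == 0.0 for w in windows)

    def test_bimodal_series_takes_majority_level(self):
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 5000.0, 5.0) + 1.0
        lv = np.where(rng.random(len(t)) < 0.6, 0.0, 20.0)
        s = EnergySeries(t, lv)
        (w,) = pmax_series(s, window=6000.0, halfwidth=4.0, temperature=0.2)
        assert w.p_max == pytest.approx(np.mean(lv == 0.0))
        assert abs(w.e_max) < 1e-12

    def test_matches_brute_force_band_search(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = rng.integers(5, 120)
            e = rng.normal(0, rng.uniform(1, 12), n)
            t = np.sort(rng.uniform(0, 4000, n))
            t += np.arange(n) * 1e-6  # strictly increasing
            (w,) = pmax_series(EnergySeries(t, e), window=5000.0,
                               halfwidth=4.0, temperature=0.2)
            p_ref, _e_ref = brute_force_pmax(e, 4.0)
            assert w.p_max == pytest.approx(p_ref)

    def test_invalid_inputs(self):
        s = EnergySeries(np.array([1.0, 2.0]), np.zeros(2))
        with pytest.raises(ValueError):
            pmax_series(s, window=-1.0)
        with pytest.raises(ValueError):
            EnergySeries(np.array([1.0, 1.0]), np.zeros(2))

    @given(seed=st.integers(0, 10 ** 6))
    @settings(max_examples=20, deadline=None)
    def test_pmax_bounded(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        t = np.cumsum(rng.uniform(0.1, 10.0, n))
        e = rng.normal(0, 5, n)
        for w in pmax_series(EnergySeries(t, e), window=50.0, halfwidth=4.0,
                             temperature=0.2):
            assert 0 < w.p_max <= 1


class TestSaltBridges:
    def _state_with_kd(self, ff, separation, n_chains=1):
        chain = build_chain("KAD", ff.residues)
        top = SystemTopology.replicate(chain, max(n_chains, 1))
        phi = np.zeros(3)
        psi = np.zeros(3)
        pos = chain_coordinates(chain, phi, psi, ff.residues)
        stack = [pos + 100.0]
        for c in range(1, n_chains):
            stack.append(pos + 100.0 + np.array([0.0, 0.0, 40.0 * c]))
        allpos = np.vstack(stack)
        state = SystemState(allpos, np.zeros_like(allpos), 400.0)
        # place the D side sphere of the target chain at the requested
        # distance from the K side sphere
        k_id = top.sphere_id(0, 0, ROLE_R)
        d_id = top.sphere_id(n_chains - 1, 2, ROLE_R)
        direction = np.array([1.0, 0, 0])
        state.positions[d_id] = state.positions[k_id] + direction * separation
        return top, state, k_id, d_id

    def test_far_apart_counts_zero(self, ff):
        top, state, *_ = self._state_with_kd(ff, 30.0)
        assert count_salt_bridges(state, top, ff) == (0, 0)

    def test_intra_chain_contact(self, ff):
        d_out = ff.pair_potential("K", "D").d_outer
        top, state, *_ = self._state_with_kd(ff, d_out - 0.2)
        assert count_salt_bridges(state, top, ff) == (1, 0)

    def test_inter_chain_contact(self, ff):
        d_out = ff.pair_potential("K", "D").d_outer
        top, state, *_ = self._state_with_kd(ff, d_out - 0.2, n_chains=2)
        intra, inter = count_salt_bridges(state, top, ff)
        assert inter == 1

    def test_counts_invariant_under_chain_relabeling(self, ab_top8, fresh_coils, ff):
        base = count_salt_bridges(fresh_coils, ab_top8, ff)
        # swap two whole chains in the coordinate array
        state = fresh_coils.copy()
        a0, b0 = ab_top8.offsets[0], ab_top8.offsets[3]
        n = 99
        state.positions[a0:a0 + n], state.positions[b0:b0 + n] = \
            fresh_coils.positions[b0:b0 + n].copy(), fresh_coils.positions[a0:a0 + n].copy()
        assert count_salt_bridges(state, ab_top8, ff) == base


class TestChainShapes:
    def test_u_shape(self, ff):
        top, state = shaped_chain_state(((25, 26),), ff=ff)
        assert classify_chain_shape(state, top, 0, ff) == "U"

    def test_s_shape_extra_cterm_turn(self, ff):
        top, state = shaped_chain_state(((25, 26), (37, 38)), ff=ff)
        assert classify_chain_shape(state, top, 0, ff) == "S"

    def test_triangular_extra_turn_near_g33(self, ff):
        top, state = shaped_chain_state(((25, 26), (33, 34)), ff=ff)
        assert classify_chain_shape(state, top, 0, ff) == "triangular"

    def test_extended_chain_disordered(self, ff):
        top, state = shaped_chain_state((), ff=ff)
        assert detect_turns(state, top, 0) == []
        assert classify_chain_shape(state, top, 0, ff) == "disordered"

    def test_short_chain_unclassified(self, ff):
        top, state = shaped_chain_state((), sequence="AVAVA", ff=ff,
                                        numbering_offset=1)
        assert classify_chain_shape(state, top, 0, ff) == "unclassified"
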