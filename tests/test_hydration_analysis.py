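"""Water HB graphs, coordination fields, per-bond hydration, and the action."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dhtopo.bhb_wrapping import annotate_bonds
from dhtopo.hydration_analysis import (
    action,
    bhb_hydration,
    coordination_field,
    theta_profiles,
    water_hb_graph,
)
from dhtopo.structure_model import SolventFrame, StructureError
from dhtopo.synthetic_data import make_solvated_bond, make_water_lattice


def frame_from(oxygens, hydrogens=None, index=0):
    return SolventFrame(
        frame_index=index,
        oxygens=np.asarray(oxygens, dtype=float),
        hydrogens=None if hydrogens is None else np.asarray(hydrogens, dtype=float),
    )


def brute_force_edges(frame, oo_cutoff=3.2, lo=120.0, hi=180.0):
    """Independent pairwise recount of the HB criterion."""
    o = frame.oxygens
    edges = set()
    for j, n in itertools.combinations(range(len(o)), 2):
        if np.linalg.norm(o[j] - o[n]) >= oo_cutoff:
            continue
        ok = False
        for donor, acceptor in ((j, n), (n, j)):
            for h in frame.hydrogens[donor]:
                if not np.all(np.isfinite(h)):
                    continue
                u, v = o[donor] - h, o[acceptor] - h
                ang = math.degrees(
                    math.acos(
                        np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)
                    )
                )
                if lo <= ang <= hi:
                    ok = True
        if ok:
            edges.add((j, n))
    return edges


def _dimer(oo=2.8):
    o = [[0.0, 0.0, 0.0], [oo, 0.0, 0.0]]
    h = [
        [[1.0, 0.0, 0.0], [-0.3, 0.95, 0.0]],  # donor H on the O-O axis
        [[oo + 0.5, 0.87, 0.0], [oo + 0.5, -0.87, 0.0]],
    ]
    return frame_from(o, h)


class TestWaterHBGraph:
    def test_linear_dimer_bonds(self):
        g = water_hb_graph(_dimer(2.8))
        assert g.edges == [(0, 1)]
        np.testing.assert_array_equal(g.g, [1, 1])

    def test_distance_cutoff_exclusive(self):
        assert water_hb_graph(_dimer(3.5)).edges == []
        assert water_hb_graph(_dimer(3.2)).edges == []

    def test_angle_criterion(self):
        o = [[0.0, 0.0, 0.0], [2.8, 0.0, 0.0]]
        # both hydrogens point away from the neighbor: angle at H < 120
        h = [
            [[-0.5, 0.87, 0.0], [-0.5, -0.87, 0.0]],
            [[2.8 + 0.5, 0.87, 0.0], [2.8 + 0.5, -0.87, 0.0]],
        ]
        assert water_hb_graph(frame_from(o, h)).edges == []

    def test_hydrogen_free_frame_needs_fallback(self):
        frame = frame_from([[0, 0, 0], [2.8, 0, 0]])
        with pytest.raises(StructureError, match="distance_only"):
            water_hb_graph(frame)
        g = water_hb_graph(frame, distance_only=True)
        assert g.distance_only and g.edges == [(0, 1)]

    @pytest.mark.parametrize("g_star", [1, 2, 3, 4])
    def test_lattice_matches_intended_and_brute_force(self, g_star):
        frame = make_water_lattice(g_star, 60, seed=g_star)
        graph = water_hb_graph(frame)
        np.testing.assert_array_equal(graph.g, frame.expected_g)
        assert set(graph.edges) == brute_force_edges(frame)
        interior = frame.expected_g == g_star
        assert interior.sum() > 0

    def test_five_water_tetrahedral_cluster(self):
        frame = make_water_lattice(4, 5, seed=0)
        graph = water_hb_graph(frame)
        degrees = sorted(graph.g)
        assert degrees == [1, 1, 1, 1, 4]


class TestCoordinationField:
    def test_single_water_at_query(self):
        frame = make_water_lattice(3, 30, seed=2)
        graph = water_hb_graph(frame)
        interior = np.nonzero(frame.expected_g == 3)[0]
        q = frame.oxygens[interior[0]]
        field = coordination_field([frame], [q], radius=0.5, graphs=[graph])
        assert field.g_of_r[0] == pytest.approx(3.0)

    def test_mean_over_frames(self):
        f1 = _dimer(2.8)  # both waters have g = 1
        o = [[0.0, 0.0, 0.0]]
        f2 = frame_from(o, [[[1.0, 0, 0], [-0.3, 0.95, 0]]], index=1)  # isolated: g = 0
        field = coordination_field([f1, f2], [[0.0, 0.0, 0.0]], radius=1.0)
        assert field.g_of_r[0] == pytest.approx(0.5)  # mean of 1 and 0

    def test_unvisited_query_flagged(self):
        field = coordination_field([_dimer()], [[50.0, 50.0, 50.0]])
        assert not field.defined[0]
        assert field.n_contributions[0] == 0

    def test_uniform_interior_lattice(self):
        frame = make_water_lattice(3, 80, seed=5)
        interior = frame.oxygens[frame.expected_g == 3]
        field = coordination_field([frame], interior, radius=0.5)
        np.testing.assert_allclose(field.g_of_r, 3.0)


class TestBhbHydration:
    def _bond(self):
        s, _ = make_solvated_bond(d_star=3.0, g_star=0, n_frames=1, seed=0)
        return annotate_bonds(s)[0]

    def test_single_distant_water(self):
        bond = self._bond()
        o_c = bond.carbonyl_o.position
        frame = frame_from(
            [o_c + [0.0, 0.0, 4.2]],
            [[[*(o_c + [1.0, 0.0, 4.2])], [*(o_c + [-0.3, 0.95, 4.2])]]],
        )
        rec = bhb_hydration(bond, [frame])
        assert rec.d_min == pytest.approx(4.2, abs=1e-9)
        assert rec.g_min == 0.0

    def test_argmin_selection(self):
        bond = self._bond()
        o_c = bond.carbonyl_o.position
        # near water (isolated, g=0) vs far hydrogen-bonded pair (g=1 each)
        o = [o_c + [0, 0, 3.0], o_c + [0, 0, 5.0], o_c + [0, 2.8, 5.0]]
        h = np.empty((3, 2, 3))
        h[0] = [o_c + np.array([1.0, 0, 3.0]), o_c + np.array([-0.3, 0.95, 3.0])]
        h[1] = [o_c + np.array([0, 1.0, 5.0]), o_c + np.array([0.95, 0, 5.0])]
        h[2] = [o_c + np.array([0, 1.8, 5.0]), o_c + np.array([0.95, 2.8, 5.0])]
        rec = bhb_hydration(bond, [frame_from(o, h)])
        assert rec.d_min == pytest.approx(3.0, abs=1e-9)
        assert rec.g_min == 0.0  # coordination of the argmin water

    def test_equidistant_tie_takes_lowest_index(self):
        bond = self._bond()
        o_c = bond.carbonyl_o.position
        o = [o_c + [0, 0, 4.0], o_c + [0, 0, -4.0], o_c + [0, 2.8, 4.0]]
        h = np.empty((3, 2, 3))
        h[0] = [o_c + np.array([0, 1.0, 4.0]), o_c + np.array([0.95, 0, 4.0])]
        h[1] = [o_c + np.array([0, 1.0, -4.0]), o_c + np.array([0.95, 0, -4.0])]
        h[2] = [o_c + np.array([0, 1.8, 4.0]), o_c + np.array([0.95, 2.8, 4.0])]
        rec = bhb_hydration(bond, [frame_from(o, h)])
        # waters 0 and 1 tie at 4.0; water 0 (bonded to water 2, g=1) wins
        assert rec.g_min == water_hb_graph(frame_from(o, h)).coordination(0)

    def test_waterless_frames_skipped(self):
        bond = self._bond()
        o_c = bond.carbonyl_o.position
        empty = SolventFrame(frame_index=0, oxygens=np.empty((0, 3)))
        full = frame_from(
            [o_c + [0, 0, 4.0]],
            [[[*(o_c + [1.0, 0, 4.0])], [*(o_c + [-0.3, 0.95, 4.0])]]],
            index=1,
        )
        rec = bhb_hydration(bond, [empty, full])
        assert rec.n_frames == 1

    def test_frame_averaged_generator_truth(self):
        s, frames = make_solvated_bond(d_star=5.0, g_star=3, n_frames=10, seed=9)
        bond = annotate_bonds(s)[0]
        rec = bhb_hydration(bond, frames)
        assert rec.d_min == pytest.approx(5.0, abs=0.1)
        assert rec.g_min == 3.0
        assert rec.n_frames == 10


class TestThetaProfiles:
    def test_single_bin(self):
        s, frames = make_solvated_bond(d_star=5.0, g_star=1, n_frames=2, seed=3)
        bond = annotate_bonds(s)[0]
        bond.summary_theta = 2.3
        rec = bhb_hydration(bond, frames)
        table = theta_profiles([rec])
        assert len(table) == 1
        assert table.loc[0, "theta_bin"] == pytest.approx(2.25)
        assert table.loc[0, "mean_d_min"] == pytest.approx(rec.d_min)

    def test_two_populations_partition(self):
        s, frames = make_solvated_bond(d_star=3.0, g_star=1, n_frames=2, seed=4)
        bond = annotate_bonds(s)[0]
        recs = []
        for theta, n in ((2.1, 3), (5.6, 2)):
            for _ in range(n):
                rec = bhb_hydration(bond, frames)
                rec.bond = type(bond)(**{**bond.__dict__})
                rec.bond.summary_theta = theta
                recs.append(rec)
        table = theta_profiles(recs)
        assert list(table["n_bonds"]) == [3, 2]
        assert list(table["theta_bin"]) == [2.0, 5.5]


class TestAction:
    def test_uniform_components_zero(self):
        frame = make_water_lattice(1, 10, seed=0)  # dimers: g constant per component
        assert action(water_hb_graph(frame)).A == 0.0

    def test_path_of_three(self):
        # degrees 1,2,1: each edge contributes (1-2)² twice
        frame = make_water_lattice(2, 3, seed=0)
        graph = water_hb_graph(frame)
        assert sorted(graph.g) == [1, 1, 2]
        assert action(graph).A == 4.0

    def test_hand_enumeration_small_graphs(self):
        # (g*, n, hand-computed A over ordered neighbor pairs)
        cases = [(1, 2, 0.0), (2, 4, 4.0), (4, 5, 4 * 2 * (4 - 1) ** 2)]
        for g_star, n, expected in cases:
            frame = make_water_lattice(g_star, n, seed=1)
            graph = water_hb_graph(frame)
            g = dict(graph.graph.degree)
            manual = sum(
                (g[a] - g[b]) ** 2 for a, b in graph.graph.edges for _ in (0, 1)
            )
            assert action(graph).A == manual == expected

    def test_relabeling_invariance(self):
        frame = make_water_lattice(3, 40, seed=6)
        a1 = action(water_hb_graph(frame)).A
        perm = np.random.default_rng(0).permutation(frame.n_waters)
        shuffled = SolventFrame(
            frame_index=0,
            oxygens=frame.oxygens[perm],
            hydrogens=frame.hydrogens[perm],
        )
        assert action(water_hb_graph(shuffled)).A == a1

    @settings(deadline=None, max_examples=60)
    @given(st.integers(min_value=1, max_value=4), st.integers(min_value=0, max_value=2**31 - 1))
    def test_action_nonnegative_and_zero_iff_component_constant(self, g_star, seed):
        n = 8 + (seed % 20)
        try:
            frame = make_water_lattice(g_star, n, seed=seed)
        except ValueError:
            return
        graph = water_hb_graph(frame)
        a = action(graph).A
        assert a >= 0.0
        import networkx as nx

        constant = all(
            len({graph.graph.degree(v) for v in comp}) == 1
            for comp in nx.connected_components(graph.graph)
        )
        assert (a == 0.0) == constant
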