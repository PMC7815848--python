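"""Cell features: closeness, lobe/neck calling, junctions, morphometrics."""

import math

import numpy as np
import pytest

import visishape as vs
from visishape.features import (
    DEFAULT_CENTRALITIES,
    feature_names,
    shortest_path_matrix,
)

from _oracles import floyd_warshall
from test_spectral import graph_from_adjacency


class TestCloseness:
    def test_complete_unit_graph(self):
        n = 6
        A = np.ones((n, n)) - np.eye(n)
        g = graph_from_adjacency(A)
        g.W = A.copy()  # unit weights
        np.testing.assert_allclose(vs.closeness(g), 1.0)

    def test_path_of_three_unit_nodes(self):
        g = graph_from_adjacency(
            [[0, 1, 0], [1, 0, 1], [0, 1, 0]],
            coords=np.array([[0.0, 0], [1, 0], [2, 0]]),
        )
        np.testing.assert_allclose(vs.closeness(g), [2 / 3, 1.0, 2 / 3])

    def test_matches_floyd_warshall_oracle(self, lobed_cell_k5):
        g = vs.graph_from_contour(lobed_cell_k5.contour, spacing=8)
        D = floyd_warshall(g.W)
        expected = (g.n - 1) / D.sum(axis=1)
        np.testing.assert_allclose(vs.closeness(g), expected, atol=1e-9)
        np.testing.assert_allclose(shortest_path_matrix(g), D, atol=1e-9)


class TestCallLobesNecks:
    def test_constant_profile_no_extrema(self):
        lobes, necks = vs.call_lobes_necks(np.ones(30))
        assert len(lobes) == 0 and len(necks) == 0

    def test_near_constant_within_tolerance(self):
        v = 1.0 + 1e-5 * np.sin(np.linspace(0, 4 * np.pi, 50, endpoint=False))
        lobes, necks = vs.call_lobes_necks(v)
        assert len(lobes) == 0 and len(necks) == 0

    def test_alternating_sequence_every_node_extremum(self):
        v = np.tile([1.0, 2.0], 10)
        lobes, necks = vs.call_lobes_necks(v, window=1)
        assert len(lobes) == 10 and len(necks) == 10
        assert set(lobes) == set(range(0, 20, 2))

    def test_coordinate_circle_no_extrema(self):
        g = vs.graph_from_points(vs.make_ellipse_nodes(20, (5.0, 5.0)).points)
        lobes, necks = vs.call_lobes_necks(vs.closeness(g))
        assert len(lobes) == 0 and len(necks) == 0

    def test_plateau_collapses_to_left_center(self):
        v = np.array([5, 5, 1, 1, 5, 5, 5, 9, 9, 5], dtype=float)
        lobes, necks = vs.call_lobes_necks(v, window=1)
        assert lobes.tolist() == [2]  # even plateau {2,3} -> left-centre 2
        assert necks.tolist() == [7]

    def test_alternation_along_cycle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            v = rng.uniform(0, 1, 40)
            lobes, necks = vs.call_lobes_necks(v, window=2)
            if len(lobes) == 0:
                continue
            kinds = sorted(
                [(int(i), "L") for i in lobes] + [(int(i), "N") for i in necks]
            )
            for (_, a), (_, b) in zip(kinds, kinds[1:] + kinds[:1]):
                assert a != b

    @pytest.mark.parametrize("k", range(3, 9))
    def test_phantom_lobe_recovery(self, k):
        cell = vs.make_lobed_cell(k, 60.0, 0.3)
        g = vs.graph_from_contour(cell.contour, spacing=8)
        lobes, necks = vs.call_lobes_necks(vs.closeness(g))
        assert len(lobes) == k
        assert len(necks) == k
        for tip in cell.true_lobes:
            node = int(np.argmin(np.hypot(*(g.nodes - tip).T)))
            dist = min(
                min(abs(l - node), g.n - abs(l - node)) for l in lobes
            )
            assert dist <= 2


class TestJunctions:
    def test_plus_sign_single_junction(self):
        skel = np.zeros((11, 11), dtype=bool)
        skel[5, 1:10] = True
        skel[1:10, 5] = True
        j = vs.detect_junctions(skel)
        assert len(j) == 1
        np.testing.assert_allclose(j[0], [5.0, 5.0], atol=1.0)

    def test_closed_loop_no_junctions(self, lobed_cell_k5):
        skel = np.zeros(lobed_cell_k5.mask.shape, dtype=bool)
        px = lobed_cell_k5.contour.pixels
        skel[px[:, 1], px[:, 0]] = True
        assert len(vs.detect_junctions(skel)) == 0

    def test_phantom_junction_recovery(self, segmented_clean_phantom):
        phantom, tissue = segmented_clean_phantom
        detected = vs.detect_junctions(tissue.skeleton)
        for t in phantom.true_junctions:
            assert np.hypot(*(detected - t).T).min() <= 2.0


class TestMatchJunctions:
    nodes = np.array([[10.0, 10.0], [40.0, 40.0], [70.0, 10.0]])

    def test_empty_junctions_all_true_lobes(self):
        jl, tl = vs.match_junctions([0, 2], self.nodes, np.empty((0, 2)))
        assert len(jl) == 0
        assert tl.tolist() == [0, 2]

    def test_boundary_of_three_pixel_rule(self):
        jl, tl = vs.match_junctions([0], self.nodes, np.array([[13.0, 13.0]]))
        assert jl.tolist() == [0]
        jl, tl = vs.match_junctions([0], self.nodes, np.array([[14.0, 10.0]]))
        assert len(jl) == 0 and tl.tolist() == [0]

    def test_one_junction_consumes_one_lobe(self):
        nodes = np.array([[10.0, 10.0], [12.0, 10.0]])
        jl, tl = vs.match_junctions([0, 1], nodes, np.array([[11.0, 10.0]]))
        assert len(jl) == 1 and len(tl) == 1


class TestMorphometrics:
    def test_square_circularity(self):
        region = np.zeros((120, 120), dtype=bool)
        region[10:110, 10:110] = True
        contour = vs.trace_boundary(region, resolution=1.0)
        g = vs.graph_from_contour(contour, spacing=8)
        m = vs.morphometrics(contour, g, [], [])
        assert m["circularity"] == pytest.approx(math.pi / 4, rel=0.02)
        assert m["area_um2"] == 100 * 100

    @pytest.mark.parametrize("R", [30.0, 60.0])
    def test_circle_circularity_near_one(self, R):
        cell = vs.make_lobed_cell(0, R, 0.0, resolution=1.0)
        g = vs.graph_from_contour(cell.contour, spacing=8)
        m = vs.morphometrics(cell.contour, g, [], [])
        assert m["circularity"] == pytest.approx(1.0, rel=0.02)

    def test_resolution_scaling(self, lobed_cell_k5):
        c = lobed_cell_k5.contour
        g = vs.graph_from_contour(c, spacing=8)
        m1 = vs.morphometrics(c, g, [], [])
        c.resolution = 0.5
        m2 = vs.morphometrics(c, g, [], [])
        assert m2["area_um2"] == pytest.approx(m1["area_um2"] / 4)
        assert m2["perimeter_um"] == pytest.approx(m1["perimeter_um"] / 2)
        assert m2["circularity"] == pytest.approx(m1["circularity"])
        c.resolution = 1.0

    def test_lobe_length_matches_analytic_geometry(self):
        k, R, a = 5, 40.0, 0.3
        cell = vs.make_lobed_cell(k, R, a, resolution=1.0)
        g = vs.graph_from_contour(cell.contour, spacing=8)
        lobes, necks = vs.call_lobes_necks(vs.closeness(g))
        m = vs.morphometrics(cell.contour, g, lobes, necks)
        analytic = R * (1 + a) - R * (1 - a) * math.cos(math.pi / k)
        assert np.all(np.abs(m["lobe_lengths_um"] - analytic) <= 2.0)
        neck_analytic = 2 * R * (1 - a) * math.sin(math.pi / k)
        assert np.all(np.abs(m["neck_widths_um"] - neck_analytic) <= 2.0)

    def test_lobe_without_flanking_necks_is_nan(self, lobed_cell_k5):
        g = vs.graph_from_contour(lobed_cell_k5.contour, spacing=8)
        m = vs.morphometrics(lobed_cell_k5.contour, g, [3], [])
        assert np.isnan(m["lobe_lengths_um"]).all()


class TestFeatureVector:
    def test_vector_length(self, lobed_cell_k5):
        g = vs.graph_from_contour(lobed_cell_k5.contour, spacing=8)
        ann = vs.annotate_cell(lobed_cell_k5.contour, g)
        vec = vs.feature_vector(g, ann)
        assert len(vec) == 1 + 6 * len(DEFAULT_CENTRALITIES) + 1
        assert len(feature_names()) == len(vec)
        assert np.isfinite(vec).all()

    def test_complete_unit_graph_moments(self):
        n = 6
        A = np.ones((n, n)) - np.eye(n)
        g = graph_from_adjacency(A)
        g.W = A.copy()
        ann = vs.CellAnnotation(
            cell_id=0, closeness=vs.closeness(g),
            lobes=np.empty(0, int), necks=np.empty(0, int),
            junction_lobes=np.empty(0, int), true_lobes=np.empty(0, int),
            delta=1.0,
        )
        vec = vs.feature_vector(g, ann, centrality_set=("closeness",))
        # lobe count, then mean/median/min/max all 1, skew/kurt 0, delta
        np.testing.assert_allclose(vec, [0, 1, 1, 1, 1, 0, 0, 1.0], atol=1e-12)

    def test_isomorphic_graphs_same_vector(self, lobed_cell_k5):
        g = vs.graph_from_contour(lobed_cell_k5.contour, spacing=8)
        ann = vs.annotate_cell(lobed_cell_k5.contour, g)
        v1 = vs.feature_vector(g, ann)
        v2 = vs.feature_vector(g, ann)
        np.testing.assert_array_equal(v1, v2)


def test_delta_tracks_circularity_across_lobedness():
    """More lobed cells are both less circular and less complete."""
    from scipy.stats import spearmanr

    deltas, circs = [], []
    for k in range(0, 9):
        a = 0.0 if k == 0 else 0.25
        cell = vs.make_lobed_cell(k, 45.0, a, resolution=1.0)
        g = vs.graph_from_contour(cell.contour, spacing=8)
        lobes, necks = vs.call_lobes_necks(vs.closeness(g))
        m = vs.morphometrics(cell.contour, g, lobes, necks)
        deltas.append(vs.relative_completeness(g))
        circs.append(m["circularity"])
    rho = spearmanr(deltas, circs).statistic
    assert rho > 0.5
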