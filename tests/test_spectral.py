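"""Spectral comparison: closed forms, KS distance, clustering, reduction, BHI."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import visishape as vs
from visishape.spectral import Spectrum, dendrogram_newick

from _oracles import brute_rotational_distance


def graph_from_adjacency(A, coords=None):
    A = np.asarray(A, dtype=float)
    n = len(A)
    if coords is None:
        ang = 2 * np.pi * np.arange(n) / n
        coords = np.column_stack([np.cos(ang), np.sin(ang)])
    from scipy.spatial.distance import pdist, squareform

    W = A * squareform(pdist(coords))
    wmax = W.max()
    return vs.VisibilityGraph(
        nodes=coords,
        edges={(i, j) for i in range(n) for j in range(i + 1, n) if A[i, j]},
        A=A, W=W, W_scaled=W / wmax if wmax else W,
    )


K3 = graph_from_adjacency(np.ones((3, 3)) - np.eye(3))
P3 = graph_from_adjacency([[0, 1, 0], [1, 0, 1], [0, 1, 0]])


class TestLaplacianSpectrum:
    def test_complete_k3(self):
        s = vs.laplacian_spectrum(K3)
        np.testing.assert_allclose(s.values, [0.0, 1.0, 1.0], atol=1e-12)

    def test_path_p3(self):
        s = vs.laplacian_spectrum(P3)
        np.testing.assert_allclose(s.values, [0.0, 1 / 3, 1.0], atol=1e-12)

    @pytest.mark.parametrize("n", [5, 8, 13])
    def test_cycle_closed_form(self, n):
        A = np.zeros((n, n))
        idx = np.arange(n)
        A[idx, (idx + 1) % n] = A[(idx + 1) % n, idx] = 1
        s = vs.laplacian_spectrum(graph_from_adjacency(A))
        expected = np.sort(2 - 2 * np.cos(2 * np.pi * np.arange(n) / n))
        np.testing.assert_allclose(s.values, expected / expected[-1], atol=1e-9)

    def test_relabeling_invariance(self, shape_set_graphs):
        g = shape_set_graphs[0]
        perm = np.random.default_rng(3).permutation(g.n)
        gp = graph_from_adjacency(g.A[np.ix_(perm, perm)], coords=g.nodes[perm])
        np.testing.assert_allclose(
            vs.laplacian_spectrum(g).values, vs.laplacian_spectrum(gp).values, atol=1e-9
        )

    def test_disconnected_rejected(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = A[2, 3] = A[3, 2] = 1
        with pytest.raises(ValueError):
            vs.laplacian_spectrum(graph_from_adjacency(A))


class TestKSDistance:
    def test_identical_spectra(self):
        s = vs.laplacian_spectrum(K3)
        assert vs.ks_distance(s, s) == 0.0

    def test_k3_vs_p3(self):
        d = vs.ks_distance(vs.laplacian_spectrum(K3), vs.laplacian_spectrum(P3))
        assert d == pytest.approx(1 / 3)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_pseudometric_properties(self, seed):
        rng = np.random.default_rng(seed)
        spectra = [
            Spectrum(values=np.sort(rng.uniform(0, 1, rng.integers(3, 30))), n=0)
            for _ in range(3)
        ]
        a, b, c = spectra
        dab, dba = vs.ks_distance(a, b), vs.ks_distance(b, a)
        assert dab == pytest.approx(dba)
        assert vs.ks_distance(a, a) == 0.0
        assert 0.0 <= dab <= 1.0
        assert dab <= vs.ks_distance(a, c) + vs.ks_distance(c, b) + 1e-12


class TestDistanceMatrixAndClustering:
    def test_identical_graphs_zero_matrix(self):
        dm = vs.distance_matrix([K3, K3, K3])
        assert np.all(dm.d == 0)

    def test_matrix_matches_pairwise_recomputation(self, shape_set_graphs):
        dm = vs.distance_matrix(shape_set_graphs)
        spectra = [vs.laplacian_spectrum(g) for g in shape_set_graphs]
        for i in range(len(spectra)):
            for j in range(len(spectra)):
                expected = vs.ks_distance(spectra[i], spectra[j]) if i != j else 0.0
                assert dm.d[i, j] == pytest.approx(expected)

    def test_shape_classes_recovered(self, shape_set_graphs, shape_set_classes):
        dm = vs.distance_matrix(shape_set_graphs)
        labels = vs.cluster(dm, 3)
        assert vs.bhi(labels, shape_set_classes) == 1.0

    def test_k_equals_n_singletons(self, shape_set_graphs):
        dm = vs.distance_matrix(shape_set_graphs)
        labels = vs.cluster(dm, len(shape_set_graphs))
        assert len(set(labels)) == len(shape_set_graphs)

    def test_invalid_k(self, shape_set_graphs):
        dm = vs.distance_matrix(shape_set_graphs)
        with pytest.raises(ValueError):
            vs.cluster(dm, 0)
        with pytest.raises(ValueError):
            vs.cluster(dm, 99)

    def test_newick_leaves(self, shape_set_graphs):
        dm = vs.distance_matrix(shape_set_graphs)
        nwk = dendrogram_newick(dm)
        assert nwk.endswith(";")
        for sid in dm.ids:
            assert sid in nwk


class TestEmbed2D:
    def test_equilateral_for_equidistant_shapes(self):
        d = np.full((3, 3), 0.6)
        np.fill_diagonal(d, 0.0)
        coords = vs.embed_2d(vs.SpectralDistanceMatrix(ids=list("abc"), d=d))
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(coords), [0.6] * 3, atol=1e-9)

    def test_zero_matrix_collapses_to_origin(self):
        dm = vs.SpectralDistanceMatrix(ids=list("abc"), d=np.zeros((3, 3)))
        np.testing.assert_allclose(vs.embed_2d(dm), 0.0, atol=1e-12)

    def test_embedding_correlates_with_distances(self, shape_set_graphs):
        from scipy.spatial.distance import pdist, squareform
        from scipy.stats import spearmanr

        dm = vs.distance_matrix(shape_set_graphs)
        emb = vs.embed_2d(dm)
        rho = spearmanr(squareform(dm.d, checks=False), pdist(emb)).statistic
        assert rho > 0.7


class TestRotationalDistance:
    def test_self_distance_zero(self, shape_set_graphs):
        g = shape_set_graphs[3]
        assert vs.rotational_distance(g, g) == 0.0

    def test_cyclic_relabeling_invariance(self, shape_set_graphs):
        g = shape_set_graphs[4]
        shift = 7
        perm = np.roll(np.arange(g.n), shift)
        gp = graph_from_adjacency(g.A[np.ix_(perm, perm)], coords=g.nodes[perm])
        assert vs.rotational_distance(g, gp) == pytest.approx(0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            A1 = (rng.uniform(size=(8, 8)) < 0.4).astype(float)
            A1 = np.triu(A1, 1) + np.triu(A1, 1).T
            A2 = (rng.uniform(size=(8, 8)) < 0.4).astype(float)
            A2 = np.triu(A2, 1) + np.triu(A2, 1).T
            g1, g2 = graph_from_adjacency(A1), graph_from_adjacency(A2)
            assert vs.rotational_distance(g1, g2) == pytest.approx(
                brute_rotational_distance(A1, A2)
            )

    def test_unequal_sizes_direct_to_reduce(self, shape_set_graphs):
        small = vs.reduce_nodes(shape_set_graphs[0], 15)
        with pytest.raises(ValueError, match="reduce_nodes"):
            vs.rotational_distance(shape_set_graphs[0], small)


class TestReduceNodes:
    def test_target_equals_n_unchanged(self, shape_set_graphs):
        g = shape_set_graphs[0]
        r = vs.reduce_nodes(g, g.n)
        assert np.array_equal(r.A, g.A)

    def test_convex_stays_complete(self):
        g = vs.graph_from_points(vs.make_ellipse_nodes(20, (5.0, 5.0)).points)
        r = vs.reduce_nodes(g, 12)
        assert r.n == 12
        assert r.m == 12 * 11 // 2

    def test_bhi_retained_after_one_step(self, shape_set_graphs, shape_set_classes):
        reduced = [vs.reduce_nodes(g, 19) for g in shape_set_graphs]
        labels = vs.cluster(vs.distance_matrix(reduced), 3)
        assert vs.bhi(labels, shape_set_classes) == 1.0

    def test_bhi_floor_after_reduction_to_17(self, shape_set_graphs, shape_set_classes):
        reduced = [vs.reduce_nodes(g, 17) for g in shape_set_graphs]
        labels = vs.cluster(vs.distance_matrix(reduced), 3)
        assert vs.bhi(labels, shape_set_classes) >= 0.64

    def test_invalid_targets(self, shape_set_graphs):
        with pytest.raises(ValueError):
            vs.reduce_nodes(shape_set_graphs[0], 2)


class TestBHI:
    def test_pure_clusters(self):
        assert vs.bhi([0, 0, 1, 1], ["a", "a", "b", "b"]) == 1.0

    def test_one_mixed_cluster(self):
        assert vs.bhi([0, 0, 0], ["a", "a", "b"]) == pytest.approx(1 / 3)

    def test_singletons_skipped(self):
        assert vs.bhi([0, 0, 1], ["a", "a", "b"]) == 1.0

    def test_all_singletons_rejected(self):
        with pytest.raises(ValueError):
            vs.bhi([0, 1, 2], ["a", "a", "b"])

    def test_random_labels_near_class_frequency(self):
        rng = np.random.default_rng(0)
        classes = np.repeat(["a", "b", "c"], 10)
        vals = [
            vs.bhi(rng.integers(0, 3, 30), classes) for _ in range(200)
        ]
        # expectation for random grouping of 3 balanced classes is ~1/3
        assert np.mean(vals) == pytest.approx(1 / 3, abs=0.05)
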