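"""Connectome construction: cube nodes, similarity, FDR threshold, graph metrics."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gmconnsurv.connectome import (
    aggregate_regional_efficiency,
    all_local_efficiencies,
    assemble_connectome_features,
    binarize_and_connect,
    connectome_feature_names,
    degree_and_size,
    estimate_fdr_threshold,
    extract_cube_nodes,
    local_efficiency,
    regional_gray_matter_volumes,
    similarity_matrix,
    subject_connectome_features,
    total_gray_matter_volume,
    CubeNodeSet,
)
from gmconnsurv.synthetic import GrayMatterVolume, generate_atlas


def _nodes_from_matrix(X: np.ndarray) -> CubeNodeSet:
    n = X.shape[0]
    return CubeNodeSet(
        node_values=np.asarray(X, dtype=float),
        node_centers=np.zeros((n, 3), dtype=int),
        cube_edge=3,
        node_region=np.ones(n, dtype=np.int64),
    )


from oracles import brute_force_local_efficiency  # noqa: E402


class TestCubeNodes:
    def test_full_mask_tiling_count(self):
        vol = GrayMatterVolume(values=np.random.default_rng(0).uniform(size=(6, 6, 6)))
        atlas = np.ones((6, 6, 6), dtype=np.int32)
        nodes = extract_cube_nodes(vol, atlas)
        assert nodes.n_nodes == 8
        assert nodes.node_values.shape == (8, 27)

    def test_out_of_mask_cube_excluded(self):
        values = np.random.default_rng(1).uniform(size=(6, 3, 3))
        mask = np.ones((6, 3, 3), dtype=bool)
        mask[3:] = False  # second cube entirely out of mask
        atlas = np.ones((6, 3, 3), dtype=np.int32)
        atlas[3:] = 0
        with pytest.raises(ValueError):  # only one node left
            extract_cube_nodes(GrayMatterVolume(values=values, mask=mask), atlas)

    def test_node_values_match_direct_indexing(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(size=(9, 9, 9))
        vol = GrayMatterVolume(values=values)
        atlas = np.ones((9, 9, 9), dtype=np.int32)
        nodes = extract_cube_nodes(vol, atlas)
        for k in range(nodes.n_nodes):
            x, y, z = nodes.node_centers[k]
            cube = values[x : x + 3, y : y + 3, z : z + 3].ravel()
            assert np.array_equal(nodes.node_values[k], cube)

    def test_majority_region_label(self):
        values = np.full((3, 3, 3), 0.5)
        atlas = np.ones((3, 3, 3), dtype=np.int32)
        atlas[0] = 2  # 9 voxels region 2, 18 voxels region 1
        nodes = extract_cube_nodes(
            GrayMatterVolume(values=np.tile(values, (2, 1, 1))),
            np.tile(atlas, (2, 1, 1)),
        )
        assert set(nodes.node_region) == {1}

    def test_min_mask_fraction_boundary_rule(self):
        values = np.random.default_rng(3).uniform(size=(9, 3, 3))
        mask = np.ones((9, 3, 3), dtype=bool)
        mask[6:, :, :2] = False  # third cube has 9/27 in-mask
        atlas = np.ones((9, 3, 3), dtype=np.int32)
        vol = GrayMatterVolume(values=values, mask=mask)
        assert extract_cube_nodes(vol, atlas, min_mask_fraction=0.5).n_nodes == 2
        assert extract_cube_nodes(vol, atlas, min_mask_fraction=0.3).n_nodes == 3


class TestSimilarity:
    def test_self_and_affine_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(size=27)
        X = np.stack([a, 2 * a + 1, rng.uniform(size=27)])
        r, kept = similarity_matrix(_nodes_from_matrix(X))
        assert np.allclose(np.diag(r), 1.0)
        assert r[0, 1] == pytest.approx(1.0)

    def test_matches_direct_pearson(self):
        X = np.array(
            [
                np.arange(27) % 5,
                (np.arange(27) * 7) % 11,
                (np.arange(27) * 3 + 2) % 13,
            ],
            dtype=float,
        )
        r, _ = similarity_matrix(_nodes_from_matrix(X))
        expected = np.corrcoef(X)
        assert np.allclose(r, expected, atol=1e-12)

    def test_constant_node_dropped_or_raises(self):
        X = np.vstack([np.full(27, 0.5), np.random.default_rng(5).uniform(size=(2, 27))])
        r, kept = similarity_matrix(_nodes_from_matrix(X), drop_constant=True)
        assert r.shape == (2, 2) and np.array_equal(kept, [1, 2])
        with pytest.raises(ValueError, match="node 0"):
            similarity_matrix(_nodes_from_matrix(X), drop_constant=False)

    def test_rotation_maximized_at_least_plain(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(size=(4, 27))
        nodes = _nodes_from_matrix(X)
        plain, _ = similarity_matrix(nodes)
        rot, _ = similarity_matrix(nodes, maximize_over_rotations=True)
        assert np.all(rot + 1e-12 >= plain)


def _correlated_nodes(n_nodes=60, seed=7, signal=0.8):
    """Nodes sharing a latent 27-vector: genuine supra-null correlations."""
    rng = np.random.default_rng(seed)
    shared = rng.normal(size=27)
    X = signal * shared + rng.normal(size=(n_nodes, 27))
    return _nodes_from_matrix(X), X


class TestFDRThreshold:
    def test_null_exceedance_bounded_by_alpha(self):
        nodes, X = _correlated_nodes()
        thr = estimate_fdr_threshold(nodes, alpha=0.05, n_permutations=40, seed=0)
        # permutation oracle: fresh independent permutations
        rng = np.random.default_rng(99)
        null = []
        for _ in range(40):
            Xp = np.take_along_axis(X, np.argsort(rng.random(X.shape), axis=1), axis=1)
            null.append(np.corrcoef(Xp)[np.triu_indices(X.shape[0], 1)])
        null = np.concatenate(null)
        assert (null > thr).mean() <= 0.05

    def test_pure_noise_has_no_attainable_threshold(self):
        # with no real covariance, observed ≈ null at every threshold, so
        # the discovery-rate bound cannot be met and the advisory error fires
        rng = np.random.default_rng(7)
        nodes = _nodes_from_matrix(rng.normal(size=(60, 27)))
        with pytest.raises(ValueError, match="larger alpha"):
            estimate_fdr_threshold(nodes, alpha=0.05, n_permutations=40, seed=0)

    def test_monotone_in_alpha(self):
        nodes, _ = _correlated_nodes(seed=8)
        t_strict = estimate_fdr_threshold(nodes, alpha=0.01, n_permutations=10, seed=1)
        t_loose = estimate_fdr_threshold(nodes, alpha=0.10, n_permutations=10, seed=1)
        assert t_strict >= t_loose

    def test_deterministic_per_seed(self):
        nodes, _ = _correlated_nodes(n_nodes=30, seed=9)
        assert estimate_fdr_threshold(nodes, seed=3) == estimate_fdr_threshold(
            nodes, seed=3
        )


class TestBinarize:
    def test_all_isolated_raises_under_error_policy(self):
        r = np.eye(3)
        with pytest.raises(ValueError, match="isolated"):
            binarize_and_connect(r, 0.5, reconnect_policy="error")

    def test_relax_policy_lowers_threshold_until_connected(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.9
        r[0, 2] = r[2, 0] = 0.2
        r[1, 2] = r[2, 1] = 0.1
        conn = binarize_and_connect(r, 0.5, reconnect_policy="relax")
        assert conn.threshold_used < 0.5
        assert conn.adjacency.any(axis=1).all()

    def test_exact_enumeration_three_nodes(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.9
        r[0, 2] = r[2, 0] = 0.2
        r[1, 2] = r[2, 1] = 0.1
        with pytest.raises(ValueError):
            binarize_and_connect(r, 0.5, reconnect_policy="error")
        conn = binarize_and_connect(r, 0.05, reconnect_policy="error")
        assert conn.adjacency.sum() == 6  # complete graph on 3 nodes

    def test_postconditions_on_random_input(self, rng):
        X = rng.normal(size=(20, 27))
        r = np.corrcoef(X)
        conn = binarize_and_connect(r, 0.1)
        A = conn.adjacency
        assert np.array_equal(A, A.T)
        assert not A.diagonal().any()


class TestLocalEfficiency:
    def test_complete_graph_is_one(self):
        A = ~np.eye(4, dtype=bool)
        for i in range(4):
            assert local_efficiency(A, i) == pytest.approx(1.0)

    def test_star_center_is_zero(self):
        A = np.zeros((5, 5), dtype=bool)
        A[0, 1:] = A[1:, 0] = True
        assert local_efficiency(A, 0) == 0.0

    def test_square_with_diagonal(self):
        # edges 12,23,34,41,13 (1-indexed); node 1 -> 5/6
        A = np.zeros((4, 4), dtype=bool)
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)]:
            A[i, j] = A[j, i] = True
        assert local_efficiency(A, 0) == pytest.approx(5.0 / 6.0)

    def test_out_of_range_raises(self):
        A = np.zeros((3, 3), dtype=bool)
        with pytest.raises(IndexError):
            local_efficiency(A, 5)

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 31))
            p = float(rng.uniform(0.1, 0.6))
            A = rng.random((n, n)) < p
            A = np.triu(A, 1)
            A = A | A.T
            i = int(rng.integers(n))
            assert local_efficiency(A, i) == pytest.approx(
                brute_force_local_efficiency(A, i), abs=1e-12
            )

    def test_matches_networkx_local_efficiency(self, rng):
        # independent library cross-check of the whole-graph average
        for seed in range(10):
            G = nx.gnp_random_graph(25, 0.25, seed=seed)
            A = nx.to_numpy_array(G, dtype=bool)
            ours = all_local_efficiencies(A).mean()
            assert ours == pytest.approx(nx.local_efficiency(G), abs=1e-12)


class TestDegreeAndAggregation:
    def test_complete_and_path_graph_degrees(self):
        K4 = ~np.eye(4, dtype=bool)
        deg, size, mean = degree_and_size(K4)
        assert np.array_equal(deg, [3, 3, 3, 3]) and size == 4 and mean == 3.0
        P3 = np.zeros((3, 3), dtype=bool)
        P3[0, 1] = P3[1, 0] = P3[1, 2] = P3[2, 1] = True
        deg, size, mean = degree_and_size(P3)
        assert np.array_equal(deg, [1, 2, 1]) and mean == pytest.approx(4 / 3)

    @given(st.integers(min_value=2, max_value=25), st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=50, deadline=None)
    def test_handshake_lemma(self, n, seed):
        rng = np.random.default_rng(seed)
        A = rng.random((n, n)) < 0.3
        A = np.triu(A, 1)
        A = A | A.T
        deg, size, mean = degree_and_size(A)
        assert deg.sum() == 2 * np.triu(A, 1).sum()
        assert size == n

    def test_regional_means(self):
        eff = np.array([0.0, 1.0, 0.5])
        reg = np.array([1, 1, 2])
        out = aggregate_regional_efficiency(eff, reg, 2)
        assert np.allclose(out, [0.5, 0.5])

    def test_single_region_degenerate(self):
        eff = np.array([0.2, 0.4, 0.9])
        assert aggregate_regional_efficiency(eff, np.ones(3, dtype=int), 1)[
            0
        ] == pytest.approx(eff.mean())

    def test_matches_groupby_oracle(self, rng):
        import pandas as pd

        eff = rng.uniform(size=100)
        reg = rng.integers(1, 8, size=100)
        reg[:7] = np.arange(1, 8)  # every region occupied
        ours = aggregate_regional_efficiency(eff, reg, 7)
        oracle = pd.Series(eff).groupby(reg).mean().sort_index().to_numpy()
        assert np.allclose(ours, oracle)

    def test_empty_region_raises(self):
        with pytest.raises(ValueError, match=r"\[2\]"):
            aggregate_regional_efficiency(np.ones(3), np.array([1, 1, 3]), 3)


class TestVolumes:
    def test_unit_conversion(self):
        values = np.zeros((10, 10, 10))
        values[:10, :10, :10] = 0.0
        values.ravel()[:1000] = 1.0
        vol = GrayMatterVolume(values=values)
        assert total_gray_matter_volume(vol) == pytest.approx(1.0)

    def test_voxel_size_scaling(self):
        values = np.full((4, 4, 4), 0.5)
        v1 = total_gray_matter_volume(GrayMatterVolume(values=values))
        v2 = total_gray_matter_volume(
            GrayMatterVolume(values=values, voxel_size_mm=(2.0, 2.0, 2.0))
        )
        assert v2 == pytest.approx(8 * v1)

    def test_regional_partition_additivity(self):
        atlas = generate_atlas((18, 18, 18), 12)
        rng = np.random.default_rng(11)
        values = np.where(atlas > 0, rng.uniform(size=atlas.shape), 0.0)
        vol = GrayMatterVolume(values=values, mask=atlas > 0)
        regional = regional_gray_matter_volumes(vol, atlas)
        assert regional.sum() == pytest.approx(total_gray_matter_volume(vol))

    def test_regional_matches_masked_sum_oracle(self):
        atlas = generate_atlas((18, 18, 18), 12)
        ix = np.indices(atlas.shape).sum(axis=0)
        values = np.where(atlas > 0, (ix % 2).astype(float), 0.0)  # checkerboard
        vol = GrayMatterVolume(values=values, mask=atlas > 0)
        regional = regional_gray_matter_volumes(vol, atlas)
        for lab in range(1, 13):
            assert regional[lab - 1] == pytest.approx(values[atlas == lab].sum() / 1000)


class TestFeatureAssembly:
    def test_93_predictors_for_90_regions(self):
        fv = assemble_connectome_features(np.linspace(0, 1, 90), 1200.0, 800, 12.5)
        assert fv.to_array().shape == (93,)
        assert len(fv.names) == 93
        assert len(set(fv.names)) == 93
        assert fv.names[-3:] == ["brain_volume_ml", "network_size", "mean_degree"]

    def test_names_deterministic(self):
        assert connectome_feature_names(4) == connectome_feature_names(4)

    def test_end_to_end_subject_deterministic(self, small_cohort):
        vol, atlas = small_cohort.volumes[0], small_cohort.atlas
        f1 = subject_connectome_features(vol, atlas, seed=5)
        f2 = subject_connectome_features(vol, atlas, seed=5)
        assert np.array_equal(f1.to_array(), f2.to_array())

    def test_full_pipeline_invariants(self, small_cohort, small_spec):
        fv = subject_connectome_features(
            small_cohort.volumes[1], small_cohort.atlas, seed=0
        )
        assert fv.to_array().size == small_spec.n_regions + 3
        assert np.all(fv.regional_efficiency >= 0) and np.all(
            fv.regional_efficiency <= 1
        )
        assert fv.total_brain_volume_ml > 0


class TestPlantedStructureRecovery:
    def test_coloaded_regions_correlate_more(self, small_cohort, small_spec):
        """Cube pairs in co-loaded regions beat independent-region pairs on average."""
        L = small_spec.loading_matrix
        dom = np.argmax(np.abs(L), axis=1)
        acc_same = []
        acc_diff = []
        for vol in small_cohort.volumes:
            nodes = extract_cube_nodes(vol, small_cohort.atlas)
            r, kept = similarity_matrix(nodes)
            reg = nodes.node_region[kept]
            fac = dom[reg - 1]
            cross_region = reg[:, None] != reg[None, :]
            same_fac = (fac[:, None] == fac[None, :]) & cross_region
            diff_fac = (fac[:, None] != fac[None, :]) & cross_region
            iu = np.triu(np.ones_like(r, dtype=bool), 1)
            acc_same.append(r[same_fac & iu].mean())
            acc_diff.append(r[diff_fac & iu].mean())
        assert np.mean(acc_same) > np.mean(acc_diff)
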