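"""Scene assembly: normalization, downsampling, colors, full pipeline."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cellvr import (
    BuildConfig,
    IngestError,
    assign_categorical_colors,
    build_scene,
    downsample,
    lift_to_3d,
    map_continuous_colors,
    normalize_coordinates,
    write_scene_package,
)
from cellvr.scene_build import downsample_indices, stratified_quotas


class TestNormalize:
    def test_two_point_symmetry(self):
        out, tf = normalize_coordinates(np.array([[1, 1, 0], [3, 1, 0]],
                                                 float))
        np.testing.assert_allclose(tf["centroid"], [2, 1, 0])
        assert tf["scale"] == pytest.approx(1.0)
        np.testing.assert_allclose(out, [[-1, 0, 0], [1, 0, 0]])

    def test_single_cell_degenerate_rule(self):
        out, tf = normalize_coordinates(np.array([[5.0, 5.0, 5.0]]))
        np.testing.assert_allclose(out, [[0, 0, 0]])
        assert tf["scale"] == 1.0

    def test_inverse_transform_recovers_input(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(scale=40.0, size=(200, 3))
        out, tf = normalize_coordinates(pts)
        back = out * tf["scale"] + tf["centroid"]
        np.testing.assert_allclose(back, pts, atol=1e-9)
        assert np.linalg.norm(out, axis=1).max() == pytest.approx(1.0)

    def test_idempotent_up_to_degenerate_scale(self):
        rng = np.random.default_rng(1)
        out1, _ = normalize_coordinates(rng.normal(size=(50, 3)))
        out2, tf2 = normalize_coordinates(out1)
        np.testing.assert_allclose(out1, out2, atol=1e-12)
        assert tf2["scale"] == pytest.approx(1.0, abs=1e-12)

    def test_rejects_empty_and_nan(self):
        with pytest.raises(ValueError):
            normalize_coordinates(np.zeros((0, 3)))
        with pytest.raises(ValueError):
            normalize_coordinates(np.array([[np.nan, 0, 0]]))


class TestLift:
    def test_plane_embedding(self):
        out = lift_to_3d(np.array([[0.3, -0.7]]))
        np.testing.assert_array_equal(out, [[0.3, -0.7, 0.0]])

    def test_empty_set(self):
        assert lift_to_3d(np.zeros((0, 2))).shape == (0, 3)

    def test_all_z_exactly_zero(self):
        rng = np.random.default_rng(2)
        out = lift_to_3d(rng.normal(size=(100, 2)))
        assert (out[:, 2] == 0.0).all()


def _quota_oracle(counts, max_cells):
    """Independent largest-remainder apportionment using exact Fractions."""
    n = sum(counts)
    shares = [Fraction(c * max_cells, n) for c in counts]
    quotas = [int(s) for s in shares]
    order = sorted(range(len(counts)),
                   key=lambda i: (-(shares[i] - quotas[i]), i))
    for i in order[: max_cells - sum(quotas)]:
        quotas[i] += 1
    for i, c in enumerate(counts):
        if c > 0 and quotas[i] == 0:
            donor = max(range(len(quotas)), key=lambda j: quotas[j])
            quotas[donor] -= 1
            quotas[i] = 1
    return quotas


class TestDownsample:
    def test_identity_when_small(self, cluster_data):
        raw, _ = cluster_data
        assert downsample(raw, 1000, seed=0) is raw

    def test_proportional_split_900_100(self):
        labels = np.array(["big"] * 900 + ["small"] * 100)
        idx = downsample_indices(1000, 100, seed=4, labels=labels)
        kept = labels[idx]
        assert (kept == "big").sum() == 90
        assert (kept == "small").sum() == 10

    def test_same_seed_same_selection(self):
        labels = np.array(["a", "b"] * 500)
        i1 = downsample_indices(1000, 77, seed=9, labels=labels)
        i2 = downsample_indices(1000, 77, seed=9, labels=labels)
        np.testing.assert_array_equal(i1, i2)

    def test_quotas_match_exact_oracle_over_random_splits(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            k = int(rng.integers(2, 8))
            counts = [int(c) for c in rng.integers(1, 500, size=k)]
            max_cells = int(rng.integers(k, sum(counts)))
            got = stratified_quotas(counts, max_cells)
            assert got == _quota_oracle(counts, max_cells)
            assert sum(got) == max_cells
            assert all(q >= 1 for q in got)

    def test_minimum_one_per_category(self):
        counts = [997, 1, 1, 1]
        quotas = stratified_quotas(counts, 10)
        assert quotas[1:] == [1, 1, 1] and quotas[0] == 7

    def test_more_categories_than_budget_rejected(self):
        with pytest.raises(ValueError):
            stratified_quotas([5, 5, 5], 2)

    def test_all_tracks_subset_consistently(self, cluster_data):
        raw, _ = cluster_data
        small = downsample(raw, 100, seed=5, stratify_key="cluster")
        assert small.n_cells == 100
        assert len(small.obs) == 100
        assert small.matrix_layers["X"].shape[0] == 100
        assert small.embeddings["umap"].shape[0] == 100
        assert [small.cell_ids[i] for i in range(100)] == \
            list(small.obs.index)

    def test_scene_downsample_subsets_tracks(self, full_scene):
        small = downsample(full_scene, 50, seed=1)
        assert small.cells.n_cells == 50
        assert all(len(t.values) == 50 for t in small.annotations)
        assert all(len(t.values) == 50 for t in small.features)
        assert small.velocity.cell_vectors.shape == (50, 3)


class TestColors:
    def test_lexicographic_assignment(self):
        palette = ["#111111", "#222222"]
        mapping = assign_categorical_colors(["B", "A"], palette)
        assert mapping == {"A": "#111111", "B": "#222222"}

    def test_palette_cycles(self):
        palette = [f"#{i:06x}" for i in range(20)]
        labels = [f"{i:02d}" for i in range(21)]
        mapping = assign_categorical_colors(labels, palette)
        assert mapping["20"] == palette[0]

    def test_mapping_order_invariant(self):
        rng = np.random.default_rng(0)
        labels = [f"cat{i}" for i in range(8)]
        m1 = assign_categorical_colors(labels)
        m2 = assign_categorical_colors(list(rng.permutation(labels)))
        assert m1 == m2

    def test_affine_scaling_without_clip(self):
        u = map_continuous_colors([0.0, 0.5, 1.0])
        np.testing.assert_allclose(u, [0, 0.5, 1.0])

    def test_constant_input_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="degenerate range"):
            u = map_continuous_colors([3.0, 3.0, 3.0])
        np.testing.assert_array_equal(u, 0.0)

    def test_percentile_clipping_matches_empirical_oracle(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=1000)
        u = map_continuous_colors(vals, clip_percentiles=(1, 99))
        q1, q99 = np.percentile(vals, [1, 99])
        assert (u[vals <= q1] == 0.0).all()
        assert (u[vals >= q99] == 1.0).all()
        inside = (vals > q1) & (vals < q99)
        np.testing.assert_allclose(u[inside],
                                   (vals[inside] - q1) / (q99 - q1),
                                   atol=1e-12)

    def test_nan_values_rejected(self):
        with pytest.raises(ValueError):
            map_continuous_colors([1.0, np.nan])


class TestBuildScene:
    def test_end_to_end_counts_and_validity(self, cluster_data):
        from cellvr import validate_scene

        raw, _ = cluster_data
        scene = build_scene(raw, BuildConfig(
            annotation_keys=["cluster", "score"],
            feature_ids=["gene0", "gene1", "gene2"]))
        assert scene.cells.n_cells == 300
        assert len(scene.annotations) == 2 and len(scene.features) == 3
        assert validate_scene(scene) == []

    def test_downsampled_build_preserves_proportions(self, cluster_data):
        raw, _ = cluster_data
        scene = build_scene(raw, BuildConfig(
            annotation_keys=["cluster"], max_cells=100, seed=3))
        assert scene.cells.n_cells == 100
        tr = scene.annotations[0]
        counts = np.bincount(np.asarray(tr.values, dtype=int))
        # 300 cells in 3 balanced clusters -> 100 kept, quota 33/33/34-ish
        oracle = _quota_oracle([100, 100, 100], 100)
        assert sorted(counts.tolist()) == sorted(oracle)

    def test_unknown_feature_named_in_error(self, cluster_data):
        raw, _ = cluster_data
        with pytest.raises(IngestError, match="XYZ"):
            build_scene(raw, BuildConfig(feature_ids=["XYZ"]))

    def test_conservation_without_downsampling(self, trajectory_data):
        raw, _ = trajectory_data
        scene = build_scene(raw, BuildConfig(
            annotation_keys=["branch", "pseudotime"],
            feature_ids=["geneUp"]))
        n = raw.n_cells
        assert scene.cells.n_cells == n
        assert all(len(t.values) == n for t in scene.annotations)
        assert all(len(t.values) == n for t in scene.features)

    def test_graph_nodes_equal_scene_centroids(self, cluster_scene):
        labels_track = cluster_scene.annotations[0]
        labels = np.asarray(labels_track.labels)[
            np.asarray(labels_track.values, dtype=int)]
        pos = np.asarray(cluster_scene.cells.positions)
        for node in cluster_scene.graph.nodes:
            member = labels == node.node_id
            np.testing.assert_allclose(node.position,
                                       pos[member].mean(axis=0),
                                       atol=1e-9)

    def test_fixed_seed_is_byte_reproducible(self, tmp_path, cluster_data):
        raw, _ = cluster_data
        cfg = BuildConfig(annotation_keys=["cluster", "score"],
                          feature_ids=["gene0"], max_cells=150, seed=12)
        write_scene_package(build_scene(raw, cfg), tmp_path / "a.zip")
        write_scene_package(build_scene(raw, cfg), tmp_path / "b.zip")
        assert (tmp_path / "a.zip").read_bytes() == \
            (tmp_path / "b.zip").read_bytes()

    def test_2d_embedding_lifted_and_flagged(self):
        from cellvr.ingest import RawDataset

        rng = np.random.default_rng(6)
        raw = RawDataset(cell_ids=[f"c{i}" for i in range(20)],
                         embeddings={"tsne": rng.normal(size=(20, 2))})
        scene = build_scene(raw, BuildConfig(embedding_name="tsne"))
        assert scene.manifest.source_dims == 2
        assert (np.asarray(scene.cells.positions)[:, 2] == 0.0).all()

    def test_velocity_vectors_share_scale_only(self, velocity_data):
        raw, _ = velocity_data
        scene = build_scene(raw, BuildConfig())
        scale = scene.manifest.transform["scale"]
        np.testing.assert_allclose(
            scene.velocity.cell_vectors,
            np.asarray(raw.velocity_embedding) / scale, atol=1e-12)

    def test_config_file_round_trip(self, tmp_path):
        cfg_path = tmp_path / "build.cfg"
        cfg_path.write_text(
            "embedding_name = tsne\n"
            "annotation_keys = cluster, score  # keys\n"
            "max_cells = 50\n"
            "clip_percentiles = 1, 99\n"
            "include_velocity = false\n")
        cfg = BuildConfig.from_file(cfg_path)
        assert cfg.embedding_name == "tsne"
        assert cfg.annotation_keys == ["cluster", "score"]
        assert cfg.max_cells == 50
        assert cfg.clip_percentiles == (1.0, 99.0)
        assert cfg.include_velocity is False


@given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=40))
def test_normalized_points_stay_in_unit_ball(xs):
    pts = np.column_stack([xs, np.roll(xs, 1), np.roll(xs, 2)])
    out, _ = normalize_coordinates(pts)
    assert np.linalg.norm(out, axis=1).max() <= 1.0 + 1e-9
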