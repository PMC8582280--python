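"""Readers and extraction: format round trips, graphs, curves, velocity."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cellvr import (
    IngestError,
    NoVelocityError,
    StructuralError,
    extract_abstract_graph,
    extract_embedding,
    extract_principal_curves,
    extract_velocity,
    read_annotated_matrix,
    read_delimited,
    read_loom,
)
from cellvr.ingest import Curve, RawDataset, resample_polyline
from cellvr.synthetic import write_h5ad, write_loom, write_tsv_bundle


# ---------------------------------------------------------------------------
# readers

class TestReaders:
    def test_h5ad_round_trip_preserves_everything(self, tmp_path,
                                                  cluster_data):
        raw, _ = cluster_data
        path = write_h5ad(raw, tmp_path / "c.h5ad")
        back = read_annotated_matrix(path)
        assert back.cell_ids == raw.cell_ids
        assert set(back.embeddings) == {"umap"}
        np.testing.assert_allclose(back.embeddings["umap"],
                                   raw.embeddings["umap"])
        assert list(back.obs.columns) == ["cluster", "score"]
        assert back.var_names == raw.var_names
        np.testing.assert_allclose(back.matrix_layers["X"],
                                   raw.matrix_layers["X"])
        assert back.cluster_key == "cluster"
        np.testing.assert_allclose(back.abstract_connectivities,
                                   raw.abstract_connectivities)

    def test_h5ad_and_loom_agree(self, tmp_path, velocity_data):
        raw, _ = velocity_data
        a = read_annotated_matrix(write_h5ad(raw, tmp_path / "v.h5ad"))
        b = read_loom(write_loom(raw, tmp_path / "v.loom"))
        assert a.cell_ids == b.cell_ids
        np.testing.assert_allclose(a.embeddings["umap"],
                                   b.embeddings["umap"], atol=1e-9)
        np.testing.assert_allclose(a.velocity_embedding,
                                   b.velocity_embedding, atol=1e-9)
        assert a.velocity_basis == b.velocity_basis == "umap"

    def test_loom_2d_embedding(self, tmp_path):
        rng = np.random.default_rng(3)
        raw = RawDataset(
            cell_ids=[f"c{i}" for i in range(100)],
            embeddings={"tsne": rng.normal(size=(100, 2))},
            var_names=["g0"],
            matrix_layers={"X": rng.normal(size=(100, 1))})
        back = read_loom(write_loom(raw, tmp_path / "t.loom"))
        assert back.embeddings["tsne"].shape == (100, 2)

    def test_loom_without_velocity_has_none(self, tmp_path, cluster_data):
        raw, _ = cluster_data
        back = read_loom(write_loom(raw, tmp_path / "c.loom"))
        assert back.velocity_embedding is None

    def test_loom_attribute_length_mismatch_is_structural(self, tmp_path,
                                                          cluster_data):
        import h5py

        raw, _ = cluster_data
        path = write_loom(raw, tmp_path / "bad.loom")
        with h5py.File(path, "a") as f:
            del f["col_attrs"]["score"]
            f["col_attrs"].create_dataset("score", data=np.zeros(7))
        with pytest.raises(StructuralError):
            read_loom(path)

    def test_missing_file_is_io_error(self, tmp_path):
        with pytest.raises(IngestError):
            read_annotated_matrix(tmp_path / "nope.h5ad")
        with pytest.raises(IngestError):
            read_loom(tmp_path / "nope.loom")

    def test_h5ad_without_embedding_lists_keys(self, tmp_path):
        import anndata

        adata = anndata.AnnData(X=np.zeros((5, 2)))
        adata.write_h5ad(tmp_path / "noemb.h5ad")
        with pytest.raises(StructuralError, match="obsm"):
            read_annotated_matrix(tmp_path / "noemb.h5ad")

    def test_zero_cell_container_reads_cleanly(self, tmp_path):
        import anndata

        adata = anndata.AnnData(X=np.zeros((0, 3)))
        adata.write_h5ad(tmp_path / "empty.h5ad")
        back = read_annotated_matrix(tmp_path / "empty.h5ad")
        assert back.n_cells == 0

    def test_tsv_bundle_round_trip(self, tmp_path, cluster_data):
        raw, _ = cluster_data
        paths = write_tsv_bundle(raw, tmp_path / "tsv")
        back = read_delimited(paths["coords"], paths["annotations"],
                              paths["features"], paths["graph"])
        assert back.cell_ids == raw.cell_ids
        np.testing.assert_allclose(back.embeddings["embedding"],
                                   raw.embeddings["umap"], rtol=1e-9)
        assert back.cluster_key == "cluster"
        np.testing.assert_allclose(back.abstract_connectivities,
                                   raw.abstract_connectivities, rtol=1e-9)

    def test_tsv_unmatched_annotation_id_named(self, tmp_path):
        (tmp_path / "coords.tsv").write_text(
            "cell_id\tx\ty\tz\nc1\t0\t0\t0\nc2\t1\t1\t1\n")
        (tmp_path / "ann.tsv").write_text(
            "cell_id\tlabel\nc1\ta\nc2\tb\ncX\tb\n")
        with pytest.raises(StructuralError, match="cX"):
            read_delimited(tmp_path / "coords.tsv", tmp_path / "ann.tsv")

    def test_tsv_duplicate_id_rejected(self, tmp_path):
        (tmp_path / "coords.tsv").write_text(
            "cell_id\tx\ty\nc1\t0\t0\nc1\t1\t1\n")
        with pytest.raises(StructuralError, match="c1"):
            read_delimited(tmp_path / "coords.tsv")

    def test_tsv_non_numeric_coordinate_rejected(self, tmp_path):
        (tmp_path / "coords.tsv").write_text(
            "cell_id\tx\ty\nc1\t0\toops\n")
        with pytest.raises(StructuralError, match="numeric"):
            read_delimited(tmp_path / "coords.tsv")

    def test_curve_sidecar_passthrough(self, tmp_path, trajectory_data):
        raw, _ = trajectory_data
        paths = write_tsv_bundle(raw, tmp_path / "tsv")
        back = read_delimited(paths["coords"], paths["annotations"],
                              paths["features"], paths["graph"])
        assert len(back.curve_set) == 3
        assert {c.curve_id for c in back.curve_set} == \
            {c.curve_id for c in raw.curve_set}

    def test_sidecar_unknown_group_rejected(self, tmp_path):
        (tmp_path / "coords.tsv").write_text(
            "cell_id\tx\ty\nc1\t0\t0\nc2\t1\t1\n")
        (tmp_path / "ann.tsv").write_text(
            "cell_id\tcluster\nc1\tg0\nc2\tg1\n")
        sidecar = {"kind": "abstract", "groups": ["g0", "g1", "gZ"],
                   "cluster_key": "cluster",
                   "connectivities": [[0, 1, 1], [1, 0, 1], [1, 1, 0]]}
        (tmp_path / "graph.json").write_text(json.dumps(sidecar))
        with pytest.raises(StructuralError, match="gZ"):
            read_delimited(tmp_path / "coords.tsv", tmp_path / "ann.tsv",
                           graph_sidecar=tmp_path / "graph.json")


# ---------------------------------------------------------------------------
# extraction

class TestExtractEmbedding:
    def test_three_dim_passthrough(self, cluster_data):
        raw, _ = cluster_data
        coords, dims = extract_embedding(raw, "umap")
        assert dims == 3 and coords.shape == (raw.n_cells, 3)

    def test_wide_embedding_truncated_to_first_three(self):
        rng = np.random.default_rng(0)
        raw = RawDataset(cell_ids=["a", "b"],
                         embeddings={"pca": rng.normal(size=(2, 50))})
        coords, dims = extract_embedding(raw, "pca")
        assert dims == 3
        np.testing.assert_array_equal(coords,
                                      raw.embeddings["pca"][:, :3])

    def test_two_dim_reported_as_two(self):
        raw = RawDataset(cell_ids=["a"],
                         embeddings={"tsne": np.zeros((1, 2))})
        _, dims = extract_embedding(raw, "tsne")
        assert dims == 2

    def test_unknown_name_lists_available(self, cluster_data):
        raw, _ = cluster_data
        with pytest.raises(IngestError, match="umap"):
            extract_embedding(raw, "missing")


class TestAbstractGraph:
    def _raw(self, conn, labels, coords):
        groups = sorted(set(labels))
        return RawDataset(
            cell_ids=[f"c{i}" for i in range(len(labels))],
            embeddings={"e": coords},
            obs=pd.DataFrame({"g": labels},
                             index=[f"c{i}" for i in range(len(labels))]),
            cluster_key="g", connectivity_groups=groups,
            abstract_connectivities=conn)

    def test_nodes_at_known_centroids_full_connectivity(self):
        centroids = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0]], float)
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        offsets = np.array([[1, 1, 0], [-1, 1, 0], [1, -1, 0], [-1, -1, 0]],
                           float)
        coords = np.vstack([c + offsets for c in centroids])
        conn = np.ones((3, 3)) - np.eye(3)
        g = extract_abstract_graph(self._raw(conn, labels, coords), coords,
                                   "g")
        assert len(g.nodes) == 3 and len(g.edges) == 3
        for node, c in zip(g.nodes, centroids):
            np.testing.assert_allclose(node.position, c, atol=1e-12)

    def test_weight_floor_drops_all_edges_keeps_nodes(self):
        labels = ["a", "a", "b", "b"]
        coords = np.arange(12, dtype=float).reshape(4, 3)
        conn = np.array([[0.0, 0.02], [0.02, 0.0]])
        g = extract_abstract_graph(self._raw(conn, labels, coords), coords,
                                   "g", weight_floor=0.05)
        assert len(g.nodes) == 2 and len(g.edges) == 0

    def test_widths_ordered_like_weights_over_random_matrices(self):
        rng = np.random.default_rng(42)
        labels = [f"g{i}" for i in range(5) for _ in range(3)]
        coords = rng.normal(size=(15, 3))
        for _ in range(100):
            m = rng.uniform(0.1, 1.0, size=(5, 5))
            conn = np.triu(m, 1) + np.triu(m, 1).T
            g = extract_abstract_graph(self._raw(conn, labels, coords),
                                       coords, "g", weight_floor=0.0)
            es = sorted(g.edges, key=lambda e: e.weight)
            assert all(a.width < b.width
                       for a, b in zip(es, es[1:]) if a.weight < b.weight)

    def test_node_positions_permutation_invariant(self):
        rng = np.random.default_rng(7)
        labels = np.array(["a"] * 6 + ["b"] * 6)
        coords = rng.normal(size=(12, 3))
        conn = np.array([[0.0, 0.5], [0.5, 0.0]])
        g1 = extract_abstract_graph(self._raw(conn, list(labels), coords),
                                    coords, "g")
        perm = rng.permutation(12)
        g2 = extract_abstract_graph(
            self._raw(conn, list(labels[perm]), coords[perm]),
            coords[perm], "g")
        for n1, n2 in zip(g1.nodes, g2.nodes):
            np.testing.assert_allclose(n1.position, n2.position,
                                       atol=1e-12)

    def test_empty_group_rejected(self):
        labels = ["a", "a", "b", "b"]
        coords = np.zeros((4, 3))
        raw = self._raw(np.zeros((3, 3)), labels, coords)
        raw.connectivity_groups = ["a", "b", "ghost"]
        with pytest.raises(StructuralError):
            extract_abstract_graph(raw, coords, "g")

    def test_matrix_size_mismatch_rejected(self):
        labels = ["a", "a", "b", "b"]
        coords = np.zeros((4, 3))
        raw = self._raw(np.zeros((2, 2)), labels, coords)
        raw.abstract_connectivities = np.zeros((5, 5))
        with pytest.raises(StructuralError):
            extract_abstract_graph(raw, coords, "g")


class TestPrincipalCurves:
    def test_straight_segment_uniformly_resampled(self):
        pts = np.array([[0, 0, 0], [1, 0, 0]], float)
        out = resample_polyline(pts, 5)
        np.testing.assert_allclose(out[:, 0], [0, 0.25, 0.5, 0.75, 1.0],
                                   atol=1e-12)
        np.testing.assert_allclose(out[:, 1:], 0, atol=1e-12)

    def test_right_angle_midpoint_lands_on_corner(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]], float)
        out = resample_polyline(pts, 3)
        np.testing.assert_allclose(out[1], [1, 0, 0], atol=1e-12)

    def test_matches_dense_arc_length_oracle_on_random_curves(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            t = np.linspace(0, 1, 200)
            coeff = rng.normal(size=(3, 4))
            curve = np.column_stack([
                sum(c * t ** k for k, c in enumerate(row))
                for row in coeff])
            k = int(rng.integers(5, 40))
            got = resample_polyline(curve, k)
            # oracle: dense cumulative arc-length table, brute interpolation
            seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
            s = np.concatenate([[0.0], np.cumsum(seg)])
            targets = np.linspace(0.0, s[-1], k)
            expect = np.empty((k, 3))
            for i, target in enumerate(targets):
                j = int(np.searchsorted(s, target, side="right")) - 1
                j = min(j, len(seg) - 1)
                f = 0.0 if seg[j] == 0 else (target - s[j]) / seg[j]
                expect[i] = curve[j] + f * (curve[j + 1] - curve[j])
            assert np.abs(got - expect).max() < 1e-6

    def test_consecutive_duplicates_dropped(self):
        pts = np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 0, 0]], float)
        out = resample_polyline(pts, 3)
        np.testing.assert_allclose(out[:, 0], [0, 0.5, 1.0], atol=1e-12)

    def test_degenerate_curve_rejected(self):
        pts = np.zeros((4, 3))
        with pytest.raises(StructuralError):
            resample_polyline(pts, 3)

    def test_graph_from_curve_set(self, trajectory_data):
        raw, _ = trajectory_data
        g = extract_principal_curves(raw, k_samples=30)
        assert g.graph_kind == "principal_curve"
        assert len(g.nodes) == 4 and len(g.edges) == 3
        for e in g.edges:
            assert e.polyline.shape == (30, 3)
            assert e.weight == 1.0

    @given(st.integers(2, 50))
    def test_resampled_endpoints_are_curve_termini(self, k):
        pts = np.array([[0, 0, 0], [2, 1, 0], [3, -1, 2]], float)
        out = resample_polyline(pts, k)
        np.testing.assert_allclose(out[0], pts[0], atol=1e-12)
        np.testing.assert_allclose(out[-1], pts[-1], atol=1e-12)


class TestExtractVelocity:
    def test_two_dim_vectors_lifted_and_scaled(self):
        raw = RawDataset(cell_ids=["a", "b"],
                         embeddings={"umap": np.zeros((2, 2))},
                         velocity_embedding=np.ones((2, 2)),
                         velocity_basis="umap")
        vec = extract_velocity(raw, "umap", scale=2.0)
        np.testing.assert_allclose(vec, [[0.5, 0.5, 0], [0.5, 0.5, 0]])

    def test_zero_vectors_stay_zero(self):
        raw = RawDataset(cell_ids=["a"],
                         embeddings={"umap": np.zeros((1, 3))},
                         velocity_embedding=np.zeros((1, 3)),
                         velocity_basis="umap")
        np.testing.assert_array_equal(extract_velocity(raw, "umap", 3.0),
                                      np.zeros((1, 3)))

    def test_known_linear_field_recovered(self, tmp_path):
        from cellvr.synthetic import make_velocity_dataset

        A = np.diag([0.5, -0.25, 1.0])
        raw, truth = make_velocity_dataset(n_cells=100, field="linear",
                                           seed=3, A=A)
        vec = extract_velocity(raw, "umap", scale=4.0)
        expect = (raw.embeddings["umap"] @ A.T) / 4.0
        np.testing.assert_allclose(vec, expect, atol=1e-12)

    def test_absent_velocity_is_typed_signal(self, cluster_data):
        raw, _ = cluster_data
        with pytest.raises(NoVelocityError):
            extract_velocity(raw, "umap")

    def test_basis_mismatch_rejected(self):
        raw = RawDataset(cell_ids=["a"],
                         embeddings={"umap": np.zeros((1, 3)),
                                     "tsne": np.zeros((1, 2))},
                         velocity_embedding=np.zeros((1, 3)),
                         velocity_basis="umap")
        with pytest.raises(StructuralError):
            extract_velocity(raw, "tsne")
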