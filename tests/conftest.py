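import numpy as np
import pytest
from hypothesis import settings

from cellvr import BuildConfig, build_scene, write_scene_package
from cellvr.synthetic import (
    make_branching_trajectory,
    make_cluster_dataset,
    make_velocity_dataset,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cluster_data():
    return make_cluster_dataset(n_cells=300, n_clusters=3, seed=11)


@pytest.fixture(scope="session")
def trajectory_data():
    return make_branching_trajectory(n_cells=300, seed=11)


@pytest.fixture(scope="session")
def velocity_data():
    return make_velocity_dataset(n_cells=500, field="rotational", seed=11)


@pytest.fixture(scope="session")
def cluster_scene(cluster_data):
    raw, _ = cluster_data
    return build_scene(raw, BuildConfig(
        name="clusters", annotation_keys=["cluster", "score"],
        feature_ids=["gene0", "gene1", "gene2"]))


@pytest.fixture(scope="session")
def trajectory_scene(trajectory_data):
    raw, _ = trajectory_data
    return build_scene(raw, BuildConfig(
        name="trajectory", annotation_keys=["branch", "pseudotime"],
        feature_ids=["geneUp", "geneDown", "geneBranchA"]))


@pytest.fixture(scope="session")
def velocity_scene(velocity_data):
    raw, _ = velocity_data
    return build_scene(raw, BuildConfig(
        name="velocity", annotation_keys=["hemisphere", "speed"],
        feature_ids=["geneA"], velocity_grid=True))


@pytest.fixture(scope="session")
def full_scene(cluster_data):
    """One scene exercising every optional layer: abstract graph plus a
    velocity layer with a grid field."""
    raw, _ = cluster_data
    raw = _with_velocity(raw)
    return build_scene(raw, BuildConfig(
        name="full", annotation_keys=["cluster", "score"],
        feature_ids=["gene0", "gene1"], velocity_grid=True))


def _with_velocity(raw):
    from dataclasses import replace

    vec = 0.1 * np.asarray(raw.embeddings["umap"], dtype=float)
    return replace(raw, velocity_embedding=vec, velocity_basis="umap")


@pytest.fixture(scope="session")
def package_dir(tmp_path_factory, cluster_scene, trajectory_scene,
                velocity_scene, full_scene):
    root = tmp_path_factory.mktemp("packages")
    for name, scene in [("clusters", cluster_scene),
                        ("trajectory", trajectory_scene),
                        ("velocity", velocity_scene),
                        ("full", full_scene)]:
        write_scene_package(scene, root / f"{name}.zip")
    return root
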