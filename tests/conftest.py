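import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import train_test_split

from ceda import (
    CompetitionConfig,
    LetClassifier,
    build_let,
    relative_distance_matrix,
    triplet_competitions,
)
from ceda.chain import ChainStage
from ceda.let import RelativeDistanceMatrix
from ceda.synthdata import (
    CloudSpec,
    generate_clouds,
    generate_complementary_clouds,
    generate_manifold,
    load_iris_fixture,
)

PETAL = ["petal_length", "petal_width"]
SEPAL = ["sepal_length", "sepal_width"]


@pytest.fixture(scope="session")
def iris():
    return load_iris_fixture()


@pytest.fixture(scope="session")
def iris_clouds(iris):
    """Per-species petal-pair point clouds (full data)."""
    return {lab: g[PETAL].to_numpy(float) for lab, g in iris.groupby("species")}


def split_iris(iris, seed):
    train, test = train_test_split(
        iris, test_size=0.2, random_state=seed, stratify=iris["species"]
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


def fit_stage(train, features, seed, label_column="label", cfg=None):
    """Train one chain stage: clouds -> dominance -> LET -> classifier."""
    clouds = {
        lab: g[list(features)].to_numpy(float) for lab, g in train.groupby(label_column)
    }
    if len(clouds) >= 3:
        dom = triplet_competitions(clouds, seed=seed)
        rel = relative_distance_matrix(dom)
    else:
        labels = tuple(sorted(clouds))
        rel = RelativeDistanceMatrix(labels, np.array([[0.0, 1.0], [1.0, 0.0]]))
    tree = build_let(rel)
    return ChainStage(
        "+".join(features), tuple(features), LetClassifier(clouds, tree, cfg or CompetitionConfig())
    )


@pytest.fixture(scope="session")
def manifold():
    table, truth = generate_manifold(n=1500, seed=0)
    return table, truth


@pytest.fixture(scope="session")
def complementary():
    df, truth = generate_complementary_clouds(seed=0)
    return df, truth


@pytest.fixture(scope="session")
def separated_pair():
    """Two fully separated Gaussian clouds."""
    specs = [CloudSpec("x", (0.0, 0.0), 0.5, 100), CloudSpec("y", (20.0, 0.0), 0.5, 100)]
    return generate_clouds(specs, seed=7)


@pytest.fixture(scope="session")
def engulfed_pair():
    """Cloud A partially engulfed by the larger cloud B (asymmetric mixing)."""
    specs = [
        CloudSpec("B", (0.0, 0.0), 1.0, 450),
        CloudSpec("A", (1.6, 0.0), 0.35, 150, engulfed_by="B"),
    ]
    df = generate_clouds(specs, seed=0)
    train = df.groupby("label", group_keys=False)[["f1", "f2", "label"]].apply(
        lambda g: g.iloc[: int(len(g) * 0.8)]
    )
    test = df.drop(train.index)
    return train.reset_index(drop=True), test.reset_index(drop=True)


def hierarchy_clouds(seed, n=60, delete_frac=0.0):
    """Eight labels on a planted 3-level binary hierarchy with position
    separations 16 : 4 : 1 and within-cloud spread 0.08."""
    rng = np.random.default_rng(seed)
    clouds = {}
    for i in range(8):
        b0, b1, b2 = i // 4, (i // 2) % 2, i % 2
        pos = np.array([16.0 * b0 + 4.0 * b1 + 1.0 * b2, 0.0])
        pts = pos + rng.normal(0, 0.08, (n, 2))
        if delete_frac > 0:
            d = np.linalg.norm(pts - pts.mean(0), axis=1)
            pts = pts[d <= np.quantile(d, 1 - delete_frac)]
        clouds[f"L{i}"] = pts
    return clouds


def tree_topology(tree):
    """Order-free nested-set representation of an LET topology."""

    def walk(node):
        if node.is_leaf:
            return node.label
        return tuple(sorted((walk(node.left), walk(node.right)), key=str))

    return walk(tree.root)
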