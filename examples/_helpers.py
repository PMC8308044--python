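"""Shared helper for the examples: train one chain stage end to end."""

import numpy as np

from ceda import (
    CompetitionConfig,
    LetClassifier,
    build_let,
    relative_distance_matrix,
    triplet_competitions,
)
from ceda.chain import ChainStage
from ceda.let import RelativeDistanceMatrix


def fit_stage(train, features, seed, label_column="label", cfg=None):
    clouds = {
        lab: g[list(features)].to_numpy(float) for lab, g in train.groupby(label_column)
    }
    if len(clouds) >= 3:
        rel = relative_distance_matrix(triplet_competitions(clouds, seed=seed))
    else:
        rel = RelativeDistanceMatrix(tuple(sorted(clouds)), np.array([[0.0, 1.0], [1.0, 0.0]]))
    return ChainStage(
        "+".join(features),
        tuple(features),
        LetClassifier(clouds, build_let(rel), cfg or CompetitionConfig()),
    )
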