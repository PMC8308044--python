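"""Set-valued classification by descending a label-embedding tree.

A query point enters at the root of the LET and plays a binary
Left-branch-vs-Right-branch competition at each internal node, based on
its k* nearest training neighbors among the labels under that node:

* if one branch holds an overwhelming majority of the pooled neighbors
  (minority share below ``dominance_share``), it wins outright;
* otherwise each branch's distance sample (from the query to the branch's
  k* nearest own members) is turned into a Gaussian-kernel
  pseudo-likelihood, both densities are evaluated at a common reference
  distance, and the ratio PL_left / PL_right is compared with the
  threshold band [cl, cu].  A ratio inside the band means neither branch
  is credibly closer: the competition stops and the node's full member
  set is the prediction.

The descent therefore ends either at a leaf (singleton prediction) or at
an internal node (multi-label prediction); a pre-check against the
training set's leave-one-out nearest-neighbor distances lets the
classifier return the empty set for outliers instead of guessing.
Setting cl = cu = 1 forces a winner at every node and reduces the scheme
to an ordinary singleton classifier (losing the reject and outlier
options).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .let import LabelEmbeddingTree, LetNode

__all__ = [
    "CompetitionConfig",
    "PredictionOutcome",
    "PredictiveMap",
    "LetClassifier",
    "branch_competition",
    "descend_let",
    "predictive_map",
    "set_label",
]

_TINY = 1e-300


@dataclass(frozen=True)
class CompetitionConfig:
    """Tunables of the branch competition.

    k_star : pooled neighborhood size (20 unless stated otherwise).
    cl, cu : pseudo-likelihood ratio band; inside it neither branch wins.
        cl = cu = 1 forces singleton predictions.
    dominance_share : minority neighbor share below which the majority
        branch wins outright, skipping the density stage.
    outlier_quantile : quantile of leave-one-out nearest-neighbor training
        distances beyond which a query is declared an outlier (empty set).
    pl_pool : "neighbors" builds each branch's distance sample from its
        k* nearest own members; "all" uses every branch member.
    pl_reference : "pooled_median" evaluates both densities at the median
        of the two pooled samples; "branch_median" evaluates each density
        at its own sample median.
    """

    k_star: int = 20
    cl: float = 0.65
    cu: float = 100.0 / 65.0
    dominance_share: float = 0.10
    outlier_quantile: float = 0.99
    pl_pool: str = "neighbors"
    pl_reference: str = "pooled_median"

    def __post_init__(self):
        if self.k_star < 2:
            raise ValueError("k_star must be >= 2")
        if not (self.cl <= 1.0 <= self.cu):
            raise ValueError("threshold band must satisfy cl <= 1 <= cu")
        if self.pl_pool not in ("neighbors", "all"):
            raise ValueError("pl_pool must be 'neighbors' or 'all'")
        if self.pl_reference not in ("pooled_median", "branch_median"):
            raise ValueError("pl_reference must be 'pooled_median' or 'branch_median'")

    @property
    def forced_singleton(self) -> bool:
        return self.cl == 1.0 == self.cu


@dataclass(frozen=True)
class PredictionOutcome:
    predicted_set: frozenset
    stop_node: LetNode | None
    path: tuple[str, ...]

    @property
    def is_outlier(self) -> bool:
        return len(self.predicted_set) == 0


@dataclass(frozen=True)
class PredictiveMap:
    """Per-true-label counts over observed predicted label-sets."""

    matrix: pd.DataFrame  # rows = predicted sets (as strings), cols = true labels

    def pie_data(self) -> dict:
        return {
            str(col): {idx: int(v) for idx, v in self.matrix[col].items() if v > 0}
            for col in self.matrix.columns
        }


def set_label(labels) -> str:
    """Canonical string form of a predicted label-set."""
    if len(labels) == 0:
        return "outlier"
    return "+".join(str(x) for x in sorted(labels))


def _pl_density(sample: np.ndarray, at: float) -> float:
    """Gaussian-KDE (Silverman bandwidth) density of a distance sample at a
    reference point; degenerate samples collapse to a point mass."""
    sample = np.asarray(sample, dtype=float)
    if sample.size < 2 or np.ptp(sample) == 0:
        center = float(sample[0]) if sample.size else 0.0
        return 1e12 if abs(at - center) < 1e-12 else _TINY
    kde = gaussian_kde(sample, bw_method="silverman")
    return float(kde(at)[0])


def branch_competition(
    x: np.ndarray, node: LetNode, clouds: dict, cfg: CompetitionConfig
) -> str:
    """Decide 'left', 'right', or 'both' at one internal LET node."""
    if node.is_leaf:
        raise ValueError("branch competition requires an internal node")
    xl = np.vstack([clouds[lab] for lab in sorted(node.left.members)])
    xr = np.vstack([clouds[lab] for lab in sorted(node.right.members)])
    if len(xl) < 1 or len(xr) < 1:
        raise ValueError("both branches need at least one training point")
    x = np.asarray(x, dtype=float).ravel()
    dl = np.sort(np.linalg.norm(xl - x, axis=1))
    dr = np.sort(np.linalg.norm(xr - x, axis=1))

    k = min(cfg.k_star, len(dl) + len(dr))
    pooled = np.concatenate([dl, dr])
    tags = np.concatenate([np.zeros(len(dl), bool), np.ones(len(dr), bool)])
    nearest = np.argsort(pooled, kind="stable")[:k]
    n_right = int(tags[nearest].sum())
    n_left = k - n_right
    minority = min(n_left, n_right) / k
    if minority < cfg.dominance_share and n_left != n_right:
        return "left" if n_left > n_right else "right"

    if cfg.pl_pool == "neighbors":
        sl = dl[: min(cfg.k_star, len(dl))]
        sr = dr[: min(cfg.k_star, len(dr))]
    else:
        sl, sr = dl, dr
    if cfg.pl_reference == "pooled_median":
        ref = float(np.median(np.concatenate([sl, sr])))
        pl_l, pl_r = _pl_density(sl, ref), _pl_density(sr, ref)
    else:
        pl_l = _pl_density(sl, float(np.median(sl)))
        pl_r = _pl_density(sr, float(np.median(sr)))
    ratio = (pl_l + _TINY) / (pl_r + _TINY)
    if ratio > cfg.cu:
        return "left"
    if ratio < cfg.cl:
        return "right"
    return "both"


class LetClassifier:
    """A label-embedding tree bound to its training clouds and config.

    Bundles the LET, the per-label training arrays (restricted to the
    feature subset the tree was built on), and the leave-one-out
    nearest-neighbor outlier threshold.
    """

    def __init__(self, clouds: dict, let: LabelEmbeddingTree, cfg: CompetitionConfig | None = None):
        self.cfg = cfg or CompetitionConfig()
        self.clouds = {
            lab: np.atleast_2d(np.asarray(a, dtype=float)) for lab, a in clouds.items()
        }
        missing = set(let.labels) - set(self.clouds)
        if missing:
            raise ValueError(f"training clouds missing for labels: {sorted(missing)}")
        self.let = let
        pooled = np.vstack([self.clouds[lab] for lab in sorted(self.clouds)])
        self._pooled = pooled
        if len(pooled) >= 2:
            from sklearn.neighbors import NearestNeighbors

            nn = NearestNeighbors(n_neighbors=2).fit(pooled)
            loo = nn.kneighbors(pooled)[0][:, 1]
            self.outlier_threshold = float(np.quantile(loo, self.cfg.outlier_quantile))
        else:
            self.outlier_threshold = np.inf

    def predict(self, x) -> PredictionOutcome:
        return descend_let(x, self.let, self.clouds, self.cfg, self.outlier_threshold)

    def predict_set(self, x) -> frozenset:
        return self.predict(x).predicted_set

    def with_config(self, cfg: CompetitionConfig) -> "LetClassifier":
        clone = LetClassifier.__new__(LetClassifier)
        clone.cfg = cfg
        clone.clouds = self.clouds
        clone.let = self.let
        clone._pooled = self._pooled
        clone.outlier_threshold = self.outlier_threshold
        return clone


def descend_let(
    x,
    let: LabelEmbeddingTree,
    clouds: dict,
    cfg: CompetitionConfig | None = None,
    outlier_threshold: float | None = None,
) -> PredictionOutcome:
    """Descend the LET from the root, one branch competition per node,
    stopping at the first no-winner node or at a leaf.

    If the query's nearest training point is farther than
    ``outlier_threshold``, the empty set is returned without descending.
    """
    cfg = cfg or CompetitionConfig()
    x = np.asarray(x, dtype=float).ravel()
    if outlier_threshold is not None and np.isfinite(outlier_threshold):
        pooled = np.vstack([np.atleast_2d(clouds[lab]) for lab in sorted(clouds)])
        nearest = float(np.min(np.linalg.norm(pooled - x, axis=1)))
        if nearest > outlier_threshold:
            return PredictionOutcome(frozenset(), None, ("outlier",))
    node = let.root
    path: list[str] = []
    while not node.is_leaf:
        decision = branch_competition(x, node, clouds, cfg)
        path.append(decision)
        if decision == "both":
            return PredictionOutcome(frozenset(node.members), node, tuple(path))
        node = node.left if decision == "left" else node.right
    return PredictionOutcome(frozenset(node.members), node, tuple(path))


def predictive_map(
    queries,
    true_labels,
    classifier: LetClassifier,
) -> PredictiveMap:
    """Aggregate set-valued outcomes into the predicted-set x true-label
    count matrix (the tabular form of the per-label pie charts)."""
    x = np.atleast_2d(np.asarray(queries, dtype=float))
    y = np.asarray(true_labels)
    if len(x) != len(y):
        raise ValueError("queries and labels must align")
    rows: dict[str, dict] = {}
    col_levels = sorted(set(y.tolist()))
    for xi, yi in zip(x, y):
        out = classifier.predict(xi)
        key = set_label(out.predicted_set)
        rows.setdefault(key, {c: 0 for c in col_levels})
        rows[key][yi] += 1
    matrix = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    matrix = matrix.reindex(columns=col_levels).sort_index()
    return PredictiveMap(matrix)
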