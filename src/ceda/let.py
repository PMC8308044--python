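"""Label-embedding trees from triplet-dominance competitions.

Direct distances between whole point-clouds (optimal transport,
Gromov-type metrics) are sensitive to the clouds' edges and tails.  The
*relative distance* used here is rank-based instead: repeatedly sample one
point from each cloud of a randomly chosen label triple, compute the three
pairwise Euclidean distances, and record that the two larger label-pairs
*dominate* the minimal one.  Accumulated over many rounds into a
pair-by-pair dominance matrix, each pair's row sum — how often it
dominated some other pair — measures its relative distance: pairs of
clouds that sit close together are dominated often and dominate rarely.
Hierarchical clustering of the resulting label-by-label relative-distance
matrix yields the label-embedding tree (LET), the binary hierarchy over
classes that the set-valued classifier descends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "DominanceMatrix",
    "RelativeDistanceMatrix",
    "LetNode",
    "LabelEmbeddingTree",
    "triplet_competitions",
    "relative_distance_matrix",
    "build_let",
]


@dataclass(frozen=True)
class DominanceMatrix:
    """P x P tally over label-pairs: counts[p, q] = rounds in which pair p's
    distance dominated (exceeded) the minimal pair q's distance."""

    labels: tuple
    pairs: tuple[tuple, ...]
    counts: np.ndarray
    n_rounds: int
    participation: np.ndarray

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class RelativeDistanceMatrix:
    labels: tuple
    values: np.ndarray


@dataclass
class LetNode:
    """One node of a label-embedding tree; leaves carry a single label."""

    members: frozenset
    height: float = 0.0
    left: "LetNode | None" = None
    right: "LetNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def label(self):
        if not self.is_leaf:
            raise ValueError("internal node has no single label")
        return next(iter(self.members))


@dataclass(frozen=True)
class LabelEmbeddingTree:
    root: LetNode
    labels: tuple
    linkage: np.ndarray = field(repr=False, default=None)

    @property
    def depth(self) -> int:
        def _d(node):
            return 0 if node.is_leaf else 1 + max(_d(node.left), _d(node.right))

        return _d(self.root)

    def internal_nodes(self) -> list[LetNode]:
        out = []

        def _walk(node):
            if not node.is_leaf:
                out.append(node)
                _walk(node.left)
                _walk(node.right)

        _walk(self.root)
        return out


def _prepare_clouds(clouds: dict, feature_subset=None, standardize: bool = False) -> dict:
    labels = sorted(clouds)
    arrays = {}
    for lab in labels:
        a = np.asarray(clouds[lab], dtype=float)
        if a.ndim == 1:
            a = a[:, None]
        if a.shape[0] == 0:
            raise ValueError(f"empty point-cloud for label {lab!r}")
        if feature_subset is not None:
            a = a[:, list(feature_subset)]
        arrays[lab] = a
    if standardize:
        pooled = np.vstack(list(arrays.values()))
        mu, sd = pooled.mean(axis=0), pooled.std(axis=0)
        sd[sd == 0] = 1.0
        arrays = {lab: (a - mu) / sd for lab, a in arrays.items()}
    return arrays


def triplet_competitions(
    clouds: dict,
    n_rounds: int | None = None,
    seed: int | None = None,
    feature_subset=None,
    standardize: bool = False,
    max_resample: int = 100,
) -> DominanceMatrix:
    """Run seeded triplet dominance competitions among label point-clouds.

    Each round draws a label triple uniformly, samples one point per label
    (with replacement), and records the two non-minimal pairs as dominating
    the minimal pair.  Rounds with an exact distance tie are discarded and
    resampled (up to ``max_resample`` passes per batch).

    Default ``n_rounds`` is 1000 x C(L,3), capped at 10**6.
    """
    arrays = _prepare_clouds(clouds, feature_subset, standardize)
    labels = tuple(sorted(arrays))
    if len(labels) < 3:
        raise ValueError("need at least 3 labels for triplet competitions")
    pairs = tuple(combinations(labels, 2))
    pair_idx = {frozenset(p): i for i, p in enumerate(pairs)}
    triples = list(combinations(labels, 3))
    if n_rounds is None:
        n_rounds = min(1000 * len(triples), 10**6)
    rng = np.random.default_rng(seed)

    counts = np.zeros((len(pairs), len(pairs)), dtype=int)
    participation = np.zeros(len(pairs), dtype=int)
    accepted_total = 0

    assignment = rng.integers(0, len(triples), size=n_rounds)
    for t_i, triple in enumerate(triples):
        m = int(np.sum(assignment == t_i))
        if m == 0:
            continue
        a, b, c = triple
        p_ab, p_ac, p_bc = (pair_idx[frozenset(x)] for x in ((a, b), (a, c), (b, c)))
        pair_rows = np.array([p_ab, p_ac, p_bc])
        accepted = 0
        remaining = m
        for _ in range(max_resample):
            if remaining == 0:
                break
            ia = rng.integers(0, len(arrays[a]), remaining)
            ib = rng.integers(0, len(arrays[b]), remaining)
            ic = rng.integers(0, len(arrays[c]), remaining)
            pa, pb, pc = arrays[a][ia], arrays[b][ib], arrays[c][ic]
            d = np.stack(
                [
                    np.linalg.norm(pa - pb, axis=1),
                    np.linalg.norm(pa - pc, axis=1),
                    np.linalg.norm(pb - pc, axis=1),
                ]
            )  # rows follow pair_rows order
            order = np.argsort(d, axis=0)
            dmin = d[order[0], np.arange(remaining)]
            dsecond = d[order[1], np.arange(remaining)]
            ok = dmin < dsecond  # exact-tie rounds are discarded
            min_pair = pair_rows[order[0, ok]]
            others = pair_rows[order[1:, ok]]
            np.add.at(counts, (others[0], min_pair), 1)
            np.add.at(counts, (others[1], min_pair), 1)
            accepted += int(np.sum(ok))
            remaining = int(np.sum(~ok))
        participation[pair_rows] += accepted
        accepted_total += accepted

    return DominanceMatrix(labels, pairs, counts, accepted_total, participation)


def relative_distance_matrix(dom: DominanceMatrix) -> RelativeDistanceMatrix:
    """Convert dominance row sums into a symmetric label-by-label
    relative-distance matrix, normalizing each pair's row sum by the number
    of rounds the pair participated in (pairs enter unequal numbers of
    triples when L > 3)."""
    labels = dom.labels
    idx = {lab: i for i, lab in enumerate(labels)}
    values = np.zeros((len(labels), len(labels)))
    row_sums = dom.row_sums
    for p, (a, b) in enumerate(dom.pairs):
        denom = dom.participation[p]
        v = row_sums[p] / denom if denom > 0 else 0.0
        values[idx[a], idx[b]] = values[idx[b], idx[a]] = v
    return RelativeDistanceMatrix(labels, values)


def build_let(rel: RelativeDistanceMatrix, linkage_method: str = "average") -> LabelEmbeddingTree:
    """Hierarchical clustering of the relative-distance matrix into a
    binary label tree (deterministic given the matrix)."""
    labels = rel.labels
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    z = hierarchy.linkage(squareform(rel.values, checks=False), method=linkage_method)
    nodes: dict[int, LetNode] = {
        i: LetNode(members=frozenset([lab])) for i, lab in enumerate(labels)
    }
    n = len(labels)
    for k, (i, j, h, _) in enumerate(z):
        left, right = nodes[int(i)], nodes[int(j)]
        nodes[n + k] = LetNode(
            members=left.members | right.members, height=float(h), left=left, right=right
        )
    return LabelEmbeddingTree(root=nodes[n + len(z) - 1], labels=labels, linkage=z)
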