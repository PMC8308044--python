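"""Directional and mutual conditional entropy feature associations.

A contingency table framed by two categorized features carries all the
(possibly nonlinear) association between them.  On each row, the Shannon
entropy of the cell proportions measures the residual uncertainty about
the column variable once the row category is known; rescaling by the
entropy of the column marginal and weighting by row occupancy gives the
*directed conditional entropy* H(col|row)/H(col) in [0, 1] — 0 means the
row variable determines the column variable, 1 means independence.
Averaging the two directions gives the symmetric *mutual conditional
entropy* (MCE).  The K x K MCE matrix, reordered by hierarchical
clustering with the matrix itself as the distance, is the association
roadmap from which synergistic feature-groups are read off as diagonal
blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import entropy as _shannon

from .binning import ContingencyTable, GappedHistogram, assign_bins, build_gapped_histogram, contingency_table

__all__ = [
    "MCEMatrix",
    "FeatureGroup",
    "directed_conditional_entropy",
    "mutual_conditional_entropy",
    "mce_matrix",
    "label_feature_ranking",
    "extract_feature_groups",
]


@dataclass(frozen=True)
class MCEMatrix:
    """Symmetric K x K mutual-conditional-entropy matrix with HC ordering."""

    feature_names: tuple[str, ...]
    values: np.ndarray
    leaf_order: np.ndarray
    linkage: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_names, columns=self.feature_names)

    def ordered_frame(self) -> pd.DataFrame:
        names = [self.feature_names[i] for i in self.leaf_order]
        return self.to_frame().loc[names, names]


@dataclass(frozen=True)
class FeatureGroup:
    members: tuple[str, ...]
    cut_height: float


def _entropy_bits(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        return 0.0
    return float(_shannon(counts / total, base=2))


def directed_conditional_entropy(table: ContingencyTable, direction: str = "row_to_col") -> float:
    """Empirical H(col|row) / H(col) for ``row_to_col`` (transposed for
    ``col_to_row``); 0 if the target marginal is degenerate."""
    if table.n_total <= 0:
        raise ValueError("empty contingency table")
    if direction == "col_to_row":
        table = table.transpose()
    elif direction != "row_to_col":
        raise ValueError(f"unknown direction: {direction!r}")
    m = table.counts.astype(float)
    n = m.sum()
    h_marginal = _entropy_bits(m.sum(axis=0))
    if h_marginal == 0.0:
        return 0.0
    row_sums = m.sum(axis=1)
    weighted = sum(
        (row_sums[i] / n) * _entropy_bits(m[i]) for i in range(m.shape[0]) if row_sums[i] > 0
    )
    return float(min(max(weighted / h_marginal, 0.0), 1.0))


def mutual_conditional_entropy(table: ContingencyTable) -> float:
    """Mean of the two directed conditional entropies; symmetric in axes."""
    return 0.5 * (
        directed_conditional_entropy(table, "row_to_col")
        + directed_conditional_entropy(table, "col_to_row")
    )


def _binned_columns(
    features: pd.DataFrame, histograms: dict[str, GappedHistogram] | None = None, **hist_kwargs
) -> tuple[dict[str, np.ndarray], dict[str, GappedHistogram]]:
    hists = dict(histograms) if histograms else {}
    codes = {}
    for name in features.columns:
        if name not in hists:
            hists[name] = build_gapped_histogram(features[name].to_numpy(), feature_name=name, **hist_kwargs)
        codes[name] = assign_bins(hists[name], features[name].to_numpy())
    return codes, hists


def mce_matrix(
    features: pd.DataFrame,
    histograms: dict[str, GappedHistogram] | None = None,
    linkage_method: str = "average",
    **hist_kwargs,
) -> MCEMatrix:
    """Pairwise MCE on binned features, with hierarchical-clustering leaf
    order computed from the matrix used as a distance.

    Features whose histogram collapses to a single bin resolve no
    association; their off-diagonal entries are set to 1 with a warning.
    """
    names = tuple(features.columns)
    k = len(names)
    if k < 2:
        raise ValueError("need at least 2 features")
    codes, _ = _binned_columns(features, histograms, **hist_kwargs)
    single = [n for n in names if len(np.unique(codes[n])) < 2]
    if single:
        warnings.warn(
            f"features with a single occupied bin carry no association: {single}", stacklevel=2
        )
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if names[i] in single or names[j] in single:
                v = 1.0
            else:
                v = mutual_conditional_entropy(contingency_table(codes[names[i]], codes[names[j]]))
            values[i, j] = values[j, i] = v
    z = hierarchy.linkage(squareform(values, checks=False), method=linkage_method)
    leaf_order = np.asarray(hierarchy.leaves_list(z))
    return MCEMatrix(names, values, leaf_order, z)


def label_feature_ranking(
    features: pd.DataFrame,
    labels,
    sort_key: str = "mce",
    histograms: dict[str, GappedHistogram] | None = None,
    **hist_kwargs,
) -> pd.DataFrame:
    """Rank features by association with a categorical label.

    Returns a DataFrame with both directed conditional entropies
    (feature->label and label->feature) and the MCE, sorted ascending by
    ``sort_key`` — lower means more predictive.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 label levels")
    codes, _ = _binned_columns(features, histograms, **hist_kwargs)
    rows = []
    for name in features.columns:
        tab = contingency_table(codes[name], y)  # rows = feature bins, cols = labels
        f2l = directed_conditional_entropy(tab, "row_to_col")
        l2f = directed_conditional_entropy(tab, "col_to_row")
        rows.append({"feature": name, "feature_to_label": f2l, "label_to_feature": l2f,
                     "mce": 0.5 * (f2l + l2f)})
    out = pd.DataFrame(rows).sort_values(sort_key, kind="stable").reset_index(drop=True)
    return out


def extract_feature_groups(mce: MCEMatrix, cut_height: float | None = None) -> list[FeatureGroup]:
    """Cut the HC dendrogram of the MCE matrix into feature-groups.

    Default cut height is 0.7 x the median off-diagonal MCE.  Groups are
    returned in dendrogram leaf order.
    """
    if cut_height is None:
        off = squareform(mce.values, checks=False)
        cut_height = 0.7 * float(np.median(off))
    assignments = hierarchy.fcluster(mce.linkage, t=cut_height, criterion="distance")
    order = {name: pos for pos, name in enumerate(mce.feature_names[i] for i in mce.leaf_order)}
    groups: dict[int, list[str]] = {}
    for name, g in zip(mce.feature_names, assignments):
        groups.setdefault(int(g), []).append(name)
    members = sorted(
        (sorted(ms, key=order.get) for ms in groups.values()),
        key=lambda ms: order[ms[0]],
    )
    return [FeatureGroup(tuple(ms), float(cut_height)) for ms in members]
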