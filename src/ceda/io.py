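"""Plain-text file formats: feature tables, histogram specs, Newick trees.

Everything is CSV/TSV, JSON, or Newick so pipeline artifacts stay
auditable and bit-reproducible across runs and languages.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .binning import GappedHistogram
from .let import LabelEmbeddingTree, LetNode

__all__ = [
    "read_feature_table",
    "write_histogram_json",
    "read_histogram_json",
    "export_newick",
    "linkage_to_newick",
]


def read_feature_table(
    path, feature_columns: list[str] | None = None, dialect: str | None = None
) -> pd.DataFrame:
    """Read a CSV/TSV table with a header row.

    Missing values are rejected with a row report; the requested feature
    columns (all numeric-looking columns if unspecified) are coerced to
    float, and any non-numeric cell fails with its row and column named.
    """
    path = Path(path)
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(path, sep=sep)
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"{path.name}: missing values in rows {bad[:10]}")
    cols = feature_columns
    if cols is None:
        cols = [c for c in df.columns if pd.to_numeric(df[c], errors="coerce").notna().all()]
    for col in cols:
        if col not in df.columns:
            raise ValueError(f"{path.name}: column {col!r} not found")
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.index[coerced.isna()][0])
            raise ValueError(
                f"{path.name}: non-numeric value in column {col!r}, row {row}: "
                f"{df.loc[row, col]!r}"
            )
        df[col] = coerced.astype(float)
    return df


def write_histogram_json(hist: GappedHistogram, path) -> None:
    Path(path).write_text(json.dumps(hist.to_dict(), indent=2))


def read_histogram_json(path) -> GappedHistogram:
    return GappedHistogram.from_dict(json.loads(Path(path).read_text()))


def _escape(name) -> str:
    s = str(name)
    if re.search(r"[\s();,:\[\]']", s):
        return "'" + s.replace("'", "''") + "'"
    return s


def _node_newick(node: LetNode, parent_height: float) -> str:
    length = max(parent_height - node.height, 0.0)
    if node.is_leaf:
        return f"{_escape(node.label)}:{length:.10g}"
    inner = f"({_node_newick(node.left, node.height)},{_node_newick(node.right, node.height)})"
    return f"{inner}:{length:.10g}"


def export_newick(tree: LabelEmbeddingTree) -> str:
    """Serialize a label tree to Newick; branch lengths are differences of
    merge heights, so parse-back reproduces topology and heights."""
    root = tree.root
    left = _node_newick(root.left, root.height)
    right = _node_newick(root.right, root.height)
    return f"({left},{right}):0;"


def linkage_to_newick(linkage: np.ndarray, names: list[str]) -> str:
    """Newick form of a scipy linkage over named leaves (for feature
    dendrograms)."""
    # rebuild the tree directly from the merge history
    nodes: dict[int, LetNode] = {i: LetNode(members=frozenset([n])) for i, n in enumerate(names)}
    n = len(names)
    for k, (i, j, h, _) in enumerate(linkage):
        left, right = nodes[int(i)], nodes[int(j)]
        nodes[n + k] = LetNode(
            members=left.members | right.members, height=float(h), left=left, right=right
        )
    tree = LabelEmbeddingTree(root=nodes[n + len(linkage) - 1], labels=tuple(names), linkage=linkage)
    return export_newick(tree)
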