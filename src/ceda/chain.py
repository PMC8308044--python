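"""Chains of complementary feature-groups and pattern-category registries.

One feature-group's mixing geometry may leave some regions ambiguous —
queries there receive multi-label predictions.  A *chain* resolves such
ambiguity by re-examining exactly those queries through the perspective
of a second (and possibly third) feature-group, each with its own
label-embedding tree.  The ordered tuple of predicted label-sets a point
accumulates is its *pattern-category*; a category is *certain* when every
calibration point that ever landed in it carries the same true label, in
which case the category itself identifies the label even if the sets it
contains are not singletons (asymmetric mixing at work).

The registry of calibration categories doubles as a yardstick for
external classifiers: any single-label decision can be placed in its
pattern-category and dissected into certainty/uncertainty x
coherent/incoherent cases.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .predict import LetClassifier, set_label

__all__ = [
    "ChainStage",
    "PatternCategory",
    "RegistryEntry",
    "CertaintyRegistry",
    "build_registry",
    "chain_predict",
    "chain_predict_table",
    "classify_ml_decision",
]

MAX_CHAIN_LENGTH = 3


@dataclass(frozen=True)
class ChainStage:
    """One stage of a chain: a named feature-group and its fitted LET
    classifier (trained on the same split as every other stage)."""

    name: str
    features: tuple[str, ...]
    classifier: LetClassifier


@dataclass(frozen=True)
class PatternCategory:
    """Ordered tuple of predicted label-sets, one per chain stage applied."""

    stages: tuple[frozenset, ...]

    def __str__(self) -> str:
        return "-".join(set_label(s) for s in self.stages)


@dataclass(frozen=True)
class RegistryEntry:
    status: str  # "certain" | "uncertain" | "novel"
    supported: frozenset
    counts: Counter

    @property
    def odds(self) -> dict:
        total = sum(self.counts.values())
        return {lab: c / total for lab, c in self.counts.items()} if total else {}


class CertaintyRegistry:
    """Map from observed pattern-category tuples to certainty status."""

    def __init__(self, entries: dict[tuple, RegistryEntry], stage1_members: frozenset):
        self._entries = dict(entries)
        self._stage1_members = stage1_members

    def lookup(self, stages: tuple[frozenset, ...]) -> RegistryEntry:
        entry = self._entries.get(tuple(stages))
        if entry is None:
            # unseen tuple: flag, don't guess — support the union of the
            # first stage's branch members
            supported = stages[0] if stages else self._stage1_members
            return RegistryEntry("novel", frozenset(supported), Counter())
        return entry

    def __contains__(self, stages) -> bool:
        return tuple(stages) in self._entries

    def items(self):
        return self._entries.items()

    def terminal_items(self):
        """Entries not refined by a later stage (the leaves of the chain)."""
        keys = set(self._entries)
        for key, entry in self._entries.items():
            if not any(len(other) == len(key) + 1 and other[: len(key)] == key for other in keys):
                yield key, entry

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, entry in sorted(self._entries.items(), key=lambda kv: (len(kv[0]), str(PatternCategory(kv[0])))):
            row = {
                "category": str(PatternCategory(key)),
                "order": len(key),
                "status": entry.status,
            }
            row.update({f"n[{lab}]": c for lab, c in sorted(entry.counts.items(), key=lambda t: str(t[0]))})
            rows.append(row)
        return pd.DataFrame(rows).fillna(0)


def _predict_sets(stage: ChainStage, x: pd.DataFrame) -> list[frozenset]:
    cols = list(stage.features)
    return [stage.classifier.predict_set(row) for row in x[cols].to_numpy(dtype=float)]


def build_registry(
    stages: list[ChainStage],
    calibration: pd.DataFrame,
    labels,
    max_length: int = MAX_CHAIN_LENGTH,
) -> CertaintyRegistry:
    """Run calibration points through the chain, refining only the
    categories that remain uncertain, and record every observed tuple.

    A category is *certain* iff exactly one true label was observed among
    the calibration points landing in it.
    """
    if not stages:
        raise ValueError("need at least one chain stage")
    y = np.asarray(labels)
    if len(calibration) != len(y):
        raise ValueError("calibration table and labels must align")
    stages = stages[:max_length]
    entries: dict[tuple, RegistryEntry] = {}
    stage1_members = frozenset(stages[0].classifier.let.labels)

    # active: tuple-so-far -> row indices still being refined
    active: dict[tuple, np.ndarray] = {(): np.arange(len(y))}
    for depth, stage in enumerate(stages):
        if not active:
            break
        nxt: dict[tuple, np.ndarray] = {}
        for prefix, idx in active.items():
            preds = _predict_sets(stage, calibration.iloc[idx])
            by_set: dict[frozenset, list[int]] = {}
            for i, s in zip(idx, preds):
                by_set.setdefault(s, []).append(int(i))
            for s, members in by_set.items():
                key = prefix + (s,)
                counts = Counter(y[members].tolist())
                status = "certain" if len(counts) == 1 else "uncertain"
                entries[key] = RegistryEntry(status, frozenset(counts), counts)
                if status == "uncertain" and depth + 1 < len(stages):
                    nxt[key] = np.asarray(members)
        active = nxt
    return CertaintyRegistry(entries, stage1_members)


def chain_predict(
    x_row,
    stages: list[ChainStage],
    registry: CertaintyRegistry,
    max_length: int = MAX_CHAIN_LENGTH,
) -> tuple[PatternCategory, RegistryEntry]:
    """Classify one query through the chain.

    Stage 1 always applies; stage t+1 applies only while the running tuple
    is registered as uncertain.  The returned entry carries the supported
    label-set and the calibration odds of the terminal category (or the
    'novel' flag for tuples never seen in calibration).
    """
    if isinstance(x_row, dict):
        x_row = pd.Series(x_row)
    stages = stages[:max_length]
    tup: tuple[frozenset, ...] = ()
    for stage in stages:
        vec = x_row[list(stage.features)].to_numpy(dtype=float)
        tup = tup + (stage.classifier.predict_set(vec),)
        entry = registry.lookup(tup)
        if entry.status != "uncertain":
            break
    return PatternCategory(tup), registry.lookup(tup)


def chain_predict_table(
    queries: pd.DataFrame,
    true_labels,
    stages: list[ChainStage],
    registry: CertaintyRegistry,
) -> pd.DataFrame:
    """Terminal pattern-category x true-label count matrix for a query set
    (the layout of the chain tables)."""
    y = np.asarray(true_labels)
    col_levels = sorted(set(y.tolist()))
    rows: dict[str, dict] = {}
    for (_, x_row), yi in zip(queries.iterrows(), y):
        cat, _ = chain_predict(x_row, stages, registry)
        key = str(cat)
        rows.setdefault(key, {c: 0 for c in col_levels})
        rows[key][yi] += 1
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int).reindex(columns=col_levels).sort_index()


def classify_ml_decision(ml_label, category: PatternCategory | tuple, registry: CertaintyRegistry) -> str:
    """Place an external classifier's single-label decision into one of the
    four coherence cases against the pattern-category registry."""
    stages = category.stages if isinstance(category, PatternCategory) else tuple(category)
    entry = registry.lookup(stages)
    certainty = "certainty" if entry.status == "certain" else "uncertainty"
    coherence = "coherent" if ml_label in entry.supported else "incoherent"
    return f"{certainty}_{coherence}"
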