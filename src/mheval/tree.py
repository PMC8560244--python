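"""C4.5 decision-tree induction with exact or Maclaurin-approximated scoring.

The tree splits categorical attributes multiway (one branch per level) and
continuous attributes binary at an equal-division threshold. At each node the
attribute set is scored by gain ratio; only attributes whose ratio is at
least the mean ratio over valid candidates remain eligible, and the largest
among them wins (ties: lexicographic attribute name, then smaller threshold).
Categorical attributes are consumed along a path; continuous attributes may
be reused deeper with different thresholds. There is no pruning — depth and
node-size limits are the only regularizers.

``mode="tam"`` routes all candidate scoring through the log-free polynomial
criterion of :mod:`mheval.entropy`; ``mode="exact"`` uses true logarithms.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import entropy as ent
from .datasets import Dataset

__all__ = [
    "TreeParams",
    "DecisionNode",
    "build_tree",
    "predict_proba",
    "serialize_tree",
    "deserialize_tree",
    "DecisionTreeModel",
    "DecisionTreeResults",
]

LEAF = "leaf"
CATEGORICAL_SPLIT = "categorical_split"
CONTINUOUS_SPLIT = "continuous_split"

_LE, _GT = "le", "gt"
_TOL = 1e-12


@dataclass(frozen=True)
class TreeParams:
    mode: str = "tam"
    max_depth: int = 25
    min_samples_split: int = 2
    n_discretization_points: int = 10
    midpoint_candidates: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("exact", "tam"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")
        if self.n_discretization_points < 1:
            raise ValueError("n_discretization_points must be >= 1")


@dataclass
class DecisionNode:
    kind: str
    class_distribution: np.ndarray
    majority_class: str
    n_samples: int
    attribute: str | None = None
    threshold: float | None = None
    children: dict[str, "DecisionNode"] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.kind == LEAF

    def count_nodes(self) -> int:
        return 1 + sum(c.count_nodes() for c in self.children.values())

    def count_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return sum(c.count_leaves() for c in self.children.values())

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(c.depth() for c in self.children.values())


def _distribution(label_idx: np.ndarray, n_classes: int) -> np.ndarray:
    counts = np.bincount(label_idx, minlength=n_classes).astype(float)
    return counts / counts.sum()


def _make_leaf(label_idx: np.ndarray, class_names: Sequence[str]) -> DecisionNode:
    dist = _distribution(label_idx, len(class_names))
    return DecisionNode(
        kind=LEAF,
        class_distribution=dist,
        majority_class=str(class_names[int(np.argmax(dist))]),
        n_samples=len(label_idx),
    )


def build_tree(train: Dataset, params: TreeParams | None = None) -> DecisionNode:
    """Grow a C4.5 tree on ``train``; see the module docstring for the rules."""
    if train.n_records == 0:
        raise ValueError("cannot build a tree on an empty dataset")
    params = params or TreeParams()
    class_names = train.class_names
    n_classes = len(class_names)
    label_idx = train.label_indices()
    columns = {a.name: train.features[a.name].to_numpy() for a in train.schema}
    specs = {a.name: a for a in train.schema}
    score = ent.exact_gain_ratio if params.mode == "exact" else ent.approx_gain_ratio

    def score_categorical(name: str, rows: np.ndarray) -> ent.SplitCandidate:
        levels = specs[name].levels
        vals = columns[name][rows]
        table = np.zeros((len(levels), n_classes), dtype=np.int64)
        for j, lev in enumerate(levels):
            sel = vals == lev
            if sel.any():
                table[j] = np.bincount(label_idx[rows][sel], minlength=n_classes)
        part = ent.PartitionCounts(table=table)
        cand = score(part.parent_counts(), part)
        if not cand.valid:
            return ent.SplitCandidate.invalid(attribute=name)
        return ent.SplitCandidate(
            gain=cand.gain,
            split_info=cand.split_info,
            gain_ratio=cand.gain_ratio,
            attribute=name,
        )

    def score_continuous(name: str, rows: np.ndarray) -> ent.SplitCandidate:
        cand = ent.discretize_continuous(
            columns[name][rows],
            train.labels[rows],
            n_points=params.n_discretization_points,
            mode=params.mode,
            class_names=class_names,
            midpoint_candidates=params.midpoint_candidates,
        )
        if not cand.valid:
            return ent.SplitCandidate.invalid(attribute=name)
        return ent.SplitCandidate(
            gain=cand.gain,
            split_info=cand.split_info,
            gain_ratio=cand.gain_ratio,
            threshold=cand.threshold,
            attribute=name,
        )

    def grow(rows: np.ndarray, available: tuple[str, ...], depth: int) -> DecisionNode:
        y = label_idx[rows]
        pure = len(np.unique(y)) == 1
        if (
            pure
            or depth >= params.max_depth
            or len(rows) < params.min_samples_split
            or not available
        ):
            return _make_leaf(y, class_names)

        candidates = []
        for name in available:
            if specs[name].is_categorical:
                cand = score_categorical(name, rows)
            else:
                cand = score_continuous(name, rows)
            if cand.valid:
                candidates.append(cand)
        # drop zero-gain candidates: splitting on them cannot improve purity
        candidates = [c for c in candidates if c.gain > _TOL]
        if not candidates:
            return _make_leaf(y, class_names)

        mean_ratio = sum(c.gain_ratio for c in candidates) / len(candidates)
        eligible = [c for c in candidates if c.gain_ratio >= mean_ratio - _TOL]
        best = min(
            eligible,
            key=lambda c: (
                -c.gain_ratio,
                c.attribute,
                c.threshold if c.threshold is not None else 0.0,
            ),
        )

        node = DecisionNode(
            kind=(
                CATEGORICAL_SPLIT
                if specs[best.attribute].is_categorical
                else CONTINUOUS_SPLIT
            ),
            class_distribution=_distribution(y, n_classes),
            majority_class=str(class_names[int(np.argmax(np.bincount(y, minlength=n_classes)))]),
            n_samples=len(rows),
            attribute=best.attribute,
            threshold=best.threshold,
        )
        if node.kind == CATEGORICAL_SPLIT:
            remaining = tuple(a for a in available if a != best.attribute)
            vals = columns[best.attribute][rows]
            for lev in specs[best.attribute].levels:
                sel = vals == lev
                if sel.any():
                    node.children[lev] = grow(rows[sel], remaining, depth + 1)
                else:
                    # level absent at this node: fall back to the parent mix
                    node.children[lev] = DecisionNode(
                        kind=LEAF,
                        class_distribution=node.class_distribution.copy(),
                        majority_class=node.majority_class,
                        n_samples=0,
                    )
        else:
            vals = columns[best.attribute][rows]
            left = vals <= best.threshold
            node.children[_LE] = grow(rows[left], available, depth + 1)
            node.children[_GT] = grow(rows[~left], available, depth + 1)
        return node

    all_rows = np.arange(train.n_records, dtype=np.intp)
    return grow(all_rows, train.attribute_names, 0)


def predict_proba(
    tree: DecisionNode,
    record: Mapping[str, object],
    schema: Sequence | None = None,
) -> np.ndarray:
    """Route one record to a leaf and return its class distribution.

    An unseen categorical level stops routing and returns the distribution of
    the node reached so far.
    """
    node = tree
    while not node.is_leaf:
        try:
            value = record[node.attribute]
        except (KeyError, IndexError, TypeError) as exc:
            raise ValueError(f"record lacks attribute {node.attribute!r}") from exc
        if node.kind == CONTINUOUS_SPLIT:
            node = node.children[_LE if float(value) <= node.threshold else _GT]
        else:
            child = node.children.get(str(value))
            if child is None:
                return node.class_distribution.copy()
            node = child
    return node.class_distribution.copy()


def _node_to_json(node: DecisionNode) -> dict:
    obj: dict = {
        "kind": node.kind,
        "class_distribution": [round(float(p), 12) for p in node.class_distribution],
        "majority_class": node.majority_class,
        "n_samples": node.n_samples,
    }
    if not node.is_leaf:
        obj["attribute"] = node.attribute
        if node.threshold is not None:
            obj["threshold"] = float(node.threshold)
        obj["children"] = {k: _node_to_json(v) for k, v in node.children.items()}
    return obj


def _node_from_json(obj: Mapping) -> DecisionNode:
    try:
        node = DecisionNode(
            kind=obj["kind"],
            class_distribution=np.asarray(obj["class_distribution"], dtype=float),
            majority_class=obj["majority_class"],
            n_samples=int(obj.get("n_samples", 0)),
            attribute=obj.get("attribute"),
            threshold=obj.get("threshold"),
        )
        for key, child in obj.get("children", {}).items():
            node.children[key] = _node_from_json(child)
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed tree JSON: {exc}") from exc
    if node.kind not in (LEAF, CATEGORICAL_SPLIT, CONTINUOUS_SPLIT):
        raise ValueError(f"malformed tree JSON: unknown node kind {node.kind!r}")
    return node


def serialize_tree(tree: DecisionNode, mode: str = "tam", schema_hash: str = "") -> str:
    return json.dumps(
        {"mode": mode, "schema_hash": schema_hash, "root": _node_to_json(tree)},
        indent=2,
    )


def deserialize_tree(text: str) -> DecisionNode:
    try:
        obj = json.loads(text)
        root = obj["root"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(f"malformed tree JSON: {exc}") from exc
    return _node_from_json(root)


def _schema_hash(data: Dataset) -> str:
    desc = json.dumps(
        [[a.name, a.kind, list(a.levels)] for a in data.schema] + [list(data.class_names)]
    )
    return hashlib.sha256(desc.encode()).hexdigest()[:16]


class DecisionTreeModel:
    """C4.5 classifier over a :class:`~mheval.datasets.Dataset`.

    Parameters
    ----------
    data:
        Training data; must contain at least one record.
    params:
        Tree hyper-parameters; ``mode`` chooses exact or TAM scoring.
    """

    def __init__(self, data: Dataset, params: TreeParams | None = None):
        if data.n_records == 0:
            raise ValueError("empty training data")
        self.data = data
        self.params = params or TreeParams()

    def fit(self) -> "DecisionTreeResults":
        before = ent.transcendental_call_count()
        root = build_tree(self.data, self.params)
        log_calls = ent.transcendental_call_count() - before
        return DecisionTreeResults(self, root, log_calls)


class DecisionTreeResults:
    """Fitted tree plus fit diagnostics."""

    def __init__(self, model: DecisionTreeModel, root: DecisionNode, log_calls: int):
        self.model = model
        self.root = root
        self.log_calls_during_fit = log_calls
        self.class_names = model.data.class_names

    @property
    def n_nodes(self) -> int:
        return self.root.count_nodes()

    @property
    def n_leaves(self) -> int:
        return self.root.count_leaves()

    @property
    def depth(self) -> int:
        return self.root.depth()

    def predict_proba(self, data: Dataset) -> np.ndarray:
        return np.vstack([predict_proba(self.root, rec) for rec in data.records()])

    def predict(self, data: Dataset) -> np.ndarray:
        probs = self.predict_proba(data)
        idx = probs.argmax(axis=1)
        return np.array([self.class_names[i] for i in idx], dtype=object)

    def training_accuracy(self) -> float:
        return float(np.mean(self.predict(self.model.data) == self.model.data.labels))

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(
                serialize_tree(
                    self.root,
                    mode=self.model.params.mode,
                    schema_hash=_schema_hash(self.model.data),
                )
            )

    def summary(self) -> str:
        p = self.model.params
        lines = [
            "Decision Tree Results",
            "=" * 42,
            f"mode:                 {p.mode}",
            f"records:              {self.model.data.n_records}",
            f"classes:              {len(self.class_names)}",
            f"nodes / leaves:       {self.n_nodes} / {self.n_leaves}",
            f"depth:                {self.depth}",
            f"max_depth:            {p.max_depth}",
            f"log calls during fit: {self.log_calls_during_fit}",
            f"training accuracy:    {self.training_accuracy():.4f}",
        ]
        return "\n".join(lines)
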