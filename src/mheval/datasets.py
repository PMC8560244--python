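"""Typed tabular datasets for assessment records.

A :class:`Dataset` couples a schema (attributes typed as categorical or
continuous) with labelled records. It is the currency passed between the
generator, the tree and network models, and the evaluation harness. CSV files
carry the records; a JSON sidecar carries the schema, so files remain
self-describing and round-trip exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AttributeSpec",
    "Dataset",
    "ClassCounts",
    "SchemaError",
    "ParseError",
    "load_dataset",
    "save_dataset",
    "split_train_test",
    "class_counts",
]

CATEGORICAL = "categorical"
CONTINUOUS = "continuous"


class SchemaError(ValueError):
    """Schema file or CSV header does not describe a usable dataset."""


class ParseError(ValueError):
    """A cell value cannot be interpreted under the schema."""


@dataclass(frozen=True)
class AttributeSpec:
    """One typed attribute: a name, its kind, and (if categorical) its levels."""

    name: str
    kind: str
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in (CATEGORICAL, CONTINUOUS):
            raise SchemaError(f"unknown attribute kind {self.kind!r} for {self.name!r}")
        if self.kind == CATEGORICAL and not self.levels:
            raise SchemaError(f"categorical attribute {self.name!r} needs levels")
        if self.kind == CONTINUOUS and self.levels:
            raise SchemaError(f"continuous attribute {self.name!r} must not list levels")
        object.__setattr__(self, "levels", tuple(str(x) for x in self.levels))

    @property
    def is_categorical(self) -> bool:
        return self.kind == CATEGORICAL


@dataclass
class Dataset:
    """Labelled records under a typed schema.

    ``features`` holds one column per attribute (object dtype for categorical,
    float for continuous); ``labels`` holds one class label per row, each a
    member of ``class_names``.
    """

    schema: tuple[AttributeSpec, ...]
    class_names: tuple[str, ...]
    features: pd.DataFrame
    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.schema = tuple(self.schema)
        self.class_names = tuple(str(c) for c in self.class_names)
        names = [a.name for a in self.schema]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate attribute names in schema")
        if list(self.features.columns) != names:
            raise SchemaError("feature columns do not match schema order")
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != len(self.features):
            raise ValueError("labels and features disagree on record count")
        unknown = set(self.labels) - set(self.class_names)
        if unknown:
            raise ParseError(f"labels outside class_names: {sorted(unknown)!r}")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def n_records(self) -> int:
        return len(self.features)

    @property
    def attribute_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.schema)

    def attribute(self, name: str) -> AttributeSpec:
        for a in self.schema:
            if a.name == name:
                return a
        raise KeyError(name)

    def label_indices(self) -> np.ndarray:
        """Labels as integer indices into ``class_names``."""
        lut = {c: i for i, c in enumerate(self.class_names)}
        return np.array([lut[y] for y in self.labels], dtype=np.intp)

    def subset(self, index: Sequence[int] | np.ndarray) -> "Dataset":
        idx = np.asarray(index, dtype=np.intp)
        return Dataset(
            schema=self.schema,
            class_names=self.class_names,
            features=self.features.iloc[idx].reset_index(drop=True),
            labels=self.labels[idx],
        )

    def records(self) -> Iterable[Mapping[str, object]]:
        """Iterate records as attribute-name → value mappings."""
        for _, row in self.features.iterrows():
            yield row.to_dict()


@dataclass(frozen=True)
class ClassCounts:
    """Per-class record tallies, ordered like the dataset's class_names."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        if any(c < 0 for c in self.counts):
            raise ValueError("class counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


def _schema_from_json(obj: Mapping) -> tuple[tuple[AttributeSpec, ...], tuple[str, ...], str]:
    try:
        class_column = obj["class_column"]
        classes = tuple(str(c) for c in obj["classes"])
        attrs = tuple(
            AttributeSpec(
                name=str(a["name"]),
                kind=str(a["kind"]),
                levels=tuple(a.get("levels", ())),
            )
            for a in obj["attributes"]
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed schema file: {exc}") from exc
    if not classes:
        raise SchemaError("schema lists no classes")
    return attrs, classes, str(class_column)


def schema_to_json(data: Dataset, class_column: str = "class") -> dict:
    return {
        "class_column": class_column,
        "classes": list(data.class_names),
        "attributes": [
            {"name": a.name, "kind": a.kind, **({"levels": list(a.levels)} if a.is_categorical else {})}
            for a in data.schema
        ],
    }


def load_dataset(csv_path: str | Path, schema_path: str | Path) -> Dataset:
    """Read a CSV + JSON-schema pair into a :class:`Dataset`.

    Continuous cells are parsed as decimals; categorical cells must be one of
    the declared levels. Missing values are rejected.
    """
    with open(schema_path, "r", encoding="utf-8") as fh:
        schema, classes, class_column = _schema_from_json(json.load(fh))
    frame = pd.read_csv(csv_path, dtype=str, keep_default_na=False)
    missing = [a.name for a in schema if a.name not in frame.columns]
    if class_column not in frame.columns:
        missing.append(class_column)
    if missing:
        raise SchemaError(f"CSV is missing columns {missing!r}")

    cols: dict[str, object] = {}
    for attr in schema:
        raw = frame[attr.name]
        if attr.is_categorical:
            allowed = set(attr.levels)
            bad = [i for i, v in enumerate(raw) if v not in allowed]
            if bad:
                raise ParseError(
                    f"row {bad[0]}: value {raw.iloc[bad[0]]!r} not a level of "
                    f"categorical attribute {attr.name!r}"
                )
            cols[attr.name] = raw.astype(object)
        else:
            parsed = pd.to_numeric(raw, errors="coerce")
            bad_mask = parsed.isna().to_numpy()
            if bad_mask.any():
                row = int(np.flatnonzero(bad_mask)[0])
                raise ParseError(
                    f"row {row}: cannot parse {raw.iloc[row]!r} as a decimal for "
                    f"continuous attribute {attr.name!r}"
                )
            cols[attr.name] = parsed.astype(float)
    features = pd.DataFrame(cols, columns=[a.name for a in schema])
    labels = frame[class_column].astype(object).to_numpy()
    return Dataset(schema=schema, class_names=classes, features=features, labels=labels)


def save_dataset(
    data: Dataset,
    csv_path: str | Path,
    schema_path: str | Path,
    class_column: str = "class",
) -> None:
    """Write the CSV + JSON-schema pair that :func:`load_dataset` reads."""
    out = data.features.copy()
    out[class_column] = data.labels
    out.to_csv(csv_path, index=False)
    with open(schema_path, "w", encoding="utf-8") as fh:
        json.dump(schema_to_json(data, class_column), fh, indent=2)
        fh.write("\n")


def split_train_test(
    data: Dataset, n_parts: int, n_train: int, seed: int
) -> tuple[Dataset, Dataset]:
    """Shuffle, cut into ``n_parts`` near-equal folds, take the first
    ``n_train`` folds as training data and the remainder as test data.

    When the record count is not divisible by ``n_parts`` the remainder is
    distributed one extra record per fold starting from the first fold, so the
    partition is deterministic and as equal as possible.
    """
    if n_train >= n_parts:
        raise ValueError("n_train must be smaller than n_parts")
    if n_train < 1 or n_parts < 2:
        raise ValueError("need n_parts >= 2 and n_train >= 1")
    n = data.n_records
    if n < n_parts:
        raise ValueError(f"dataset of {n} records cannot be cut into {n_parts} parts")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    base, rem = divmod(n, n_parts)
    sizes = [base + (1 if i < rem else 0) for i in range(n_parts)]
    n_train_records = sum(sizes[:n_train])
    train_idx = order[:n_train_records]
    test_idx = order[n_train_records:]
    return data.subset(train_idx), data.subset(test_idx)


def class_counts(data: Dataset) -> ClassCounts:
    """Tally records per class, in ``class_names`` order."""
    if data.n_records == 0:
        raise ValueError("cannot count classes of an empty dataset")
    idx = data.label_indices()
    counts = np.bincount(idx, minlength=len(data.class_names))
    return ClassCounts(counts=tuple(int(c) for c in counts))
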