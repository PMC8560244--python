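"""Feature encoding for the network models.

Continuous attributes are standardized with the training mean and standard
deviation; categorical attributes are one-hot encoded over the schema's level
list (so the encoding is schema-driven, not data-driven, and test records
never change the layout). Labels map to one-hot rows in class order.
"""

from __future__ import annotations

import numpy as np

from .datasets import Dataset

__all__ = ["DatasetEncoder"]


class DatasetEncoder:
    """Fit on a training :class:`Dataset`, then transform any conforming one."""

    def __init__(self) -> None:
        self.fitted = False
        self.means: dict[str, float] = {}
        self.stds: dict[str, float] = {}
        self.class_names: tuple[str, ...] = ()
        self._schema = None

    def fit(self, train: Dataset) -> "DatasetEncoder":
        self._schema = train.schema
        self.class_names = train.class_names
        for attr in train.schema:
            if not attr.is_categorical:
                col = train.features[attr.name].to_numpy(dtype=float)
                mu = float(col.mean())
                sd = float(col.std())
                self.means[attr.name] = mu
                self.stds[attr.name] = sd if sd > 1e-12 else 1.0
        self.fitted = True
        return self

    @property
    def n_features(self) -> int:
        self._check()
        n = 0
        for attr in self._schema:
            n += len(attr.levels) if attr.is_categorical else 1
        return n

    def _check(self) -> None:
        if not self.fitted:
            raise RuntimeError("encoder is not fitted")

    def transform(self, data: Dataset) -> np.ndarray:
        self._check()
        blocks = []
        for attr in self._schema:
            if attr.is_categorical:
                col = data.features[attr.name].to_numpy()
                block = np.zeros((len(data), len(attr.levels)))
                for j, lev in enumerate(attr.levels):
                    block[:, j] = col == lev
                blocks.append(block)
            else:
                col = data.features[attr.name].to_numpy(dtype=float)
                blocks.append(
                    ((col - self.means[attr.name]) / self.stds[attr.name])[:, None]
                )
        return np.hstack(blocks)

    def one_hot_labels(self, data: Dataset) -> np.ndarray:
        self._check()
        idx = data.label_indices()
        out = np.zeros((len(data), len(self.class_names)))
        out[np.arange(len(data)), idx] = 1.0
        return out

    def state(self) -> dict:
        self._check()
        return {
            "means": self.means,
            "stds": self.stds,
            "class_names": list(self.class_names),
        }

    @staticmethod
    def from_state(state: dict, schema) -> "DatasetEncoder":
        enc = DatasetEncoder()
        enc.means = {k: float(v) for k, v in state["means"].items()}
        enc.stds = {k: float(v) for k, v in state["stds"].items()}
        enc.class_names = tuple(state["class_names"])
        enc._schema = tuple(schema)
        enc.fitted = True
        return enc
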