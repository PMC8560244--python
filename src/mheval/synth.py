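"""Synthetic mental-health-assessment datasets.

Real screening corpora of this shape mix Likert-style questionnaire items
with continuous activity features (post counts, session durations) and a
latent risk class. The generator emulates that structure with full control
over class balance, class separation and label noise:

* a class is drawn per record from ``class_weights``;
* continuous features come from class-conditional unit-variance Gaussians
  whose means sit at the vertices of a regular simplex with side length
  ``separation`` (so ``separation`` is the between-class distance in
  within-class standard deviations; 0 means no continuous signal);
* Likert items are drawn from class-conditional multinomials over five
  levels, peaked at a class-specific mode with sharpness proportional to
  ``separation`` (so at separation 0 the items are uninformative too);
* each label is flipped to a uniformly-drawn other class with probability
  ``label_noise``.

Everything is a deterministic function of ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import AttributeSpec, Dataset, split_train_test

__all__ = ["GeneratorConfig", "generate", "default_benchmark"]

LIKERT_LEVELS = ("1", "2", "3", "4", "5")
_DEFAULT_CLASS_NAMES = ("low", "moderate", "high")

# sharpness of the Likert class-conditional modes per unit of separation
_LIKERT_SHARPNESS = 0.5


@dataclass(frozen=True)
class GeneratorConfig:
    n_samples: int = 2000
    n_classes: int = 3
    n_likert_items: int = 6
    n_continuous: int = 4
    class_weights: tuple[float, ...] | None = None
    separation: float = 2.5
    label_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_classes < 2:
            raise ValueError("need n_samples >= 1 and n_classes >= 2")
        if self.n_likert_items < 0 or self.n_continuous < 0:
            raise ValueError("feature counts must be >= 0")
        if self.n_likert_items + self.n_continuous == 0:
            raise ValueError("need at least one feature")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must lie in [0, 0.5)")
        if self.class_weights is not None:
            w = tuple(float(x) for x in self.class_weights)
            if len(w) != self.n_classes or any(x <= 0 for x in w):
                raise ValueError("class_weights must be positive, one per class")
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValueError("class_weights must sum to 1")
            object.__setattr__(self, "class_weights", w)

    @property
    def weights(self) -> np.ndarray:
        if self.class_weights is None:
            return np.full(self.n_classes, 1.0 / self.n_classes)
        return np.asarray(self.class_weights)

    @property
    def names(self) -> tuple[str, ...]:
        if self.n_classes == 3:
            return _DEFAULT_CLASS_NAMES
        return tuple(f"class_{k}" for k in range(self.n_classes))


def _simplex_means(n_classes: int, dim: int, side: float) -> np.ndarray:
    """Class means at regular-simplex vertices with pairwise distance ``side``.

    Built from scaled standard-basis vectors in K dims (pairwise distance √2)
    and truncated/padded to ``dim`` columns; with dim < K some pairs end up
    closer than ``side``, which only matters for many classes in few features.
    """
    verts = np.eye(n_classes) * (side / np.sqrt(2.0))
    verts = verts - verts.mean(axis=0)
    if dim >= n_classes:
        return np.hstack([verts, np.zeros((n_classes, dim - n_classes))])
    return verts[:, :dim]


def _likert_probs(n_classes: int, separation: float) -> np.ndarray:
    """Per-class multinomial over the 5 levels, peaked at a class-shifted mode."""
    levels = np.arange(5)
    probs = np.empty((n_classes, 5))
    for c in range(n_classes):
        mode = round(c * 4 / (n_classes - 1)) if n_classes > 1 else 2
        logit = -np.abs(levels - mode) * _LIKERT_SHARPNESS * separation
        w = np.exp(logit)
        probs[c] = w / w.sum()
    return probs


def generate(config: GeneratorConfig) -> Dataset:
    """Draw a labelled dataset under ``config``; see the module docstring."""
    rng = np.random.default_rng(config.seed)
    n, K = config.n_samples, config.n_classes
    true_class = rng.choice(K, size=n, p=config.weights)

    cols: dict[str, object] = {}
    schema: list[AttributeSpec] = []

    lik = _likert_probs(K, config.separation)
    for j in range(config.n_likert_items):
        name = f"likert_{j + 1}"
        draws = np.empty(n, dtype=np.intp)
        for c in range(K):
            sel = true_class == c
            draws[sel] = rng.choice(5, size=int(sel.sum()), p=lik[c])
        cols[name] = np.array([LIKERT_LEVELS[d] for d in draws], dtype=object)
        schema.append(AttributeSpec(name=name, kind="categorical", levels=LIKERT_LEVELS))

    if config.n_continuous:
        means = _simplex_means(K, config.n_continuous, config.separation)
        X = rng.standard_normal((n, config.n_continuous)) + means[true_class]
        for j in range(config.n_continuous):
            name = f"activity_{j + 1}"
            cols[name] = X[:, j]
            schema.append(AttributeSpec(name=name, kind="continuous"))

    observed = true_class.copy()
    if config.label_noise > 0:
        flip = rng.random(n) < config.label_noise
        shift = rng.integers(1, K, size=n)
        observed[flip] = (observed[flip] + shift[flip]) % K

    names = config.names
    labels = np.array([names[c] for c in observed], dtype=object)
    features = pd.DataFrame(cols, columns=[a.name for a in schema])
    return Dataset(schema=tuple(schema), class_names=names, features=features, labels=labels)


def default_benchmark(seed: int = 0) -> tuple[Dataset, Dataset]:
    """The study's standard benchmark: 2000 records, 3 risk classes, 6 Likert
    items, 4 activity features, separation 2.5, 5% label noise — cut into 10
    near-equal folds of which 6 train and 4 test (1200 / 800 records)."""
    data = generate(GeneratorConfig(seed=seed))
    return split_train_test(data, n_parts=10, n_train=6, seed=seed)
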