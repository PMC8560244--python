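import numpy as np
import pandas as pd
import pytest

from mheval.datasets import AttributeSpec, Dataset


def make_dataset(columns, labels, class_names=None, levels=None):
    """Build a Dataset from plain lists.

    ``columns`` maps attribute name -> list of values; values given as str
    become categorical attributes (levels inferred unless given in
    ``levels``), numeric values become continuous attributes.
    """
    schema = []
    cols = {}
    for name, vals in columns.items():
        if isinstance(vals[0], str):
            lv = tuple(levels[name]) if levels and name in levels else tuple(
                sorted(set(vals))
            )
            schema.append(AttributeSpec(name=name, kind="categorical", levels=lv))
            cols[name] = np.array(vals, dtype=object)
        else:
            schema.append(AttributeSpec(name=name, kind="continuous"))
            cols[name] = np.array(vals, dtype=float)
    if class_names is None:
        class_names = tuple(sorted(set(labels)))
    features = pd.DataFrame(cols, columns=list(columns))
    return Dataset(
        schema=tuple(schema),
        class_names=tuple(class_names),
        features=features,
        labels=np.array(labels, dtype=object),
    )


@pytest.fixture
def quad_dataset():
    """Four records, one continuous attribute, separable at x = 2.5."""
    return make_dataset({"x": [1.0, 2.0, 3.0, 4.0]}, ["A", "A", "B", "B"])


@pytest.fixture
def categorical_dataset():
    return make_dataset(
        {"color": ["red", "red", "blue", "blue", "green", "green"]},
        ["A", "A", "B", "B", "B", "B"],
        levels={"color": ["red", "blue", "green"]},
    )
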