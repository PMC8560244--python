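"""Joint tree/network classifier and the model-comparison harness.

The joint model soft-votes the class-probability outputs of a TAM-scored
C4.5 tree and a Levenberg–Marquardt-trained perceptron:

    p_joint = w_tree · p_tree + w_net · p_net,    w_tree + w_net = 1.

Weights are either fixed at 0.5/0.5 or picked on a held-out fifth of the
training split by a grid search over w_tree ∈ {0, 0.1, …, 1}.

:func:`compare_models` fits the five study models — exact-gain-ratio tree
(DT), TAM tree (IDT), gradient-descent net (ANN), LM net (IANN) and the
joint model — on one train/test split and tabulates their metrics,
iteration counts and transcendental-log call counts.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .datasets import Dataset, split_train_test
from .metrics import EvaluationReport, classification_report
from .nnet import (
    NeuralNetModel,
    NeuralNetResults,
    TrainConfig,
    init_network,
    sse_loss,
    train_gd,
    train_lm,
)
from .tree import DecisionTreeModel, DecisionTreeResults, TreeParams

__all__ = [
    "JointModel",
    "JointResults",
    "fit_joint",
    "joint_predict_proba",
    "compare_models",
    "xor_convergence",
]

WEIGHT_GRID = np.round(np.arange(0.0, 1.01, 0.1), 10)


class JointModel:
    """Soft-vote combination of the improved tree and the improved network.

    ``weight_mode="equal"`` fixes both mixing weights at 0.5;
    ``"validation_grid"`` trains the members on four fifths of the data and
    grid-searches w_tree on the held-out fifth (ties go to the smallest
    w_tree on the grid).
    """

    def __init__(
        self,
        data: Dataset,
        tree_params: TreeParams | None = None,
        net_config: TrainConfig | None = None,
        hidden_layer_sizes=(12,),
        weight_mode: str = "equal",
        seed: int = 0,
    ):
        if weight_mode not in ("equal", "validation_grid"):
            raise ValueError(f"unknown weight_mode {weight_mode!r}")
        counts = np.unique(data.labels)
        if len(counts) < 2:
            raise ValueError("joint model needs at least 2 classes in training data")
        self.data = data
        self.tree_params = tree_params or TreeParams(mode="tam")
        self.net_config = net_config or TrainConfig(objective="sse_lm", seed=seed)
        self.hidden_layer_sizes = hidden_layer_sizes
        self.weight_mode = weight_mode
        self.seed = seed

    def _fit_members(self, data: Dataset) -> tuple[DecisionTreeResults, NeuralNetResults]:
        tree = DecisionTreeModel(data, self.tree_params).fit()
        net = NeuralNetModel(data, self.hidden_layer_sizes, self.net_config).fit()
        return tree, net

    def fit(self) -> "JointResults":
        if self.weight_mode == "equal":
            tree, net = self._fit_members(self.data)
            w_tree = 0.5
        else:
            sub, val = split_train_test(self.data, n_parts=5, n_train=4, seed=self.seed)
            tree, net = self._fit_members(sub)
            p_tree = tree.predict_proba(val)
            p_net = net.predict_proba(val)
            y_val = val.label_indices()
            best_w, best_acc = 0.0, -1.0
            for w in WEIGHT_GRID:
                mix = w * p_tree + (1.0 - w) * p_net
                acc = float(np.mean(mix.argmax(axis=1) == y_val))
                if acc > best_acc + 1e-12:
                    best_w, best_acc = float(w), acc
            w_tree = best_w
        return JointResults(self, tree, net, w_tree)


class JointResults:
    def __init__(self, model, tree: DecisionTreeResults, net: NeuralNetResults, w_tree):
        self.model = model
        self.tree = tree
        self.net = net
        self.w_tree = float(w_tree)
        self.w_net = 1.0 - float(w_tree)
        self.class_names = tree.class_names

    def predict_proba(self, data: Dataset) -> np.ndarray:
        return self.w_tree * self.tree.predict_proba(data) + self.w_net * self.net.predict_proba(data)

    def predict(self, data: Dataset) -> np.ndarray:
        idx = self.predict_proba(data).argmax(axis=1)
        return np.array([self.class_names[i] for i in idx], dtype=object)

    def summary(self) -> str:
        lines = [
            "Joint Model Results",
            "=" * 42,
            f"mixing weights:   tree {self.w_tree:.2f} / net {self.w_net:.2f}",
            f"tree nodes:       {self.tree.n_nodes}",
            f"net iterations:   {self.net.n_iterations}",
        ]
        return "\n".join(lines)


def fit_joint(
    train: Dataset,
    tree_params: TreeParams | None = None,
    net_config: TrainConfig | None = None,
    weight_mode: str = "equal",
    seed: int = 0,
    hidden_layer_sizes=(12,),
) -> JointResults:
    """Functional form of :class:`JointModel` + ``fit``."""
    return JointModel(
        train,
        tree_params=tree_params,
        net_config=net_config,
        hidden_layer_sizes=hidden_layer_sizes,
        weight_mode=weight_mode,
        seed=seed,
    ).fit()


def joint_predict_proba(model: JointResults, data: Dataset) -> np.ndarray:
    return model.predict_proba(data)


def _default_net_configs(n_train: int, seed: int) -> tuple[TrainConfig, TrainConfig]:
    """Study-default trainer settings: both nets hold out a validation fifth
    and keep the iterate with the best validation accuracy; the GD step size
    is scaled so the batch-mean step is 0.3 regardless of sample count."""
    n_sub = max(int(round(n_train * 0.8)), 1)
    gd = TrainConfig(
        objective="cross_entropy_gd",
        learning_rate=0.3 / n_sub,
        max_iters=400,
        tol=1e-12,
        seed=seed,
        validation_fraction=0.2,
    )
    lm = TrainConfig(
        objective="sse_lm", max_iters=50, tol=1e-8, seed=seed, validation_fraction=0.2
    )
    return gd, lm


def compare_models(
    train: Dataset,
    test: Dataset,
    seed: int = 0,
    tree_params: TreeParams | None = None,
    gd_config: TrainConfig | None = None,
    lm_config: TrainConfig | None = None,
    hidden_layer_sizes=(8,),
    weight_mode: str = "validation_grid",
) -> tuple[pd.DataFrame, dict[str, EvaluationReport]]:
    """Fit DT, IDT, ANN, IANN and the joint model; score all five on ``test``.

    Returns a five-row table (one per model) with accuracy, macro recall and
    the four error metrics, plus net iteration counts and the number of
    transcendental log calls each tree fit made, and the full reports.
    """
    base_tree = tree_params or TreeParams()
    gd_cfg, lm_cfg = _default_net_configs(train.n_records, seed)
    gd_cfg = gd_config or gd_cfg
    lm_cfg = lm_config or lm_cfg

    y_test = test.label_indices()
    rows = []
    reports: dict[str, EvaluationReport] = {}

    def add(model_id: str, proba: np.ndarray, extra: dict) -> None:
        rep = classification_report(proba, y_test, test.class_names, model_id, seed)
        reports[model_id] = rep
        rows.append(
            {
                "model": model_id,
                "accuracy": rep.accuracy,
                "macro_recall": rep.macro_recall,
                "mae": rep.mae,
                "mse": rep.mse,
                "rmse": rep.rmse,
                "mape": rep.mape,
                **extra,
            }
        )

    dt = DecisionTreeModel(train, dataclasses.replace(base_tree, mode="exact")).fit()
    add("DT", dt.predict_proba(test), {"iterations": None, "log_calls": dt.log_calls_during_fit})

    idt = DecisionTreeModel(train, dataclasses.replace(base_tree, mode="tam")).fit()
    add("IDT", idt.predict_proba(test), {"iterations": None, "log_calls": idt.log_calls_during_fit})

    ann = NeuralNetModel(train, hidden_layer_sizes, gd_cfg).fit()
    add("ANN", ann.predict_proba(test), {"iterations": ann.n_iterations, "log_calls": None})

    iann = NeuralNetModel(train, hidden_layer_sizes, lm_cfg).fit()
    add("IANN", iann.predict_proba(test), {"iterations": iann.n_iterations, "log_calls": None})

    joint = fit_joint(
        train,
        tree_params=dataclasses.replace(base_tree, mode="tam"),
        net_config=lm_cfg,
        weight_mode=weight_mode,
        seed=seed,
        hidden_layer_sizes=hidden_layer_sizes,
    )
    add(
        "Joint",
        joint.predict_proba(test),
        {"iterations": joint.net.n_iterations, "log_calls": joint.tree.log_calls_during_fit},
    )

    return pd.DataFrame(rows), reports


_XOR_X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
_XOR_Y = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0], [1.0, 0.0]])


def xor_convergence(
    seed: int,
    sse_threshold: float = 0.01,
    hidden: int = 2,
    gd_learning_rate: float = 0.5,
    gd_max_iters: int = 5000,
    lm_max_iters: int = 200,
) -> dict:
    """Iterations each trainer needs to push XOR below an SSE threshold.

    Both trainers start from the same seeded 2-``hidden``-2 network. The SSE
    of the sigmoid output head is recorded after every update; the count is
    the first iteration at which it drops below ``sse_threshold`` (the
    trainer's iteration cap if it never does).
    """
    params0 = init_network((2, hidden, 2), seed=seed)

    gd_hits: list[int] = []

    def gd_cb(it: int, p) -> None:
        if not gd_hits and sse_loss(p, _XOR_X, _XOR_Y) < sse_threshold:
            gd_hits.append(it + 1)

    gd_cfg = TrainConfig(
        objective="cross_entropy_gd",
        learning_rate=gd_learning_rate,
        max_iters=gd_max_iters,
        tol=0.0,
        seed=seed,
    )
    train_gd(params0.copy(), _XOR_X, _XOR_Y, gd_cfg, callback=gd_cb)

    lm_hits: list[int] = []

    def lm_cb(it: int, p) -> None:
        if not lm_hits and sse_loss(p, _XOR_X, _XOR_Y) < sse_threshold:
            lm_hits.append(it)

    lm_cfg = TrainConfig(objective="sse_lm", max_iters=lm_max_iters, tol=0.0, seed=seed)
    _, lm_trace, lm_info = train_lm(params0.copy(), _XOR_X, _XOR_Y, lm_cfg, callback=lm_cb)

    return {
        "gd_iterations": gd_hits[0] if gd_hits else gd_max_iters,
        "lm_iterations": lm_hits[0] if lm_hits else lm_max_iters,
        "lm_final_sse": lm_trace[-1],
        "lm_status": lm_info["status"],
    }
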