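"""Evaluation metrics: MAE, MSE, RMSE, MAPE, accuracy and recall.

The four error metrics are the usual

    MAE  = (1/n) Σ |P_i − T_i|          MSE  = (1/n) Σ (P_i − T_i)²
    RMSE = √MSE                         MAPE = (1/n) Σ |P_i − T_i| / |T_i|

For classifiers they are applied to probability calibration: P_i is the
predicted probability of the i-th record's true class and T_i = 1, which
keeps them bounded and sensitive to confidence, not just correctness.
Recall is reported per class and macro-averaged over the classes present.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

__all__ = ["EvaluationReport", "regression_metrics", "classification_report"]


@dataclass
class EvaluationReport:
    mae: float
    mse: float
    rmse: float
    mape: float | None
    accuracy: float | None = None
    recall: dict | None = None
    macro_recall: float | None = None
    model_id: str = ""
    seed: int | None = None
    n_test: int | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @staticmethod
    def from_json(text: str) -> "EvaluationReport":
        return EvaluationReport(**json.loads(text))


def regression_metrics(P: Sequence[float], T: Sequence[float]) -> dict:
    """MAE/MSE/RMSE/MAPE between predictions P and truths T.

    MAPE is reported as None when any T_i is zero; the other metrics are
    still computed.
    """
    p = np.asarray(P, dtype=float)
    t = np.asarray(T, dtype=float)
    if p.shape != t.shape or p.ndim != 1 or p.size < 1:
        raise ValueError("P and T must be equal-length vectors with >= 1 entry")
    err = p - t
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    rmse = math.sqrt(mse)
    if np.any(t == 0):
        mape = None
    else:
        with np.errstate(over="ignore"):
            mape = float(np.mean(np.abs(err) / np.abs(t)))
    return {"mae": mae, "mse": mse, "rmse": rmse, "mape": mape}


def classification_report(
    proba: np.ndarray,
    true_idx: Sequence[int],
    class_names: Sequence[str],
    model_id: str = "",
    seed: int | None = None,
) -> EvaluationReport:
    """Score class-probability predictions against true labels.

    ``proba`` is (n, K); ``true_idx`` holds integer class indices. Accuracy
    uses the argmax rule (ties → lowest class index). The error metrics
    compare the predicted probability of the true class with 1.0.
    """
    proba = np.atleast_2d(np.asarray(proba, dtype=float))
    y = np.asarray(true_idx, dtype=np.intp)
    if len(y) == 0:
        raise ValueError("empty evaluation set")
    if proba.shape[0] != len(y) or proba.shape[1] != len(class_names):
        raise ValueError("probability matrix shape does not match labels/classes")
    pred = proba.argmax(axis=1)
    accuracy = float(np.mean(pred == y))
    recall: dict[str, float] = {}
    present = []
    for k, name in enumerate(class_names):
        in_class = y == k
        if in_class.any():
            r = float(np.mean(pred[in_class] == k))
            recall[str(name)] = r
            present.append(r)
        else:
            recall[str(name)] = float("nan")
    macro = float(np.mean(present))
    p_true = proba[np.arange(len(y)), y]
    reg = regression_metrics(p_true, np.ones(len(y)))
    return EvaluationReport(
        mae=reg["mae"],
        mse=reg["mse"],
        rmse=reg["rmse"],
        mape=reg["mape"],
        accuracy=accuracy,
        recall=recall,
        macro_recall=macro,
        model_id=model_id,
        seed=seed,
        n_test=len(y),
    )
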