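"""Four-class posture classification and its evaluation protocol.

Two classifier backends mirror the study design: a single-hidden-layer
back-propagation network (20 hidden units) and a C-SVC support vector
machine with an RBF kernel. Features enter exactly as fused — layer
entries are already in [0, 1]; the proportion value P_m passes through
unscaled.

Evaluation reports a 4x4 confusion matrix (rows = true class) and
per-class precision TP/(TP+FP) in percent, macro-averaged. A class that
receives no predictions has undefined precision; it is reported as 0
and flagged so the macro average stays defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product as iproduct
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

LABELS = ("standing_walking", "sitting", "stooping", "lying")
METHODS = ("ann", "svm")


@dataclass
class TrainedModel:
    method: str
    estimator: object
    label_set: tuple[str, ...]
    layers: int
    alpha: float
    flavor: str
    seed: int
    hidden_nodes: int = 20

    def predict(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(np.asarray(vectors, dtype=np.float64)))


@dataclass
class EvalReport:
    confusion: np.ndarray                 # (C, C) counts, rows = true
    per_class_precision: dict[str, float]  # percent
    average_precision: float               # macro mean, percent
    undefined_classes: list[str] = field(default_factory=list)
    label_set: tuple[str, ...] = LABELS

    def to_dict(self) -> dict:
        return {
            "labels": list(self.label_set),
            "confusion": self.confusion.tolist(),
            "per_class_precision": self.per_class_precision,
            "average_precision": self.average_precision,
            "undefined_classes": self.undefined_classes,
        }


def _as_matrix(vectors) -> np.ndarray:
    rows = [np.asarray(getattr(v, "values", v), dtype=np.float64) for v in vectors]
    lengths = {r.shape for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"feature vectors have mixed lengths: {lengths}")
    return np.stack(rows)


def train(
    vectors,
    labels: Sequence[str],
    method: str = "ann",
    seed: int = 0,
    hidden_nodes: int = 20,
    layers: int = 3,
    alpha: float = 0.9,
    flavor: str = "depth",
    svm_c: float = 1.0,
    svm_gamma: str | float = "scale",
    max_iter: int = 3000,
) -> TrainedModel:
    """Fit a posture classifier; deterministic for a fixed seed.

    The back-propagation network is trained with the full-batch lbfgs
    solver: the feature vectors are short (2N+2 entries) and corpora
    modest, where lbfgs converges reliably and reproducibly.
    """
    x = _as_matrix(vectors)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training needs at least two classes")
    if method == "ann":
        estimator = MLPClassifier(
            hidden_layer_sizes=(hidden_nodes,),
            solver="lbfgs",
            max_iter=max_iter,
            random_state=seed,
        )
    elif method == "svm":
        estimator = SVC(kernel="rbf", C=svm_c, gamma=svm_gamma, random_state=seed)
    else:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    estimator.fit(x, y)
    return TrainedModel(
        method=method, estimator=estimator, label_set=LABELS, layers=layers,
        alpha=alpha, flavor=flavor, seed=seed, hidden_nodes=hidden_nodes,
    )


def evaluate(model: TrainedModel, vectors, labels: Sequence[str]) -> EvalReport:
    """Confusion matrix and per-class / macro-average precision in percent."""
    x = _as_matrix(vectors)
    y_true = np.asarray(labels)
    y_pred = model.predict(x)
    return score_predictions(y_true, y_pred, label_set=model.label_set)


def score_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, label_set: tuple[str, ...] = LABELS
) -> EvalReport:
    present = [c for c in label_set if (y_true == c).any() or (y_pred == c).any()]
    cm = confusion_matrix(y_true, y_pred, labels=present)
    precisions: dict[str, float] = {}
    undefined = []
    for j, cls in enumerate(present):
        predicted = cm[:, j].sum()
        if predicted == 0:
            precisions[cls] = 0.0
            undefined.append(cls)
        else:
            precisions[cls] = 100.0 * cm[j, j] / predicted
    avg = float(np.mean(list(precisions.values())))
    return EvalReport(
        confusion=cm,
        per_class_precision=precisions,
        average_precision=avg,
        undefined_classes=undefined,
        label_set=tuple(present),
    )


def train_eval_split(
    vectors,
    labels: Sequence[str],
    method: str = "ann",
    seed: int = 0,
    test_size: float = 0.3,
    groups: Optional[Sequence] = None,
    **train_kwargs,
) -> tuple[TrainedModel, EvalReport]:
    """Stratified hold-out protocol for a single corpus.

    When ``groups`` is given (e.g. a sequence id per frame), whole
    groups go to one side of the split so frames of the same recording
    never leak between train and test.

    Rows are put into a canonical order before splitting, so the
    protocol is invariant to how the input table happened to be sorted.
    """
    x = _as_matrix(vectors)
    y = np.asarray(labels)
    if groups is None:
        order = np.lexsort(tuple(x.T) + (y,))
        x, y = x[order], y[order]
        x_tr, x_te, y_tr, y_te = train_test_split(
            x, y, test_size=test_size, random_state=seed, stratify=y
        )
    else:
        groups = np.asarray(groups)
        uniq, first = np.unique(groups, return_index=True)
        group_label = y[first]
        g_tr, g_te = train_test_split(
            uniq, test_size=test_size, random_state=seed, stratify=group_label
        )
        tr = np.isin(groups, g_tr)
        x_tr, y_tr, x_te, y_te = x[tr], y[tr], x[~tr], y[~tr]
    model = train(x_tr, y_tr, method=method, seed=seed, **train_kwargs)
    return model, evaluate(model, x_te, y_te)


def sweep(
    dataset,
    layer_list: Sequence[int],
    alpha_list: Sequence[float],
    methods: Sequence[str] = METHODS,
    seed: int = 0,
    test_size: float = 0.3,
) -> pd.DataFrame:
    """Grid of hold-out average precision over (layers, alpha, method).

    ``dataset`` is a callable ``(layers, alpha) -> (vectors, labels,
    groups-or-None)`` so each cell re-extracts features at its own
    parameter setting.
    """
    rows = []
    for layers, alpha, method in iproduct(layer_list, alpha_list, methods):
        vectors, labels, groups = dataset(layers, alpha)
        _, report = train_eval_split(
            vectors, labels, method=method, seed=seed, test_size=test_size,
            groups=groups, layers=layers, alpha=alpha,
        )
        rows.append(
            {
                "layers": layers,
                "alpha": alpha,
                "method": method,
                "average_precision": report.average_precision,
            }
        )
    return pd.DataFrame(rows)
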