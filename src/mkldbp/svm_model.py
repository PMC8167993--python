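"""Binary SVM on a precomputed kernel, with C selected by grid search.

Training solves the standard soft-margin dual

    max_alpha  sum_i alpha_i - (1/2) sum_ij alpha_i alpha_j y_i y_j K_ij
    s.t.       0 <= alpha_i <= C,   sum_i alpha_i y_i = 0

and prediction applies f(x) = sign(sum_i y_i alpha_i K(x, x_i) + b), with
sign(0) mapped to +1 by convention.  The dual is delegated to libsvm via
scikit-learn in precomputed-kernel mode; the stored model exposes the full
signed coefficient vector y_i * alpha_i so that the KKT feasibility
conditions can be audited directly.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .kernels import KernelMatrix

DEFAULT_C = 2.0
DEFAULT_C_GRID = tuple(2.0**p for p in range(-5, 6))


@dataclasses.dataclass
class TrainedModel:
    """Dual solution of a precomputed-kernel SVM fit."""

    signed_alpha: np.ndarray      # y_i * alpha_i over all training samples
    bias: float
    C: float
    train_ids: list[str]
    y_train: np.ndarray
    kernel_provenance: dict = dataclasses.field(default_factory=dict)

    @property
    def alpha(self) -> np.ndarray:
        return np.abs(self.signed_alpha)

    @property
    def support_indices(self) -> np.ndarray:
        return np.flatnonzero(self.alpha > 0)


@dataclasses.dataclass
class PredictionResult:
    sample_id: str
    decision_value: float
    label: int  # sign of the decision value; 0 maps to +1


def _as_matrix(K) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(K, KernelMatrix):
        return K.values, list(K.row_ids), list(K.col_ids)
    K = np.asarray(K, dtype=float)
    rows = [str(i) for i in range(K.shape[0])]
    cols = [str(j) for j in range(K.shape[1])]
    return K, rows, cols


def train_svm(
    K_train: KernelMatrix | np.ndarray,
    y: np.ndarray,
    C: float = DEFAULT_C,
    provenance: dict | None = None,
) -> TrainedModel:
    """Fit the dual on a square training Gram matrix."""
    values, row_ids, col_ids = _as_matrix(K_train)
    if values.shape[0] != values.shape[1] or row_ids != col_ids:
        raise ValueError("training kernel must be square with matching ids")
    if C <= 0:
        raise ValueError("C must be positive")
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != values.shape[0]:
        raise ValueError("label length must match kernel size")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError("labels must be +1 or -1")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    asym = float(np.abs(values - values.T).max())
    if asym > 1e-8:
        raise ValueError(f"training kernel asymmetric (max |K-K^T| = {asym:g})")
    min_eig = float(np.linalg.eigvalsh(0.5 * (values + values.T)).min())
    if min_eig < -1e-6 * max(float(np.abs(values).max()), 1.0):
        raise ValueError(
            f"training kernel not PSD (min eigenvalue {min_eig:g}); "
            "check the kernel construction"
        )

    svc = SVC(kernel="precomputed", C=C)
    svc.fit(values, y)
    signed_alpha = np.zeros(len(y))
    signed_alpha[svc.support_] = svc.dual_coef_.ravel()
    return TrainedModel(
        signed_alpha=signed_alpha,
        bias=float(svc.intercept_[0]),
        C=C,
        train_ids=row_ids,
        y_train=y,
        kernel_provenance=provenance or {},
    )


def decision_values(
    model: TrainedModel, K_test_train: KernelMatrix | np.ndarray
) -> np.ndarray:
    """f(x) = sum_i y_i alpha_i K(x, x_i) + b for each test row."""
    values, _rows, cols = _as_matrix(K_test_train)
    if values.shape[1] != len(model.signed_alpha):
        raise ValueError("kernel columns must match training sample count")
    if isinstance(K_test_train, KernelMatrix) and cols != model.train_ids:
        raise ValueError("kernel columns not aligned to training sample order")
    return values @ model.signed_alpha + model.bias


def predict(
    model: TrainedModel, K_test_train: KernelMatrix | np.ndarray
) -> list[PredictionResult]:
    values = decision_values(model, K_test_train)
    if isinstance(K_test_train, KernelMatrix):
        ids = list(K_test_train.row_ids)
    else:
        ids = [str(i) for i in range(len(values))]
    return [
        PredictionResult(sample_id=i, decision_value=float(v),
                         label=+1 if v >= 0 else -1)
        for i, v in zip(ids, values)
    ]


def grid_search_C(
    K_train: KernelMatrix | np.ndarray,
    y: np.ndarray,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, list[tuple[float, float]]]:
    """Stratified k-fold CV accuracy for each C; ties break toward smaller C.

    Returns (best_C, [(C, mean_accuracy), ...] in grid order).
    """
    if len(C_grid) == 0:
        raise ValueError("empty C grid")
    values, _rows, _cols = _as_matrix(K_train)
    y = np.asarray(y, dtype=float).ravel()
    counts = [int((y == c).sum()) for c in (-1.0, 1.0)]
    if folds > min(counts):
        raise ValueError(f"folds={folds} exceeds the smaller class size {min(counts)}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))
    table: list[tuple[float, float]] = []
    for C in C_grid:
        correct = 0
        for train_idx, test_idx in splits:
            model = train_svm(values[np.ix_(train_idx, train_idx)],
                              y[train_idx], C=C)
            dec = decision_values(model, values[np.ix_(test_idx, train_idx)])
            pred = np.where(dec >= 0, 1.0, -1.0)
            correct += int((pred == y[test_idx]).sum())
        table.append((float(C), correct / len(y)))
    best_acc = max(acc for _, acc in table)
    candidates = [C for C, acc in table if acc == best_acc]
    best_C = min(candidates)
    return best_C, table
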