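"""Metrics and cross-validation drivers.

Implements the benchmark metric battery — accuracy, sensitivity,
specificity, Matthews correlation coefficient, ROC/AUC and sensitivity at
a fixed specificity — plus leave-one-out, stratified k-fold and
independent-test drivers that run the full pipeline (scale features, build
kernels, learn combination weights, train the SVM) with every fitted
quantity estimated on the training portion of each fold only.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from . import mkl_cka, svm_model
from .config import RunConfig
from .kernels import build_kernel_set, fit_scaler
from .pssm_features import encode_profiles
from .seq_features import FeatureMatrix, encode_sequences, load_property_table
from .sequence_io import Dataset


# ---------------------------------------------------------------------------
# Confusion-matrix metrics
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def counts_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == -1) & (y_pred == -1))),
        FP=int(np.sum((y_true == -1) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == -1))),
    )


def confusion_metrics(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """(ACC, SN, SP, MCC); each ratio is 0 when its denominator is 0."""
    if counts.total == 0:
        raise ValueError("empty confusion matrix")
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    acc = (tp + tn) / counts.total
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return acc, sn, sp, mcc


# ---------------------------------------------------------------------------
# Rank-based metrics
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> tuple[float, np.ndarray]:
    """AUC (midrank tie convention) plus (fpr, tpr) ROC points."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores)
    return auc, np.column_stack([fpr, tpr])


def sensitivity_at_specificity(scores, labels, spec_target: float = 0.5) -> float:
    """Highest sensitivity among thresholds whose specificity >= the target.

    The threshold sweep includes the all-negative operating point
    (specificity 1, sensitivity 0), so any target <= 1 is reachable.
    """
    if not 0.0 <= spec_target <= 1.0:
        raise ValueError("specificity target must be in [0, 1]")
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    pos, neg = scores[labels == 1], scores[labels == -1]
    best = 0.0  # the all-negative point: sensitivity 0, specificity 1
    for t in np.unique(scores):
        spec = float(np.mean(neg < t))
        if spec >= spec_target:
            best = max(best, float(np.mean(pos >= t)))
    return best


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def compute_features(dataset: Dataset, config: RunConfig) -> dict[str, FeatureMatrix]:
    """Encode every configured descriptor for every record, in dataset order."""
    table = load_property_table()
    features: dict[str, FeatureMatrix] = {}
    for name in config.feature_names():
        if name in ("GE", "MCD", "NMBAC"):
            features[name] = encode_sequences(
                dataset.records, name, table=table, lg_max=config.lg_max
            )
        else:
            if dataset.profiles is None:
                raise ValueError(
                    f"feature {name!r} needs PSSM profiles; use sequence_only "
                    "mode for sequence-only datasets"
                )
            profiles = [dataset.profiles[r.id] for r in dataset.records]
            features[name] = encode_profiles(
                profiles, name, lag_max=config.lag_max,
                n_blocks=config.n_blocks, wavelet=config.wavelet,
                levels=config.levels,
            )
    return features


def fit_fold(
    features: dict[str, FeatureMatrix],
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: RunConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Train on ``train_idx`` and score ``test_idx``.

    Returns (decision values on the test rows, kernel weights beta).  All
    fitted quantities — scalers, MKL weights, the SVM — see only the
    training rows.
    """
    names = list(config.feature_names())
    train_f: dict[str, FeatureMatrix] = {}
    test_f: dict[str, FeatureMatrix] = {}
    for name in names:
        X = features[name]
        Xtr = FeatureMatrix(name, X.values[train_idx],
                            [X.sample_ids[i] for i in train_idx])
        Xte = FeatureMatrix(name, X.values[test_idx],
                            [X.sample_ids[i] for i in test_idx])
        scaler = fit_scaler(Xtr)
        train_f[name] = FeatureMatrix(name, scaler.transform(Xtr.values),
                                      Xtr.sample_ids)
        test_f[name] = FeatureMatrix(name, scaler.transform(Xte.values),
                                     Xte.sample_ids)

    if config.strategy.startswith("single:"):
        chosen = config.strategy.split(":", 1)[1]
        order: tuple[str, ...] = (chosen,)
    else:
        order = tuple(names)
    K_train = build_kernel_set(train_f, config.gammas, order=order)
    K_test = build_kernel_set(test_f, config.gammas, col_features=train_f,
                              order=order)

    m = len(K_train)
    if config.strategy == "cka":
        problem = mkl_cka.build_problem(K_train, y[train_idx], lam=config.lam)
        beta = mkl_cka.solve_weights(problem).beta
    else:  # mean or single (single has m = 1, so uniform is exact)
        beta = mkl_cka.mean_weights(m)

    K_star_train = mkl_cka.combine_kernels(K_train, beta)
    K_star_test = mkl_cka.combine_kernels(K_test, beta)
    model = svm_model.train_svm(K_star_train, y[train_idx], C=config.C)
    return svm_model.decision_values(model, K_star_test), beta


@dataclasses.dataclass
class EvalReport:
    ACC: float
    SN: float
    SP: float
    MCC: float
    AUC: float
    counts: ConfusionCounts
    decision_values: np.ndarray   # aggregated over held-out samples
    y_true: np.ndarray
    sample_ids: list[str]
    fold_assignment: np.ndarray
    seed: Optional[int]
    betas: list[np.ndarray] = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "ACC": self.ACC, "SN": self.SN, "SP": self.SP,
            "MCC": self.MCC, "AUC": self.AUC,
            "TP": self.counts.TP, "TN": self.counts.TN,
            "FP": self.counts.FP, "FN": self.counts.FN,
            "n": int(len(self.y_true)), "seed": self.seed,
        }


def _aggregate(
    y: np.ndarray,
    ids: list[str],
    decisions: np.ndarray,
    fold_assignment: np.ndarray,
    seed: Optional[int],
    betas: list[np.ndarray],
) -> EvalReport:
    """Pool all held-out decisions into one confusion matrix and report."""
    y_pred = np.where(decisions >= 0, 1, -1)
    counts = counts_from_predictions(y, y_pred)
    acc, sn, sp, mcc = confusion_metrics(counts)
    auc, _ = roc_auc(decisions, y)
    return EvalReport(ACC=acc, SN=sn, SP=sp, MCC=mcc, AUC=auc, counts=counts,
                      decision_values=decisions, y_true=y, sample_ids=ids,
                      fold_assignment=fold_assignment, seed=seed, betas=betas)


def _run_folds(
    dataset: Dataset,
    config: RunConfig,
    splits: list[tuple[np.ndarray, np.ndarray]],
    seed: Optional[int],
    features: Optional[dict[str, FeatureMatrix]] = None,
) -> EvalReport:
    if features is None:
        features = compute_features(dataset, config)
    y = dataset.labels()
    n = len(y)
    decisions = np.full(n, np.nan)
    fold_assignment = np.full(n, -1)
    betas = []
    for fold, (train_idx, test_idx) in enumerate(splits):
        try:
            dec, beta = fit_fold(features, y, train_idx, test_idx, config)
        except Exception as exc:
            raise RuntimeError(f"fold {fold} failed: {exc}") from exc
        decisions[test_idx] = dec
        fold_assignment[test_idx] = fold
        betas.append(beta)
    assert not np.any(np.isnan(decisions))
    return _aggregate(y, dataset.ids, decisions, fold_assignment, seed, betas)


def loocv(
    dataset: Dataset,
    config: RunConfig | None = None,
    features: Optional[dict[str, FeatureMatrix]] = None,
) -> EvalReport:
    """Leave-one-out CV; the N held-out decisions form one confusion matrix."""
    if config is None:
        config = RunConfig()
    n = len(dataset.records)
    all_idx = np.arange(n)
    splits = [(np.delete(all_idx, i), np.array([i])) for i in range(n)]
    return _run_folds(dataset, config, splits, seed=None, features=features)


def kfold_cv(
    dataset: Dataset,
    k: int = 5,
    seed: int = 0,
    config: RunConfig | None = None,
    features: Optional[dict[str, FeatureMatrix]] = None,
) -> EvalReport:
    """Stratified k-fold CV; k = N reduces to leave-one-out fold structure."""
    if config is None:
        config = RunConfig()
    y = dataset.labels()
    n = len(y)
    if k == n:
        return loocv(dataset, config, features=features)
    class_sizes = [int((y == c).sum()) for c in (-1, 1)]
    if k > min(class_sizes):
        raise ValueError(f"k={k} exceeds the smaller class size {min(class_sizes)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = [(tr, te) for tr, te in skf.split(np.zeros(n), y)]
    return _run_folds(dataset, config, splits, seed=seed, features=features)


def independent_test(
    train_dataset: Dataset,
    test_dataset: Dataset,
    config: RunConfig | None = None,
    allow_overlap: bool = False,
) -> EvalReport:
    """Train once on the training set, evaluate once on the test set."""
    if config is None:
        config = RunConfig()
    if not test_dataset.records:
        raise ValueError("empty test set")
    overlap = set(train_dataset.ids) & set(test_dataset.ids)
    if overlap and not allow_overlap:
        raise ValueError(
            f"train/test id overlap ({sorted(overlap)[:5]}); pass "
            "allow_overlap=True to evaluate anyway"
        )
    merged = Dataset(
        records=train_dataset.records + [
            r for r in test_dataset.records if r.id not in set(train_dataset.ids)
        ],
        profiles=(
            {**(train_dataset.profiles or {}), **(test_dataset.profiles or {})}
            or None
        ),
        name="merged",
    )
    # Feature encoding is per-sample, so computing it jointly leaks nothing;
    # scalers / weights / the SVM are fitted inside fit_fold on train rows.
    config_feats = compute_features(merged, config)
    n_train = len(train_dataset.records)
    id_pos = {rid: i for i, rid in enumerate(merged.ids)}
    train_idx = np.arange(n_train)
    test_idx = np.array([id_pos[r.id] for r in test_dataset.records])
    y = np.zeros(len(merged.records), dtype=int)
    for i, r in enumerate(merged.records):
        if r.label is not None:
            y[i] = r.label
    for r in test_dataset.records:  # test labels may differ on overlap
        y[id_pos[r.id]] = r.label
    dec, beta = fit_fold(config_feats, y, train_idx, test_idx, config)
    return _aggregate(
        y[test_idx], [r.id for r in test_dataset.records], dec,
        np.zeros(len(test_idx), dtype=int), config.seed, [beta],
    )


def paired_t_test(metrics_a, metrics_b) -> tuple[float, float]:
    """Paired t-test over two equal-length per-fold metric vectors.

    Returns (t statistic, two-sided p value).
    """
    from scipy import stats

    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("metric vectors must have equal length")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
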