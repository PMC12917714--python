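"""RBF-SVM training protocol for agonist/antagonist classification.

Protocol: stratified 80/20 split, standardization fitted on training rows
only, stratified 5-fold grid-search cross-validation over
C ∈ {0.1, 1, 10} × gamma ∈ {scale, auto} with an RBF kernel, refit on the
full training set with the winning combination, and calibrated probability
outputs (probability of antagonism, label 1).

Probability calibration is Platt scaling fitted on internal
cross-validated decision values: the training set is split into stratified
folds, each fold's decision values come from an SVM fitted on the other
folds, and a regularized sigmoid  P(antagonist | f) = 1 / (1 + exp(a·f + b))
is fitted to those out-of-fold values.  This keeps the calibration free of
training-set optimism and makes every probability an exact, reproducible
function of the decision value.

The *confidence score* reported per prediction defaults to the calibrated
probability of the predicted class; the absolute decision-function margin
is available as an alternative.  Confidence *percentile* is the weak
within-batch rank (fraction of batch scores <= the score), so selecting
"percentile >= 0.90" yields the top 10 % most confident predictions.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "SplitSpec",
    "HyperParams",
    "DEFAULT_GRID",
    "TrainedClassifier",
    "PredictionRecord",
    "stratified_split",
    "resolve_gamma",
    "grid_search_cv",
    "cv_accuracy",
    "fit_final",
    "predict",
    "confidence_percentiles",
    "fit_platt",
    "save_model",
    "load_model",
]

POSITIVE_CLASS = 1  # antagonist
CLASS_NAMES = {0: "agonist", 1: "antagonist"}


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.2
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass(frozen=True)
class HyperParams:
    C: float = 1.0
    gamma: float | Literal["scale", "auto"] = "scale"
    kernel: str = "rbf"


#: Grid-search space, in declared (tie-breaking) order: C outer, gamma inner.
DEFAULT_GRID: tuple[HyperParams, ...] = tuple(
    HyperParams(C=c, gamma=g) for c in (0.1, 1.0, 10.0) for g in ("scale", "auto")
)


@dataclass
class PredictionRecord:
    ligand_id: str
    predicted_class: int
    predicted_label: str
    probability: float            # of the predicted class
    prob_antagonist: float
    confidence_score: float
    confidence_percentile: float = float("nan")


def fit_platt(decision_values, labels, prior_correction: bool = True) -> tuple[float, float]:
    """Fit the Platt sigmoid P(y=1 | f) = 1 / (1 + exp(a·f + b)).

    Maximum-likelihood with the standard smoothed targets
    t+ = (N+ + 1)/(N+ + 2), t- = 1/(N- + 2) to regularize the fit on small
    samples (disable with ``prior_correction=False`` for raw logistic).
    """
    f = np.asarray(decision_values, float)
    y = np.asarray(labels)
    n_pos, n_neg = int(np.sum(y == 1)), int(np.sum(y != 1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required to calibrate probabilities")
    if prior_correction:
        t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    else:
        t = (y == 1).astype(float)

    def nll(params):
        a, b = params
        z = a * f + b
        # -log p with p = sigmoid(-z); stable via logaddexp
        return np.sum(t * np.logaddexp(0.0, z) + (1 - t) * np.logaddexp(0.0, -z))

    def grad(params):
        a, b = params
        z = np.clip(a * f + b, -500, 500)
        s = 1.0 / (1.0 + np.exp(-z))  # sigmoid(z)
        d = s - (1 - t)               # d(nll_i)/dz
        return np.array([np.sum(d * f), np.sum(d)])

    # initialization as in Platt (1999)
    b0 = np.log((n_neg + 1.0) / (n_pos + 1.0))
    res = minimize(nll, x0=[-1.0, b0], jac=grad, method="BFGS")
    a, b = res.x
    return float(a), float(b)


@dataclass
class TrainedClassifier:
    """Scaler + fitted RBF-SVM + Platt calibration + feature-column manifest."""

    hyperparams: HyperParams
    scaler: StandardScaler
    svm: SVC
    platt_a: float
    platt_b: float
    feature_columns: list[str]
    seed: int
    confidence_mode: str = "probability"  # or "margin"

    @property
    def scaler_mean(self) -> np.ndarray:
        return self.scaler.mean_

    @property
    def scaler_std(self) -> np.ndarray:
        return self.scaler.scale_

    def _check_columns(self, matrix: pd.DataFrame) -> None:
        cols = list(matrix.columns)
        if cols != self.feature_columns:
            extra = [c for c in cols if c not in self.feature_columns]
            missing = [c for c in self.feature_columns if c not in cols]
            raise ValueError(
                "feature columns do not match the training layout"
                + (f"; missing: {missing[:5]}" if missing else "")
                + (f"; unexpected: {extra[:5]}" if extra else "")
                + ("; same names, different order" if not missing and not extra else "")
            )

    def _rbf_decision(self, Xs: np.ndarray) -> np.ndarray:
        """Decision function on already-scaled rows via explicit kernel.

        Identical to libsvm's decision values but computed with BLAS matrix
        products, which matters on the large hybrid batches attribution
        generates.
        """
        sv = self.svm.support_vectors_.astype(Xs.dtype, copy=False)
        gamma = Xs.dtype.type(self.svm._gamma)
        d2 = (
            np.sum(Xs * Xs, axis=1)[:, None]
            - 2.0 * (Xs @ sv.T)
            + np.sum(sv * sv, axis=1)[None, :]
        )
        np.maximum(d2, 0.0, out=d2)
        K = np.exp(-gamma * d2)
        dual = self.svm.dual_coef_[0].astype(Xs.dtype, copy=False)
        return K @ dual + self.svm.intercept_[0]

    def decision_function(self, matrix: pd.DataFrame) -> np.ndarray:
        self._check_columns(matrix)
        return self._rbf_decision(self.scaler.transform(matrix.to_numpy(float)))

    def _platt(self, f: np.ndarray) -> np.ndarray:
        z = np.clip(self.platt_a * f + self.platt_b, -500, 500)
        return 1.0 / (1.0 + np.exp(z))

    def prob_antagonist_fn(self, X: np.ndarray) -> np.ndarray:
        """Raw-array probability-of-antagonism function (for attribution).

        Preserves float32 input (used for large hybrid attribution batches).
        """
        X = np.asarray(X)
        if X.dtype not in (np.float32, np.float64):
            X = X.astype(float)
        # manual affine transform so float32 batches stay float32
        mean = self.scaler.mean_.astype(X.dtype, copy=False)
        scale = self.scaler.scale_.astype(X.dtype, copy=False)
        Xs = (X - mean) / scale
        return self._platt(self._rbf_decision(Xs))

    def predict_proba(self, matrix: pd.DataFrame) -> np.ndarray:
        """Class-probability matrix, columns ordered [agonist(0), antagonist(1)]."""
        p1 = self._platt(self.decision_function(matrix))
        return np.column_stack([1.0 - p1, p1])


def stratified_split(
    matrix: pd.DataFrame,
    labels: Sequence[int],
    spec: SplitSpec = SplitSpec(),
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test row-index split.

    Test size is ceil(test_fraction * n); per-class proportions are
    preserved to within one sample.  Deterministic for a given seed.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to stratify")
    if counts.min() < 2:
        raise ValueError(
            f"class {classes[counts.argmin()]} has fewer than 2 members; cannot stratify"
        )
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=spec.test_fraction, random_state=spec.seed, stratify=y
    )
    return np.sort(train_idx), np.sort(test_idx)


def resolve_gamma(mode: float | str, matrix) -> float:
    """Resolve an RBF gamma setting to a positive real.

    'auto' -> 1/d; 'scale' -> 1/(d * var) with var the pooled variance of
    all matrix entries.  Numeric input passes through unchanged.
    """
    X = np.asarray(matrix, dtype=float)
    if X.size == 0:
        raise ValueError("empty matrix")
    d = X.shape[1]
    if isinstance(mode, (int, float)):
        if mode <= 0:
            raise ValueError("gamma must be positive")
        return float(mode)
    if mode == "auto":
        return 1.0 / d
    if mode == "scale":
        var = X.var()
        if var == 0:
            raise ValueError("pooled variance is zero; gamma='scale' undefined")
        return 1.0 / (d * var)
    raise ValueError(f"unknown gamma mode {mode!r}")


def _fold_accuracy(
    X: np.ndarray, y: np.ndarray, params: HyperParams, k: int, seed: int
) -> float:
    """Mean stratified k-fold accuracy; scaler refit inside each fold."""
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for tr, va in skf.split(X, y):
        scaler = StandardScaler().fit(X[tr])
        svm = SVC(C=params.C, gamma=params.gamma, kernel=params.kernel,
                  random_state=seed)
        svm.fit(scaler.transform(X[tr]), y[tr])
        accs.append(float(np.mean(svm.predict(scaler.transform(X[va])) == y[va])))
    return float(np.mean(accs))


def cv_accuracy(
    matrix, labels, params: HyperParams, k: int = 5, seed: int = 42
) -> float:
    """Stratified k-fold CV accuracy at fixed hyperparameters."""
    return _fold_accuracy(np.asarray(matrix, float), np.asarray(labels), params, k, seed)


def grid_search_cv(
    matrix,
    labels,
    grid: Sequence[HyperParams] = DEFAULT_GRID,
    k: int = 5,
    seed: int = 42,
) -> tuple[HyperParams, float]:
    """Exhaustive grid search by stratified k-fold CV accuracy.

    Every grid point is evaluated on identical folds; the highest mean fold
    accuracy wins, ties broken by position in the declared grid order.
    """
    X = np.asarray(matrix, float)
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class ({counts.min()}) has fewer members than k={k}")
    best: HyperParams | None = None
    best_acc = -np.inf
    for params in grid:
        acc = _fold_accuracy(X, y, params, k, seed)
        if acc > best_acc:
            best, best_acc = params, acc
    assert best is not None
    return best, best_acc


def fit_final(
    matrix: pd.DataFrame,
    labels,
    params: HyperParams,
    seed: int = 42,
    confidence_mode: str = "probability",
    calibration_folds: int = 5,
) -> TrainedClassifier:
    """Refit scaler + SVM on the full training set with the chosen grid point.

    The Platt sigmoid is fitted on stratified out-of-fold decision values
    (each fold scored by an SVM trained on the remaining folds), then the
    final SVM is fitted on all rows.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    # contiguous copy: scaler statistics must be bit-identical for equal
    # values regardless of the source frame's block layout
    X = np.ascontiguousarray(matrix.to_numpy(float))
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)

    def make_svm() -> SVC:
        return SVC(C=params.C, gamma=params.gamma, kernel=params.kernel,
                   random_state=seed)

    # out-of-fold decision values for leakage-free calibration
    k = min(calibration_folds, int(np.min(np.bincount(y))))
    cv_dec = np.empty(len(y))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for tr, va in skf.split(Xs, y):
        fold_svm = make_svm().fit(Xs[tr], y[tr])
        cv_dec[va] = fold_svm.decision_function(Xs[va])
    a, b = fit_platt(cv_dec, y)

    svm = make_svm().fit(Xs, y)
    return TrainedClassifier(
        hyperparams=params,
        scaler=scaler,
        svm=svm,
        platt_a=a,
        platt_b=b,
        feature_columns=list(matrix.columns),
        seed=seed,
        confidence_mode=confidence_mode,
    )


def confidence_percentiles(scores: Sequence[float]) -> np.ndarray:
    """Weak within-batch rank: fraction of batch scores <= each score.

    Ties share the same (maximal) percentile, so a batch of equal scores
    all sit at percentile 1.0.
    """
    s = np.asarray(scores, float)
    if s.size == 0:
        return np.empty(0)
    sorted_s = np.sort(s)
    counts = np.searchsorted(sorted_s, s, side="right")
    return counts / s.size


def predict(model: TrainedClassifier, matrix: pd.DataFrame) -> list[PredictionRecord]:
    """Per-row class, probability, confidence score and within-batch percentile.

    The predicted class is antagonist when the calibrated probability of
    antagonism reaches 0.5, so class labels and probabilities are always
    mutually consistent.
    """
    f = model.decision_function(matrix)
    p1 = model._platt(f)
    pred = (p1 >= 0.5).astype(int)
    prob_pred = np.where(pred == 1, p1, 1.0 - p1)
    if model.confidence_mode == "margin":
        conf = np.abs(f)
    else:
        conf = prob_pred
    pct = confidence_percentiles(conf)
    return [
        PredictionRecord(
            ligand_id=str(lid),
            predicted_class=int(c),
            predicted_label=CLASS_NAMES[int(c)],
            probability=float(pp),
            prob_antagonist=float(pa),
            confidence_score=float(cs),
            confidence_percentile=float(q),
        )
        for lid, c, pp, pa, cs, q in zip(matrix.index, pred, prob_pred, p1, conf, pct)
    ]


# ---------------------------------------------------------------------------
# Model persistence: a versioned archive whose manifest is verified on load.

_FORMAT_VERSION = 2


def save_model(model: TrainedClassifier, path) -> None:
    payload = {
        "format_version": _FORMAT_VERSION,
        "hyperparams": model.hyperparams,
        "scaler": model.scaler,
        "svm": model.svm,
        "platt": (model.platt_a, model.platt_b),
        "feature_columns": model.feature_columns,
        "seed": model.seed,
        "confidence_mode": model.confidence_mode,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> TrainedClassifier:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model archive version: {payload.get('format_version')}")
    cols = payload["feature_columns"]
    n_scaler = payload["scaler"].mean_.shape[0]
    if len(cols) != n_scaler:
        raise ValueError(
            f"model archive manifest inconsistent: {len(cols)} columns vs scaler dim {n_scaler}"
        )
    a, b = payload["platt"]
    return TrainedClassifier(
        hyperparams=payload["hyperparams"],
        scaler=payload["scaler"],
        svm=payload["svm"],
        platt_a=a,
        platt_b=b,
        feature_columns=cols,
        seed=payload["seed"],
        confidence_mode=payload["confidence_mode"],
    )
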