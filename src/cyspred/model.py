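"""Feature scaling, SVM-RBF training/prediction, and grid search.

Training data is linearly scaled per feature into [-1, 1] (min -> -1,
max -> +1, constant features -> 0); test values are clipped into that
range. Class weighting is balanced by default: the curated site data is
heavily imbalanced toward negatives, and an unweighted fit would not
produce near-equal sensitivity and specificity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.svm import SVC


@dataclass(frozen=True)
class ScalerParams:
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        mins = np.asarray(self.mins, dtype=float)
        maxs = np.asarray(self.maxs, dtype=float)
        if mins.shape != maxs.shape:
            raise ValueError("mins and maxs must have equal shape")
        if np.any(maxs < mins):
            raise ValueError("max must be >= min for every feature")
        object.__setattr__(self, "mins", mins)
        object.__setattr__(self, "maxs", maxs)


@dataclass(frozen=True)
class SVMConfig:
    C: float = 1.0
    gamma: float = 0.01
    class_weighting: str = "balanced"  # "none" | "balanced"

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if self.class_weighting not in ("none", "balanced"):
            raise ValueError(
                f"class_weighting must be 'none' or 'balanced', "
                f"got {self.class_weighting!r}"
            )


@dataclass
class TrainedModel:
    """Fitted classifier together with its scaler and feature manifest."""

    classifier: SVC
    scaler: ScalerParams
    config: SVMConfig
    feature_names: tuple | None = None


def fit_scaler(train_matrix: np.ndarray) -> ScalerParams:
    X = np.asarray(train_matrix, dtype=float)
    if X.size == 0:
        raise ValueError("cannot fit a scaler on an empty matrix")
    return ScalerParams(X.min(axis=0), X.max(axis=0))


def apply_scaler(params: ScalerParams, matrix: np.ndarray) -> np.ndarray:
    """Map each feature into [-1, 1] using training min/max; constant
    training features map to 0; out-of-range values are clipped."""
    X = np.asarray(matrix, dtype=float)
    if X.shape[-1] != params.mins.shape[0]:
        raise ValueError(
            f"matrix has {X.shape[-1]} features, scaler expects "
            f"{params.mins.shape[0]}"
        )
    span = params.maxs - params.mins
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(span > 0, -1.0 + 2.0 * (X - params.mins) / span, 0.0)
    return np.clip(scaled, -1.0, 1.0)


def train_svm(
    matrix: np.ndarray,
    labels: Sequence[int],
    config: SVMConfig,
    feature_names: Sequence[str] | None = None,
) -> TrainedModel:
    """Fit the scaler and an RBF-kernel soft-margin SVM on +-1 labels."""
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    if set(np.unique(y).tolist()) - {1, -1}:
        raise ValueError(f"labels must be +1/-1, got {sorted(set(y.tolist()))}")
    if len(set(y.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    scaler = fit_scaler(X)
    clf = SVC(
        C=config.C,
        gamma=config.gamma,
        kernel="rbf",
        class_weight="balanced" if config.class_weighting == "balanced" else None,
        cache_size=200,
    )
    clf.fit(apply_scaler(scaler, X), y)
    names = tuple(feature_names) if feature_names is not None else None
    return TrainedModel(clf, scaler, config, names)


def predict(
    model: TrainedModel,
    matrix: np.ndarray,
    names: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Predict +-1 labels and decision values.

    If *names* is given and the model carries a manifest, columns are
    permuted into manifest order first, making prediction invariant to
    feature column order.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X.reshape(0 if X.size == 0 else 1, model.scaler.mins.shape[0])
    if names is not None and model.feature_names is not None:
        names = tuple(names)
        if set(names) != set(model.feature_names):
            raise ValueError("feature names do not match the model manifest")
        if names != model.feature_names:
            order = [names.index(n) for n in model.feature_names]
            X = X[:, order]
    if X.shape[0] == 0:
        return np.array([], dtype=int), np.array([])
    if X.shape[1] != model.scaler.mins.shape[0]:
        raise ValueError(
            f"matrix has {X.shape[1]} features, model expects "
            f"{model.scaler.mins.shape[0]}"
        )
    Xs = apply_scaler(model.scaler, X)
    decision = model.classifier.decision_function(Xs)
    # decision_function sign is relative to classes_[1]; map to +-1
    pos_is_second = model.classifier.classes_[1] == 1
    labels = np.where((decision > 0) == pos_is_second, 1, -1)
    return labels.astype(int), decision


def default_grid() -> dict[str, list[float]]:
    """The conventional coarse log2 grid for C and gamma."""
    return {
        "C": [2.0**e for e in range(-5, 16, 2)],
        "gamma": [2.0**e for e in range(-15, 4, 2)],
    }


def grid_search(
    matrix: np.ndarray,
    labels: Sequence[int],
    grid: Mapping[str, Sequence[float]],
    cv,
    class_weighting: str = "balanced",
) -> tuple[SVMConfig, "MetricsReport"]:
    """Exhaustive search maximizing pooled CV MCC; ties prefer smaller C
    then smaller gamma."""
    from .evaluation import cross_validate

    Cs = sorted(grid["C"])
    gammas = sorted(grid["gamma"])
    if not Cs or not gammas:
        raise ValueError("grid must be non-empty")
    best: tuple[SVMConfig, object] | None = None
    for C in Cs:
        for gamma in gammas:
            config = SVMConfig(C=C, gamma=gamma, class_weighting=class_weighting)
            pooled, _ = cross_validate(matrix, labels, config, cv)
            if best is None or pooled.mcc > best[1].mcc:
                best = (config, pooled)
    return best


def save_model(model: TrainedModel, path, extra: dict | None = None) -> None:
    """Serialize a model (plus optional pipeline artifacts) to one archive."""
    payload = {
        "classifier": model.classifier,
        "scaler": model.scaler,
        "config": model.config,
        "feature_names": model.feature_names,
        "extra": extra or {},
    }
    joblib.dump(payload, path)


def load_model(path) -> tuple[TrainedModel, dict]:
    payload = joblib.load(path)
    model = TrainedModel(
        payload["classifier"],
        payload["scaler"],
        payload["config"],
        payload["feature_names"],
    )
    return model, payload.get("extra", {})
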