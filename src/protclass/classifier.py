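"""Binary kernel-SVM training, scoring and persistence.

The underlying quadratic-program solver is scikit-learn's ``SVC``
(libsvm); this module owns the domain contract around it: the four kernel
specifications, the +1/-1 label convention, feature-fingerprint checking,
dual-constraint access and versioned model files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import joblib
import numpy as np
from sklearn.svm import SVC

from .descriptors import FeatureMatrix

logger = logging.getLogger(__name__)

KERNEL_KINDS = ("linear", "polynomial", "rbf", "sigmoid")
_SKLEARN_KERNEL = {
    "linear": "linear",
    "polynomial": "poly",
    "rbf": "rbf",
    "sigmoid": "sigmoid",
}

MODEL_FORMAT_VERSION = 1


class FingerprintMismatchError(ValueError):
    """Feature matrix does not match the scheme the model was trained on."""


@dataclass(frozen=True)
class KernelSpec:
    """One of the four kernels: linear, polynomial, rbf, sigmoid.

    ``gamma=None`` resolves to 1 / n_features at training time.  Parameters
    irrelevant to the chosen kind are ignored.  The rbf kernel is the
    positive-definite exp(-gamma * ||x - z||^2).
    """

    kind: Literal["linear", "polynomial", "rbf", "sigmoid"]
    gamma: float | None = None
    coef0: float = 0.0
    degree: int = 3

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel {self.kind!r}; choose {KERNEL_KINDS}")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.degree < 1:
            raise ValueError(f"degree must be >= 1, got {self.degree}")

    def resolve_gamma(self, n_features: int) -> float:
        return self.gamma if self.gamma is not None else 1.0 / n_features

    def __call__(self, x: np.ndarray, z: np.ndarray, n_features: int | None = None) -> np.ndarray:
        """Evaluate the kernel on row batches (reference implementation)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        z = np.atleast_2d(np.asarray(z, dtype=float))
        g = self.resolve_gamma(n_features if n_features is not None else x.shape[1])
        dots = x @ z.T
        if self.kind == "linear":
            return dots
        if self.kind == "polynomial":
            return (g * dots + self.coef0) ** self.degree
        if self.kind == "sigmoid":
            return np.tanh(g * dots + self.coef0)
        sq = (
            (x**2).sum(axis=1)[:, None]
            - 2.0 * dots
            + (z**2).sum(axis=1)[None, :]
        )
        return np.exp(-g * np.maximum(sq, 0.0))


@dataclass
class SvmModel:
    """Trained classifier state.

    Dual coefficients are stored as alpha_i * y_i over the support vectors
    (the libsvm convention); ``alphas`` recovers the non-negative alpha_i.
    """

    kernel: KernelSpec
    c: float
    scheme: str
    feature_names: tuple[str, ...]
    fingerprint: str
    svc: SVC = field(repr=False)
    calibrated: bool = True

    @property
    def support_vectors(self) -> np.ndarray:
        return self.svc.support_vectors_

    @property
    def dual_coef(self) -> np.ndarray:
        """alpha_i * y_i per support vector."""
        return self.svc.dual_coef_.ravel()

    @property
    def alphas(self) -> np.ndarray:
        return np.abs(self.dual_coef)

    @property
    def intercept(self) -> float:
        return float(self.svc.intercept_[0])

    @property
    def n_support(self) -> int:
        return int(self.svc.support_vectors_.shape[0])

    def check_features(self, features: FeatureMatrix) -> None:
        if features.fingerprint != self.fingerprint:
            raise FingerprintMismatchError(
                f"feature fingerprint {features.fingerprint} does not match "
                f"model fingerprint {self.fingerprint} "
                f"(model scheme {self.scheme!r}, features scheme {features.scheme!r})"
            )
        if features.n_features != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, "
                f"got {features.n_features}"
            )


@dataclass(frozen=True)
class Predictions:
    """Per-row outcome: hard label, calibrated probability of +1, raw score."""

    labels: np.ndarray
    probabilities: np.ndarray | None
    decision_values: np.ndarray


def train_svm(
    features: FeatureMatrix,
    labels: np.ndarray,
    kernel: KernelSpec = KernelSpec("rbf"),
    c: float = 1.0,
    probability: bool = True,
    seed: int = 0,
    tol: float = 1e-3,
) -> SvmModel:
    """Fit a binary SVM on encoded features with labels in {+1, -1}.

    With ``probability`` on, Platt sigmoid calibration (fitted by internal
    cross-validation within the training data) maps decision values to
    positive-class probabilities.  Reproducible given ``seed``.
    """
    y = np.asarray(labels, dtype=int)
    if y.shape != (len(features),):
        raise ValueError("one label per feature row required")
    if set(np.unique(y)) != {-1, 1}:
        raise ValueError("training requires both classes, labels in {+1, -1}")
    if not np.isfinite(features.values).all():
        raise ValueError("non-finite feature values")
    if c <= 0:
        raise ValueError(f"c must be > 0, got {c}")

    svc_kwargs = dict(
        C=c,
        kernel=_SKLEARN_KERNEL[kernel.kind],
        gamma=kernel.resolve_gamma(features.n_features),
        coef0=kernel.coef0,
        degree=kernel.degree,
        random_state=seed,
        cache_size=200,
        tol=tol,
    )
    if probability:
        # scikit-learn 1.9 deprecates the probability flag; Platt-calibrated
        # SVC is still the construction we want, so silence just that warning.
        svc_kwargs["probability"] = True
    svc = SVC(**svc_kwargs)
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*probability.*", category=FutureWarning
        )
        svc.fit(features.values, y)
    return SvmModel(
        kernel=kernel,
        c=c,
        scheme=features.scheme,
        feature_names=features.feature_names,
        fingerprint=features.fingerprint,
        svc=svc,
        calibrated=probability,
    )


def decision_values(model: SvmModel, features: FeatureMatrix) -> np.ndarray:
    """Pre-sign decision quantity sum_i y_i alpha_i K(x, x_i) + b per row."""
    model.check_features(features)
    return model.svc.decision_function(features.values)


def predict(model: SvmModel, features: FeatureMatrix) -> Predictions:
    """Hard labels plus calibrated +1 probabilities.

    Label is the sign of the decision value; an exact tie at 0 predicts +1
    and is logged.  When calibration is available, probability/label
    disagreements (possible with Platt scaling) are counted and logged.
    """
    model.check_features(features)
    dv = decision_values(model, features)
    n_ties = int(np.sum(dv == 0.0))
    if n_ties:
        logger.warning("predict: %d decision value(s) exactly 0, predicting +1", n_ties)
    labels = np.where(dv >= 0.0, 1, -1)
    probs = None
    if model.calibrated:
        pos_col = int(np.flatnonzero(model.svc.classes_ == 1)[0])
        probs = model.svc.predict_proba(features.values)[:, pos_col]
        n_disagree = int(np.sum((labels == 1) != (probs >= 0.5)))
        if n_disagree:
            logger.info(
                "predict: %d row(s) where calibrated probability disagrees "
                "with decision sign",
                n_disagree,
            )
    return Predictions(labels=labels, probabilities=probs, decision_values=dv)


def save_model(model: SvmModel, path: str | Path) -> None:
    """Serialize to a single versioned file embedding the feature fingerprint."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "kernel": model.kernel,
        "c": model.c,
        "scheme": model.scheme,
        "feature_names": model.feature_names,
        "fingerprint": model.fingerprint,
        "svc": model.svc,
        "calibrated": model.calibrated,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> SvmModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model file {path} has format version {version}, "
            f"this build reads version {MODEL_FORMAT_VERSION}"
        )
    return SvmModel(
        kernel=payload["kernel"],
        c=payload["c"],
        scheme=payload["scheme"],
        feature_names=tuple(payload["feature_names"]),
        fingerprint=payload["fingerprint"],
        svc=payload["svc"],
        calibrated=payload["calibrated"],
    )


def tune_hyperparameters(
    features: FeatureMatrix,
    labels: np.ndarray,
    kernel_kind: str = "rbf",
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0),
    gamma_grid: tuple[float, ...] | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[float, float | None]:
    """Optional grid search over (c, gamma) by k-fold CV accuracy.

    Off by default everywhere; returns the best (c, gamma) pair.  gamma is
    None (meaning 1/n_features) when the grid is not supplied or the kernel
    ignores it.
    """
    from .evaluation import kfold_split  # local import to avoid a cycle

    y = np.asarray(labels, dtype=int)
    gammas: tuple[float | None, ...]
    if kernel_kind == "linear" or gamma_grid is None:
        gammas = (None,)
    else:
        gammas = gamma_grid
    folds = kfold_split(len(features), k, seed=seed, stratified=True, labels=y)
    best = (-np.inf, None, None)
    for c in c_grid:
        for g in gammas:
            kernel = KernelSpec(kernel_kind, gamma=g)
            accs = []
            for i, test_idx in enumerate(folds):
                train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
                m = train_svm(
                    features.subset(train_idx), y[train_idx], kernel, c,
                    probability=False, seed=seed,
                )
                pred = predict(m, features.subset(test_idx))
                accs.append(float(np.mean(pred.labels == y[test_idx])))
            score = float(np.mean(accs))
            if score > best[0]:
                best = (score, c, g)
    logger.info("grid search best accuracy %.4f at c=%s gamma=%s", *best)
    return best[1], best[2]
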