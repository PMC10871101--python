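"""JSON persistence for fitted response models.

A fitted model is serialised to a self-describing JSON document —
algorithm, hyperparameters, feature names, standardization statistics and
the fitted coefficients the family exposes (linear weights for LDA and
linear SVM, support vectors and dual coefficients for RBF SVM, layer
weights for the MLP). Loading reconstructs a predictor whose decision
scores and labels are computed directly from those arrays, so a model
file is portable and independent of the training session.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.pipeline import Pipeline

from .exceptions import ValidationError
from .response import (
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
    HotspotResponseResults,
)

__all__ = ["save_model", "load_model", "LoadedModel"]


def _inner(estimator):
    if isinstance(estimator, Pipeline):
        return estimator.named_steps["clf"], estimator.named_steps["scale"]
    return estimator, None


def save_model(results: HotspotResponseResults, path: str | Path) -> Path:
    """Serialise a fitted model to JSON."""
    clf, scaler = _inner(results.estimator)
    doc: dict = {
        "format": "hotspotnac-model",
        "version": 1,
        "algorithm": results.algorithm,
        "params": {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in results.params.items()
        },
        "feature_names": results.model.feature_names,
        "cv_accuracy": results.cv_accuracy,
        "positive_label": POSITIVE_LABEL,
        "standardization": None,
    }
    if scaler is not None:
        doc["standardization"] = {
            "mean": scaler.mean_.tolist(),
            "scale": scaler.scale_.tolist(),
        }
    if results.algorithm == "LDA":
        doc["weights"] = {
            "coef": np.asarray(clf.coef_).ravel().tolist(),
            "intercept": float(np.asarray(clf.intercept_).ravel()[0]),
        }
    elif results.algorithm == "SVM":
        if clf.kernel == "linear":
            doc["weights"] = {
                "kernel": "linear",
                "coef": np.asarray(clf.coef_).ravel().tolist(),
                "intercept": float(clf.intercept_[0]),
            }
        else:
            doc["weights"] = {
                "kernel": "rbf",
                "support_vectors": clf.support_vectors_.tolist(),
                "dual_coef": np.asarray(clf.dual_coef_).ravel().tolist(),
                "intercept": float(clf.intercept_[0]),
                "gamma": float(clf._gamma),
            }
    elif results.algorithm == "MLP":
        doc["weights"] = {
            "coefs": [w.tolist() for w in clf.coefs_],
            "intercepts": [b.tolist() for b in clf.intercepts_],
            "activation": clf.activation,
        }
    else:
        raise ValidationError(f"cannot serialise algorithm {results.algorithm!r}")

    path = Path(path)
    path.write_text(json.dumps(doc, indent=2))
    return path


@dataclass
class LoadedModel:
    """A deserialised model: scores and labels from stored arrays."""

    algorithm: str
    params: dict
    feature_names: list[str]
    standardization: dict | None
    weights: dict
    cv_accuracy: float

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise ValidationError(
                f"expected {len(self.feature_names)} features "
                f"({self.feature_names}), got {X.shape[1]}"
            )
        if self.standardization is not None:
            mean = np.asarray(self.standardization["mean"])
            scale = np.asarray(self.standardization["scale"])
            X = (X - mean) / scale
        return X

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Positive-class (pCR) decision score per row."""
        X = self._prepare(X)
        w = self.weights
        if self.algorithm == "LDA" or (
            self.algorithm == "SVM" and w.get("kernel") == "linear"
        ):
            return X @ np.asarray(w["coef"]) + w["intercept"]
        if self.algorithm == "SVM":
            sv = np.asarray(w["support_vectors"])
            dual = np.asarray(w["dual_coef"])
            d2 = ((X[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
            kernel = np.exp(-w["gamma"] * d2)
            return kernel @ dual + w["intercept"]
        if self.algorithm == "MLP":
            act = X
            coefs = [np.asarray(c) for c in w["coefs"]]
            intercepts = [np.asarray(b) for b in w["intercepts"]]
            for c, b in zip(coefs[:-1], intercepts[:-1]):
                act = np.maximum(act @ c + b, 0.0)  # relu hidden layers
            logits = (act @ coefs[-1] + intercepts[-1]).ravel()
            return logits  # monotone in P(pCR); sigmoid output unit
        raise ValidationError(f"unknown stored algorithm {self.algorithm!r}")

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(X)
        return np.where(scores > 0, POSITIVE_LABEL, NEGATIVE_LABEL)


def load_model(path: str | Path) -> LoadedModel:
    """Load a model written by :func:`save_model`."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: not a valid model file ({exc})") from exc
    if doc.get("format") != "hotspotnac-model":
        raise ValidationError(f"{path}: not a hotspotnac model file")
    return LoadedModel(
        algorithm=doc["algorithm"],
        params=doc["params"],
        feature_names=doc["feature_names"],
        standardization=doc["standardization"],
        weights=doc["weights"],
        cv_accuracy=doc["cv_accuracy"],
    )
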