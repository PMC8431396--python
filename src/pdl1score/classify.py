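"""Cell typing into tumor / immune / stromal with a multilayer perceptron.

A single-hidden-layer MLP on standardized features assigns each detected cell
to one of the three classes relevant for PD-L1 scoring (stromal cells are kept
as a class precisely so they can be excluded from the scores).  Inference runs
through an explicit forward pass over the stored weight matrices, so a model
serialized to JSON reproduces its probabilities exactly after loading, and the
same arrays feed the Olden connection-weight variable importance
``importance(i, c) = sum_h w_ih * w_hc`` (signed, on the standardized scale,
which makes importances comparable across features measured in µm, µm² and
OD units).
"""

from __future__ import annotations

import json
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

__all__ = ["CellClass", "CellTypeClassifier", "train_mlp", "classify_cells",
           "variable_importance"]


class CellClass(str, Enum):
    TUMOR = "TUMOR"
    IMMUNE = "IMMUNE"
    STROMAL = "STROMAL"


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class CellTypeClassifier(BaseEstimator, ClassifierMixin):
    """Single-hidden-layer MLP cell-type classifier (scikit-learn estimator).

    Features are standardized inside the model (zero-variance features get
    unit scale).  Training is delegated to :class:`MLPClassifier`; the learned
    weights are stored as plain arrays and all inference uses them directly.

    Parameters
    ----------
    hidden_units : width of the single hidden layer (logistic activation).
    l2 : L2 penalty.
    max_iter : training iterations cap.
    seed : RNG seed; fixed seed gives identical weights across runs.
    validation_fraction : stratified held-out share for the reported
        ``holdout_accuracy_`` / ``confusion_matrix_``.
    balance_classes : resample classes to equal counts before fitting.
    required_classes : classes that must appear in the training labels
        (None = no requirement).
    """

    def __init__(self, hidden_units: int = 32, l2: float = 1e-4,
                 max_iter: int = 500, seed: int = 0,
                 validation_fraction: float = 0.2,
                 balance_classes: bool = False,
                 required_classes: tuple[str, ...] | None = None):
        self.hidden_units = hidden_units
        self.l2 = l2
        self.max_iter = max_iter
        self.seed = seed
        self.validation_fraction = validation_fraction
        self.balance_classes = balance_classes
        self.required_classes = required_classes

    # ------------------------------------------------------------------
    def _prepare(self, X) -> tuple[np.ndarray, list[str]]:
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), list(X.columns)
        X = np.asarray(X, dtype=float)
        return X, [f"f{i}" for i in range(X.shape[1])]

    def fit(self, X, y):
        Xa, names = self._prepare(X)
        y = np.asarray([str(v) for v in y])
        if np.isnan(Xa).any():
            raise ValueError("missing feature values in training data")
        classes = np.unique(y)
        if self.required_classes is not None:
            missing = set(self.required_classes) - set(classes)
            if missing:
                raise ValueError(f"class absent from training labels: {sorted(missing)}")
        if len(classes) < 2:
            raise ValueError("need at least two classes to train")

        rng = np.random.default_rng(self.seed)
        if self.balance_classes:
            target = max(np.bincount(pd.factorize(y)[0]))
            parts = []
            for c in classes:
                idx = np.nonzero(y == c)[0]
                take = rng.choice(idx, size=target, replace=len(idx) < target)
                parts.append(take)
            sel = np.concatenate(parts)
            Xa, y = Xa[sel], y[sel]

        self.feature_names_ = names
        mean = Xa.mean(axis=0)
        sd = Xa.std(axis=0)
        sd[sd == 0] = 1.0
        self.scaler_mean_, self.scaler_scale_ = mean, sd
        Xs = (Xa - mean) / sd

        mlp_kw = dict(hidden_layer_sizes=(self.hidden_units,),
                      activation="logistic", alpha=self.l2,
                      max_iter=self.max_iter, random_state=self.seed)
        idx = np.arange(len(y))
        tr, te = train_test_split(idx, test_size=self.validation_fraction,
                                  stratify=y, random_state=self.seed)
        probe = MLPClassifier(**mlp_kw).fit(Xs[tr], y[tr])
        pred = probe.predict(Xs[te])
        self.holdout_accuracy_ = float((pred == y[te]).mean())
        self.confusion_matrix_ = pd.DataFrame(
            _sk_confusion(y[te], pred, labels=classes), index=classes, columns=classes)

        final = MLPClassifier(**mlp_kw).fit(Xs, y)
        self.classes_ = final.classes_
        self.coefs_ = [w.copy() for w in final.coefs_]
        self.intercepts_ = [b.copy() for b in final.intercepts_]
        self.n_features_in_ = Xa.shape[1]
        return self

    # ------------------------------------------------------------------
    def _forward(self, Xs: np.ndarray) -> np.ndarray:
        a = _logistic(Xs @ self.coefs_[0] + self.intercepts_[0])
        z = a @ self.coefs_[1] + self.intercepts_[1]
        if z.shape[1] == 1:  # binary: sklearn trains one logistic output
            p = _logistic(z[:, 0])
            return np.column_stack([1 - p, p])
        return _softmax(z)

    def predict_proba(self, X) -> np.ndarray:
        Xa, names = self._prepare(X)
        if isinstance(X, pd.DataFrame) and list(names) != list(self.feature_names_):
            if set(names) >= set(self.feature_names_):
                Xa = X[self.feature_names_].to_numpy(dtype=float)
            else:
                raise ValueError("feature columns do not match the trained model")
        if Xa.shape[1] != self.n_features_in_:
            raise ValueError("feature dimension mismatch")
        Xs = (Xa - self.scaler_mean_) / self.scaler_scale_
        return self._forward(Xs)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    # ------------------------------------------------------------------
    def variable_importance(self) -> pd.DataFrame:
        """Olden connection-weight importance, one column per class.

        ``importance(i, c) = sum_h w_ih * w_hc`` on the standardized-scale
        weights of the single hidden layer.
        """
        if len(self.coefs_) != 2:
            raise ValueError("importance defined for one hidden layer")
        imp = self.coefs_[0] @ self.coefs_[1]
        if imp.shape[1] == 1:  # binary logistic output: signed toward classes_[1]
            imp = np.column_stack([-imp[:, 0], imp[:, 0]])
        return pd.DataFrame(imp, index=self.feature_names_, columns=self.classes_)

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        payload = {
            "format": "pdl1score.cell_mlp",
            "version": 1,
            "params": self.get_params(),
            "classes": self.classes_.tolist(),
            "feature_names": self.feature_names_,
            "scaler_mean": self.scaler_mean_.tolist(),
            "scaler_scale": self.scaler_scale_.tolist(),
            "coefs": [w.tolist() for w in self.coefs_],
            "intercepts": [b.tolist() for b in self.intercepts_],
            "holdout_accuracy": self.holdout_accuracy_,
            "confusion_matrix": self.confusion_matrix_.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "CellTypeClassifier":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "pdl1score.cell_mlp":
            raise ValueError("not a cell-classifier file")
        params = payload["params"]
        if params.get("required_classes") is not None:
            params["required_classes"] = tuple(params["required_classes"])
        obj = cls(**params)
        obj.classes_ = np.array(payload["classes"])
        obj.feature_names_ = payload["feature_names"]
        obj.scaler_mean_ = np.array(payload["scaler_mean"])
        obj.scaler_scale_ = np.array(payload["scaler_scale"])
        obj.coefs_ = [np.array(w) for w in payload["coefs"]]
        obj.intercepts_ = [np.array(b) for b in payload["intercepts"]]
        obj.holdout_accuracy_ = payload["holdout_accuracy"]
        obj.confusion_matrix_ = pd.DataFrame(payload["confusion_matrix"])
        obj.n_features_in_ = len(obj.scaler_mean_)
        return obj


def train_mlp(features, labels, *, hidden_units: int = 32, max_iter: int = 500,
              l2: float = 1e-4, seed: int = 0, **kwargs) -> CellTypeClassifier:
    """Train the cell-type MLP (thin wrapper over the estimator)."""
    return CellTypeClassifier(hidden_units=hidden_units, max_iter=max_iter,
                              l2=l2, seed=seed, **kwargs).fit(features, labels)


def classify_cells(model: CellTypeClassifier, features) -> tuple[np.ndarray, np.ndarray]:
    """Class label and probability matrix for each cell (stateless batch)."""
    proba = model.predict_proba(features)
    labels = model.classes_[np.argmax(proba, axis=1)]
    return labels, proba


def variable_importance(model: CellTypeClassifier) -> pd.DataFrame:
    return model.variable_importance()
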