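"""Broadband-emission precursor classifier: a small sigmoid MLP.

The classifier maps the 12 per-pulse features (1st-7th ultra-harmonic levels,
pressure, target x/y, normalized microbubble kinetics, tumor presence) to the
probability that the *next* pulse contains a broadband emission.  The network
is deliberately small — one hidden layer of 10 sigmoid units and a sigmoid
output — and is trained by Levenberg-Marquardt on the mean-squared error of
the sigmoid output, after min-max feature scaling fitted on the training set
only.  Class imbalance (~8% positives) is handled by under-sampling the
majority class in the training split; the test split keeps its natural
imbalance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.model_selection import train_test_split

__all__ = [
    "MLP_FEATURES",
    "TrainConfig",
    "MLPModel",
    "ConfusionMetrics",
    "split_and_undersample",
    "train_mlp",
    "confusion_metrics",
]

#: Canonical 12-feature ordering of the precursor classifier.
MLP_FEATURES: tuple[str, ...] = (
    "uh1", "uh2", "uh3", "uh4", "uh5", "uh6", "uh7",
    "pressure_mpa", "x_mm", "y_mm", "mb_kinetics", "tumor",
)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (fixed architecture: hidden sigmoid layer)."""

    hidden_units: int = 10
    epochs: int = 1000          # mapped to the optimizer's evaluation budget
    learning_rate: float = 0.01  # initial LM damping scale
    split_fraction: float = 0.8
    decision_threshold: float = 0.5
    restarts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    def to_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "precision": self.precision, "specificity": self.specificity,
        }


class MLPModel:
    """Trained D -> hidden -> 1 sigmoid network with its min-max scaler.

    ``predict_proba`` is a pure function of (weights, input); labels use a
    strictly-greater comparison against ``decision_threshold``.
    """

    def __init__(self, w1: np.ndarray, b1: np.ndarray, w2: np.ndarray, b2: float,
                 feature_min: np.ndarray, feature_max: np.ndarray,
                 feature_names: Sequence[str] = MLP_FEATURES,
                 decision_threshold: float = 0.5,
                 metadata: dict[str, Any] | None = None) -> None:
        self.w1 = np.asarray(w1, dtype=float)           # (D, H)
        self.b1 = np.asarray(b1, dtype=float)           # (H,)
        self.w2 = np.asarray(w2, dtype=float)           # (H,)
        self.b2 = float(b2)
        self.feature_min = np.asarray(feature_min, dtype=float)
        self.feature_max = np.asarray(feature_max, dtype=float)
        self.feature_names = tuple(feature_names)
        self.decision_threshold = float(decision_threshold)
        self.metadata = dict(metadata or {})

    @property
    def input_dim(self) -> int:
        return self.w1.shape[0]

    def _scale(self, x: np.ndarray) -> np.ndarray:
        span = np.where(self.feature_max > self.feature_min,
                        self.feature_max - self.feature_min, 1.0)
        return (x - self.feature_min) / span

    def predict_proba(self, features: np.ndarray | pd.DataFrame) -> np.ndarray:
        x = self._coerce(features)
        h = _sigmoid(self._scale(x) @ self.w1 + self.b1)
        return _sigmoid(h @ self.w2 + self.b2)

    def predict(self, features: np.ndarray | pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """(probability, label) with label = probability > threshold."""
        p = self.predict_proba(features)
        return p, p > self.decision_threshold

    def _coerce(self, features: np.ndarray | pd.DataFrame) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            features = features[list(self.feature_names)].to_numpy(dtype=float)
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if x.shape[1] != self.input_dim:
            raise ValueError(f"expected {self.input_dim} features, got {x.shape[1]}")
        if not np.all(np.isfinite(x)):
            raise ValueError("features must be finite")
        return x

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        blob = {
            "w1": self.w1.tolist(), "b1": self.b1.tolist(),
            "w2": self.w2.tolist(), "b2": self.b2,
            "feature_min": self.feature_min.tolist(),
            "feature_max": self.feature_max.tolist(),
            "feature_names": list(self.feature_names),
            "decision_threshold": self.decision_threshold,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(blob, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MLPModel":
        blob = json.loads(Path(path).read_text())
        return cls(
            w1=np.array(blob["w1"]), b1=np.array(blob["b1"]),
            w2=np.array(blob["w2"]), b2=blob["b2"],
            feature_min=np.array(blob["feature_min"]),
            feature_max=np.array(blob["feature_max"]),
            feature_names=blob["feature_names"],
            decision_threshold=blob["decision_threshold"],
            metadata=blob.get("metadata", {}),
        )


def split_and_undersample(corpus: pd.DataFrame, config: TrainConfig | None = None,
                          feature_names: Sequence[str] = MLP_FEATURES,
                          label_col: str = "label",
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified 80/20 split, then balance the training portion.

    The training set keeps every training-portion positive and adds an equal
    count of seeded-random training-portion negatives; the test set is left
    untouched with its natural class imbalance.  No row appears in both.
    """
    config = config or TrainConfig()
    y = corpus[label_col].to_numpy()
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise ValueError("corpus must contain both classes")
    train_df, test_df = train_test_split(
        corpus, train_size=config.split_fraction, stratify=y,
        random_state=config.seed)
    pos = train_df[train_df[label_col] == 1]
    neg = train_df[train_df[label_col] == 0]
    if len(neg) < len(pos):
        raise ValueError("not enough negatives to match positives after split")
    neg_sample = neg.sample(n=len(pos), random_state=config.seed)
    balanced = pd.concat([pos, neg_sample]).sample(frac=1.0, random_state=config.seed)
    return balanced.reset_index(drop=True), test_df.reset_index(drop=True)


def _pack(w1: np.ndarray, b1: np.ndarray, w2: np.ndarray, b2: float) -> np.ndarray:
    return np.concatenate([w1.ravel(), b1, w2, [b2]])


def _unpack(theta: np.ndarray, d: int, h: int):
    i = 0
    w1 = theta[i:i + d * h].reshape(d, h); i += d * h
    b1 = theta[i:i + h]; i += h
    w2 = theta[i:i + h]; i += h
    b2 = theta[i]
    return w1, b1, w2, b2


def train_mlp(train_set: pd.DataFrame, config: TrainConfig | None = None,
              feature_names: Sequence[str] = MLP_FEATURES,
              label_col: str = "label") -> MLPModel:
    """Fit the sigmoid MLP by Levenberg-Marquardt on per-sample residuals.

    Residuals are ``sigmoid_output - label`` so the objective is exactly the
    MSE of the network output.  The min-max scaler is fitted on the training
    set alone.  Several seeded restarts are made and the best final MSE kept;
    reproducible under ``config.seed``.
    """
    config = config or TrainConfig()
    names = list(feature_names)
    x_raw = train_set[names].to_numpy(dtype=float)
    y = train_set[label_col].to_numpy(dtype=float)
    if not np.all(np.isfinite(x_raw)):
        raise ValueError("features must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("training set is single-class (degenerate)")

    fmin, fmax = x_raw.min(axis=0), x_raw.max(axis=0)
    span = np.where(fmax > fmin, fmax - fmin, 1.0)
    x = (x_raw - fmin) / span

    d, h = x.shape[1], config.hidden_units
    n_params = d * h + h + h + 1
    if x.shape[0] < n_params:
        # MINPACK's LM needs at least as many residuals as parameters
        raise ValueError(
            f"training set has {x.shape[0]} rows but the network has "
            f"{n_params} parameters; LM requires rows >= parameters")

    def residuals(theta: np.ndarray) -> np.ndarray:
        w1, b1, w2, b2 = _unpack(theta, d, h)
        hid = _sigmoid(x @ w1 + b1)
        return _sigmoid(hid @ w2 + b2) - y

    def jacobian(theta: np.ndarray) -> np.ndarray:
        w1, b1, w2, b2 = _unpack(theta, d, h)
        hid = _sigmoid(x @ w1 + b1)           # (N, H)
        out = _sigmoid(hid @ w2 + b2)         # (N,)
        dout = out * (1.0 - out)              # sigmoid'
        dhid = hid * (1.0 - hid)              # (N, H)
        # d r / d w2 = dout * hid ; d r / d b2 = dout
        j_w2 = dout[:, None] * hid
        j_b2 = dout[:, None]
        # d r / d b1_j = dout * w2_j * dhid_j ; d r / d w1_ij = that * x_i
        back = dout[:, None] * w2[None, :] * dhid   # (N, H)
        j_w1 = back[:, None, :] * x[:, :, None]     # (N, D, H)
        return np.concatenate(
            [j_w1.reshape(x.shape[0], d * h), back, j_w2, j_b2], axis=1)

    rng = np.random.default_rng(config.seed)
    best = None
    for _ in range(max(1, config.restarts)):
        theta0 = rng.normal(0.0, 1.0, size=n_params)
        res = least_squares(residuals, theta0, jac=jacobian, method="lm",
                            max_nfev=config.epochs)
        if best is None or res.cost < best.cost:
            best = res
    w1, b1, w2, b2 = _unpack(best.x, d, h)
    return MLPModel(
        w1=w1, b1=b1, w2=w2, b2=b2, feature_min=fmin, feature_max=fmax,
        feature_names=names, decision_threshold=config.decision_threshold,
        metadata={
            "optimizer": "levenberg-marquardt (scipy.optimize.least_squares, method='lm')",
            "objective": "mse on sigmoid output",
            "hidden_units": h, "epochs_budget": config.epochs,
            "seed": config.seed, "final_mse": float(2 * best.cost / len(y)),
            "n_train": int(len(y)),
        })


def confusion_metrics(predictions: Sequence[int] | np.ndarray,
                      labels: Sequence[int] | np.ndarray) -> ConfusionMetrics:
    """Confusion counts and the four derived proportions."""
    p = np.asarray(predictions).astype(bool)
    y = np.asarray(labels).astype(bool)
    if p.shape != y.shape:
        raise ValueError("predictions and labels must have equal length")
    if p.size == 0:
        raise ValueError("empty input")
    return ConfusionMetrics(
        tp=int(np.sum(p & y)), fp=int(np.sum(p & ~y)),
        fn=int(np.sum(~p & y)), tn=int(np.sum(~p & ~y)))
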