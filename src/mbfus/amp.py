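"""Attentive multilayer perceptron (AMP) for broadband-emission prediction.

The AMP separates what is known about the *subject* from what the detector
*hears*: six subject-state features (target x/y, pulse number, microbubble
kinetics, pressure, tumor presence) are encoded into a query vector Q, while
the 14 spectral measurements (harmonics 2-8 and ultra-harmonics 1-7) enter as
a 14-token sequence whose per-token encodings serve as keys K and values V.
Scaled dot-product attention, ``softmax(Q K^T / sqrt(d)) V``, lets the
subject context weight individual frequency bands before a linear head with
sigmoid output produces the event probability.

Class imbalance is handled in the loss rather than by resampling: the
positive class carries a weight of ``(n_neg / n_pos) * epsilon`` (epsilon 2
by default) in the cross-entropy.  Training uses full-batch Adam with L2
regularization, layer normalization and dropout; model selection runs
stratified 10-fold cross-validation.  The network is small enough that the
whole model, including the attention backward pass, is plain numpy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "SUBJECT_FEATURES",
    "SPECTRAL_FEATURES",
    "AMP_FEATURES",
    "AMPTrainConfig",
    "AMPModel",
    "positive_class_weight",
    "cross_attention",
    "train_amp",
]

SUBJECT_FEATURES: tuple[str, ...] = (
    "x_mm", "y_mm", "pulse_index", "mb_kinetics", "pressure_mpa", "tumor")
SPECTRAL_FEATURES: tuple[str, ...] = tuple(
    [f"h{n}" for n in range(2, 9)] + [f"uh{k}" for k in range(1, 8)])
AMP_FEATURES: tuple[str, ...] = SUBJECT_FEATURES + SPECTRAL_FEATURES


def positive_class_weight(n_neg: int, n_pos: int, epsilon: float = 2.0) -> float:
    """Cross-entropy weight of the positive class: ``(n_neg / n_pos) * epsilon``."""
    if n_pos <= 0:
        raise ValueError("n_pos must be positive")
    if epsilon == 0:
        warnings.warn("epsilon = 0 silences the positive class entirely",
                      stacklevel=2)
    return n_neg / n_pos * epsilon


def cross_attention(q: np.ndarray, k: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Scaled dot-product attention: ``softmax(q k^T / sqrt(d)) v``.

    ``q``: (n_q, d); ``k``: (n_tokens, d); ``v``: (n_tokens, d_v).  Attention
    weights are normalized per query row.
    """
    q, k, v = (np.asarray(a, dtype=float) for a in (q, k, v))
    if q.ndim != 2 or k.ndim != 2 or v.ndim != 2:
        raise ValueError("q, k, v must be 2-D")
    if q.shape[1] != k.shape[1] or k.shape[0] != v.shape[0]:
        raise ValueError("incompatible attention dimensions")
    scores = q @ k.T / np.sqrt(q.shape[1])
    scores -= scores.max(axis=1, keepdims=True)
    w = np.exp(scores)
    w /= w.sum(axis=1, keepdims=True)
    return w @ v


@dataclass(frozen=True)
class AMPTrainConfig:
    epsilon: float = 2.0            # positive-weight scale
    split_fraction: float = 0.8     # stratified train share
    k_folds: int = 10
    latent_dim: int = 16
    dropout_rate: float = 0.1
    l2_strength: float = 1e-4
    epochs: int = 300
    learning_rate: float = 0.01
    decision_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                    np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))


class AMPModel:
    """Trained cross-attention classifier; exposes the same predict contract
    as the plain MLP so a controller can use either interchangeably."""

    _LN_EPS = 1e-5

    def __init__(self, params: dict[str, np.ndarray],
                 feature_min: np.ndarray, feature_max: np.ndarray,
                 decision_threshold: float = 0.5,
                 feature_names: Sequence[str] = AMP_FEATURES,
                 metadata: dict | None = None) -> None:
        self.params = {k: np.asarray(v, dtype=float) for k, v in params.items()}
        self.feature_min = np.asarray(feature_min, dtype=float)
        self.feature_max = np.asarray(feature_max, dtype=float)
        self.decision_threshold = float(decision_threshold)
        self.feature_names = tuple(feature_names)
        self.metadata = dict(metadata or {})

    # -- forward ------------------------------------------------------------
    @classmethod
    def init_params(cls, rng: np.random.Generator, latent_dim: int,
                    n_subject: int = len(SUBJECT_FEATURES),
                    n_tokens: int = len(SPECTRAL_FEATURES)) -> dict[str, np.ndarray]:
        d = latent_dim
        scale = 1.0 / np.sqrt(d)
        return {
            "wq": rng.normal(0, scale, (n_subject, d)), "bq": np.zeros(d),
            "wk": rng.normal(0, scale, (n_tokens, d)), "ck": np.zeros((n_tokens, d)),
            "wv": rng.normal(0, scale, (n_tokens, d)), "cv": np.zeros((n_tokens, d)),
            "gamma": np.ones(d), "beta": np.zeros(d),
            "u": rng.normal(0, scale, d), "b": np.zeros(1),
        }

    def _scale(self, x: np.ndarray) -> np.ndarray:
        span = np.where(self.feature_max > self.feature_min,
                        self.feature_max - self.feature_min, 1.0)
        return (x - self.feature_min) / span

    def _forward(self, x: np.ndarray, dropout_mask: np.ndarray | None = None,
                 keep_cache: bool = False):
        p = self.params
        n_sub = p["wq"].shape[0]
        s, tok = x[:, :n_sub], x[:, n_sub:]
        d = p["wq"].shape[1]
        q = np.tanh(s @ p["wq"] + p["bq"])                       # (N, d)
        k = np.tanh(tok[:, :, None] * p["wk"][None] + p["ck"][None])  # (N, T, d)
        v = tok[:, :, None] * p["wv"][None] + p["cv"][None]           # (N, T, d)
        scores = np.einsum("nd,ntd->nt", q, k) / np.sqrt(d)
        scores = scores - scores.max(axis=1, keepdims=True)
        a = np.exp(scores)
        a /= a.sum(axis=1, keepdims=True)                         # (N, T)
        z = np.einsum("nt,ntd->nd", a, v)
        mu = z.mean(axis=1, keepdims=True)
        var = z.var(axis=1, keepdims=True)
        zh = (z - mu) / np.sqrt(var + self._LN_EPS)
        out = p["gamma"] * zh + p["beta"]
        if dropout_mask is not None:
            out = out * dropout_mask
        logit = out @ p["u"] + p["b"][0]
        prob = _sigmoid(logit)
        if not keep_cache:
            return prob
        cache = dict(s=s, tok=tok, q=q, k=k, v=v, a=a, z=z, zh=zh,
                     var=var, out=out, logit=logit, prob=prob,
                     dropout_mask=dropout_mask)
        return prob, cache

    def predict_proba(self, features: np.ndarray | pd.DataFrame) -> np.ndarray:
        x = self._coerce(features)
        return self._forward(self._scale(x))

    def predict(self, features: np.ndarray | pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        prob = self.predict_proba(features)
        return prob, prob > self.decision_threshold

    def attention_weights(self, features: np.ndarray | pd.DataFrame) -> np.ndarray:
        """(n, 14) attention distribution over the spectral tokens."""
        x = self._scale(self._coerce(features))
        _, cache = self._forward(x, keep_cache=True)
        return cache["a"]

    def _coerce(self, features: np.ndarray | pd.DataFrame) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            features = features[list(self.feature_names)].to_numpy(dtype=float)
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if x.shape[1] != len(self.feature_names):
            raise ValueError(f"expected {len(self.feature_names)} features")
        return x

    # -- training -----------------------------------------------------------
    def _loss_grads(self, x: np.ndarray, y: np.ndarray, pos_weight: float,
                    l2: float, dropout_mask: np.ndarray | None):
        p = self.params
        n = x.shape[0]
        prob, c = self._forward(x, dropout_mask=dropout_mask, keep_cache=True)
        eps = 1e-12
        w = np.where(y == 1, pos_weight, 1.0)
        loss = float(np.mean(-w * (y * np.log(prob + eps)
                                   + (1 - y) * np.log(1 - prob + eps)) / max(pos_weight, 1.0)))
        # d loss / d logit (weighted BCE), normalized like the loss
        g = (np.where(y == 1, pos_weight * (prob - 1.0), prob)
             / max(pos_weight, 1.0)) / n                          # (N,)
        grads: dict[str, np.ndarray] = {}
        grads["u"] = c["out"].T @ g
        grads["b"] = np.array([g.sum()])
        dout = np.outer(g, p["u"])
        if dropout_mask is not None:
            dout = dout * dropout_mask
        grads["gamma"] = (dout * c["zh"]).sum(axis=0)
        grads["beta"] = dout.sum(axis=0)
        dzh = dout * p["gamma"]
        inv = 1.0 / np.sqrt(c["var"] + self._LN_EPS)
        dz = inv * (dzh - dzh.mean(axis=1, keepdims=True)
                    - c["zh"] * (dzh * c["zh"]).mean(axis=1, keepdims=True))
        da = np.einsum("nd,ntd->nt", dz, c["v"])
        dv = c["a"][:, :, None] * dz[:, None, :]
        dscores = c["a"] * (da - (c["a"] * da).sum(axis=1, keepdims=True))
        d = p["wq"].shape[1]
        dq = np.einsum("nt,ntd->nd", dscores, c["k"]) / np.sqrt(d)
        dk = dscores[:, :, None] * c["q"][:, None, :] / np.sqrt(d)
        dqpre = dq * (1.0 - c["q"] ** 2)
        grads["wq"] = c["s"].T @ dqpre
        grads["bq"] = dqpre.sum(axis=0)
        dkpre = dk * (1.0 - c["k"] ** 2)
        grads["wk"] = np.einsum("nt,ntd->td", c["tok"], dkpre)
        grads["ck"] = dkpre.sum(axis=0)
        grads["wv"] = np.einsum("nt,ntd->td", c["tok"], dv)
        grads["cv"] = dv.sum(axis=0)
        for name in ("wq", "wk", "wv", "u"):
            loss += l2 * float(np.sum(p[name] ** 2))
            grads[name] = grads[name] + 2.0 * l2 * p[name]
        return loss, grads

    def fit(self, x: np.ndarray, y: np.ndarray, config: AMPTrainConfig,
            pos_weight: float, rng: np.random.Generator) -> list[float]:
        """Full-batch Adam on the weighted cross-entropy; returns the loss
        trace.  Scaling parameters must already be set."""
        xs = self._scale(x)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        vv = {k: np.zeros_like(v) for k, v in self.params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        trace = []
        for step in range(1, config.epochs + 1):
            mask = None
            if config.dropout_rate > 0:
                keep = 1.0 - config.dropout_rate
                mask = (rng.random((x.shape[0], config.latent_dim)) < keep) / keep
            loss, grads = self._loss_grads(xs, y, pos_weight,
                                           config.l2_strength, mask)
            trace.append(loss)
            for kname, gval in grads.items():
                m[kname] = b1 * m[kname] + (1 - b1) * gval
                vv[kname] = b2 * vv[kname] + (1 - b2) * gval ** 2
                mh = m[kname] / (1 - b1 ** step)
                vh = vv[kname] / (1 - b2 ** step)
                self.params[kname] = self.params[kname] - \
                    config.learning_rate * mh / (np.sqrt(vh) + eps)
        return trace


def _balanced_accuracy(labels: np.ndarray, preds: np.ndarray) -> float:
    pos, neg = labels == 1, labels == 0
    sens = preds[pos].mean() if pos.any() else 0.0
    spec = (1 - preds[neg]).mean() if neg.any() else 0.0
    return 0.5 * (sens + spec)


def train_amp(corpus: pd.DataFrame, config: AMPTrainConfig | None = None,
              label_col: str = "label") -> tuple[AMPModel, pd.DataFrame, pd.DataFrame]:
    """Stratified split + k-fold model selection for the AMP.

    The 80/20 split preserves the natural class ratio; within the training
    portion, stratified ``k_folds``-fold cross-validation trains one model
    per fold and the model with the best validation balanced accuracy is
    returned together with the per-fold metric table and the untouched test
    split.
    """
    config = config or AMPTrainConfig()
    y_all = corpus[label_col].to_numpy(dtype=int)
    n_pos = int(y_all.sum())
    if n_pos < config.k_folds:
        raise ValueError("fewer positives than folds")
    train_df, test_df = train_test_split(
        corpus, train_size=config.split_fraction, stratify=y_all,
        random_state=config.seed)
    x = train_df[list(AMP_FEATURES)].to_numpy(dtype=float)
    y = train_df[label_col].to_numpy(dtype=int)
    pos_w = positive_class_weight(int((y == 0).sum()), int(y.sum()), config.epsilon)
    fmin, fmax = x.min(axis=0), x.max(axis=0)

    skf = StratifiedKFold(n_splits=config.k_folds, shuffle=True,
                          random_state=config.seed)
    fold_rows = []
    best: tuple[float, AMPModel] | None = None
    for fold, (tr_idx, va_idx) in enumerate(skf.split(x, y)):
        rng = np.random.default_rng(config.seed + 1000 * fold)
        model = AMPModel(AMPModel.init_params(rng, config.latent_dim),
                         feature_min=fmin, feature_max=fmax,
                         decision_threshold=config.decision_threshold)
        model.fit(x[tr_idx], y[tr_idx], config, pos_w, rng)
        _, pred = model.predict(x[va_idx])
        bal = _balanced_accuracy(y[va_idx], pred.astype(float))
        sens = pred[y[va_idx] == 1].mean() if (y[va_idx] == 1).any() else 0.0
        fold_rows.append({"fold": fold, "balanced_accuracy": bal,
                          "sensitivity": float(sens),
                          "val_positives": int(y[va_idx].sum())})
        if best is None or bal > best[0]:
            best = (bal, model)
    fold_metrics = pd.DataFrame(fold_rows)
    model = best[1]
    model.metadata.update({
        "positive_class_weight": pos_w, "epsilon": config.epsilon,
        "k_folds": config.k_folds, "seed": config.seed,
        "latent_dim": config.latent_dim,
        "best_fold_balanced_accuracy": best[0],
    })
    return model, fold_metrics, test_df.reset_index(drop=True)
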