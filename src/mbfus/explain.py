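"""Shapley-value attribution for trained precursor classifiers.

Feature contributions are interventional Shapley values: the value of a
coalition S is the model's expected probability when the features in S come
from the explained sample and the rest are drawn from a background set.  Two
estimators are provided:

* :func:`exact_shap_values` — full 2^d coalition enumeration (d <= ~15),
  exact up to the background average; the oracle for the sampler.
* :func:`shap_values` — permutation sampling (Castro-style): for each of
  ``n_permutations`` random feature orderings, marginal contributions are
  accumulated as features switch from background to sample values.

Both satisfy the efficiency property: per-sample contributions sum (with the
baseline, i.e. the expected model output over the background) to the model
output for that sample — exactly for enumeration, to Monte-Carlo tolerance
for the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "AttributionResult",
    "exact_shap_values",
    "shap_values",
    "global_importance",
    "partial_dependence",
]

ModelFn = Callable[[np.ndarray], np.ndarray]  # (n, d) -> (n,) probabilities


@dataclass
class AttributionResult:
    """Per-sample, per-feature Shapley contributions plus the baseline
    (expected model output over the background set)."""

    shap_values: np.ndarray          # (n_samples, d)
    baseline_value: float
    feature_names: tuple[str, ...]
    samples: np.ndarray              # the explained rows, (n_samples, d)
    model_output: np.ndarray         # f(x) per explained sample

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.shap_values, columns=list(self.feature_names))


def _as_matrix(x: np.ndarray | pd.DataFrame,
               feature_names: Sequence[str] | None) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(x, pd.DataFrame):
        names = tuple(x.columns) if feature_names is None else tuple(feature_names)
        return x[list(names)].to_numpy(dtype=float), names
    arr = np.atleast_2d(np.asarray(x, dtype=float))
    names = tuple(feature_names) if feature_names is not None \
        else tuple(f"f{i}" for i in range(arr.shape[1]))
    return arr, names


def _coalition_value(model: ModelFn, x: np.ndarray, background: np.ndarray,
                     members: Sequence[int]) -> float:
    """E_b[f(x_S, b_rest)] over the background rows."""
    rows = background.copy()
    rows[:, list(members)] = x[list(members)]
    return float(np.mean(model(rows)))


def exact_shap_values(model: ModelFn, samples: np.ndarray | pd.DataFrame,
                      background: np.ndarray | pd.DataFrame,
                      feature_names: Sequence[str] | None = None) -> AttributionResult:
    """Exact Shapley values by enumerating all 2^d coalitions."""
    x_mat, names = _as_matrix(samples, feature_names)
    bg, _ = _as_matrix(background, names if isinstance(background, pd.DataFrame) else None)
    if bg.shape[0] == 0:
        raise ValueError("background set must be non-empty")
    d = x_mat.shape[1]
    if d > 15:
        raise ValueError(f"exact enumeration limited to d <= 15, got {d}")
    from math import factorial
    weights = {s: factorial(s) * factorial(d - s - 1) / factorial(d) for s in range(d)}

    baseline = float(np.mean(model(bg)))
    phi = np.zeros_like(x_mat)
    outputs = np.empty(x_mat.shape[0])
    all_feats = range(d)
    for si, x in enumerate(x_mat):
        values = {}
        for size in range(d + 1):
            for coal in combinations(all_feats, size):
                values[coal] = _coalition_value(model, x, bg, coal)
        outputs[si] = values[tuple(all_feats)]
        for i in all_feats:
            rest = [j for j in all_feats if j != i]
            for size in range(d):
                for coal in combinations(rest, size):
                    with_i = tuple(sorted(coal + (i,)))
                    phi[si, i] += weights[size] * (values[with_i] - values[coal])
    return AttributionResult(shap_values=phi, baseline_value=baseline,
                             feature_names=names, samples=x_mat, model_output=outputs)


def shap_values(model: ModelFn, samples: np.ndarray | pd.DataFrame,
                background: np.ndarray | pd.DataFrame,
                n_permutations: int = 200, seed: int = 0,
                feature_names: Sequence[str] | None = None) -> AttributionResult:
    """Sampling-based Shapley estimates (random feature permutations).

    For each permutation, features flip one by one from background to sample
    values; the induced change in the background-averaged model output is the
    marginal contribution of the flipped feature.  Deterministic under
    ``seed``; the estimate converges to :func:`exact_shap_values` as
    ``n_permutations`` grows.
    """
    x_mat, names = _as_matrix(samples, feature_names)
    bg, _ = _as_matrix(background, names if isinstance(background, pd.DataFrame) else None)
    if bg.shape[0] == 0:
        raise ValueError("background set must be non-empty")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    d = x_mat.shape[1]
    baseline = float(np.mean(model(bg)))
    phi = np.zeros_like(x_mat)
    outputs = np.empty(x_mat.shape[0])
    for si, x in enumerate(x_mat):
        outputs[si] = _coalition_value(model, x, bg, tuple(range(d)))
        acc = np.zeros(d)
        for _ in range(n_permutations):
            order = rng.permutation(d)
            rows = bg.copy()
            prev = float(np.mean(model(rows)))
            for i in order:
                rows[:, i] = x[i]
                cur = float(np.mean(model(rows)))
                acc[i] += cur - prev
                prev = cur
        phi[si] = acc / n_permutations
    return AttributionResult(shap_values=phi, baseline_value=baseline,
                             feature_names=names, samples=x_mat, model_output=outputs)


def global_importance(result: AttributionResult) -> pd.DataFrame:
    """Mean absolute Shapley value per feature, ranked descending (ties keep
    feature order)."""
    if result.shap_values.size == 0:
        raise ValueError("empty attribution result")
    imp = np.abs(result.shap_values).mean(axis=0)
    df = pd.DataFrame({"feature": result.feature_names, "mean_abs_shap": imp})
    return df.sort_values("mean_abs_shap", ascending=False,
                          kind="stable").reset_index(drop=True)


def partial_dependence(result: AttributionResult, feature: str,
                       ) -> tuple[pd.DataFrame, float, bool]:
    """(featureValue, shap) scatter for one feature plus a Spearman rank
    correlation; returns (pairs, correlation, defined) with correlation 0 and
    ``defined=False`` when either column is constant."""
    if feature not in result.feature_names:
        raise KeyError(f"unknown feature {feature!r}")
    idx = result.feature_names.index(feature)
    pairs = pd.DataFrame({
        "value": result.samples[:, idx],
        "shap": result.shap_values[:, idx],
    })
    if pairs["value"].nunique() < 2 or pairs["shap"].nunique() < 2:
        return pairs, 0.0, False
    rho = spearmanr(pairs["value"], pairs["shap"]).statistic
    if not np.isfinite(rho):
        return pairs, 0.0, False
    return pairs, float(rho), True
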