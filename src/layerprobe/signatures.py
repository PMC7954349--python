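"""Behavioral performance signatures and their prediction from layer features.

A *behavioral performance signature* is the pattern of percent-correct values
across a task's conditions (object transformations, stimuli, or
target-distractor pairs).  For each layer, a partial-least-squares (PLS)
regression maps the layer's feature components to the logit-transformed
signature; prediction quality is the percentage of variance explained,
``100 * corr(y_pred, y_obs)^2`` on the logit scale, evaluated on an
independent generalization phase when one exists and by leave-one-out
cross-validation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.cross_decomposition import PLSRegression

__all__ = [
    "PerformanceSignature",
    "SignatureModel",
    "logit_transform",
    "inverse_logit",
    "pair_difference_features",
    "fit_signature_map",
    "predict_signature",
    "explained_variance",
    "loocv_explained_variance",
]


@dataclass
class PerformanceSignature:
    """Per-condition percent correct with trial counts and partition roles."""

    conditions: list  # condition keys (stimulus ids or (target, distractor) pairs)
    pct_correct: np.ndarray  # 0-100
    n_trials: np.ndarray
    partition: np.ndarray  # 'train' / 'test' per condition

    def __post_init__(self):
        self.pct_correct = np.asarray(self.pct_correct, dtype=np.float64)
        self.n_trials = np.asarray(self.n_trials)
        self.partition = np.asarray(self.partition)
        if np.any(self.pct_correct < 0) or np.any(self.pct_correct > 100):
            raise ValueError("percent correct must lie in [0, 100]")

    @property
    def logits(self) -> np.ndarray:
        return logit_transform(self.pct_correct / 100.0, self.n_trials)

    def mask(self, partition: str) -> np.ndarray:
        return self.partition == partition

    def to_frame(self) -> pd.DataFrame:
        cond = self.conditions
        tgt = [c[0] if isinstance(c, tuple) else c for c in cond]
        dst = [c[1] if isinstance(c, tuple) else "" for c in cond]
        return pd.DataFrame({
            "condition": [str(c) for c in cond], "target_id": tgt, "distractor_id": dst,
            "pct_correct": self.pct_correct, "n_trials": self.n_trials,
            "partition": self.partition,
        })


@dataclass
class SignatureModel:
    """Linear map (via PLS components) from feature components to logit
    performance."""

    coef: np.ndarray
    intercept: float
    n_components: int
    layer: str = ""


def logit_transform(p, n_trials) -> np.ndarray:
    """log-odds of a proportion, with saturation clipped by the half-a-count
    rule ``eps = 0.5 / n_trials`` so that 0% and 100% stay finite.

    ``n_trials = inf`` (or 0, the "analytic" sentinel) disables clipping, in
    which case p must lie strictly inside (0, 1).
    """
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("proportions must lie in [0, 1]")
    n = np.asarray(n_trials, dtype=np.float64)
    n = np.where(n == 0, np.inf, n)  # sentinel: exact proportions
    with np.errstate(divide="ignore"):
        eps = np.where(np.isinf(n), 0.0, 0.5 / n)
    clipped = np.clip(p, eps, 1.0 - eps)
    if np.any((clipped <= 0) | (clipped >= 1)):
        raise ValueError("saturated proportion with no trial count to clip by")
    return np.log(clipped / (1.0 - clipped))


def inverse_logit(x) -> np.ndarray:
    """Inverse of :func:`logit_transform` on the clipped range."""
    x = np.asarray(x, dtype=np.float64)
    return 1.0 / (1.0 + np.exp(-x))


def pair_difference_features(feature_matrix, pairing) -> np.ndarray:
    """Predictor rows for 2AFC conditions: target feature row minus distractor
    feature row, one row per (target id, distractor id) pair."""
    targets = feature_matrix.rows_for([t for t, _ in pairing])
    distractors = feature_matrix.rows_for([d for _, d in pairing])
    return targets - distractors


def fit_signature_map(features: np.ndarray, logits: np.ndarray, n_components: int,
                      layer: str = "") -> SignatureModel:
    """PLS regression of logit performance onto feature components.

    Predictors and response are centered; predictors are not rescaled (they
    arrive standardized from the feature pipeline).  Three components are the
    convention for two-object transformation tasks, ten otherwise.  Fitting
    must only ever see training-phase conditions.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(logits, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features and logits disagree on the number of conditions")
    if not np.all(np.isfinite(X)):
        raise ValueError("predictors contain non-finite values")
    n = X.shape[0]
    if n_components >= n:
        raise ValueError(f"n_components ({n_components}) must be < n conditions ({n})")
    if np.ptp(y) == 0:  # constant response: PLS degenerates; fit is exact
        return SignatureModel(coef=np.zeros(X.shape[1]), intercept=float(y[0]),
                              n_components=n_components, layer=layer)
    k = min(n_components, X.shape[1], n - 1)
    pls = PLSRegression(n_components=k, scale=False)
    pls.fit(X, y)
    coef = pls.coef_.ravel()
    intercept = float(y.mean() - X.mean(axis=0) @ coef)
    return SignatureModel(coef=coef, intercept=intercept, n_components=k, layer=layer)


def predict_signature(model: SignatureModel, features: np.ndarray) -> np.ndarray:
    """Predicted logit performance per condition (use :func:`inverse_logit`
    for the percent scale)."""
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.coef.shape[0]:
        raise ValueError(
            f"features have {X.shape[1] if X.ndim == 2 else '?'} columns; "
            f"model expects {model.coef.shape[0]}"
        )
    return X @ model.coef + model.intercept


def explained_variance(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Percent variance explained: ``100 * corr(y_pred, y_obs)^2`` (logit
    scale).  Undefined (error) for constant vectors."""
    predicted = np.asarray(predicted, dtype=np.float64)
    observed = np.asarray(observed, dtype=np.float64)
    if predicted.size != observed.size or predicted.size < 3:
        raise ValueError("need >= 3 paired conditions")
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        raise ValueError("explained variance undefined for a constant vector")
    r = pearsonr(predicted, observed).statistic
    return float(100.0 * r * r)


def loocv_explained_variance(features: np.ndarray, logits: np.ndarray,
                             n_components: int, layer: str = "") -> float:
    """Leave-one-out cross-validated explained variance: each condition is
    predicted by a model fit on all the others, and the variance explained is
    computed over the stacked held-out predictions.

    Used when the experiment has no independent generalization phase.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(logits, dtype=np.float64)
    n = X.shape[0]
    if n < n_components + 2:
        raise ValueError(
            f"leave-one-out needs >= n_components + 2 conditions ({n_components + 2}), got {n}"
        )
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        model = fit_signature_map(X[keep], y[keep], n_components, layer=layer)
        preds[i] = predict_signature(model, X[i : i + 1])[0]
    return explained_variance(preds, y)
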