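"""Linear decoders over layer features and ideal-observer task scoring.

One linear support-vector-machine decoder is trained per layer on the
experiment's *training* stimuli, then generalization is scored on held-out
stimuli under two task rules:

* **yes-no** — one stimulus per trial; correct iff the stimulus falls on its
  true side of the decision boundary.
* **2AFC** — a target and a distractor per trial; correct iff the target's
  decision value exceeds the distractor's (equivalently: both on their
  correct sides, or both target-side with the target farther from the
  boundary, or both distractor-side with the target closer to it).

Uncertainty is summarized with leave-one-out jackknife standard errors along
an analysis-specific resampling axis (transformation cells, stimuli,
target-distractor pairs, or neural units — always an explicit choice).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .features import (
    FeatureMatrix,
    apply_feature_pipeline,
    extract_activations,
    fit_feature_pipeline,
    pixel_features,
    temporal_average,
)

__all__ = [
    "Decoder",
    "TaskResult",
    "train_decoder",
    "score_yes_no",
    "score_2afc",
    "layer_sweep",
    "jackknife_ci",
]


@dataclass
class Decoder:
    """Linear decision function f(x) = w.x + b; positive f means the target
    (positive-class) side."""

    w: np.ndarray
    b: float
    positive_label: object
    layer: str = ""

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return X @ self.w + self.b


@dataclass
class TaskResult:
    """Per-trial correctness (1 / 0.5 / 0) with grouping labels."""

    correctness: np.ndarray
    groups: pd.DataFrame  # one row per trial: ids plus condition labels
    partition: str = ""
    layer: str = ""

    @property
    def accuracy(self) -> float:
        """Percent correct = mean correctness x 100."""
        return float(np.mean(self.correctness) * 100.0)

    def accuracy_by(self, column: str) -> pd.Series:
        df = self.groups.copy()
        df["correct"] = self.correctness
        return df.groupby(column)["correct"].mean() * 100.0


def _hinge_objective(params, X, y, lam):
    w, b = params[:-1], params[-1]
    margins = 1.0 - y * (X @ w + b)
    active = margins > 0
    loss = margins[active].sum() / X.shape[0] + 0.5 * lam * (w @ w)
    grad_w = -(X[active].T @ y[active]) / X.shape[0] + lam * w
    grad_b = -y[active].sum() / X.shape[0]
    return loss, np.append(grad_w, grad_b)


def train_decoder(
    features: np.ndarray,
    labels: Sequence,
    positive_label=None,
    lam: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    layer: str = "",
) -> Decoder:
    """Train an L2-regularized hinge-loss (soft-margin SVM) linear decoder.

    Minimizes ``mean_i hinge(y_i f(x_i)) + (lam/2) ||w||^2`` with L-BFGS from a
    zero start — deterministic given the inputs.  ``lam`` defaults to
    ``1 / n_train``, the cited linear-classifier implementation's default
    regularization.  The bias is unregularized.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain NaN or infinite values")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    if positive_label is None:
        positive_label = classes[1]
    elif positive_label not in classes:
        raise ValueError(f"positive_label {positive_label!r} not among {classes.tolist()}")
    y = np.where(labels == positive_label, 1.0, -1.0)
    if lam is None:
        lam = 1.0 / X.shape[0]
    x0 = np.zeros(X.shape[1] + 1)
    res = minimize(
        _hinge_objective,
        x0,
        args=(X, y, lam),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": tol},
    )
    return Decoder(w=res.x[:-1], b=float(res.x[-1]), positive_label=positive_label, layer=layer)


def score_yes_no(decoder: Decoder, features: np.ndarray, labels: Sequence,
                 groups: pd.DataFrame | None = None, partition: str = "") -> TaskResult:
    """Score each stimulus by the side of the decision boundary it falls on.

    Correct = 1 when sign(f(x)) matches the label side, 0 otherwise; an exact
    tie f(x) = 0 is credited 0.5.
    """
    labels = np.asarray(labels)
    f = decoder.decision_values(features)
    truth = np.where(labels == decoder.positive_label, 1.0, -1.0)
    correctness = np.where(np.sign(f) == truth, 1.0, 0.0)
    correctness[f == 0.0] = 0.5
    if groups is None:
        groups = pd.DataFrame({"label": labels})
    return TaskResult(correctness=correctness, groups=groups.reset_index(drop=True),
                      partition=partition, layer=decoder.layer)


def score_2afc(decoder: Decoder, target_features: np.ndarray, distractor_features: np.ndarray,
               groups: pd.DataFrame | None = None, partition: str = "") -> TaskResult:
    """Score target/distractor trials: correct iff f(target) > f(distractor)
    (ties credited 0.5).

    This single comparison reproduces the three enumerated cases: (a) both
    stimuli on their correct sides; (b) both target-side with the target
    farther from the boundary; (c) both distractor-side with the target
    closer to it.
    """
    ft = decoder.decision_values(target_features)
    fd = decoder.decision_values(distractor_features)
    if ft.shape != fd.shape:
        raise ValueError("target and distractor trial counts differ")
    correctness = np.where(ft > fd, 1.0, 0.0)
    correctness[ft == fd] = 0.5
    if groups is None:
        groups = pd.DataFrame(index=range(ft.size))
    return TaskResult(correctness=correctness, groups=groups.reset_index(drop=True),
                      partition=partition, layer=decoder.layer)


# ---------------------------------------------------------------------------
# per-layer sweep


def layer_sweep(
    extractor,
    stimulus_set,
    label_column: str,
    task: str = "yes_no",
    positive_label=None,
    pairing: Sequence[tuple[str, str]] | None = None,
    include_pixels: bool = True,
    layers: Sequence[str] | None = None,
    frames_per_bin: int = 16,
) -> pd.DataFrame:
    """Fit pipeline + decoder per layer (training stimuli only) and score the
    train and test partitions; includes the pixel baseline as layer 0.

    Returns a tidy frame ``layer, partition, accuracy, n`` in forward layer
    order.  For video sets, items must already be :class:`FrameBin` objects;
    frame-based extractors are averaged over time within each bin before the
    pipeline.  ``pairing`` (2AFC) lists (target id, distractor id) per trial.
    """
    items = list(stimulus_set)
    ids = [it.id for it in items]
    roles = np.array([it.role for it in items])
    labels = np.array([it.labels[label_column] for it in items])
    train_mask = roles == "train"
    if train_mask.sum() < 2:
        raise ValueError("layer sweep needs >= 2 training stimuli")

    layer_names = [s.name for s in extractor.layers]
    if layers is not None:
        layer_names = [l for l in layer_names if l in set(layers)]

    matrices: dict[str, FeatureMatrix] = {}
    if include_pixels:
        matrices["pixels"] = pixel_features(items, [i for i, m in zip(ids, train_mask) if m])
    raw_all = _extract_rows(extractor, items, frames_per_bin)
    for layer in layer_names:
        raw = raw_all[layer]
        pipe = fit_feature_pipeline(raw[train_mask], layer=layer)
        matrices[layer] = FeatureMatrix(apply_feature_pipeline(pipe, raw), ids, layer)

    records = []
    for layer, fm in matrices.items():
        Xtr, ytr = fm.data[train_mask], labels[train_mask]
        dec = train_decoder(Xtr, ytr, positive_label=positive_label, layer=layer)
        for part, mask in (("train", train_mask), ("test", ~train_mask)):
            if mask.sum() == 0:
                continue
            if task == "yes_no":
                res = score_yes_no(dec, fm.data[mask], labels[mask],
                                   groups=pd.DataFrame({"id": np.array(ids)[mask]}),
                                   partition=part)
            elif task == "2afc":
                part_ids = {i for i, m in zip(ids, mask) if m}
                pairs = [(t, d) for t, d in (pairing or []) if t in part_ids and d in part_ids]
                if not pairs:
                    continue
                res = score_2afc(dec, fm.rows_for([t for t, _ in pairs]),
                                 fm.rows_for([d for _, d in pairs]),
                                 groups=pd.DataFrame(pairs, columns=["target", "distractor"]),
                                 partition=part)
            else:
                raise ValueError(f"unknown task {task!r}")
            records.append({"layer": layer, "partition": part,
                            "accuracy": res.accuracy, "n": int(res.correctness.size)})
    return pd.DataFrame.from_records(records)


def _extract_rows(extractor, items, frames_per_bin: int) -> dict[str, np.ndarray]:
    """Per-item feature rows for every layer (videos: time-averaged per bin)."""
    per_frame_counts = []
    batches = []
    for it in items:
        px = it.pixels
        if px.ndim == 4 and not extractor.temporal:
            batches.append(px)
            per_frame_counts.append(px.shape[0])
        else:
            batches.append(px[None] if px.ndim == 3 else px[None])
            per_frame_counts.append(1)
    batch = np.concatenate(batches, axis=0)
    out: dict[str, np.ndarray] = {}
    acts_all = (extractor.forward_all(batch) if hasattr(extractor, "forward_all")
                else {s.name: extractor.extract(s.name, batch) for s in extractor.layers})
    for layer, acts in acts_all.items():
        if all(c == 1 for c in per_frame_counts):
            out[layer] = acts
        else:
            rows, pos = [], 0
            for c in per_frame_counts:
                chunk = acts[pos : pos + c]
                rows.append(chunk.mean(axis=0) if c > 1 else chunk[0])
                pos += c
            out[layer] = np.stack(rows)
    return out


# ---------------------------------------------------------------------------
# jackknife


def jackknife_ci(values: np.ndarray, statistic: Callable[[np.ndarray], float] = np.mean,
                 z: float = 1.96) -> tuple[float, float, tuple[float, float]]:
    """Leave-one-out jackknife estimate, standard error, and 95% CI.

    ``SE = sqrt(((n-1)/n) * sum_i (theta_{-i} - mean(theta_{-i}))^2)`` over the
    n leave-one-out replicates; the CI is ``estimate +/- z * SE``.  The
    resampling axis (what one "value" is) must be chosen by the analysis.
    """
    v = np.asarray(values, dtype=np.float64)
    n = v.size
    if n < 2:
        raise ValueError("jackknife needs n >= 2 values")
    est = float(statistic(v))
    loo = np.array([statistic(np.delete(v, i)) for i in range(n)])
    se = float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))
    return est, se, (est - z * se, est + z * se)
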