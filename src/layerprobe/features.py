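"""Layer registries, activation extraction, and the train-fitted feature pipeline.

Every representational analysis in this package operates on per-layer feature
matrices: unit activations taken *before* the rectifying nonlinearity,
averaged over time within 16-frame bins for videos, then standardized and
projected to principal-component space.  Standardization and PCA parameters
are always fit on the training stimuli only and applied unchanged to test
stimuli — the single most important discipline of the whole framework.

The registries describe the published architectures (AlexNet, VGG16,
VGG11-C3D, with their eight-block layer nomenclature).  Because pretrained
weights are an optional external input, a small self-contained convolutional
network ("tinynet", Glorot-initialized, zero bias, pure numpy) is provided so
that every analysis runs end-to-end without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import h5py
import numpy as np

__all__ = [
    "LayerSpec",
    "FeatureExtractor",
    "TinyNetExtractor",
    "FeaturePipeline",
    "FeatureMatrix",
    "RegistryError",
    "list_layers",
    "random_init_network",
    "extract_activations",
    "temporal_average",
    "fit_feature_pipeline",
    "apply_feature_pipeline",
    "pixel_features",
    "save_pipeline",
    "load_pipeline",
    "save_features",
    "load_features",
]


class RegistryError(KeyError):
    """Unknown architecture or layer."""


@dataclass(frozen=True)
class LayerSpec:
    """One extractable layer: name, layer block (1-8), kind, forward order."""

    name: str
    block: int
    kind: str  # conv | norm | pool | fc
    index: int
    rf_px: int | None = None


def _specs(entries):
    return tuple(LayerSpec(name, block, kind, i, rf) for i, (name, block, kind, rf) in enumerate(entries))


_REGISTRY: dict[str, tuple[LayerSpec, ...]] = {
    # The eight-block nomenclature of the published architectures.
    "alexnet": _specs([
        ("conv1", 1, "conv", 11), ("norm1", 1, "norm", None), ("pool1", 1, "pool", 19),
        ("conv2", 2, "conv", 51), ("norm2", 2, "norm", None), ("pool2", 2, "pool", None),
        ("conv3", 3, "conv", None), ("conv4", 4, "conv", None),
        ("conv5", 5, "conv", None), ("pool5", 5, "pool", None),
        ("fc6", 6, "fc", None), ("fc7", 7, "fc", None), ("fc8", 8, "fc", None),
    ]),
    "vgg16": _specs([
        ("conv1a", 1, "conv", None), ("conv1b", 1, "conv", None), ("pool1", 1, "pool", None),
        ("conv2a", 2, "conv", None), ("conv2b", 2, "conv", None), ("pool2", 2, "pool", None),
        ("conv3a", 3, "conv", None), ("conv3b", 3, "conv", None), ("conv3c", 3, "conv", None),
        ("pool3", 3, "pool", None),
        ("conv4a", 4, "conv", None), ("conv4b", 4, "conv", None), ("conv4c", 4, "conv", None),
        ("pool4", 4, "pool", None),
        ("conv5a", 5, "conv", None), ("conv5b", 5, "conv", None), ("conv5c", 5, "conv", None),
        ("pool5", 5, "pool", None),
        ("fc6", 6, "fc", None), ("fc7", 7, "fc", None), ("fc8", 8, "fc", None),
    ]),
    "vgg11-c3d": _specs([
        ("conv1a", 1, "conv", None), ("pool1", 1, "pool", None),
        ("conv2a", 2, "conv", None), ("pool2", 2, "pool", None),
        ("conv3a", 3, "conv", None), ("conv3b", 3, "conv", None), ("pool3", 3, "pool", None),
        ("conv4a", 4, "conv", None), ("conv4b", 4, "conv", None), ("pool4", 4, "pool", None),
        ("conv5a", 5, "conv", None), ("conv5b", 5, "conv", None), ("pool5", 5, "pool", None),
        ("fc6", 6, "fc", None), ("fc7", 7, "fc", None), ("fc8", 8, "fc", None),
    ]),
    "tinynet": _specs([
        ("conv1", 1, "conv", 5), ("pool1", 1, "pool", 7),
        ("conv2", 2, "conv", None), ("pool2", 2, "pool", None),
        ("conv3", 3, "conv", None), ("pool3", 3, "pool", None),
        ("conv4", 4, "conv", None), ("pool4", 4, "pool", None),
        ("fc5", 5, "fc", None), ("fc6", 6, "fc", None),
    ]),
}


def list_layers(architecture: str) -> list[LayerSpec]:
    """All extractable layers of an architecture in forward order, with their
    layer-block assignment."""
    try:
        return list(_REGISTRY[architecture])
    except KeyError:
        raise RegistryError(
            f"unknown architecture {architecture!r}; known: {sorted(_REGISTRY)}"
        ) from None


@runtime_checkable
class FeatureExtractor(Protocol):
    """Contract for a layered feature extractor.

    ``extract(layer, batch)`` maps a pixel batch (N, H, W, C) to a pre-ReLU
    activation matrix with one row per input.  ``temporal`` extractors consume
    16-frame bins directly (N, 16, H, W, C).
    """

    architecture: str
    input_size: int
    channels: int
    temporal: bool

    @property
    def layers(self) -> list[LayerSpec]: ...

    def extract(self, layer: str, batch: np.ndarray) -> np.ndarray: ...


# ---------------------------------------------------------------------------
# tinynet: a small, deterministic numpy CNN


def _glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    # x: (N, H, W, C) -> (N, Ho*Wo, k*k*C)
    n, h, w, c = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    ho = (x.shape[1] - k) // stride + 1
    wo = (x.shape[2] - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, ho, wo, k, k, c),
        strides=(s0, s1 * stride, s2 * stride, s1, s2, s3),
        writeable=False,
    )
    return windows.reshape(n, ho * wo, k * k * c), ho, wo


def _maxpool(x: np.ndarray, k: int = 2) -> np.ndarray:
    n, h, w, c = x.shape
    h2, w2 = h // k, w // k
    return x[:, : h2 * k, : w2 * k].reshape(n, h2, k, w2, k, c).max(axis=(2, 4))


class TinyNetExtractor:
    """Built-in test network: four conv/max-pool stages plus two fully
    connected layers on a 64-px RGB input.

    Weights are Glorot-uniform with zero biases and are a pure function of the
    seed; convolutional and fully connected activations are recorded before
    the ReLU, pooling layers at their direct output.  Frame-based (videos are
    extracted per frame and temporally averaged downstream).
    """

    architecture = "tinynet"
    input_size = 64
    channels = 3
    temporal = False

    _conv_defs = (  # (name, k, stride, pad, out_channels_base)
        ("conv1", 5, 2, 2, 8),
        ("conv2", 3, 1, 1, 16),
        ("conv3", 3, 1, 1, 16),
        ("conv4", 3, 1, 1, 32),
    )

    def __init__(self, seed: int = 0, width: int = 1):
        self.seed = int(seed)
        self.width = int(width)
        rng = np.random.default_rng(self.seed)
        self.weights: dict[str, np.ndarray] = {}
        self.biases: dict[str, np.ndarray] = {}
        in_c = self.channels
        for name, k, _, _, base in self._conv_defs:
            out_c = base * self.width
            fan_in, fan_out = k * k * in_c, k * k * out_c
            self.weights[name] = _glorot_uniform(rng, (k * k * in_c, out_c), fan_in, fan_out)
            self.biases[name] = np.zeros(out_c)
            in_c = out_c
        flat = 2 * 2 * 32 * self.width  # spatial 64 -> 32 -> 16 -> 8 -> 4 -> 2
        for name, out_d in (("fc5", 64 * self.width), ("fc6", 16 * self.width)):
            self.weights[name] = _glorot_uniform(rng, (flat, out_d), flat, out_d)
            self.biases[name] = np.zeros(out_d)
            flat = out_d

    @property
    def layers(self) -> list[LayerSpec]:
        return list_layers("tinynet")

    def forward_all(self, batch: np.ndarray, chunk: int = 128) -> dict[str, np.ndarray]:
        """Forward pass returning every layer's pre-ReLU (conv/fc) or direct
        (pool) activation, flattened to one row per input.

        Large batches are processed in chunks to bound the im2col workspace.
        """
        x = np.asarray(batch, dtype=np.float64)
        if x.ndim != 4 or x.shape[1:] != (self.input_size, self.input_size, self.channels):
            raise ValueError(
                f"tinynet expects (N, {self.input_size}, {self.input_size}, {self.channels}), "
                f"got {x.shape}"
            )
        if x.shape[0] > chunk:
            parts = [self._forward_chunk(x[i : i + chunk]) for i in range(0, x.shape[0], chunk)]
            return {k: np.concatenate([p[k] for p in parts], axis=0) for k in parts[0]}
        return self._forward_chunk(x)

    def _forward_chunk(self, x: np.ndarray) -> dict[str, np.ndarray]:
        acts: dict[str, np.ndarray] = {}
        n = x.shape[0]
        for name, k, stride, pad, _ in self._conv_defs:
            cols, ho, wo = _im2col(x, k, stride, pad)
            pre = cols @ self.weights[name] + self.biases[name]
            pre = pre.reshape(n, ho, wo, -1)
            acts[name] = pre.reshape(n, -1)
            x = _maxpool(np.maximum(pre, 0.0), 2)
            acts[name.replace("conv", "pool")] = x.reshape(n, -1)
        h = x.reshape(n, -1)
        for name in ("fc5", "fc6"):
            pre = h @ self.weights[name] + self.biases[name]
            acts[name] = pre
            h = np.maximum(pre, 0.0)
        return acts

    def extract(self, layer: str, batch: np.ndarray) -> np.ndarray:
        names = {s.name for s in self.layers}
        if layer not in names:
            raise RegistryError(f"tinynet has no layer {layer!r}; known: {sorted(names)}")
        return self.forward_all(batch)[layer]


def random_init_network(architecture: str, seed: int, width: int = 1) -> TinyNetExtractor:
    """Instantiate a randomly initialized extractor (Glorot-uniform weights,
    all biases exactly zero, deterministic given the seed).

    Only the built-in test architecture has a bundled forward implementation;
    the published architectures are registry metadata whose weights arrive as
    external inputs.
    """
    list_layers(architecture)  # raises RegistryError for unknown ids
    if architecture != "tinynet":
        raise NotImplementedError(
            f"no bundled forward implementation for {architecture!r}; "
            "supply an external FeatureExtractor for pretrained architectures"
        )
    return TinyNetExtractor(seed=seed, width=width)


# ---------------------------------------------------------------------------
# extraction helpers


def extract_activations(extractor: FeatureExtractor, layer: str, stimuli) -> np.ndarray:
    """Raw pre-ReLU activation matrix for a stimulus set (or pixel batch).

    Images: one row per item.  Videos with a frame-based extractor: one row
    per frame (temporally average afterwards).  Temporal extractors receive
    16-frame bins whole.
    """
    if isinstance(stimuli, np.ndarray):
        return extractor.extract(layer, stimuli)
    batches = []
    for it in stimuli:
        px = it.pixels
        if px.ndim == 4 and not extractor.temporal:
            batches.append(px)  # per-frame rows
        elif px.ndim == 4:
            batches.append(px[None])
        else:
            batches.append(px[None])
    batch = np.concatenate(batches, axis=0)
    return extractor.extract(layer, batch)


def temporal_average(frame_activations: np.ndarray, frames_per_bin: int = 16) -> np.ndarray:
    """Average per-frame activation rows over time within each bin.

    Rows must be ordered bin-by-bin with exactly ``frames_per_bin`` rows each.
    """
    a = np.asarray(frame_activations, dtype=np.float64)
    if a.shape[0] % frames_per_bin != 0:
        raise ValueError(
            f"{a.shape[0]} frame rows do not divide into bins of {frames_per_bin}"
        )
    n_bins = a.shape[0] // frames_per_bin
    return a.reshape(n_bins, frames_per_bin, -1).mean(axis=1)


# ---------------------------------------------------------------------------
# standardize + full-rank PCA, fit on training stimuli only


@dataclass
class FeaturePipeline:
    """Train-fitted standardization followed by full-rank PCA.

    ``mean``/``sd`` are per-raw-feature training statistics; ``basis`` has one
    orthonormal principal axis per row (min(n_train - 1, n_features) of them).
    A zero-variance training feature standardizes to 0 everywhere.
    """

    mean: np.ndarray
    sd: np.ndarray
    basis: np.ndarray  # (n_components, n_raw_features)
    layer: str = ""

    @property
    def n_components(self) -> int:
        return self.basis.shape[0]

    def standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = (X - self.mean) / self.sd
        Z[:, self.sd == 0] = 0.0
        return Z


@dataclass
class FeatureMatrix:
    """Per-row feature vectors in the train-fitted component space."""

    data: np.ndarray
    ids: list[str]
    layer: str
    provenance: str = "network"  # or "pixels"

    def rows_for(self, ids: Sequence[str]) -> np.ndarray:
        index = {sid: i for i, sid in enumerate(self.ids)}
        missing = [sid for sid in ids if sid not in index]
        if missing:
            raise KeyError(f"ids not in feature matrix: {missing}")
        return self.data[[index[sid] for sid in ids]]


def fit_feature_pipeline(train_activations: np.ndarray, layer: str = "") -> FeaturePipeline:
    """Fit per-feature standardization and a full-rank PCA basis on the
    training activations only.

    All min(n_train - 1, n_features) principal components are retained.
    Component signs are fixed (largest-magnitude loading positive) for
    reproducibility.
    """
    X = np.asarray(train_activations, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need >= 2 training rows to fit the feature pipeline")
    if not np.all(np.isfinite(X)):
        raise ValueError("training activations contain non-finite values")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD
    # features whose spread is pure floating-point jitter are degenerate:
    # standardizing them would amplify rounding noise into O(1) garbage
    sd[sd <= 1e-12 * (np.abs(mean) + 1.0)] = 0.0
    if np.all(sd == 0):
        raise ValueError("all features are constant on the training set; nothing to decompose")
    Z = (X - mean)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = Z / sd
    Z[:, sd == 0] = 0.0
    # re-center in standardized space (exact centering there can be lost to
    # rounding) and fold the correction back into the stored mean
    z_mean = Z.mean(axis=0)
    Z = Z - z_mean
    mean = mean + z_mean * sd
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    k = min(X.shape[0] - 1, X.shape[1])
    Vt = Vt[:k]
    # deterministic sign: largest-|loading| entry of each axis made positive
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
    return FeaturePipeline(mean=mean, sd=sd, basis=Vt, layer=layer)


def apply_feature_pipeline(pipeline: FeaturePipeline, activations: np.ndarray) -> np.ndarray:
    """Standardize with the training parameters and project on the training
    PCA basis.  Test rows never influence the parameters."""
    X = np.asarray(activations, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != pipeline.mean.shape[0]:
        raise ValueError(
            f"activations have {X.shape[1] if X.ndim == 2 else '?'} columns; "
            f"pipeline expects {pipeline.mean.shape[0]}"
        )
    return pipeline.standardize(X) @ pipeline.basis.T


def pixel_features(stimuli, train_ids: Sequence[str], frames_per_bin: int = 16) -> FeatureMatrix:
    """Baseline features: flattened pixels through the identical train-fitted
    standardize+PCA pipeline.

    Videos contribute their within-bin frame-mean image per 16-frame bin.
    """
    rows, ids = [], []
    for it in stimuli:
        px = it.pixels
        if px.ndim == 4:
            px = px.mean(axis=0)  # bin-mean image
        rows.append(px.ravel())
        ids.append(it.id)
    X = np.stack(rows)
    train_idx = [i for i, sid in enumerate(ids) if sid in set(train_ids)]
    if len(train_idx) < 2:
        raise ValueError("need >= 2 training items for the pixel baseline")
    pipe = fit_feature_pipeline(X[train_idx], layer="pixels")
    return FeatureMatrix(apply_feature_pipeline(pipe, X), ids, "pixels", provenance="pixels")


# ---------------------------------------------------------------------------
# HDF5 serialization


def save_pipeline(pipeline: FeaturePipeline, path, architecture: str = "", seed: int | None = None):
    with h5py.File(path, "w") as f:
        f.create_dataset("means", data=pipeline.mean)
        f.create_dataset("sds", data=pipeline.sd)
        f.create_dataset("basis", data=pipeline.basis)
        f.attrs["layer"] = pipeline.layer
        f.attrs["architecture"] = architecture
        if seed is not None:
            f.attrs["seed"] = seed


def load_pipeline(path) -> FeaturePipeline:
    with h5py.File(path, "r") as f:
        return FeaturePipeline(
            mean=f["means"][:], sd=f["sds"][:], basis=f["basis"][:], layer=f.attrs.get("layer", "")
        )


def save_features(fm: FeatureMatrix, path, architecture: str = "", seed: int | None = None):
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=fm.data)
        f.create_dataset("ids", data=np.array(fm.ids, dtype=h5py.string_dtype()))
        f.attrs["layer"] = fm.layer
        f.attrs["provenance"] = fm.provenance
        f.attrs["architecture"] = architecture
        if seed is not None:
            f.attrs["seed"] = seed


def load_features(path) -> FeatureMatrix:
    with h5py.File(path, "r") as f:
        return FeatureMatrix(
            data=f["features"][:],
            ids=[s.decode() if isinstance(s, bytes) else str(s) for s in f["ids"][:]],
            layer=str(f.attrs.get("layer", "")),
            provenance=str(f.attrs.get("provenance", "network")),
        )
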