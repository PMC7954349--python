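"""Experiment orchestration: one config in, tidy result tables out.

Three experiment templates cover the decoding/signature analyses
(``transformation_grid``, ``silhouette_signature``, ``video_categorization``)
and :func:`run_rsa` covers the neural comparison.  Every stage respects the
train-only fitting order: feature pipelines, decoders, and signature maps
see training stimuli and training behavior only.  Re-running an archived
config reproduces the output tables byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decoding import jackknife_ci, score_2afc, score_yes_no, train_decoder
from .features import (
    FeatureMatrix,
    TinyNetExtractor,
    apply_feature_pipeline,
    fit_feature_pipeline,
    pixel_features,
)
from .rsa import (
    compute_rdm,
    mds_embed,
    neural_response_matrix,
    noise_ceiling,
    normalized_similarity,
    rdm_distance_ratio,
)
from .separability import gdv
from .signatures import (
    explained_variance,
    fit_signature_map,
    loocv_explained_variance,
    predict_signature,
)
from .stimuli import StimulusSet, bin_video_frames
from .synthetic import (
    draw_signature_weights,
    make_behavioral_signature,
    make_category_videos,
    make_neural_population,
    make_silhouette_set,
    make_transformation_grid,
)

__all__ = ["ExperimentConfig", "run_experiment", "run_rsa", "load_config", "save_config"]

TEMPLATES = ("transformation_grid", "silhouette_signature", "video_categorization")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment run."""

    template: str = "transformation_grid"
    seed: int = 0
    extractor_seed: int = 0
    extractor_width: int = 1
    layers: list | None = None  # None = all layers
    include_pixels: bool = True
    n_pls: int | None = None  # default: 3 for transformation_grid, 10 otherwise
    n_trials: int = 80
    truth_layer: str = "conv2"  # layer whose features generate synthetic behavior
    video_mode: str = "low_level_equalized"
    video_pair_aggregation: str = "matched"  # or "all_pairs"
    n_videos_per_class: int = 5
    jackknife_axis: str | None = None  # default per template
    # RSA settings
    rsa_area_layers: dict = field(default_factory=lambda: {"V1": "conv1", "TO": "conv4"})
    rsa_n_units: int = 40
    rsa_noise_sd: float = 0.5
    rsa_n_reps: int = 10
    rsa_n_splits: int = 1000
    rsa_model_seeds: list = field(default_factory=lambda: [0, 1])

    def __post_init__(self):
        if self.template not in TEMPLATES:
            raise ValueError(f"unknown template {self.template!r}; choose from {TEMPLATES}")
        if self.n_pls is None:
            self.n_pls = 3 if self.template == "transformation_grid" else 10
        if self.jackknife_axis is None:
            self.jackknife_axis = {
                "transformation_grid": "transformation",
                "silhouette_signature": "stimulus",
                "video_categorization": "pair",
            }[self.template]

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return ExperimentConfig(**data)


def save_config(config: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# shared helpers


def _extractor(config: ExperimentConfig) -> TinyNetExtractor:
    return TinyNetExtractor(seed=config.extractor_seed, width=config.extractor_width)


def _layer_feature_matrices(extractor, items, train_mask, include_pixels=True,
                            layers=None) -> dict[str, FeatureMatrix]:
    """Train-fitted standardize+PCA features for every layer (plus pixels)."""
    from .decoding import _extract_rows

    ids = [it.id for it in items]
    out: dict[str, FeatureMatrix] = {}
    if include_pixels:
        out["pixels"] = pixel_features(items, [i for i, m in zip(ids, train_mask) if m])
    raw_all = _extract_rows(extractor, items, 16)
    names = [s.name for s in extractor.layers]
    if layers is not None:
        names = [n for n in names if n in set(layers)]
    for layer in names:
        pipe = fit_feature_pipeline(raw_all[layer][train_mask], layer=layer)
        out[layer] = FeatureMatrix(apply_feature_pipeline(pipe, raw_all[layer]), ids, layer)
    return out


def _accuracy_with_ci(correctness: np.ndarray, group_keys) -> tuple[float, float, float, float]:
    """Overall percent correct with a jackknife CI resampling groups."""
    df = pd.DataFrame({"g": list(group_keys), "c": correctness})
    per_group = df.groupby("g")["c"].mean().to_numpy() * 100.0
    if per_group.size >= 2:
        est, se, (lo, hi) = jackknife_ci(per_group)
    else:
        est, se, lo, hi = float(per_group.mean()), 0.0, float(per_group.mean()), float(per_group.mean())
        return est, se, lo, hi
    return est, se, lo, hi


def _write_outputs(outdir, config: ExperimentConfig, tables: dict[str, pd.DataFrame]) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False, float_format="%.10g")
    meta = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "package_version": __version__,
        "python_version": platform.python_version(),
        "seed": config.seed,
    }
    (outdir / "run.json").write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))


# ---------------------------------------------------------------------------
# experiment templates


def run_experiment(config: ExperimentConfig, outdir=None) -> dict[str, pd.DataFrame]:
    """Execute one experiment template end-to-end.

    Returns (and optionally writes) tidy tables:

    * ``accuracy`` — layer, partition, group, accuracy, se, ci_lo, ci_hi
    * ``signature`` — layer, partition, explained_variance (logit scale)
    * ``gdv`` — layer, grouping, value
    """
    if config.template == "transformation_grid":
        tables = _run_grid(config)
    elif config.template == "silhouette_signature":
        tables = _run_silhouettes(config)
    else:
        tables = _run_videos(config)
    if outdir is not None:
        _write_outputs(outdir, config, tables)
    return tables



def _compute_layers(config: ExperimentConfig):
    """Requested layer subset, always including the ground-truth layer."""
    if config.layers is None:
        return None
    return sorted(set(config.layers) | {config.truth_layer})


def _reported(config: ExperimentConfig, layer: str) -> bool:
    return config.layers is None or layer == "pixels" or layer in config.layers


def _run_grid(config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    stimuli = make_transformation_grid(config.seed)
    extractor = _extractor(config)
    items = list(stimuli)
    ids = [it.id for it in items]
    roles = np.array([it.role for it in items])
    labels = np.array([it.labels["object"] for it in items])
    cells = [f"{it.labels['size_deg']:g}x{it.labels['rotation_deg']:g}" for it in items]
    train_mask = roles == "train"

    matrices = _layer_feature_matrices(extractor, items, train_mask,
                                       config.include_pixels, _compute_layers(config))
    truth = matrices[config.truth_layer]
    w, b0 = draw_signature_weights(config.seed + 1, truth.data.shape[1], k=config.n_pls,
                                   features=truth.data)
    signature = make_behavioral_signature(config.seed + 2, truth.data, w, b0,
                                          n_trials=config.n_trials, conditions=ids,
                                          partition=roles)
    obs_logits = signature.logits

    acc_rows, sig_rows, gdv_rows = [], [], []
    for layer, fm in matrices.items():
        if not _reported(config, layer):
            continue
        dec = train_decoder(fm.data[train_mask], labels[train_mask], layer=layer)
        for part, mask in (("train", train_mask), ("test", ~train_mask)):
            res = score_yes_no(dec, fm.data[mask], labels[mask], partition=part)
            est, se, lo, hi = _accuracy_with_ci(res.correctness,
                                                [c for c, m in zip(cells, mask) if m])
            acc_rows.append({"layer": layer, "partition": part, "group": "all",
                             "accuracy": est, "se": se, "ci_lo": lo, "ci_hi": hi})
        model = fit_signature_map(fm.data[train_mask], obs_logits[train_mask],
                                  config.n_pls, layer=layer)
        for part, mask in (("train", train_mask), ("test", ~train_mask)):
            ev = explained_variance(predict_signature(model, fm.data[mask]), obs_logits[mask])
            sig_rows.append({"layer": layer, "partition": part, "explained_variance": ev})
        gdv_rows.append({"layer": layer, "grouping": "object",
                         "value": gdv(fm.data, labels).value})
    return {"accuracy": pd.DataFrame(acc_rows), "signature": pd.DataFrame(sig_rows),
            "gdv": pd.DataFrame(gdv_rows)}


def _run_silhouettes(config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    stimuli = make_silhouette_set(config.seed)
    extractor = _extractor(config)
    items = list(stimuli)
    ids = [it.id for it in items]
    labels = np.array([it.labels["category"] for it in items])
    objects = np.array([it.labels["object"] for it in items])
    train_mask = np.ones(len(items), dtype=bool)  # no generalization phase

    matrices = _layer_feature_matrices(extractor, items, train_mask,
                                       config.include_pixels, _compute_layers(config))
    truth = matrices[config.truth_layer]
    k = min(config.n_pls, truth.data.shape[1])
    w, b0 = draw_signature_weights(config.seed + 1, truth.data.shape[1], k=k,
                                   features=truth.data)
    signature = make_behavioral_signature(config.seed + 2, truth.data, w, b0,
                                          n_trials=config.n_trials, conditions=ids)
    obs_logits = signature.logits

    acc_rows, sig_rows, gdv_rows = [], [], []
    for layer, fm in matrices.items():
        if not _reported(config, layer):
            continue
        dec = train_decoder(fm.data, labels, positive_label="reference", layer=layer)
        res = score_yes_no(dec, fm.data, labels, partition="train")
        est, se, lo, hi = _accuracy_with_ci(res.correctness, ids)
        acc_rows.append({"layer": layer, "partition": "train", "group": "all",
                         "accuracy": est, "se": se, "ci_lo": lo, "ci_hi": hi})
        n_comp = min(config.n_pls, fm.data.shape[1], fm.data.shape[0] - 2)
        ev = loocv_explained_variance(fm.data, obs_logits, n_comp, layer=layer)
        sig_rows.append({"layer": layer, "partition": "loocv", "explained_variance": ev})
        gdv_rows.append({"layer": layer, "grouping": "object",
                         "value": gdv(fm.data, objects).value})
    return {"accuracy": pd.DataFrame(acc_rows), "signature": pd.DataFrame(sig_rows),
            "gdv": pd.DataFrame(gdv_rows)}


def _video_bins(stimuli: StimulusSet) -> list:
    bins = []
    for it in stimuli:
        bins.extend(bin_video_frames(it))
    return bins


def enumerate_training_pairs(stimuli: StimulusSet) -> list[tuple[str, str]]:
    """All target x distractor combinations among training videos (the
    training-set evaluation enumerates every combination)."""
    train = [it for it in stimuli if it.role == "train"]
    targets = [it.id for it in train if it.labels["category"] == "target"]
    distractors = [it.id for it in train if it.labels["category"] != "target"]
    return [(t, d) for t in targets for d in distractors]


def fixed_test_pairs(stimuli: StimulusSet) -> list[tuple[str, str]]:
    """The manifest's fixed target-distractor pairing among test videos."""
    return [(it.labels["pair"], it.id) for it in stimuli
            if it.role == "test" and it.labels.get("pair")]


def _score_video_pairs(dec, fm: FeatureMatrix, pairs, aggregation: str) -> pd.DataFrame:
    """2AFC correctness per video pair, aggregated over the nine frame bins.

    ``matched``: bin i of the target against bin i of the distractor, mean of
    the nine bin-level outcomes.  ``all_pairs``: every target bin against
    every distractor bin (81 comparisons).
    """
    rows = []
    for t, d in pairs:
        t_bins = [f"{t}#b{k}" for k in range(9)]
        d_bins = [f"{d}#b{k}" for k in range(9)]
        if aggregation == "matched":
            res = score_2afc(dec, fm.rows_for(t_bins), fm.rows_for(d_bins))
        elif aggregation == "all_pairs":
            tt = [tb for tb in t_bins for _ in d_bins]
            dd = [db for _ in t_bins for db in d_bins]
            res = score_2afc(dec, fm.rows_for(tt), fm.rows_for(dd))
        else:
            raise ValueError(f"unknown aggregation {aggregation!r}")
        rows.append({"target": t, "distractor": d,
                     "correct": float(res.correctness.mean())})
    return pd.DataFrame(rows)


def _run_videos(config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    stimuli = make_category_videos(config.seed, n_per_class=config.n_videos_per_class,
                                   mode=config.video_mode)
    extractor = _extractor(config)
    bins = _video_bins(stimuli)
    bin_roles = np.array([b.role for b in bins])
    bin_cats = np.array([b.labels["category"] for b in bins])
    train_mask = bin_roles == "train"
    category_of = {it.id: it.labels["category"] for it in stimuli}

    matrices = _layer_feature_matrices(extractor, bins, train_mask,
                                       config.include_pixels, _compute_layers(config))
    train_pairs = enumerate_training_pairs(stimuli)
    test_pairs = fixed_test_pairs(stimuli)

    truth = matrices[config.truth_layer]
    all_pairs = train_pairs + test_pairs
    pair_roles = np.array(["train"] * len(train_pairs) + ["test"] * len(test_pairs))
    truth_bin_diffs = _video_pair_features(truth, all_pairs)
    k = min(config.n_pls, truth_bin_diffs.shape[1])
    w, b0 = draw_signature_weights(config.seed + 1, truth_bin_diffs.shape[1], k=k,
                                   features=truth_bin_diffs)
    signature = make_behavioral_signature(config.seed + 2, truth_bin_diffs, w, b0,
                                          n_trials=config.n_trials, conditions=all_pairs,
                                          partition=pair_roles)
    obs_logits = signature.logits

    binary = np.where(bin_cats == "target", "target", "distractor")
    acc_rows, sig_rows, gdv_rows = [], [], []
    for layer, fm in matrices.items():
        if not _reported(config, layer):
            continue
        dec = train_decoder(fm.data[train_mask], binary[train_mask],
                            positive_label="target", layer=layer)
        for part, pairs in (("train", train_pairs), ("test", test_pairs)):
            scored = _score_video_pairs(dec, fm, pairs, config.video_pair_aggregation)
            scored["dclass"] = [category_of[d] for d in scored["distractor"]]
            for dclass, sub in scored.groupby("dclass"):
                if len(sub) >= 2:
                    est, se, (lo, hi) = jackknife_ci(sub["correct"].to_numpy() * 100.0)
                else:
                    est = float(sub["correct"].mean() * 100.0)
                    se, lo, hi = 0.0, est, est
                acc_rows.append({"layer": layer, "partition": part, "group": dclass,
                                 "accuracy": est, "se": se, "ci_lo": lo, "ci_hi": hi})
        X = _video_pair_features(fm, all_pairs)
        model = fit_signature_map(X[pair_roles == "train"], obs_logits[pair_roles == "train"],
                                  min(config.n_pls, X.shape[1]), layer=layer)
        for part in ("train", "test"):
            mask = pair_roles == part
            if mask.sum() >= 3:
                ev = explained_variance(predict_signature(model, X[mask]), obs_logits[mask])
                sig_rows.append({"layer": layer, "partition": part, "explained_variance": ev})
        for dclass in ("natural", "scrambled"):
            sel = (bin_cats == "target") | (bin_cats == dclass)
            gdv_rows.append({"layer": layer, "grouping": f"target_vs_{dclass}",
                             "value": gdv(fm.data[sel], bin_cats[sel]).value})
    return {"accuracy": pd.DataFrame(acc_rows), "signature": pd.DataFrame(sig_rows),
            "gdv": pd.DataFrame(gdv_rows)}


def _video_pair_features(fm: FeatureMatrix, pairs) -> np.ndarray:
    """Per-pair predictors: target-minus-distractor features, averaged over
    the nine matched frame bins."""
    rows = []
    for t, d in pairs:
        t_rows = fm.rows_for([f"{t}#b{k}" for k in range(9)])
        d_rows = fm.rows_for([f"{d}#b{k}" for k in range(9)])
        rows.append((t_rows - d_rows).mean(axis=0))
    return np.stack(rows)


# ---------------------------------------------------------------------------
# RSA


def run_rsa(config: ExperimentConfig, outdir=None, recordings=None) -> dict:
    """Representational similarity analysis on the video stimulus set.

    With no ``recordings`` given, synthetic populations are generated per
    area from the layers named in ``rsa_area_layers`` (noisy readouts of
    those layers).  Returns per-layer-per-area noise-ceiling-normalized
    similarities with jackknife CIs (resampling neural units), MDS
    coordinates of the RDM ensemble, and the neural-vs-model RDM distance
    ratio over the configured model group seeds.
    """
    stimuli = make_category_videos(config.seed, n_per_class=config.n_videos_per_class,
                                   mode=config.video_mode, include_test=False)
    bins = _video_bins(stimuli)
    bin_labels = [b.id for b in bins]
    train_mask = np.ones(len(bins), dtype=bool)

    extractor = _extractor(config)
    matrices = _layer_feature_matrices(extractor, bins, train_mask, include_pixels=False,
                                       layers=config.layers)
    layer_rdms = {layer: compute_rdm(fm.data, bin_labels, source=layer)
                  for layer, fm in matrices.items()}

    if recordings is None:
        recordings = {}
        for i, (area, layer) in enumerate(config.rsa_area_layers.items()):
            recordings[area] = make_neural_population(
                config.seed + 100 + i, matrices[layer].data, bin_labels,
                n_units=config.rsa_n_units, noise_sd=config.rsa_noise_sd,
                n_reps=config.rsa_n_reps, area=area)

    sim_rows = []
    neural_rdms = {}
    for area, rec in recordings.items():
        ceiling = noise_ceiling(rec, n_splits=config.rsa_n_splits, seed=config.seed)
        neural_rdms[area] = compute_rdm(neural_response_matrix(rec), bin_labels, source=area)
        n_units = len(rec.units)
        for layer, rdm in layer_rdms.items():
            loo = np.empty(n_units)
            for u in range(n_units):
                sub = rec.subset_units([i for i in range(n_units) if i != u])
                sub_rdm = compute_rdm(neural_response_matrix(sub), bin_labels)
                loo[u] = normalized_similarity(rdm, sub_rdm, ceiling)
            full = normalized_similarity(rdm, neural_rdms[area], ceiling)
            n = n_units
            se = float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))
            sim_rows.append({"area": area, "layer": layer, "similarity": full,
                             "noise_ceiling": ceiling.value, "se": se,
                             "ci_lo": full - 1.96 * se, "ci_hi": full + 1.96 * se})
    similarity = pd.DataFrame(sim_rows)

    ensemble = list(neural_rdms.values()) + list(layer_rdms.values())
    ensemble_names = list(neural_rdms) + list(layer_rdms)
    coords = mds_embed(ensemble, dims=2, seed=config.seed)
    mds_df = pd.DataFrame({"rdm": ensemble_names, "x": coords[:, 0], "y": coords[:, 1]})

    model_groups = {}
    for ms in config.rsa_model_seeds:
        ext = TinyNetExtractor(seed=int(ms), width=config.extractor_width)
        mats = _layer_feature_matrices(ext, bins, train_mask, include_pixels=False,
                                       layers=config.layers)
        model_groups[f"model{ms}"] = [compute_rdm(fm.data, bin_labels, source=f"model{ms}:{l}")
                                      for l, fm in mats.items()]
    ratio = rdm_distance_ratio(list(neural_rdms.values()), model_groups)
    ratio_df = pd.DataFrame([{"distance_ratio": ratio}])

    tables = {"similarity": similarity, "mds": mds_df, "distance_ratio": ratio_df}
    if outdir is not None:
        _write_outputs(outdir, config, tables)
    return tables
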