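"""Representational similarity analysis between neural data and model layers.

Neural recordings (per-unit, per-repetition firing rates in 16-frame-aligned
windows, with per-unit response latencies) are reduced to a stimulus-bin x
unit response matrix; pairwise ``1 - Pearson r`` dissimilarities form a
representational dissimilarity matrix (RDM).  Model-layer RDMs are built the
same way from feature vectors.  Neural-model correspondence is the Spearman
correlation of the strictly-upper RDM triangles, normalized by a split-half
Spearman-Brown noise ceiling; RDM ensembles are visualized with non-metric
multidimensional scaling on ``1 - Spearman`` distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.manifold import MDS

__all__ = [
    "NeuralUnit",
    "NeuralRecording",
    "RDM",
    "NoiseCeiling",
    "BIN_DURATION_MS",
    "neural_response_matrix",
    "compute_rdm",
    "compare_rdms",
    "noise_ceiling",
    "normalized_similarity",
    "mds_embed",
    "embed_distances",
    "rdm_distance_ratio",
    "save_recording_h5",
    "load_recording_h5",
    "load_recording_csv",
    "save_recording_csv",
    "rdm_to_csv",
    "rdm_from_csv",
]

#: Duration of one 16-frame bin at 30 fps, used to convert response latencies
#: (ms) into whole-bin offsets.
BIN_DURATION_MS = 16 / 30 * 1000.0


@dataclass
class NeuralUnit:
    id: str
    area: str = "V1"
    unit_type: str = "single"  # or "multi"
    latency_ms: float = 0.0


@dataclass
class NeuralRecording:
    """Firing rates per unit x time-bin x repetition.

    The time axis may be longer than the stimulus-bin axis: each unit's
    response to stimulus bin b is read from time bin ``b + offset`` where
    ``offset = round(latency_ms / BIN_DURATION_MS)`` — the latency shift.
    ``bin_labels`` name the stimulus bins (e.g. ``video3#b7``).
    """

    units: list  # list[NeuralUnit]
    rates: np.ndarray  # (n_units, n_time_bins, n_reps)
    bin_labels: list

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=np.float64)
        if self.rates.ndim != 3:
            raise ValueError("rates must be (units, time bins, repetitions)")
        if self.rates.shape[0] != len(self.units):
            raise ValueError("rates row count does not match unit count")
        if any(u.latency_ms is None for u in self.units):
            raise ValueError("every unit needs a response latency")

    @property
    def n_stimulus_bins(self) -> int:
        return len(self.bin_labels)

    @property
    def n_reps(self) -> int:
        return self.rates.shape[2]

    def subset_units(self, indices) -> "NeuralRecording":
        idx = np.asarray(indices)
        return NeuralRecording([self.units[i] for i in idx], self.rates[idx], self.bin_labels)

    def areas(self) -> list[str]:
        seen = []
        for u in self.units:
            if u.area not in seen:
                seen.append(u.area)
        return seen

    def subset_area(self, area: str) -> "NeuralRecording":
        return self.subset_units([i for i, u in enumerate(self.units) if u.area == area])


def _latency_offset(latency_ms: float) -> int:
    return int(round(latency_ms / BIN_DURATION_MS))


def neural_response_matrix(recording: NeuralRecording,
                           rep_indices: np.ndarray | None = None) -> np.ndarray:
    """Stimulus-bin x unit response matrix: repetition-averaged,
    latency-shifted firing rates, z-scored per unit across bins.

    ``rep_indices`` restricts which repetitions enter the average (used by the
    split-half noise ceiling; standardization is redone within the subset).
    A unit with constant rate becomes an all-zero column.
    """
    n_bins = recording.n_stimulus_bins
    if n_bins < 2:
        raise ValueError("need >= 2 stimulus bins")
    rates = recording.rates if rep_indices is None else recording.rates[:, :, rep_indices]
    cols = []
    for i, unit in enumerate(recording.units):
        off = _latency_offset(unit.latency_ms)
        if off + n_bins > rates.shape[1]:
            raise ValueError(
                f"unit {unit.id!r}: latency offset {off} bins exceeds the recorded "
                f"time axis ({rates.shape[1]} bins for {n_bins} stimulus bins)"
            )
        mean_rate = rates[i, off : off + n_bins].mean(axis=1)
        sd = mean_rate.std()
        # a spread at rounding level is a constant unit, not a signal
        if sd <= 1e-12 * (abs(mean_rate.mean()) + 1.0):
            cols.append(np.zeros(n_bins))
        else:
            cols.append((mean_rate - mean_rate.mean()) / sd)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# RDMs


@dataclass
class RDM:
    """Square symmetric matrix of 1 - Pearson r dissimilarities."""

    values: np.ndarray
    labels: list
    source: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("RDM must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")

    @property
    def upper(self) -> np.ndarray:
        """Strictly-upper-triangle entries, the unit of all RDM comparisons."""
        iu = np.triu_indices(self.values.shape[0], k=1)
        return self.values[iu]


def compute_rdm(matrix: np.ndarray, labels=None, source: str = "") -> RDM:
    """RDM with entries ``1 - Pearson r`` between rows (response patterns)."""
    M = np.asarray(matrix, dtype=np.float64)
    if M.ndim != 2 or M.shape[0] < 3:
        raise ValueError("need >= 3 rows to build an RDM")
    sds = M.std(axis=1)
    flat = np.where(sds == 0)[0]
    if flat.size:
        names = [labels[i] for i in flat] if labels is not None else flat.tolist()
        raise ValueError(f"constant rows have undefined correlations: {names}")
    r = np.corrcoef(M)
    values = 1.0 - r
    np.fill_diagonal(values, 0.0)
    if labels is None:
        labels = list(range(M.shape[0]))
    return RDM(values=values, labels=list(labels), source=source)


def compare_rdms(rdm_a: RDM, rdm_b: RDM) -> float:
    """Spearman correlation of the strictly-upper triangles."""
    if list(rdm_a.labels) != list(rdm_b.labels):
        raise ValueError("RDM labels differ; cannot compare")
    return float(spearmanr(rdm_a.upper, rdm_b.upper).statistic)


@dataclass
class NoiseCeiling:
    """Spearman-Brown-corrected mean split-half RDM correlation."""

    value: float
    n_splits: int
    seed: int


def noise_ceiling(recording: NeuralRecording, n_splits: int = 1000, seed: int = 0) -> NoiseCeiling:
    """Split repetitions in two halves, correlate the two half-data RDMs
    (Spearman, upper triangles), average over random splits, and apply the
    Spearman-Brown correction ``2r / (1 + r)``.

    Odd repetition counts split ceil/floor at random.  Standardization is
    redone within each half so the halves stay independent.
    """
    k = recording.n_reps
    if k < 2:
        raise ValueError("noise ceiling needs >= 2 repetitions")
    rng = np.random.default_rng(seed)
    half = k // 2
    rs = np.empty(n_splits)
    for s in range(n_splits):
        perm = rng.permutation(k)
        a, b = perm[:half], perm[half:]
        rdm_a = compute_rdm(neural_response_matrix(recording, a), recording.bin_labels)
        rdm_b = compute_rdm(neural_response_matrix(recording, b), recording.bin_labels)
        rs[s] = spearmanr(rdm_a.upper, rdm_b.upper).statistic
    r = float(np.mean(rs))
    return NoiseCeiling(value=2.0 * r / (1.0 + r), n_splits=n_splits, seed=seed)


def normalized_similarity(model_rdm: RDM, neural_rdm: RDM, ceiling: NoiseCeiling | float) -> float:
    """Model-neural Spearman correlation divided by the area's noise ceiling,
    so 1 means 'as similar as the data's reliability permits'."""
    c = ceiling.value if isinstance(ceiling, NoiseCeiling) else float(ceiling)
    if c <= 0:
        raise ValueError(f"noise ceiling must be positive, got {c}")
    return compare_rdms(model_rdm, neural_rdm) / c


def mds_embed(rdms: list[RDM], dims: int = 2, seed: int = 0, n_init: int = 50) -> np.ndarray:
    """Non-metric MDS embedding of an RDM ensemble.

    Pairwise distance between RDMs is ``1 - Spearman rho`` of their upper
    triangles; the rank-preserving (Kruskal stress) embedding keeps similar
    RDMs close.  Deterministic given the seed; best of ``n_init`` restarts.
    """
    if len(rdms) < 3:
        raise ValueError("need >= 3 RDMs to embed")
    n = len(rdms)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = 1.0 - compare_rdms(rdms[i], rdms[j])
    return embed_distances(np.maximum(D, 0.0), dims=dims, seed=seed, n_init=n_init)


def embed_distances(D: np.ndarray, dims: int = 2, seed: int = 0, n_init: int = 50) -> np.ndarray:
    """Non-metric (Kruskal stress) embedding of a precomputed symmetric
    dissimilarity matrix; best of ``n_init`` seeded restarts."""
    mds = MDS(n_components=dims, metric_mds=False, metric="precomputed", init="random",
              n_init=n_init, random_state=seed, normalized_stress="auto",
              max_iter=3000, eps=1e-12)
    return mds.fit_transform(np.asarray(D, dtype=np.float64))


def rdm_distance_ratio(neural_rdms: list[RDM], model_groups: dict[str, list[RDM]]) -> float:
    """Mean ``1 - Spearman`` distance between neural and model RDMs, divided
    by the mean distance between model RDMs from *different* models.

    A ratio well above 1 says the neural geometry sits outside the family of
    model geometries.
    """
    if len(neural_rdms) < 1:
        raise ValueError("need >= 1 neural RDM")
    if len(model_groups) < 2:
        raise ValueError("need >= 2 model groups for the cross-model baseline")
    num = [1.0 - compare_rdms(nr, mr)
           for nr in neural_rdms for group in model_groups.values() for mr in group]
    names = list(model_groups)
    den = [1.0 - compare_rdms(a, b)
           for gi in range(len(names)) for gj in range(gi + 1, len(names))
           for a in model_groups[names[gi]] for b in model_groups[names[gj]]]
    mean_den = float(np.mean(den))
    if mean_den <= 1e-12:
        raise ValueError("cross-model RDM distances are all zero; ratio undefined")
    return float(np.mean(num)) / mean_den


# ---------------------------------------------------------------------------
# IO


def save_recording_h5(recording: NeuralRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("bin_labels", data=np.array(recording.bin_labels,
                                                     dtype=h5py.string_dtype()))
        grp = f.create_group("units")
        for i, u in enumerate(recording.units):
            g = grp.create_group(u.id)
            g.create_dataset("rates", data=recording.rates[i].T)  # repetition x bin
            g.attrs["area"] = u.area
            g.attrs["type"] = u.unit_type
            g.attrs["latency_ms"] = u.latency_ms


def load_recording_h5(path) -> NeuralRecording:
    with h5py.File(path, "r") as f:
        bin_labels = [s.decode() if isinstance(s, bytes) else str(s) for s in f["bin_labels"][:]]
        units, rates = [], []
        for uid in sorted(f["units"]):
            g = f["units"][uid]
            units.append(NeuralUnit(id=uid, area=str(g.attrs["area"]),
                                    unit_type=str(g.attrs["type"]),
                                    latency_ms=float(g.attrs["latency_ms"])))
            rates.append(g["rates"][:].T)
    return NeuralRecording(units=units, rates=np.stack(rates), bin_labels=bin_labels)


def save_recording_csv(recording: NeuralRecording, path) -> None:
    rows = []
    for i, u in enumerate(recording.units):
        for t in range(recording.rates.shape[1]):
            for rep in range(recording.n_reps):
                rows.append({"unit": u.id, "area": u.area, "type": u.unit_type,
                             "latency_ms": u.latency_ms, "time_bin": t, "rep": rep,
                             "rate": recording.rates[i, t, rep]})
    header = ",".join(str(l) for l in recording.bin_labels)
    df = pd.DataFrame(rows)
    df.attrs["bin_labels"] = header
    with open(path, "w") as fh:
        fh.write(f"# bin_labels: {header}\n")
        df.to_csv(fh, index=False)


def load_recording_csv(path) -> NeuralRecording:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# bin_labels:"):
            raise ValueError("long-format recording CSV must start with a '# bin_labels:' line")
        bin_labels = first.split(":", 1)[1].strip().split(",")
        df = pd.read_csv(fh)
    units, rates = [], []
    for uid, sub in df.groupby("unit", sort=True):
        units.append(NeuralUnit(id=str(uid), area=str(sub["area"].iloc[0]),
                                unit_type=str(sub["type"].iloc[0]),
                                latency_ms=float(sub["latency_ms"].iloc[0])))
        mat = sub.pivot(index="time_bin", columns="rep", values="rate").to_numpy()
        rates.append(mat)
    return NeuralRecording(units=units, rates=np.stack(rates), bin_labels=bin_labels)


def rdm_to_csv(rdm: RDM, path) -> None:
    pd.DataFrame(rdm.values, index=rdm.labels, columns=rdm.labels).to_csv(path)


def rdm_from_csv(path, source: str = "") -> RDM:
    df = pd.read_csv(path, index_col=0)
    return RDM(values=df.to_numpy(), labels=[str(c) for c in df.columns], source=source)
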