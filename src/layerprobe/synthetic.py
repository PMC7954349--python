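"""Synthetic inputs with the statistical structure the analyses assume.

Every generator is a pure function of its seed and parameters, so each
analysis stage can be exercised end-to-end without any external download:

* transformation-grid object stimuli (two procedurally generated silhouettes
  over a size x rotation grid, with a train "cross" and held-out
  combinations),
* reference-vs-distractor silhouette sets across sizes,
* 150-frame category videos (an articulated two-part "animal-like" target
  configuration vs. matched natural distractors), with per-frame Fourier
  phase-scrambled variants,
* binomially sampled behavioral signatures whose logit is linear in known
  layer features,
* neural populations that are noisy pointwise-nonlinear readouts of a known
  layer, with per-unit latencies and repetitions.

The silhouettes use low-order Fourier descriptors (<= 8 radial harmonics), so
early layers *can* but need not solve the tasks, which lets layer sweeps show
structure.  None of this attempts photorealism; see the methods note for what
these generators do and do not emulate about real experiments.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .rsa import BIN_DURATION_MS, NeuralRecording, NeuralUnit
from .signatures import PerformanceSignature
from .stimuli import StimulusItem, StimulusSet

__all__ = [
    "render_silhouette",
    "make_transformation_grid",
    "make_silhouette_set",
    "make_category_videos",
    "draw_signature_weights",
    "make_behavioral_signature",
    "make_neural_population",
]

_BG = 0.6  # background intensity
_FG = 0.3  # silhouette intensity


def _shape_coefficients(rng: np.random.Generator, n_harmonics: int = 8):
    """Random low-order Fourier descriptor of a smooth closed silhouette."""
    h = np.arange(2, n_harmonics + 1)
    amp = rng.uniform(0.08, 0.3, size=h.size) / np.sqrt(h - 1)
    phase = rng.uniform(0, 2 * np.pi, size=h.size)
    return h, amp, phase


def render_silhouette(coeffs, size_px: float, rotation_deg: float = 0.0,
                      canvas_px: int = 64, center=(0.0, 0.0),
                      bg: float = _BG, fg: float = _FG,
                      canvas: np.ndarray | None = None) -> np.ndarray:
    """Render a Fourier-descriptor blob as an anti-aliased grayscale canvas.

    ``rotation_deg`` rotates the silhouette in the image plane (the 2-D
    analogue of the azimuth rotations of the original 3-D objects).
    Returns (canvas_px, canvas_px); pass ``canvas`` to composite onto an
    existing frame.
    """
    h, amp, phase = coeffs
    yy, xx = np.mgrid[0:canvas_px, 0:canvas_px].astype(np.float64)
    cy = (canvas_px - 1) / 2 + center[1]
    cx = (canvas_px - 1) / 2 + center[0]
    dy, dx = yy - cy, xx - cx
    rho = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx) - np.deg2rad(rotation_deg)
    profile = 1.0 + np.sum(amp[:, None, None] * np.cos(h[:, None, None] * theta[None] +
                                                       phase[:, None, None]), axis=0)
    base = (size_px / 2.0) / (1.0 + amp.sum())  # max radius <= size_px / 2
    radius = base * profile
    # anti-aliased edge whose width scales with the object, so different
    # sizes of one shape are related by pure rescaling
    edge = max(0.5, size_px / 32.0)
    alpha = np.clip((radius - rho) / edge + 0.5, 0.0, 1.0)
    if canvas is None:
        canvas = np.full((canvas_px, canvas_px), bg, dtype=np.float64)
    canvas[:] = canvas * (1 - alpha) + fg * alpha
    return canvas


def _to_item(sid, gray, labels, role):
    gray = np.clip(gray, 0.0, 1.0)
    if gray.ndim == 2:
        pixels = np.repeat(gray[:, :, None], 3, axis=2)
    else:
        pixels = np.repeat(gray[:, :, :, None], 3, axis=3)
    return StimulusItem(id=sid, pixels=pixels, labels=labels, role=role)


def make_transformation_grid(
    seed: int,
    n_objects: int = 2,
    sizes=(15.0, 20.0, 25.0, 30.0, 35.0, 40.0),
    rotations=(-40.0, -30.0, -20.0, -10.0, 0.0, 10.0, 20.0, 30.0, 40.0),
    train_cross=None,
    canvas_px: int = 64,
    px_per_deg: float = 1.5,
) -> StimulusSet:
    """Objects rendered over a size x rotation transformation grid with a
    train "cross" and held-out test combinations.

    The default 6 x 9 grid with the default cross (the 30-degree size row
    plus the 0-degree rotation column: 9 + 6 - 1 = 14 cells) reproduces the
    canonical design of 14 trained and 40 novel transformations per object.
    """
    sizes = tuple(float(s) for s in sizes)
    rotations = tuple(float(r) for r in rotations)
    if train_cross is None:
        mid_size = sizes[len(sizes) // 2]
        train_cross = {(s, r) for s in sizes for r in rotations
                       if s == mid_size or r == 0.0}
    else:
        train_cross = {(float(s), float(r)) for s, r in train_cross}
    grid = {(s, r) for s in sizes for r in rotations}
    outside = train_cross - grid
    if outside:
        raise ValueError(f"train-cross cells outside the grid: {sorted(outside)}")

    rng = np.random.default_rng(seed)
    shapes = [_shape_coefficients(rng) for _ in range(n_objects)]
    items = []
    for o, coeffs in enumerate(shapes):
        for s in sizes:
            for r in rotations:
                gray = render_silhouette(coeffs, s * px_per_deg, r, canvas_px)
                role = "train" if (s, r) in train_cross else "test"
                items.append(_to_item(
                    f"obj{o}_s{s:g}_r{r:g}", gray,
                    {"object": f"obj{o}", "category": f"obj{o}",
                     "size_deg": s, "rotation_deg": r, "exemplar": f"obj{o}"},
                    role,
                ))
    return StimulusSet(items, modality="image")


def make_silhouette_set(
    seed: int,
    n_distractors: int = 11,
    sizes=(15.0, 20.0, 25.0, 30.0, 35.0),
    canvas_px: int = 64,
    px_per_deg: float = 1.5,
) -> StimulusSet:
    """One reference silhouette plus ``n_distractors`` distractor silhouettes,
    each rendered at every requested size (defaults: 12 objects x 5 sizes
    spanning 15-35 degrees).  All items belong to the training phase; the
    matching signature analysis uses leave-one-out cross-validation."""
    if n_distractors < 1:
        raise ValueError("need at least one distractor object")
    rng = np.random.default_rng(seed)
    names = ["ref"] + [f"dist{i:02d}" for i in range(1, n_distractors + 1)]
    items = []
    for name in names:
        coeffs = _shape_coefficients(rng)
        category = "reference" if name == "ref" else "distractor"
        for s in sizes:
            gray = render_silhouette(coeffs, float(s) * px_per_deg, 0.0, canvas_px)
            items.append(_to_item(
                f"{name}_s{s:g}", gray,
                {"object": name, "category": category, "size_deg": float(s),
                 "rotation_deg": 0.0, "exemplar": name},
                "train",
            ))
    return StimulusSet(items, modality="image")


# ---------------------------------------------------------------------------
# category videos


def _smooth_path(rng, frames, canvas_px, margin, n_waves=2):
    """Smooth 2-D trajectory built from a few random sinusoids."""
    t = np.linspace(0, 2 * np.pi, frames)
    path = np.zeros((frames, 2))
    for _ in range(n_waves):
        freq = rng.uniform(0.5, 1.5, size=2)
        phase = rng.uniform(0, 2 * np.pi, size=2)
        amp = rng.uniform(0.2, 0.5, size=2) * (canvas_px / 2 - margin)
        path += amp * np.sin(freq * t[:, None] + phase)
    return path / n_waves


def _render_video(rng, frames, canvas_px, px_per_deg, is_target: bool) -> np.ndarray:
    """Target: a two-part articulated figure (body with attached head that
    leads the heading).  Distractor: the same two parts moving independently.
    Shape count, sizes, and speeds are matched across categories; only the
    spatial *configuration* distinguishes them."""
    body = _shape_coefficients(rng)
    head = _shape_coefficients(rng)
    body_px = rng.uniform(14.0, 18.0) * px_per_deg
    head_px = body_px * rng.uniform(0.45, 0.6)
    margin = body_px
    path = _smooth_path(rng, frames, canvas_px, margin)
    if is_target:
        heading = np.gradient(path, axis=0)
        norm = np.maximum(np.linalg.norm(heading, axis=1, keepdims=True), 1e-9)
        heading = heading / norm
        head_path = path + heading * (0.55 * body_px + 0.35 * head_px)
    else:
        head_path = _smooth_path(rng, frames, canvas_px, margin)
    gait_phase = rng.uniform(0, 2 * np.pi)
    video = np.empty((frames, canvas_px, canvas_px))
    for f in range(frames):
        stretch = 1.0 + 0.12 * np.sin(2 * np.pi * f / 24 + gait_phase)  # articulation
        frame = np.full((canvas_px, canvas_px), _BG)
        render_silhouette(body, body_px * stretch, 0.0, canvas_px,
                          center=tuple(path[f]), canvas=frame)
        render_silhouette(head, head_px, 0.0, canvas_px,
                          center=tuple(head_path[f]), canvas=frame)
        video[f] = frame
    return video


def _equalize_frames(video: np.ndarray, mean: float = 0.55, sd: float = 0.05) -> np.ndarray:
    """Affinely map every frame to a fixed mean luminance and RMS contrast."""
    out = np.empty_like(video)
    for f in range(video.shape[0]):
        fr = video[f]
        s = fr.std()
        out[f] = mean + (fr - fr.mean()) * (sd / s if s > 0 else 0.0)
    return np.clip(out, 0.0, 1.0)


def _phase_scramble(video: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-frame 2-D Fourier phase randomization preserving each frame's
    amplitude spectrum.  One random phase field per video, shared across
    frames, so scrambled clips keep frame-to-frame temporal correlation."""
    h, w = video.shape[1:3]
    # phases of a random real field are guaranteed conjugate-antisymmetric;
    # the DC phase is pinned at 0 so the mean luminance survives scrambling
    phase_field = np.angle(np.fft.fft2(rng.standard_normal((h, w))))
    phase_field[0, 0] = 0.0
    out = np.empty_like(video)
    for f in range(video.shape[0]):
        F = np.fft.fft2(video[f])
        out[f] = np.real(np.fft.ifft2(np.abs(F) * np.exp(1j * (np.angle(F) + phase_field))))
    return np.clip(out, 0.0, 1.0)


def make_category_videos(
    seed: int,
    n_per_class: int = 5,
    frames: int = 150,
    mode: str = "low_level_equalized",
    canvas_px: int = 64,
    px_per_deg: float = 1.5,
    include_test: bool = True,
) -> StimulusSet:
    """Category videos: targets, matched natural distractors, and
    phase-scrambled versions of the targets.

    Training phase: ``n_per_class`` videos per category (default 5 + 5 + 5,
    the canonical training-set scale).  With ``include_test``, an equal-sized
    held-out generation is added with role ``test`` and a fixed pairing label
    (``pair``) naming each distractor's paired target.  In
    ``low_level_equalized`` mode per-frame mean luminance and contrast are
    matched across categories, removing trivial photometric cues.
    """
    if frames < 144:
        raise ValueError(f"videos need >= 144 frames for nine 16-frame bins, got {frames}")
    if mode not in ("low_level_solvable", "low_level_equalized"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    items = []
    phases = [("train", "")] + ([("test", "t")] if include_test else [])
    for role, tag in phases:
        targets = []
        for i in range(n_per_class):
            vid = _render_video(rng, frames, canvas_px, px_per_deg, is_target=True)
            if mode == "low_level_equalized":
                vid = _equalize_frames(vid)
            targets.append(vid)
            items.append(_to_item(
                f"{tag}target{i}", vid,
                {"category": "target", "exemplar": f"{tag}target{i}", "pair": ""},
                role,
            ))
        for i in range(n_per_class):
            vid = _render_video(rng, frames, canvas_px, px_per_deg, is_target=False)
            if mode == "low_level_equalized":
                vid = _equalize_frames(vid)
            items.append(_to_item(
                f"{tag}natural{i}", vid,
                {"category": "natural", "exemplar": f"{tag}natural{i}",
                 "pair": f"{tag}target{i}" if role == "test" else ""},
                role,
            ))
        for i in range(n_per_class):
            scr = _phase_scramble(targets[i], rng)
            items.append(_to_item(
                f"{tag}scrambled{i}", scr,
                {"category": "scrambled", "exemplar": f"{tag}scrambled{i}",
                 "pair": f"{tag}target{i}" if role == "test" else ""},
                role,
            ))
    return StimulusSet(items, modality="video")


# ---------------------------------------------------------------------------
# behavior and neurons


def draw_signature_weights(seed: int, n_features: int, k: int = 3, scale: float = 1.2,
                           features: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Sparse ground-truth readout: weights on the first ``k`` feature
    components; intercept fixed at 0.7 (above-chance average performance).

    When the condition ``features`` are supplied, the weights are rescaled so
    that the logit drive ``X w`` has SD ``scale`` across conditions — a
    signature whose dynamic range is realistic regardless of the feature
    component scales."""
    if k > n_features:
        raise ValueError(f"k ({k}) exceeds the number of feature components ({n_features})")
    rng = np.random.default_rng(seed)
    w = np.zeros(n_features)
    raw = rng.standard_normal(k)
    w[:k] = raw / np.linalg.norm(raw) * scale
    if features is not None:
        drive_sd = float(np.std(np.asarray(features, dtype=np.float64) @ w))
        if drive_sd <= 0:
            raise ValueError("features give the drawn weights zero dynamic range")
        w *= scale / drive_sd
    return w, 0.7


def make_behavioral_signature(
    seed: int,
    features: np.ndarray,
    weights: np.ndarray,
    intercept: float = 0.7,
    n_trials: int = 80,
    conditions=None,
    partition=None,
) -> PerformanceSignature:
    """Binomially sampled per-condition performance whose logit is linear in
    the given features: ``p = expit(intercept + X w)``, reported as
    ``100 * Binomial(n_trials, p) / n_trials``.

    ``n_trials = 0`` is the noiseless sentinel: the analytic percentages are
    returned exactly (and stored with infinite trial count, so the logit
    transform does not clip).
    """
    X = np.asarray(features, dtype=np.float64)
    logits = intercept + X @ np.asarray(weights, dtype=np.float64)
    # logits are scaled to stay in a realistic range, so p never saturates structurally
    p = expit(logits)
    n = X.shape[0]
    if conditions is None:
        conditions = list(range(n))
    if partition is None:
        partition = np.array(["train"] * n)
    if n_trials == 0:
        pct = 100.0 * p
        trial_counts = np.zeros(n)  # sentinel: exact proportions
    else:
        rng = np.random.default_rng(seed)
        pct = 100.0 * rng.binomial(n_trials, p) / n_trials
        trial_counts = np.full(n, n_trials)
    return PerformanceSignature(conditions=list(conditions), pct_correct=pct,
                                n_trials=trial_counts, partition=np.asarray(partition))


def make_neural_population(
    seed: int,
    features: np.ndarray,
    bin_labels,
    n_units: int = 40,
    noise_sd: float = 0.5,
    n_reps: int = 10,
    latency_range_ms=(40.0, 120.0),
    area: str = "synth",
    multi_unit_fraction: float = 0.3,
) -> NeuralRecording:
    """A synthetic cortical population: each unit is a softplus readout of a
    random projection of the given layer features, plus i.i.d. Gaussian trial
    noise, with a per-unit response latency drawn from ``latency_range_ms``.

    Latencies spanning more than one 16-frame bin shift the unit's response
    window along a correspondingly padded time axis.  ``noise_sd`` is in
    units of the (unit-normalized) clean response SD.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if n_reps < 2:
        raise ValueError("need >= 2 repetitions (noise ceilings require splits)")
    X = np.asarray(features, dtype=np.float64)
    n_bins = X.shape[0]
    if n_bins != len(bin_labels):
        raise ValueError("features rows and bin labels disagree")
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((X.shape[1], n_units))
    pre = X @ W
    # normalize each unit's drive so the softplus operates in a comparable range
    pre = (pre - pre.mean(axis=0)) / np.maximum(pre.std(axis=0), 1e-12) * 1.5
    clean = np.log1p(np.exp(pre))  # softplus firing rate (a.u.)
    latencies = rng.uniform(*latency_range_ms, size=n_units)
    offsets = np.array([int(round(l / BIN_DURATION_MS)) for l in latencies])
    n_time = n_bins + int(offsets.max())
    rates = np.empty((n_units, n_time, n_reps))
    baseline = np.log1p(np.exp(0.0))
    for u in range(n_units):
        noise = rng.normal(0.0, noise_sd, size=(n_time, n_reps)) if noise_sd > 0 else 0.0
        sig = np.full(n_time, baseline)
        sig[offsets[u] : offsets[u] + n_bins] = clean[:, u]
        rates[u] = sig[:, None] + noise
    units = [
        NeuralUnit(
            id=f"{area}_u{u:03d}", area=area,
            unit_type="multi" if u < int(multi_unit_fraction * n_units) else "single",
            latency_ms=float(latencies[u]),
        )
        for u in range(n_units)
    ]
    return NeuralRecording(units=units, rates=rates, bin_labels=list(bin_labels))
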