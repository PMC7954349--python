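"""Stimulus sets: loading, validation, temporal binning, and geometric preprocessing.

A stimulus set is an ordered collection of labelled images or videos together
with a condition manifest (object identity, category, size in degrees of
visual angle, rotation, train/test role).  Videos are consumed downstream as
16-frame bins; images are consumed whole.  All pixel data live in ``[0, 1]``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "StimulusItem",
    "FrameBin",
    "StimulusSet",
    "StimulusError",
    "load_stimulus_set",
    "save_stimulus_set",
    "bin_video_frames",
    "resize_for_rf",
    "jitter_positions",
    "modal_border_value",
    "PX_PER_DEGREE",
    "RF_SIZE_PRESETS_PX",
]

#: Pixels per degree of visual angle implied by matching an 11x11-px first-layer
#: receptive field to 5 degrees (11 / 5 = 2.2).  Used by helpers that convert
#: stimulus sizes in degrees to pixels on a canvas.
PX_PER_DEGREE = 2.2

#: Published downsizing presets (content size in px on a 227-px canvas) used to
#: match early-layer receptive fields to rat V1 receptive-field sizes.  The
#: presets are shipped verbatim; they are not all mutually consistent with a
#: single px/degree factor, so they are never recomputed from PX_PER_DEGREE.
RF_SIZE_PRESETS_PX = {
    "video_24deg": 53,
    "silhouette_35deg": 99,
    "object_40deg": 129,
    "video_62deg": 137,
}

MANIFEST_COLUMNS = ("id", "role", "object", "category", "size_deg", "rotation_deg", "exemplar")


class StimulusError(ValueError):
    """Raised for invalid stimulus data or manifests."""


@dataclass
class StimulusItem:
    """One image (H, W, C) or video (F, H, W, C) with condition labels.

    Pixel values must lie in [0, 1].  ``role`` marks whether the item belongs
    to the training phase (used for fitting feature pipelines and decoders) or
    the generalization test phase.
    """

    id: str
    pixels: np.ndarray
    labels: dict = field(default_factory=dict)
    role: str = "train"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim not in (3, 4):
            raise StimulusError(
                f"stimulus {self.id!r}: pixels must be 3-D (image) or 4-D (video), "
                f"got shape {self.pixels.shape}"
            )
        if self.pixels.ndim == 4 and self.pixels.shape[0] < 1:
            raise StimulusError(f"stimulus {self.id!r}: video needs >= 1 frame")
        h, w = self.pixels.shape[-3], self.pixels.shape[-2]
        if h < 1 or w < 1:
            raise StimulusError(f"stimulus {self.id!r}: empty spatial dimensions")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise StimulusError(
                f"stimulus {self.id!r}: pixel values outside [0, 1] (min {lo}, max {hi})"
            )
        if self.role not in ("train", "test"):
            raise StimulusError(
                f"stimulus {self.id!r}: role must be 'train' or 'test', got {self.role!r}"
            )

    @property
    def is_video(self) -> bool:
        return self.pixels.ndim == 4

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0] if self.is_video else 1


@dataclass
class FrameBin:
    """A contiguous 16-frame temporal bin cut from a parent video."""

    parent_id: str
    bin_index: int
    pixels: np.ndarray  # (bin_length, H, W, C)
    labels: dict = field(default_factory=dict)
    role: str = "train"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 4:
            raise StimulusError(
                f"frame bin {self.id!r}: expected 4-D pixels, got shape {self.pixels.shape}"
            )

    @property
    def id(self) -> str:
        return f"{self.parent_id}#b{self.bin_index}"


@dataclass
class StimulusSet:
    """Ordered collection of stimuli sharing shape, plus a label manifest."""

    items: list
    modality: str = "image"  # or "video"

    def __post_init__(self):
        ids = [it.id for it in self.items]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise StimulusError(f"duplicate stimulus ids: {sorted(dup)}")
        shapes = {it.pixels.shape[-3:] for it in self.items}
        if len(shapes) > 1:
            raise StimulusError(f"items disagree on (H, W, C): {sorted(shapes)}")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def ids(self) -> list[str]:
        return [it.id for it in self.items]

    @property
    def manifest(self) -> pd.DataFrame:
        rows = []
        for it in self.items:
            row = {"id": it.id, "role": it.role}
            row.update(it.labels)
            rows.append(row)
        return pd.DataFrame(rows).set_index("id")

    def subset(self, role: str) -> "StimulusSet":
        return StimulusSet([it for it in self.items if it.role == role], self.modality)

    def item(self, item_id: str):
        for it in self.items:
            if it.id == item_id:
                return it
        raise KeyError(f"no stimulus with id {item_id!r}")


# ---------------------------------------------------------------------------
# loading / saving


def _read_image(path: Path, channels: int) -> np.ndarray:
    with Image.open(path) as img:
        arr = np.asarray(img, dtype=np.float64)
    if arr.dtype != np.float64:
        arr = arr.astype(np.float64)
    if arr.max() > 1.0:
        arr = arr / 255.0
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.shape[2] == 1 and channels > 1:
        arr = np.repeat(arr, channels, axis=2)
    elif arr.shape[2] == 4 and channels == 3:
        arr = arr[:, :, :3]
    elif arr.shape[2] > channels:
        arr = arr[:, :, :channels]
    return np.clip(arr, 0.0, 1.0)


def _read_video(path: Path, channels: int) -> np.ndarray:
    if path.is_dir():
        frame_files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff", ".jpg", ".jpeg")
        )
        if not frame_files:
            raise StimulusError(f"frame directory {path} contains no image files")
        frames = [_read_image(p, channels) for p in frame_files]
    else:
        import imageio.v3 as iio

        raw = iio.imread(path)  # (F, H, W[, C])
        raw = np.asarray(raw, dtype=np.float64)
        if raw.max() > 1.0:
            raw = raw / 255.0
        if raw.ndim == 3:
            raw = raw[:, :, :, None]
        if raw.shape[3] == 1 and channels > 1:
            raw = np.repeat(raw, channels, axis=3)
        elif raw.shape[3] > channels:
            raw = raw[:, :, :, :channels]
        frames = list(np.clip(raw, 0.0, 1.0))
    return np.stack(frames, axis=0)


def load_stimulus_set(source, manifest, channels: int = 3) -> StimulusSet:
    """Load a stimulus set from a directory of files plus a manifest CSV.

    The manifest needs at least ``id`` and ``role`` columns plus one condition
    label column.  ``id`` values name files in ``source`` (extension optional:
    ``<id>.png/.tif/.jpg/.mp4`` or a frame directory ``<id>/``).  Grayscale
    inputs are replicated to ``channels`` channels.
    """
    source = Path(source)
    table = pd.read_csv(manifest, dtype={"id": str})
    if "id" not in table.columns or "role" not in table.columns:
        raise StimulusError("manifest must contain 'id' and 'role' columns")
    label_cols = [c for c in table.columns if c not in ("id", "role")]
    if not label_cols:
        raise StimulusError("manifest must contain at least one condition label column")
    if table["id"].duplicated().any():
        dups = table.loc[table["id"].duplicated(), "id"].tolist()
        raise StimulusError(f"duplicate ids in manifest: {dups}")
    bad_roles = set(table["role"]) - {"train", "test"}
    if bad_roles:
        raise StimulusError(f"manifest roles outside {{train, test}}: {sorted(bad_roles)}")

    items = []
    modality = "image"
    for _, row in table.iterrows():
        sid = row["id"]
        candidates = [source / sid] + [
            source / f"{sid}{ext}" for ext in (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".mp4")
        ]
        path = next((p for p in candidates if p.exists()), None)
        if path is None:
            raise IOError(f"no stimulus file found for id {sid!r} under {source}")
        if path.is_dir() or path.suffix.lower() == ".mp4":
            pixels = _read_video(path, channels)
            modality = "video"
        else:
            pixels = _read_image(path, channels)
        labels = {c: row[c] for c in label_cols if not pd.isna(row[c])}
        items.append(StimulusItem(id=sid, pixels=pixels, labels=labels, role=row["role"]))
    return StimulusSet(items, modality=modality)


def save_stimulus_set(stimulus_set: StimulusSet, directory) -> Path:
    """Write items as PNGs (videos as frame directories) plus ``manifest.csv``.

    Inverse of :func:`load_stimulus_set` up to 8-bit quantization.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for it in stimulus_set:
        if it.is_video:
            frame_dir = directory / it.id
            frame_dir.mkdir(exist_ok=True)
            for f in range(it.n_frames):
                _write_png(it.pixels[f], frame_dir / f"frame_{f:05d}.png")
        else:
            _write_png(it.pixels, directory / f"{it.id}.png")
        row = {"id": it.id, "role": it.role}
        row.update(it.labels)
        rows.append(row)
    manifest_path = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path


def _write_png(arr: np.ndarray, path: Path) -> None:
    a = np.clip(np.rint(arr * 255.0), 0, 255).astype(np.uint8)
    if a.shape[2] == 1:
        a = a[:, :, 0]
    Image.fromarray(a).save(path)


# ---------------------------------------------------------------------------
# temporal binning


def bin_video_frames(video: StimulusItem, bin_length: int = 16, n_bins: int = 9) -> list[FrameBin]:
    """Cut a video into ``n_bins`` contiguous non-overlapping bins of
    ``bin_length`` frames each (defaults: nine 16-frame bins, i.e. the first
    144 of a 150-frame, 5-second clip).  Frames beyond ``bin_length * n_bins``
    are discarded.
    """
    if not video.is_video:
        raise StimulusError(f"stimulus {video.id!r} is not a video")
    needed = bin_length * n_bins
    if video.n_frames < needed:
        raise StimulusError(
            f"video {video.id!r} has {video.n_frames} frames; binning needs >= {needed}"
        )
    bins = []
    for k in range(n_bins):
        chunk = video.pixels[k * bin_length : (k + 1) * bin_length]
        bins.append(
            FrameBin(
                parent_id=video.id,
                bin_index=k,
                pixels=chunk,
                labels=dict(video.labels),
                role=video.role,
            )
        )
    return bins


# ---------------------------------------------------------------------------
# geometric preprocessing


def modal_border_value(pixels: np.ndarray) -> float:
    """Most frequent 8-bit-quantized intensity on the 1-px border (the default
    padding value; approximates the stimulus background)."""
    frame = pixels if pixels.ndim == 3 else pixels[0]
    border = np.concatenate(
        [frame[0].ravel(), frame[-1].ravel(), frame[:, 0].ravel(), frame[:, -1].ravel()]
    )
    quantized = np.rint(border * 255.0).astype(int)
    values, counts = np.unique(quantized, return_counts=True)
    return float(values[np.argmax(counts)]) / 255.0


def _resize_frame(frame: np.ndarray, target_px: int) -> np.ndarray:
    h, w, c = frame.shape
    if h != w:  # center-crop to square first
        s = min(h, w)
        top, left = (h - s) // 2, (w - s) // 2
        frame = frame[top : top + s, left : left + s]
    chans = []
    for ch in range(frame.shape[2]):
        img = Image.fromarray((frame[:, :, ch] * 255.0).astype(np.float32), mode="F")
        img = img.resize((target_px, target_px), Image.BILINEAR)
        chans.append(np.asarray(img, dtype=np.float64) / 255.0)
    return np.clip(np.stack(chans, axis=2), 0.0, 1.0)


def resize_for_rf(
    item: StimulusItem,
    target_px: int,
    canvas_px: int = 227,
    pad_value: float | None = None,
) -> StimulusItem:
    """Bilinearly resample the stimulus content to ``target_px`` square and
    center it on a ``canvas_px`` square filled with ``pad_value``.

    Used to shrink stimuli so that early-layer receptive fields cover a
    biologically matched extent in degrees of visual angle
    (see :data:`RF_SIZE_PRESETS_PX`).  Non-square frames are center-cropped to
    square before resampling.
    """
    if not (1 <= target_px <= canvas_px):
        raise StimulusError(
            f"target_px must satisfy 1 <= target_px <= canvas_px, got {target_px} > {canvas_px}"
        )
    if pad_value is None:
        pad_value = modal_border_value(item.pixels)
    frames = item.pixels if item.is_video else item.pixels[None]
    out_frames = []
    off = (canvas_px - target_px) // 2
    for frame in frames:
        content = _resize_frame(frame, target_px)
        canvas = np.full((canvas_px, canvas_px, frame.shape[2]), pad_value, dtype=np.float64)
        canvas[off : off + target_px, off : off + target_px] = content
        out_frames.append(canvas)
    pixels = np.stack(out_frames) if item.is_video else out_frames[0]
    labels = dict(item.labels)
    labels["content_px"] = target_px
    return replace(item, pixels=pixels, labels=labels)


def jitter_positions(
    item: StimulusItem,
    offsets: Sequence[tuple[int, int]],
    pad_value: float | None = None,
) -> list[StimulusItem]:
    """Translate the stimulus by each (dx, dy) pixel offset, padding vacated
    pixels, producing one labelled variant per offset.

    Emulates trial-to-trial variation of the retinal projection position.  An
    offset that would push content off the canvas raises an error.
    """
    if pad_value is None:
        pad_value = modal_border_value(item.pixels)
    h, w = item.pixels.shape[-3], item.pixels.shape[-2]
    variants = []
    for dx, dy in offsets:
        if abs(dx) >= w or abs(dy) >= h:
            raise StimulusError(
                f"offset ({dx}, {dy}) pushes content off the {h}x{w} canvas for {item.id!r}"
            )
        shifted = _shift_frames(item.pixels, dx, dy, pad_value)
        labels = dict(item.labels)
        labels["offset_px"] = (dx, dy)
        variants.append(
            replace(item, id=f"{item.id}@{dx:+d}{dy:+d}", pixels=shifted, labels=labels)
        )
    return variants


def _shift_frames(pixels: np.ndarray, dx: int, dy: int, pad_value: float) -> np.ndarray:
    out = np.full_like(pixels, pad_value)
    src_y = slice(max(0, -dy), pixels.shape[-3] - max(0, dy))
    src_x = slice(max(0, -dx), pixels.shape[-2] - max(0, dx))
    dst_y = slice(max(0, dy), pixels.shape[-3] - max(0, -dy))
    dst_x = slice(max(0, dx), pixels.shape[-2] - max(0, -dx))
    out[..., dst_y, dst_x, :] = pixels[..., src_y, src_x, :]
    return out
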