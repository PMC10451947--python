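"""Synthetic NIR finger-vein data, ROI preprocessing, and dataset splits.

Real acquisition images a finger under near-infrared light: deoxygenated
blood absorbs NIR, so veins appear as dark curvilinear strokes on a
brighter tissue background, re-imaged across capture sessions with small
translations, illumination changes and sensor noise.  The generator
emulates exactly that: each identity owns a fixed random vein skeleton
(a few smooth dark curves running along the finger, Gaussian-blurred
into soft-edged vessels over a smooth illumination background), and each
image re-renders the skeleton with a session brightness factor, a small
random planar translation and additive Gaussian noise.

Preprocessing follows the identification pipeline: the rectangular ROI
is zero-padded to a square (content centered on the short axis),
bilinearly resized to the network input size, and the gray channel is
replicated to three channels.  Splitting is per class, proportional to
integer ratios such as 4:1:1, disjoint and exhaustive.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter, shift as nd_shift


@dataclass(frozen=True)
class DatasetProtocol:
    """Closed-set identification protocol of a public vein database:
    every finger is its own class, imaged several times per session."""
    subjects: int
    fingers_per_subject: int
    images_per_finger_per_session: int
    sessions: int
    roi_size: tuple[int, int]
    split_ratios: tuple[int, int, int]

    @property
    def n_classes(self) -> int:
        return self.subjects * self.fingers_per_subject

    @property
    def n_images(self) -> int:
        return (self.n_classes * self.images_per_finger_per_session
                * self.sessions)


#: FV-USM: 123 subjects × 4 fingers, 6 images in each of 2 sessions,
#: 300×100 ROIs, 4:1:1 split.
FV_USM = DatasetProtocol(subjects=123, fingers_per_subject=4,
                         images_per_finger_per_session=6, sessions=2,
                         roi_size=(100, 300), split_ratios=(4, 1, 1))

#: PLUSVein-FV3 (one sensor subset): 60 subjects × 6 fingers,
#: 736×192 ROIs, 3:1:1 split.
PLUSVEIN_FV3 = DatasetProtocol(subjects=60, fingers_per_subject=6,
                               images_per_finger_per_session=5, sessions=1,
                               roi_size=(192, 736), split_ratios=(3, 1, 1))


@dataclass
class RoiImage:
    pixels: np.ndarray          # 2-D grayscale, values in [0, 1]
    identity_label: int
    session_tag: int

    @property
    def source_size(self) -> tuple[int, int]:
        return self.pixels.shape

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("ROI must be a non-empty 2-D array")
        if self.pixels.min() < -1e-6 or self.pixels.max() > 1 + 1e-6:
            raise ValueError("ROI pixel range must be [0, 1]")


@dataclass(frozen=True)
class SyntheticVeinConfig:
    n_identities: int = 50
    images_per_identity: int = 12
    n_sessions: int = 2
    roi_size: tuple[int, int] = (100, 300)     # (H, W), FV-USM-like ROI
    veins_per_finger: tuple[int, int] = (3, 6)
    vein_width_px: tuple[float, float] = (2.0, 4.5)
    max_translation_px: int = 3
    brightness_jitter: float = 0.08
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if min(self.n_identities, self.images_per_identity, self.n_sessions) < 1:
            raise ValueError("counts must be positive")
        if self.images_per_identity % self.n_sessions:
            raise ValueError("images_per_identity must divide into sessions")
        if min(self.roi_size) < 8:
            raise ValueError("degenerate roi_size")


@dataclass(frozen=True)
class SplitSpec:
    ratios: tuple[int, int, int] = (4, 1, 1)
    seed: int = 0

    def __post_init__(self):
        if any(r < 0 for r in self.ratios) or sum(self.ratios) < 1:
            raise ValueError("ratios must be non-negative with positive sum")


def _vein_skeleton(cfg: SyntheticVeinConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Render one identity's vein pattern: dark smooth curves on a
    bright tissue background with a gentle illumination gradient."""
    h, w = cfg.roi_size
    yy, xx = np.mgrid[0:h, 0:w]
    base = 0.60 + 0.08 * np.sin(np.pi * yy / h) \
        + rng.uniform(-0.05, 0.05) * (xx / w)
    img = base.astype(np.float64)
    n_veins = rng.integers(cfg.veins_per_finger[0], cfg.veins_per_finger[1] + 1)
    x = np.arange(w)
    for _ in range(n_veins):
        # smooth path across the long axis: random low-order cosine mix
        y0 = rng.uniform(0.12, 0.88) * h
        amp = rng.uniform(0.03, 0.12) * h
        freq = rng.uniform(0.5, 2.0)
        phase = rng.uniform(0, 2 * np.pi)
        drift = rng.uniform(-0.08, 0.08) * h
        path = y0 + amp * np.cos(2 * np.pi * freq * x / w + phase) \
            + drift * (x / w)
        width = rng.uniform(*cfg.vein_width_px)
        depth = rng.uniform(0.25, 0.40)
        dist = (yy - path[None, :]) ** 2
        img -= depth * np.exp(-dist / (2.0 * width ** 2))
    img = gaussian_filter(img, sigma=1.2)
    return np.clip(img, 0.0, 1.0)


def generate_synthetic_dataset(cfg: SyntheticVeinConfig) -> list[RoiImage]:
    """Reproducible multi-session synthetic vein dataset.

    Exactly ``n_identities * images_per_identity`` ROI images; within an
    identity all images share one skeleton and differ by session
    brightness, per-image translation (≤ max_translation_px per axis,
    zero fill) and sensor noise.
    """
    rng = np.random.default_rng(cfg.seed)
    images: list[RoiImage] = []
    per_session = cfg.images_per_identity // cfg.n_sessions
    for identity in range(cfg.n_identities):
        skeleton = _vein_skeleton(cfg, rng)
        for session in range(cfg.n_sessions):
            gain = 1.0 + rng.uniform(-cfg.brightness_jitter,
                                     cfg.brightness_jitter)
            for _ in range(per_session):
                dy, dx = rng.integers(-cfg.max_translation_px,
                                      cfg.max_translation_px + 1, size=2)
                frame = nd_shift(skeleton, (dy, dx), order=0, cval=0.0)
                frame = frame * gain + rng.normal(0.0, cfg.noise_sd,
                                                  skeleton.shape)
                images.append(RoiImage(np.clip(frame, 0.0, 1.0),
                                       identity_label=identity,
                                       session_tag=session))
    return images


def preprocess_roi(img: RoiImage | np.ndarray, target: int = 112) -> np.ndarray:
    """ROI -> model input: square zero-pad (centered), bilinear resize,
    gray replicated to 3 channels.  Returns (1, 3, target, target)."""
    pixels = img.pixels if isinstance(img, RoiImage) else np.asarray(img)
    if pixels.ndim != 2 or min(pixels.shape) < 1:
        raise ValueError("ROI must be a non-empty 2-D array")
    h, w = pixels.shape
    side = max(h, w)
    top = (side - h) // 2
    left = (side - w) // 2
    square = np.zeros((side, side), dtype=np.float32)
    square[top:top + h, left:left + w] = pixels
    pil = Image.fromarray(square, mode="F")
    resized = np.asarray(pil.resize((target, target), Image.BILINEAR),
                         dtype=np.float32)
    resized = np.clip(resized, 0.0, 1.0)
    return np.repeat(resized[None, None], 3, axis=1)


def preprocess_batch(images: list[RoiImage], target: int = 112) -> np.ndarray:
    return np.concatenate([preprocess_roi(im, target) for im in images], axis=0)


def labels_of(images: list[RoiImage]) -> np.ndarray:
    return np.array([im.identity_label for im in images], dtype=int)


def split_dataset(images: list[RoiImage], spec: SplitSpec
                  ) -> tuple[list[RoiImage], list[RoiImage], list[RoiImage]]:
    """Per-class proportional split into (train, val, test).

    Sizes follow the integer ratios exactly when they divide the class
    size; otherwise remainders go to the earlier splits by largest
    fractional part.  Splits are disjoint and exhaustive.
    """
    total = sum(spec.ratios)
    by_class: dict[int, list[int]] = {}
    for idx, im in enumerate(images):
        by_class.setdefault(im.identity_label, []).append(idx)
    rng = np.random.default_rng(spec.seed)
    out: tuple[list[RoiImage], ...] = ([], [], [])
    for label in sorted(by_class):
        idxs = np.array(by_class[label])
        if len(idxs) < total:
            raise ValueError(
                f"class {label} has {len(idxs)} images, fewer than the "
                f"{total} the split ratios require")
        rng.shuffle(idxs)
        quota = [len(idxs) * r / total for r in spec.ratios]
        counts = [int(q) for q in quota]
        rema = sorted(range(3), key=lambda i: (-(quota[i] - counts[i]), i))
        for i in rema[: len(idxs) - sum(counts)]:
            counts[i] += 1
        start = 0
        for part, c in zip(out, counts):
            part.extend(images[j] for j in idxs[start:start + c])
            start += c
    return out


# ---------------------------------------------------------------------------
# Disk layout: identity_<k>/session_<s>/img_<i>.png + manifest.csv
# ---------------------------------------------------------------------------

def save_dataset(images: list[RoiImage], root: Path | str) -> Path:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest = root / "manifest.csv"
    counters: dict[tuple[int, int], int] = {}
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label", "session"])
        for im in images:
            key = (im.identity_label, im.session_tag)
            i = counters.get(key, 0)
            counters[key] = i + 1
            rel = Path(f"identity_{im.identity_label:04d}") / \
                f"session_{im.session_tag}" / f"img_{i:03d}.png"
            path = root / rel
            path.parent.mkdir(parents=True, exist_ok=True)
            arr = np.round(im.pixels * 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(path)
            writer.writerow([str(rel), im.identity_label, im.session_tag])
    return manifest


def load_dataset(root: Path | str) -> list[RoiImage]:
    root = Path(root)
    images: list[RoiImage] = []
    with open(root / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            arr = np.asarray(Image.open(root / row["path"]).convert("L"),
                             dtype=np.float32) / 255.0
            images.append(RoiImage(arr, int(row["label"]), int(row["session"])))
    return images
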