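"""Synthetic chest-radiograph phantom generator.

Emits labeled, imbalanced two-class image datasets that stand in for a
pediatric chest X-ray collection: a bright thorax field with two darker
elliptical lung fields and periodic rib bands (the "normal" appearance), and
a positive class whose lung fields carry added bright structure mimicking
the radiographic signs of pneumonia — hazy infiltrates, small round nodules,
a contiguous lobar consolidation, a global lung-density lift, and a bright
pleural band along the lung boundary. Lesions only ever *increase* intensity
and only inside the lung masks, so with zero noise the two classes are
separable by a threshold on total added lung-field brightness: every
downstream training stage is testable at desk scale with no download.

Default class counts follow the emulated collection: 4,273 pneumonia and
1,583 normal images (ratio ~2.70); the desk preset scales this to 270/100 at
64x64 pixels. Generation is a pure function of (spec, seed): identical specs
give bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "LesionParams",
    "PhantomSpec",
    "ImageSample",
    "DEFAULT_SPEC",
    "DESK_SPEC",
    "generate_lung_phantom",
    "add_pneumonia_features",
    "generate_dataset",
    "split_dataset",
    "lung_masks",
]


class SpecError(ValueError):
    """Invalid phantom specification."""


class DatasetError(ValueError):
    """Invalid dataset request (empty dataset, infeasible split, ...)."""


@dataclass(frozen=True)
class LesionParams:
    """Pneumonia lesion configuration.

    n_infiltrates / n_nodules are per-image counts; consolidation_prob and
    pleural_band_prob are Bernoulli probabilities; density_shift in [0,1]
    scales a global lung-field brightness lift.
    """

    n_infiltrates: int = 2
    n_nodules: int = 3
    consolidation_prob: float = 0.5
    density_shift: float = 0.3
    pleural_band_prob: float = 0.3

    def validate(self) -> None:
        if self.n_infiltrates < 0 or self.n_nodules < 0:
            raise SpecError("lesion counts must be non-negative")
        for name in ("consolidation_prob", "density_shift", "pleural_band_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecError(f"{name} must be in [0,1], got {v}")

    def is_noop(self) -> bool:
        return (self.n_infiltrates == 0 and self.n_nodules == 0
                and self.consolidation_prob == 0.0 and self.density_shift == 0.0
                and self.pleural_band_prob == 0.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Full dataset specification; (spec, seed) -> dataset is pure."""

    image_size: int = 64
    channels: int = 1
    n_pneumonia: int = 4273
    n_normal: int = 1583
    lesion_params: LesionParams = field(default_factory=LesionParams)
    noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 16:
            raise SpecError(f"image_size must be >= 16, got {self.image_size}")
        if self.channels not in (1, 3):
            raise SpecError(f"channels must be 1 or 3, got {self.channels}")
        if self.n_pneumonia < 0 or self.n_normal < 0:
            raise SpecError("class counts must be non-negative")
        if self.noise_sd < 0:
            raise SpecError(f"noise_sd must be >= 0, got {self.noise_sd}")
        self.lesion_params.validate()


#: full-scale preset mirroring the emulated collection's class counts
DEFAULT_SPEC = PhantomSpec()
#: CPU-scale preset with the same ~2.70 imbalance ratio
DESK_SPEC = PhantomSpec(image_size=64, n_pneumonia=270, n_normal=100,
                        noise_sd=0.05)


@dataclass
class ImageSample:
    """One image with its binary label (1 = pneumonia, 0 = normal)."""

    pixels: np.ndarray
    label: int
    sample_id: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise SpecError(f"label must be 0 or 1, got {self.label}")
        if not np.isfinite(self.pixels).all():
            raise SpecError("pixels must be finite")


# intensity levels of the phantom template
_BACKGROUND = 0.50
_BODY = 0.85
_LUNG = 0.25
_RIB_AMP = 0.06


def lung_masks(image_size: int) -> np.ndarray:
    """Boolean union of the two axis-aligned elliptical lung fields."""
    n = image_size
    yy, xx = np.mgrid[0:n, 0:n]
    cy = 0.52 * n
    ay, ax = 0.30 * n, 0.14 * n
    mask = np.zeros((n, n), dtype=bool)
    for cx_frac in (0.32, 0.68):
        cx = cx_frac * n
        mask |= ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    return mask


def _body_mask(image_size: int) -> np.ndarray:
    n = image_size
    yy, xx = np.mgrid[0:n, 0:n]
    return (((yy - 0.55 * n) / (0.48 * n)) ** 2
            + ((xx - 0.5 * n) / (0.42 * n)) ** 2) <= 1.0


def generate_lung_phantom(spec: PhantomSpec,
                          rng: np.random.Generator) -> ImageSample:
    """One unlabeled normal-appearance phantom: bright thorax, darker lungs,
    periodic rib bands, additive Gaussian noise of sd ``spec.noise_sd``,
    clipped to [0,1]."""
    spec.validate()
    n = spec.image_size
    body = _body_mask(n)
    lungs = lung_masks(n)
    img = np.full((n, n), _BACKGROUND)
    img[body] = _BODY
    img[lungs] = _LUNG
    # periodic rib bands crossing the thorax
    rows = np.arange(n)
    ribs = _RIB_AMP * (np.sin(rows * 2.0 * np.pi / max(6, n // 8)) > 0.3)
    img += ribs[:, None] * body
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=(n, n))
    img = np.clip(img, 0.0, 1.0)
    return ImageSample(pixels=img, label=0, sample_id="phantom",
                       meta={"lung_mask": lungs, "is_phantom": True})


def _place_disjoint_discs(rng: np.random.Generator, mask: np.ndarray,
                          count: int, radii: tuple[int, int]) -> list[tuple[int, int, int]]:
    """Sample disc (cy, cx, r) inside mask, pairwise disjoint with margin."""
    coords = np.argwhere(mask)
    # margin > sqrt(2) guarantees no 8-adjacency between clipped discs
    for margin in (2.0, 1.5):
        placed: list[tuple[int, int, int]] = []
        attempts = 0
        while len(placed) < count and attempts < 1000 * max(1, count):
            attempts += 1
            cy, cx = coords[rng.integers(len(coords))]
            r = int(rng.integers(radii[0], radii[1] + 1))
            if any((cy - py) ** 2 + (cx - px) ** 2 <= (r + pr + margin) ** 2
                   for py, px, pr in placed):
                continue
            placed.append((int(cy), int(cx), r))
        if len(placed) == count:
            return placed
    raise SpecError(
        f"could not place {count} disjoint nodules inside the lung fields")


def add_pneumonia_features(image: ImageSample, lesion_params: LesionParams,
                           rng: np.random.Generator) -> ImageSample:
    """Add pneumonia signs inside the lung masks of a phantom.

    Additions (all non-negative, all restricted to the lung masks): Gaussian-
    blurred bright blobs (infiltrates), small bright discs (nodules), an
    optional contiguous lobar brightening (consolidation), a global lung
    density lift, and an optional bright band along the lung boundary
    (pleural thickening). Output clipped to [0,1].
    """
    lesion_params.validate()
    if "lung_mask" not in image.meta:
        raise SpecError("input is not a lung phantom (missing lung-mask metadata)")
    mask = image.meta["lung_mask"]
    n = mask.shape[0]
    add = np.zeros((n, n))
    record = {"n_infiltrates": lesion_params.n_infiltrates,
              "n_nodules": lesion_params.n_nodules,
              "consolidation": 0, "pleural_band": 0}
    coords = np.argwhere(mask)

    for _ in range(lesion_params.n_infiltrates):
        cy, cx = coords[rng.integers(len(coords))]
        blob = np.zeros((n, n))
        blob[cy, cx] = 1.0
        sigma = max(1.0, n / 20.0) * (0.8 + 0.4 * rng.random())
        blob = ndimage.gaussian_filter(blob, sigma)
        amp = 0.20 + 0.10 * rng.random()
        add += amp * blob / blob.max()

    if lesion_params.n_nodules > 0:
        rmax = max(1, n // 24)
        for cy, cx, r in _place_disjoint_discs(rng, mask,
                                               lesion_params.n_nodules,
                                               (1, rmax)):
            yy, xx = np.mgrid[0:n, 0:n]
            disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
            add += 0.35 * disc

    if rng.random() < lesion_params.consolidation_prob:
        record["consolidation"] = 1
        # lobar consolidation: brighten the lower half of one lung
        side = rng.integers(2)
        half = np.zeros((n, n), dtype=bool)
        half[n // 2:, : n // 2] = True
        if side:
            half = half[:, ::-1]
        add += 0.25 * (mask & half)

    add += 0.15 * lesion_params.density_shift

    if rng.random() < lesion_params.pleural_band_prob:
        record["pleural_band"] = 1
        band = mask & ~ndimage.binary_erosion(mask, iterations=max(1, n // 32))
        add += 0.30 * band

    out = np.clip(image.pixels + add * mask, 0.0, 1.0)
    meta = dict(image.meta)
    meta["lesions"] = record
    return ImageSample(pixels=out, label=1, sample_id=image.sample_id, meta=meta)


def _to_channels(img: np.ndarray, channels: int) -> np.ndarray:
    if channels == 1:
        return img
    return np.repeat(img[:, :, None], channels, axis=2)


def generate_dataset(spec: PhantomSpec) -> tuple[list[ImageSample], pd.DataFrame]:
    """Emit the full labeled dataset plus its manifest, shuffled by seed."""
    spec.validate()
    if spec.n_pneumonia + spec.n_normal == 0:
        raise DatasetError("empty dataset: both class counts are zero")
    rng = np.random.default_rng(spec.seed)
    samples: list[ImageSample] = []
    rows = []
    for i in range(spec.n_pneumonia):
        sid = f"pneu_{i:05d}"
        base = generate_lung_phantom(spec, rng)
        base.sample_id = sid
        sample = add_pneumonia_features(base, spec.lesion_params, rng)
        rec = sample.meta["lesions"]
        sample.pixels = _to_channels(sample.pixels, spec.channels)
        samples.append(sample)
        rows.append({"sample_id": sid, "label": 1, "split": "", **rec})
    for i in range(spec.n_normal):
        sid = f"norm_{i:05d}"
        sample = generate_lung_phantom(spec, rng)
        sample.sample_id = sid
        sample.pixels = _to_channels(sample.pixels, spec.channels)
        samples.append(sample)
        rows.append({"sample_id": sid, "label": 0, "split": "",
                     "n_infiltrates": 0, "n_nodules": 0,
                     "consolidation": 0, "pleural_band": 0})
    order = np.random.default_rng(spec.seed + 1).permutation(len(samples))
    samples = [samples[i] for i in order]
    manifest = pd.DataFrame([rows[i] for i in order]).reset_index(drop=True)
    return samples, manifest


def split_dataset(samples: list[ImageSample],
                  train_counts: tuple[int, int],
                  val_counts: tuple[int, int],
                  seed: int = 0) -> tuple[list[ImageSample], list[ImageSample]]:
    """Disjoint train/validation subsets with exact per-class counts.

    Counts are (n_pneumonia, n_normal). Raises a DatasetError naming the
    class whenever a request exceeds availability.
    """
    rng = np.random.default_rng(seed)
    by_class = {1: [s for s in samples if s.label == 1],
                0: [s for s in samples if s.label == 0]}
    names = {1: "pneumonia", 0: "normal"}
    train: list[ImageSample] = []
    val: list[ImageSample] = []
    for label, n_train, n_val in ((1, train_counts[0], val_counts[0]),
                                  (0, train_counts[1], val_counts[1])):
        pool = by_class[label]
        if n_train + n_val > len(pool):
            raise DatasetError(
                f"split needs {n_train + n_val} {names[label]} samples "
                f"but only {len(pool)} are available")
        order = rng.permutation(len(pool))
        train.extend(pool[i] for i in order[:n_train])
        val.extend(pool[i] for i in order[n_train:n_train + n_val])
    return train, val
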