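"""Dataset readers/writers, YAML configuration, and run manifests.

On-disk dataset layout mirrors the class-subfolder convention:
``<root>/pneumonia/*.png`` and ``<root>/normal/*.png`` plus a
``manifest.csv`` with columns
``sample_id,label,split,n_infiltrates,n_nodules,consolidation,pleural_band``.
Images are loaded with Pillow, converted to the configured channel count,
min-max rescaled per image to [0,1] and bilinearly resized to the configured
input size. Unreadable files are skipped with a logged warning (a stand-in
for the quality-exclusion step of a clinical pipeline); an empty class is an
error.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image, UnidentifiedImageError

from . import __version__
from .losses import LossConfigError
from .model_zoo import NetworkConfig
from .synthetic_xray import ImageSample, LesionParams, PhantomSpec
from .train_eval import TrainConfig

__all__ = [
    "CLASS_FOLDERS",
    "write_image_folder",
    "read_image_folder",
    "load_config",
    "RunManifest",
    "ConfigError",
]

logger = logging.getLogger(__name__)

#: subfolder name per label
CLASS_FOLDERS = {1: "pneumonia", 0: "normal"}


class ConfigError(ValueError):
    """Invalid or unknown configuration content; message names the field."""


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def write_image_folder(samples: list[ImageSample], manifest: pd.DataFrame,
                       root: str | Path) -> Path:
    """Write samples as 8-bit PNGs into class subfolders plus manifest.csv."""
    root = Path(root)
    for folder in CLASS_FOLDERS.values():
        (root / folder).mkdir(parents=True, exist_ok=True)
    for s in samples:
        px = s.pixels
        if px.ndim == 3 and px.shape[2] == 1:
            px = px[:, :, 0]
        arr = np.clip(np.round(px * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(root / CLASS_FOLDERS[s.label] / f"{s.sample_id}.png")
    cols = ["sample_id", "label", "split", "n_infiltrates", "n_nodules",
            "consolidation", "pleural_band"]
    manifest.to_csv(root / "manifest.csv", index=False, columns=cols)
    return root


def _load_one(path: Path, channels: int, size: int) -> np.ndarray:
    with Image.open(path) as im:
        im = im.convert("L" if channels == 1 else "RGB")
        im = im.resize((size, size), Image.BILINEAR)
        arr = np.asarray(im, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    return arr if channels == 1 else arr  # (H,W) or (H,W,3)


def read_image_folder(root: str | Path, channels: int = 1,
                      image_size: int = 64) -> list[ImageSample]:
    """Load a class-subfolder dataset, skipping unreadable files.

    Ordering is deterministic: pneumonia then normal, each sorted by name.
    """
    root = Path(root)
    samples: list[ImageSample] = []
    n_skipped = 0
    for label in (1, 0):
        folder = root / CLASS_FOLDERS[label]
        if not folder.is_dir():
            raise ConfigError(f"missing class folder {folder}")
        loaded = 0
        for path in sorted(folder.iterdir()):
            if path.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            try:
                px = _load_one(path, channels, image_size)
            except (OSError, UnidentifiedImageError, ValueError) as exc:
                n_skipped += 1
                logger.warning("skipping unreadable image %s: %s", path, exc)
                continue
            samples.append(ImageSample(pixels=px, label=label,
                                       sample_id=path.stem))
            loaded += 1
        if loaded == 0:
            raise ConfigError(
                f"class folder {folder} contains no readable images")
    if n_skipped:
        logger.warning("skipped %d unreadable image(s)", n_skipped)
    return samples


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def _build_section(cls, raw: dict, section: str, **extra):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {section}: {', '.join(sorted(unknown))}")
    try:
        return cls(**{**raw, **extra})
    except (TypeError, ValueError, LossConfigError) as exc:
        raise ConfigError(f"invalid {section} config: {exc}") from exc


def load_config(path: str | Path) -> dict:
    """Parse and validate a YAML config with sections model/loss/train/data.

    Returns ``{"model": NetworkConfig, "train": TrainConfig,
    "data": PhantomSpec}`` with loss settings folded into the TrainConfig.
    Unknown sections or keys are rejected with the offending name.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {"model", "loss", "train", "data"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown section(s): {', '.join(sorted(unknown))}")

    model_raw = dict(raw.get("model", {}))
    if "input_size" in model_raw:
        model_raw["input_size"] = tuple(model_raw["input_size"])
    model = _build_section(NetworkConfig, model_raw, "model")
    try:
        model.validate()
    except ValueError as exc:
        raise ConfigError(f"invalid model config: {exc}") from exc

    loss_raw = dict(raw.get("loss", {}))
    loss_name = loss_raw.pop("name", "cross_entropy")
    loss_map = {"alpha": "loss_alpha", "gamma": "loss_gamma",
                "count_mapping": "count_mapping"}
    unknown = set(loss_raw) - set(loss_map)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in loss: {', '.join('loss.' + k for k in sorted(unknown))}")
    if loss_name not in ("cross_entropy", "focal", "modified_focal"):
        raise ConfigError(f"invalid loss.name {loss_name!r}")
    if "gamma" in loss_raw and loss_raw["gamma"] < 0:
        raise ConfigError(f"invalid loss.gamma: must be >= 0, got {loss_raw['gamma']}")
    if "alpha" in loss_raw and not 0 < loss_raw["alpha"] < 1:
        raise ConfigError(f"invalid loss.alpha: must be in (0,1), got {loss_raw['alpha']}")

    train_raw = dict(raw.get("train", {}))
    train_raw.update({loss_map[k]: v for k, v in loss_raw.items()})
    train_raw["loss_name"] = loss_name
    train = _build_section(TrainConfig, train_raw, "train")
    try:
        train.validate()
    except RuntimeError as exc:
        raise ConfigError(f"invalid train config: {exc}") from exc

    data_raw = dict(raw.get("data", {}))
    if "lesion_params" in data_raw:
        data_raw["lesion_params"] = _build_section(
            LesionParams, dict(data_raw["lesion_params"]), "data.lesion_params")
    data = _build_section(PhantomSpec, data_raw, "data")
    try:
        data.validate()
    except ValueError as exc:
        raise ConfigError(f"invalid data config: {exc}") from exc

    return {"model": model, "train": train, "data": data}


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

class RunManifest:
    """Snapshot of everything needed to re-run a run bit-identically."""

    def __init__(self, config: dict, seed: int, artifacts: dict[str, str]):
        self.config = config
        self.seed = seed
        self.artifacts = artifacts
        self.version = __version__
        self.timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()

    def to_dict(self) -> dict:
        def enc(v):
            if dataclasses.is_dataclass(v):
                return dataclasses.asdict(v)
            return v
        return {
            "version": self.version,
            "seed": self.seed,
            "timestamp": self.timestamp,
            "config": {k: enc(v) for k, v in self.config.items()},
            "artifacts": self.artifacts,
        }

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, default=str) + "\n")
        return path
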