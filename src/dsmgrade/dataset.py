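"""Dataset preparation: bicubic resize, ×5 augmentation, 70/30 split, normalization.

A manifest is a pandas DataFrame with columns ``path,label,split,provenance``;
``provenance`` is ``original`` or one of the four augmentation variants
(``hflip``, ``vflip``, ``noise``, ``scale``).  Every original contributes
exactly 5 records, and the split assigns round-half-up 70% of each class
(of the *augmented* pool — augmentation happens before splitting) to training.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "DEFAULT_GRADE_LABELS",
    "AugmentConfig",
    "resize_bicubic",
    "augment_image",
    "build_augmented_set",
    "split_dataset",
    "train_count",
    "normalize_for_model",
    "read_manifest",
    "write_manifest",
]

#: The six quality grades: premium/first/second dried flower mushroom,
#: premium/first dried thick mushroom, premium dried thin mushroom.
DEFAULT_GRADE_LABELS = ("DFM-P", "DFM-1", "DFM-2", "PDM-TH", "DTHM-1", "PDM-Th")

MANIFEST_COLUMNS = ["path", "label", "split", "provenance"]
AUGMENT_PROVENANCES = ("hflip", "vflip", "noise", "scale")


@dataclass(frozen=True)
class AugmentConfig:
    """Parameters of the four augmentation variants.

    noise_sigma : Gaussian noise standard deviation in gray-level units
        (default 12.75 = 5% of the 0–255 range).
    scale_factor : equal-scale zoom factor; the zoomed image is re-cropped
        (or edge-padded, for factors < 1) back to the input size.
    seed : random stream for the noise variant.
    """

    noise_sigma: float = 12.75
    scale_factor: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be > 0")


def resize_bicubic(image: np.ndarray, target: int = 224) -> np.ndarray:
    """Bicubic resize of a square image to target×target, values clipped to [0, 255].

    Squareness is the segmentation module's contract; a non-square input is
    rejected rather than silently distorted.
    """
    arr = np.asarray(image)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError(f"input must be square, got {arr.shape[0]}×{arr.shape[1]}")
    if arr.shape[0] == target:
        return arr.copy()
    out = Image.fromarray(arr.astype(np.uint8)).resize((target, target), Image.BICUBIC)
    return np.clip(np.asarray(out), 0, 255).astype(np.uint8)


def _zoom(arr: np.ndarray, factor: float) -> np.ndarray:
    """Equal-scale center zoom, returned at the input size."""
    size = arr.shape[0]
    new = max(int(round(size * factor)), 1)
    img = Image.fromarray(arr.astype(np.uint8)).resize((new, new), Image.BICUBIC)
    zoomed = np.asarray(img)
    if new >= size:
        off = (new - size) // 2
        return zoomed[off : off + size, off : off + size].copy()
    pad = size - new
    lo, hi = pad // 2, pad - pad // 2
    widths = [(lo, hi), (lo, hi)] + [(0, 0)] * (zoomed.ndim - 2)
    return np.pad(zoomed, widths, mode="edge")


def augment_image(image: np.ndarray, config: AugmentConfig | None = None) -> list[np.ndarray]:
    """The four augmentation variants of one image.

    Returns ``[horizontal flip, vertical flip, Gaussian-noise copy,
    center zoom]`` in that order.  Noise is seeded and clipped to [0, 255].
    """
    config = config or AugmentConfig()
    arr = np.asarray(image)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("augment_image expects a square image")
    rng = np.random.default_rng(config.seed)
    hflip = arr[:, ::-1].copy()
    vflip = arr[::-1, :].copy()
    noise = arr.astype(np.float64) + rng.normal(0.0, config.noise_sigma, size=arr.shape)
    noise = np.clip(np.rint(noise), 0, 255).astype(np.uint8)
    return [hflip, vflip, noise, _zoom(arr, config.scale_factor)]


def build_augmented_set(
    originals: pd.DataFrame,
    out_dir: str | Path,
    config: AugmentConfig | None = None,
) -> pd.DataFrame:
    """Write the 4 variants of every original and return the ×5 manifest.

    ``originals`` needs columns ``path`` and ``label``; each row yields
    exactly 5 records (itself plus the four variants), so the output has
    5 × len(originals) rows.  Variant files are written as PNG next to
    ``out_dir`` and the noise stream is derived per-image from the config
    seed so the result is order-independent.
    """
    config = config or AugmentConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records: list[dict] = []
    for idx, row in enumerate(originals.itertuples(index=False)):
        src = Path(row.path)
        arr = np.asarray(Image.open(src))
        per_image = AugmentConfig(config.noise_sigma, config.scale_factor, config.seed + idx)
        records.append({"path": str(src), "label": row.label, "provenance": "original"})
        for tag, variant in zip(AUGMENT_PROVENANCES, augment_image(arr, per_image)):
            dst = out_dir / f"{src.stem}_{tag}.png"
            Image.fromarray(variant).save(dst)
            records.append({"path": str(dst), "label": row.label, "provenance": tag})
    df = pd.DataFrame.from_records(records)
    df["split"] = pd.NA
    return df[MANIFEST_COLUMNS]


def _round_half_up(x: decimal.Decimal) -> int:
    return int(x.quantize(decimal.Decimal(1), rounding=decimal.ROUND_HALF_UP))


def train_count(n: int, train_fraction: float = 0.7) -> int:
    """Round-half-up(train_fraction · n) — the per-class training count."""
    return _round_half_up(decimal.Decimal(str(train_fraction)) * n)


def split_dataset(
    manifest: pd.DataFrame,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign train/test tags per class by a seeded shuffle.

    Per class of size n the training set gets round-half-up(train_fraction·n)
    records and the test set the remainder; membership is a seeded
    within-class shuffle, so the split is deterministic and disjoint.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    out = manifest.copy()
    out["split"] = "test"
    for label in sorted(out["label"].unique()):
        idx = out.index[out["label"] == label].to_numpy()
        perm = rng.permutation(len(idx))
        n_train = train_count(len(idx), train_fraction)
        out.loc[idx[perm[:n_train]], "split"] = "train"
    return out


def normalize_for_model(image: np.ndarray) -> np.ndarray:
    """Map 0..255 pixels to [−1, 1]: x → (x/255 − 0.5)/0.5 (mean .5, sd .5)."""
    return ((np.asarray(image).astype(np.float32) / 255.0) - 0.5) / 0.5


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS[:2]) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False)
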