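"""Raster I/O: PNG/TIFF reading and writing, tiling of large images into
fixed-size windows, and persistence of masks and score tables.

Conventions: pixel coordinates are 0-based and row-major; tile windows are
half-open ``[row0, row0+height) × [col0, col0+width)``.  Mask PNGs encode
retained pixels as 255 and whitened-out pixels as 0.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .exceptions import FormatError, InvalidArgumentError

__all__ = [
    "TileWindow",
    "ScoreRecord",
    "read_image",
    "write_image",
    "tile_image",
    "write_mask",
    "read_mask",
    "write_scores",
    "read_scores",
    "write_metadata",
]

_SUPPORTED_FORMATS = {"PNG", "TIFF"}


@dataclass(frozen=True)
class TileWindow:
    """Half-open sub-image extent: rows [row0, row0+height), cols [col0, col0+width)."""

    row0: int
    col0: int
    height: int
    width: int


@dataclass(frozen=True)
class ScoreRecord:
    """One scored tile: its non-white-pixel fraction and quality verdict."""

    tile_id: str
    non_white_fraction: float
    label: str
    k: int
    feature_space: str
    reason: str = ""


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG or TIFF as an H×W×3 uint8 array.

    Grayscale images are promoted to 3 channels; an alpha channel is
    dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            if im.format not in _SUPPORTED_FORMATS:
                raise FormatError(f"unsupported image format {im.format!r} for {path}")
            if im.mode in ("RGBA", "LA", "PA"):
                im = im.convert("RGBA").convert("RGB")
            elif im.mode != "RGB":
                im = im.convert("RGB")
            return np.asarray(im, dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise FormatError(f"cannot decode image file {path}: {exc}") from exc


def write_image(image: np.ndarray, path: str | os.PathLike) -> Path:
    """Write an H×W×3 (or H×W) uint8 array as PNG/TIFF chosen by suffix."""
    path = Path(path)
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        raise InvalidArgumentError("image must be uint8")
    Image.fromarray(arr).save(path)
    return path


def tile_image(
    image: np.ndarray,
    tile: int,
    stride: int | None = None,
    keep_partial: bool = False,
) -> list[tuple[TileWindow, np.ndarray]]:
    """Cut an image into fixed-size windows, enumerated row-major.

    Partial edge windows are dropped by default; with ``keep_partial`` they
    are kept and zero-padded to the tile size.
    """
    arr = np.asarray(image)
    h, w = arr.shape[:2]
    stride = stride or tile
    if tile < 1 or stride < 1:
        raise InvalidArgumentError("tile and stride must be >= 1")
    if tile > h or tile > w:
        raise InvalidArgumentError(f"tile size {tile} exceeds image extent {h}x{w}")

    if keep_partial:
        rows = list(range(0, h, stride))
        cols = list(range(0, w, stride))
    else:
        rows = list(range(0, h - tile + 1, stride))
        cols = list(range(0, w - tile + 1, stride))

    out: list[tuple[TileWindow, np.ndarray]] = []
    for r in rows:
        for c in cols:
            patch = arr[r:r + tile, c:c + tile]
            ph, pw = patch.shape[:2]
            if (ph, pw) != (tile, tile):
                pad = [(0, tile - ph), (0, tile - pw)] + [(0, 0)] * (arr.ndim - 2)
                patch = np.pad(patch, pad)
            out.append((TileWindow(r, c, ph, pw), patch))
    return out


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> Path:
    """Write a boolean retain-mask as a single-channel PNG (255=retained)."""
    arr = np.asarray(mask, dtype=bool)
    return write_image((arr * 255).astype(np.uint8), path)


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a mask PNG back as a boolean array."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) >= 128


_SCORE_COLUMNS = ["tile_id", "non_white_fraction", "label", "k", "feature_space", "reason"]


def write_scores(records: Iterable[ScoreRecord], path: str | os.PathLike) -> Path:
    """Write score records as a tab-delimited table with header."""
    path = Path(path)
    df = pd.DataFrame(
        [(r.tile_id, r.non_white_fraction, r.label, r.k, r.feature_space, r.reason)
         for r in records],
        columns=_SCORE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_scores(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


def write_metadata(path: str | os.PathLike, **fields) -> Path:
    """Write a JSON run-metadata file (config echo, seeds, versions)."""
    import tileqc

    path = Path(path)
    payload = {"tileqc_version": getattr(tileqc, "__version__", "unknown"), **fields}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
    return path
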