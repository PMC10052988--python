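"""Synthetic H&E-like tile generator with known ground truth.

Real slide tiling produces a mixture of informative tiles (dense purple
nuclei on pink cytoplasm) and uninformative ones — blank glass, out-of-focus
smears, tissue folds, or fields with almost no tumor cells.  This module
renders that population programmatically: purple elliptical nuclei drawn on
eosin-pink cytoplasm blobs over a near-white background, with the exact
nucleus raster kept as ground truth.  Every tile is a pure function of its
spec (seed included), so downstream quality-control stages can be tested
against known labels without any slide data.

A tile's quality label is decided purely by its true nuclear coverage:
tiles whose nucleus raster covers at least ``label_threshold`` (default 5%)
of the pixels are *good*; everything else — blank, blurred, folded, or
sparsely populated fields — is *poor*.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse

from .exceptions import InvalidSpecError

__all__ = [
    "TileSpec",
    "LabeledTile",
    "SlideSpec",
    "DEFAULT_HEMATOXYLIN",
    "DEFAULT_EOSIN",
    "DEFAULT_BACKGROUND",
    "LABEL_THRESHOLD",
    "generate_tile",
    "generate_slide",
    "write_fixture_set",
]

DEFAULT_HEMATOXYLIN = (90, 60, 150)
DEFAULT_EOSIN = (230, 140, 170)
DEFAULT_BACKGROUND = (245, 243, 245)

#: Nuclear-coverage fraction at or above which a tile is labeled good.
LABEL_THRESHOLD = 0.05

ARTIFACTS = ("none", "blank", "blur", "fold")


@dataclass(frozen=True)
class TileSpec:
    """Recipe for one synthetic tile."""

    width: int = 128
    height: int = 128
    nuclear_density: float = 0.2
    artifact: str = "none"
    hematoxylin_color: tuple[int, int, int] = DEFAULT_HEMATOXYLIN
    eosin_color: tuple[int, int, int] = DEFAULT_EOSIN
    background_color: tuple[int, int, int] = DEFAULT_BACKGROUND
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 16 or self.height < 16:
            raise InvalidSpecError("tile dimensions must be at least 16x16")
        if not 0.0 <= self.nuclear_density <= 1.0:
            raise InvalidSpecError("nuclear_density must be in [0, 1]")
        if self.artifact not in ARTIFACTS:
            raise InvalidSpecError(f"unknown artifact {self.artifact!r}; choose from {ARTIFACTS}")


@dataclass(frozen=True)
class LabeledTile:
    """A rendered tile with its ground-truth nuclear coverage and label."""

    image: np.ndarray
    true_nuclear_fraction: float
    quality_label: str
    spec: TileSpec
    nucleus_mask: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class SlideSpec:
    """Recipe for a tile collection with a fixed poor-quality mixture."""

    n_tiles: int = 100
    fraction_poor: float = 0.3
    tile_spec_template: TileSpec = field(default_factory=TileSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tiles < 1:
            raise InvalidSpecError("n_tiles must be >= 1")
        if not 0.0 <= self.fraction_poor <= 1.0:
            raise InvalidSpecError("fraction_poor must be in [0, 1]")

    @property
    def n_poor(self) -> int:
        return int(round(self.n_tiles * self.fraction_poor))


def _jitter_color(rng: np.random.Generator, color: Sequence[int], amount: int) -> np.ndarray:
    c = np.asarray(color, dtype=float) + rng.integers(-amount, amount + 1, size=3)
    return np.clip(c, 0, 255)


def _draw_eosin(rng: np.random.Generator, canvas: np.ndarray, spec: TileSpec) -> None:
    """Paint soft cytoplasm blobs covering very roughly 40% of the tile."""
    h, w = canvas.shape[:2]
    target = 0.4 * h * w
    painted = np.zeros((h, w), dtype=bool)
    for _ in range(200):
        if painted.sum() >= target:
            break
        r0, c0 = rng.integers(0, h), rng.integers(0, w)
        ra = rng.integers(max(4, h // 10), max(6, h // 4))
        rb = rng.integers(max(4, w // 10), max(6, w // 4))
        rr, cc = ellipse(r0, c0, ra, rb, shape=(h, w), rotation=rng.uniform(0, np.pi))
        canvas[rr, cc] = _jitter_color(rng, spec.eosin_color, 8)
        painted[rr, cc] = True


def _draw_nuclei(rng: np.random.Generator, canvas: np.ndarray, spec: TileSpec) -> np.ndarray:
    """Add elliptical nuclei until coverage reaches the requested density."""
    h, w = canvas.shape[:2]
    mask = np.zeros((h, w), dtype=bool)
    if spec.nuclear_density <= 0:
        return mask
    rmin = max(3, min(h, w) // 40)
    rmax = max(rmin + 1, min(h, w) // 16)
    max_attempts = int(50 * spec.nuclear_density * h * w / (np.pi * rmin * rmin)) + 200
    for _ in range(max_attempts):
        remaining = spec.nuclear_density - mask.mean()
        if remaining <= 0:
            break
        # shrink trailing nuclei toward the remaining coverage budget so a
        # sparse tile cannot overshoot its requested density by a whole
        # full-size nucleus
        r_fit = int(np.ceil(np.sqrt(remaining * h * w / np.pi)))
        hi = max(2, min(rmax, r_fit))
        lo = min(rmin, hi)
        r0, c0 = rng.integers(0, h), rng.integers(0, w)
        ra = rng.integers(lo, hi + 1)
        rb = rng.integers(lo, hi + 1)
        rr, cc = ellipse(r0, c0, ra, rb, shape=(h, w), rotation=rng.uniform(0, np.pi))
        canvas[rr, cc] = _jitter_color(rng, spec.hematoxylin_color, 10)
        mask[rr, cc] = True
    return mask


def _apply_fold(rng: np.random.Generator, canvas: np.ndarray) -> None:
    """Dark saturated band across the tile, mimicking a tissue fold."""
    h, w = canvas.shape[:2]
    band = max(2, int(round(0.025 * h)))
    r0 = rng.integers(0, h - band + 1)
    shade = np.array([45, 25, 65], dtype=float) + rng.integers(-10, 11, size=3)
    canvas[r0:r0 + band, :] = np.clip(shade, 0, 255)


def generate_tile(spec: TileSpec) -> LabeledTile:
    """Render one tile deterministically from its spec.

    Artifacts are applied after tissue rendering: ``blank`` suppresses all
    tissue, ``blur`` Gaussian-smooths the rendered tile (out-of-focus),
    ``fold`` overlays a dark saturated band.  The true nuclear fraction is
    counted from the generator's own nucleus raster, not estimated.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    canvas = np.asarray(spec.background_color, dtype=float) * np.ones((h, w, 3))
    canvas += rng.integers(-3, 4, size=(h, w, 1))

    if spec.artifact == "blank":
        mask = np.zeros((h, w), dtype=bool)
    else:
        _draw_eosin(rng, canvas, spec)
        mask = _draw_nuclei(rng, canvas, spec)
        if spec.artifact == "blur":
            sigma = 0.03 * min(h, w)
            canvas = ndimage.gaussian_filter(canvas, sigma=(sigma, sigma, 0))
        elif spec.artifact == "fold":
            _apply_fold(rng, canvas)

    image = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    frac = float(mask.mean())
    label = "good" if frac >= LABEL_THRESHOLD else "poor"
    return LabeledTile(image=image, true_nuclear_fraction=frac,
                       quality_label=label, spec=spec, nucleus_mask=mask)


# Poor-tile class mixture: the slide never characterizes its poor classes
# beyond listing them, so density ranges are chosen to keep every poor class
# safely below the labeling threshold and every good tile safely above it.
_POOR_CLASSES = ("blank", "blur", "fold", "lowdensity")
_POOR_DENSITY = {"blank": (0.0, 0.0), "blur": (0.0, 0.02),
                 "fold": (0.0, 0.01), "lowdensity": (0.005, 0.03)}
_GOOD_DENSITY = (0.10, 0.40)


def generate_slide(spec: SlideSpec) -> list[LabeledTile]:
    """Generate a tile collection with exactly ``round(n·fraction_poor)``
    poor tiles, per-tile seeds derived from the slide seed."""
    rng = np.random.default_rng(spec.seed)
    n_poor = spec.n_poor
    statuses = np.array(["poor"] * n_poor + ["good"] * (spec.n_tiles - n_poor))
    rng.shuffle(statuses)
    seeds = rng.integers(0, 2**31 - 1, size=spec.n_tiles)

    tiles: list[LabeledTile] = []
    for status, tile_seed in zip(statuses, seeds):
        if status == "poor":
            cls = _POOR_CLASSES[rng.integers(len(_POOR_CLASSES))]
            lo, hi = _POOR_DENSITY[cls]
            density = float(rng.uniform(lo, hi)) if hi > lo else lo
            artifact = "none" if cls == "lowdensity" else cls
        else:
            density = float(rng.uniform(*_GOOD_DENSITY))
            artifact = "none"
        tile_spec = replace(spec.tile_spec_template, nuclear_density=density,
                            artifact=artifact, seed=int(tile_seed))
        tile = generate_tile(tile_spec)
        if tile.quality_label != status:  # pragma: no cover - construction guard
            raise RuntimeError(
                f"rendered label {tile.quality_label} disagrees with intended {status} "
                f"(fraction {tile.true_nuclear_fraction:.4f})"
            )
        tiles.append(tile)
    return tiles


def tile_digest(tile: LabeledTile) -> str:
    """SHA-256 of the raw pixel bytes (for determinism checks)."""
    return hashlib.sha256(tile.image.tobytes()).hexdigest()


def write_fixture_set(tiles: Iterable[LabeledTile], directory: str | os.PathLike) -> Path:
    """Write one PNG per tile plus a tab-delimited manifest; returns the
    manifest path."""
    from . import raster  # local import to avoid a cycle at import time

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.tsv"
    rows = []
    for i, tile in enumerate(tiles):
        name = f"tile_{i:04d}.png"
        raster.write_image(tile.image, directory / name)
        rows.append((name, tile.quality_label,
                     f"{tile.true_nuclear_fraction:.6f}", str(tile.spec.seed)))
    with open(manifest, "w") as fh:
        fh.write("filename\tlabel\ttrue_nuclear_fraction\tseed\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
    return manifest
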