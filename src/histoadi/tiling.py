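"""Slide-to-tile conversion: rescaling, gridding, background removal.

A slide is rescaled from its native resolution to a target of 0.5
microns per pixel (bilinear), covered by a non-overlapping grid of
224x224 tiles (partial edge tiles dropped), and each tile is screened by
the background rule: global-average-pool the tile to a single pixel and
call the tile background when the mean of the three pooled channel
values exceeds 200 (strictly). Kept tiles can then be intensity
normalized for a classifier.

The background filter is applied after rescaling; its gray statistic is
the unweighted mean of the three channel means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from skimage.transform import resize

DEFAULT_TILE_PX = 224
DEFAULT_TARGET_MPP = 0.5
DEFAULT_BACKGROUND_THRESHOLD = 200.0


@dataclass
class SlideImage:
    """An in-memory slide: H x W x 3 8-bit pixels plus declared mpp."""

    slide_id: str
    pixels: np.ndarray
    mpp: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"slide pixels must be HxWx3, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("slide must have at least one pixel")
        if px.dtype != np.uint8:
            raise ValueError("slide pixels must be 8-bit (uint8)")
        if self.mpp <= 0:
            raise ValueError("mpp must be > 0")
        self.pixels = px


@dataclass(frozen=True)
class TileGrid:
    """Non-overlapping tile layout in the rescaled pixel frame.

    ``coordinates`` holds (row, col) grid indices, 0-based and row-major;
    the pixel origin of tile (r, c) is (r * tile_px, c * tile_px) in the
    rescaled frame (half-open intervals).
    """

    tile_px: int
    target_mpp: float
    scale_factor: float
    n_rows: int
    n_cols: int

    @property
    def coordinates(self) -> list[tuple[int, int]]:
        return [(r, c) for r in range(self.n_rows) for c in range(self.n_cols)]

    def __len__(self) -> int:
        return self.n_rows * self.n_cols


@dataclass
class Tile:
    """One 224x224 tile with its grid position and background status."""

    slide_id: str
    row: int
    col: int
    pixels: np.ndarray  # uint8
    gray_value: float = field(init=False)
    is_background: bool = field(init=False)

    def __post_init__(self) -> None:
        self.gray_value = tile_gray_value(self.pixels)
        self.is_background = self.gray_value > DEFAULT_BACKGROUND_THRESHOLD


@dataclass(frozen=True)
class NormalizationStats:
    """Per-channel mean/std on the unit scale (pixel values / 255)."""

    mean: tuple[float, float, float]
    std: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.std):
            raise ValueError("normalization std must be > 0 per channel")


@dataclass
class TilingReport:
    """Bookkeeping for one slide: kept + background == total, always."""

    slide_id: str
    n_total: int
    n_background: int
    n_kept: int


def tile_gray_value(pixels: np.ndarray) -> float:
    """Gray value of a tile: global average pool to 1x1, then mean of RGB."""
    pooled = np.asarray(pixels, dtype=float).mean(axis=(0, 1))
    return float(pooled.mean())


def is_background(
    pixels: np.ndarray, threshold: float = DEFAULT_BACKGROUND_THRESHOLD
) -> bool:
    """True iff the tile's pooled gray value strictly exceeds ``threshold``.

    A tile whose gray value equals the threshold exactly is kept.
    """
    return tile_gray_value(pixels) > threshold


def rescale_slide(slide: SlideImage, target_mpp: float = DEFAULT_TARGET_MPP) -> np.ndarray:
    """Resample the slide to the target resolution (bilinear), 8-bit output."""
    scale = slide.mpp / target_mpp
    if scale == 1.0:
        return slide.pixels
    h, w = slide.pixels.shape[:2]
    out_shape = (max(int(round(h * scale)), 1), max(int(round(w * scale)), 1))
    resized = resize(
        slide.pixels.astype(float), out_shape, order=1, mode="edge", anti_aliasing=False
    )
    return np.clip(np.rint(resized), 0, 255).astype(np.uint8)


def make_grid(
    slide: SlideImage,
    tile_px: int = DEFAULT_TILE_PX,
    target_mpp: float = DEFAULT_TARGET_MPP,
) -> TileGrid:
    """Tile layout of the slide after rescaling to ``target_mpp``.

    The grid is the largest array of non-overlapping ``tile_px`` squares
    fully inside the rescaled image; partial edge tiles are dropped. A
    slide smaller than one tile yields an empty grid with a warning.
    """
    if target_mpp <= 0:
        raise ValueError("target_mpp must be > 0")
    if tile_px < 1:
        raise ValueError("tile_px must be >= 1")
    scale = slide.mpp / target_mpp
    h = max(int(round(slide.pixels.shape[0] * scale)), 1)
    w = max(int(round(slide.pixels.shape[1] * scale)), 1)
    n_rows, n_cols = h // tile_px, w // tile_px
    if n_rows == 0 or n_cols == 0:
        warnings.warn(
            f"slide {slide.slide_id!r} is smaller than one {tile_px}px tile "
            f"after rescaling ({h}x{w}); empty grid",
            stacklevel=2,
        )
        n_rows = n_cols = 0
    return TileGrid(
        tile_px=tile_px,
        target_mpp=target_mpp,
        scale_factor=scale,
        n_rows=n_rows,
        n_cols=n_cols,
    )


def normalize_tile(pixels: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Per-channel (x/255 - mean)/std; returns a float array, input untouched."""
    x = np.asarray(pixels, dtype=float) / 255.0
    mean = np.asarray(stats.mean, dtype=float)
    std = np.asarray(stats.std, dtype=float)
    return (x - mean) / std


def denormalize_tile(normalized: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Inverse of :func:`normalize_tile`, back to the 0-255 float scale."""
    mean = np.asarray(stats.mean, dtype=float)
    std = np.asarray(stats.std, dtype=float)
    return (np.asarray(normalized, dtype=float) * std + mean) * 255.0


def iter_tiles(
    slide: SlideImage,
    tile_px: int = DEFAULT_TILE_PX,
    target_mpp: float = DEFAULT_TARGET_MPP,
) -> Iterator[Tile]:
    """All grid tiles (background included), row-major order."""
    grid = make_grid(slide, tile_px=tile_px, target_mpp=target_mpp)
    rescaled = rescale_slide(slide, target_mpp=target_mpp)
    for r, c in grid.coordinates:
        block = rescaled[r * tile_px : (r + 1) * tile_px, c * tile_px : (c + 1) * tile_px]
        yield Tile(slide_id=slide.slide_id, row=r, col=c, pixels=block)


def tile_slide(
    slide: SlideImage,
    tile_px: int = DEFAULT_TILE_PX,
    target_mpp: float = DEFAULT_TARGET_MPP,
    background_threshold: float = DEFAULT_BACKGROUND_THRESHOLD,
) -> tuple[list[Tile], TilingReport]:
    """Grid, filter and return the kept (non-background) tiles of a slide.

    Returns the kept tiles in row-major order plus a report whose counts
    satisfy ``n_kept + n_background == n_total``.
    """
    kept: list[Tile] = []
    n_total = n_background = 0
    for tile in iter_tiles(slide, tile_px=tile_px, target_mpp=target_mpp):
        n_total += 1
        if tile.gray_value > background_threshold:
            tile.is_background = True
            n_background += 1
        else:
            tile.is_background = False
            kept.append(tile)
    report = TilingReport(
        slide_id=slide.slide_id,
        n_total=n_total,
        n_background=n_background,
        n_kept=len(kept),
    )
    return kept, report


def compute_normalization_stats(tiles: list[np.ndarray]) -> NormalizationStats:
    """Per-channel mean/std (unit scale) over a collection of tiles."""
    if not tiles:
        raise ValueError("need at least one tile to compute statistics")
    stack = np.stack([np.asarray(t, dtype=float) / 255.0 for t in tiles])
    mean = stack.mean(axis=(0, 1, 2))
    std = stack.std(axis=(0, 1, 2))
    if np.any(std <= 0):
        raise ValueError("degenerate tiles: zero variance in a channel")
    return NormalizationStats(mean=tuple(mean), std=tuple(std))
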