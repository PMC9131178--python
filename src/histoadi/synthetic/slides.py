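"""Mosaic slides assembled from synthetic tissue tiles.

A synthetic slide is a rectangular grid of 224x224 textured tiles with a
known label for every grid cell. The interior composition is apportioned
exactly by the largest-remainder rule, an optional border of pure
background tiles emulates the empty glass around a tissue section, and
the whole construction is reproducible from the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from histoadi.labels import CLASS_LABELS, check_label
from histoadi.synthetic.textures import TILE_PX, default_texture, generate_tile


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Ground-truth description of a mosaic slide.

    ``composition`` maps class labels to interior tile fractions (must sum
    to 1 within 1e-9). ``background_margin_tiles`` is the width, in tiles,
    of a pure-BACK border framing the composed interior; the composition
    applies to the interior only. ``mpp`` is the declared resolution of
    the rendered pixels (microns per pixel).
    """

    grid_rows: int
    grid_cols: int
    composition: dict[str, float]
    mpp: float = 0.5
    background_margin_tiles: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid must have at least one tile")
        if self.mpp <= 0:
            raise ValueError("mpp must be > 0")
        if self.background_margin_tiles < 0:
            raise ValueError("background_margin_tiles must be >= 0")
        for lab, frac in self.composition.items():
            check_label(lab)
            if frac < 0:
                raise ValueError(f"composition fraction for {lab} is negative")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition fractions sum to {total!r}, not 1")
        m = self.background_margin_tiles
        if self.grid_rows - 2 * m < 1 or self.grid_cols - 2 * m < 1:
            raise ValueError("background margin leaves no interior tiles")


@dataclass
class SyntheticSlide:
    """A rendered slide plus its ground truth."""

    slide_id: str
    image: np.ndarray  # (rows*224, cols*224, 3) uint8
    labels: np.ndarray  # (rows, cols) of class-label strings
    mpp: float
    spec: SyntheticSlideSpec

    @property
    def interior_fraction(self) -> dict[str, float]:
        """Realized per-class fraction over non-margin tiles."""
        m = self.spec.background_margin_tiles
        rows, cols = self.labels.shape
        interior = self.labels[m : rows - m or None, m : cols - m or None]
        labs, counts = np.unique(interior, return_counts=True)
        n = interior.size
        return {str(lab): int(c) / n for lab, c in zip(labs, counts)}


def largest_remainder_counts(composition: dict[str, float], n: int) -> dict[str, int]:
    """Apportion ``n`` tiles to classes by the largest-remainder rule.

    Each class first receives floor(fraction * n); the leftover tiles go
    one each to the classes with the largest fractional remainders, ties
    broken by canonical class order. The result sums to ``n`` exactly and
    equals round(fraction * n) whenever the fractions are exact.
    """
    order = [lab for lab in CLASS_LABELS if lab in composition]
    quotas = {lab: composition[lab] * n for lab in order}
    counts = {lab: int(np.floor(quotas[lab])) for lab in order}
    leftover = n - sum(counts.values())
    by_remainder = sorted(
        order, key=lambda lab: (-(quotas[lab] - counts[lab]), CLASS_LABELS.index(lab))
    )
    for lab in by_remainder[:leftover]:
        counts[lab] += 1
    return counts


def generate_slide(spec: SyntheticSlideSpec, slide_id: str = "synthetic") -> SyntheticSlide:
    """Render a mosaic slide and its ground-truth label grid.

    Interior labels are apportioned by :func:`largest_remainder_counts`
    and placed uniformly at random (seeded); each tile is rendered with a
    sub-seed derived from the spec seed and the tile's grid index, so any
    single tile can be re-rendered independently.
    """
    rows, cols = spec.grid_rows, spec.grid_cols
    m = spec.background_margin_tiles
    irows, icols = rows - 2 * m, cols - 2 * m
    n_interior = irows * icols

    counts = largest_remainder_counts(spec.composition, n_interior)
    flat = [lab for lab in CLASS_LABELS for _ in range(counts.get(lab, 0))]
    rng = np.random.default_rng(np.random.SeedSequence([0x51DE, spec.seed & 0x7FFFFFFF]))
    rng.shuffle(flat)

    labels = np.full((rows, cols), "BACK", dtype="<U4")
    labels[m : m + irows, m : m + icols] = np.array(flat, dtype="<U4").reshape(
        irows, icols
    )

    image = np.empty((rows * TILE_PX, cols * TILE_PX, 3), dtype=np.uint8)
    for r in range(rows):
        for c in range(cols):
            sub_seed = (spec.seed * 1_000_003 + r * cols + c) & 0x7FFFFFFF
            params = default_texture(str(labels[r, c]), seed=sub_seed)
            image[
                r * TILE_PX : (r + 1) * TILE_PX, c * TILE_PX : (c + 1) * TILE_PX
            ] = generate_tile(params)
    return SyntheticSlide(slide_id=slide_id, image=image, labels=labels, mpp=spec.mpp, spec=spec)
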