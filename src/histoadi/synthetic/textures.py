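"""Parametric tissue textures for the nine colorectal tile classes.

The textures are geometric primitives (disks, rings, ellipses, stripes,
speckle) in class-specific palettes -- not learned models and not a stain
simulation. Each class is built to be visually and statistically
separable by simple image features, which is what a desk-scale reference
classifier needs; realism is a non-goal. Recipes, roughly:

=====  =========================================================
ADI    large white fat vacuoles with thin pink borders on pink
BACK   near-uniform near-white (mean gray > 200, so the
       background filter removes it)
DEB    granular pink-gray speckle, heavy pixel noise
LYM    dense small dark-blue dots (lymphocyte nuclei) on pink
MUC    pale blue wash with soft lighter patches
MUS    thick horizontal deep-pink fibers
NORM   ring-shaped gland outlines on light pink
STR    thin diagonal pink fibers
TUM    crowded dark-purple ellipses (tumor nuclei)
=====  =========================================================

Every non-background class keeps its tile-mean gray value safely below
the 200 background threshold, so foreground tissue survives the
background filter just as real tissue tiles do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk, ellipse

from histoadi.labels import check_label

TILE_PX = 224

RGB = tuple[int, int, int]


@dataclass(frozen=True)
class TextureParams:
    """Recipe for one synthetic tile.

    Parameters
    ----------
    class_label:
        One of the nine canonical tissue classes.
    base_color, element_color, accent_color:
        RGB triples (0-255) for the background wash, the primitive
        elements, and element outlines/highlights.
    element_density:
        Number of primitive shapes drawn on the tile (0 for BACK).
    element_size_px:
        Inclusive (min, max) radius range of the primitives, in pixels.
    noise_sd:
        Standard deviation of additive Gaussian pixel noise.
    seed:
        Seed of the tile's private RNG stream; identical params + seed
        give a bit-identical tile.
    """

    class_label: str
    base_color: RGB
    element_color: RGB
    accent_color: RGB = (0, 0, 0)
    element_density: int = 0
    element_size_px: tuple[int, int] = (1, 1)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        check_label(self.class_label)
        if self.element_density < 0:
            raise ValueError("element_density must be >= 0")
        for c in (self.base_color, self.element_color, self.accent_color):
            if not all(0 <= v <= 255 for v in c):
                raise ValueError(f"RGB values must be in [0, 255], got {c}")
        lo, hi = self.element_size_px
        if not (1 <= lo <= hi):
            raise ValueError("element_size_px must satisfy 1 <= min <= max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# Per-class defaults.  Tile-mean gray values (mean over pixels and
# channels) land near: BACK 245, ADI 190, TUM 130, LYM 178, STR 190,
# MUS 150, NORM 192, MUC 192, DEB 168 -- all foreground classes < 200.
_DEFAULTS: dict[str, dict] = {
    "ADI": dict(
        base_color=(190, 140, 170),
        element_color=(246, 243, 248),
        accent_color=(214, 120, 168),
        element_density=9,
        element_size_px=(18, 30),
        noise_sd=4.0,
    ),
    "BACK": dict(
        base_color=(245, 243, 246),
        element_color=(245, 243, 246),
        element_density=0,
        noise_sd=2.0,
    ),
    "DEB": dict(
        base_color=(184, 160, 164),
        element_color=(120, 96, 100),
        accent_color=(216, 196, 196),
        element_density=60,
        element_size_px=(2, 5),
        noise_sd=30.0,
    ),
    "LYM": dict(
        base_color=(212, 184, 204),
        element_color=(40, 45, 110),
        element_density=320,
        element_size_px=(2, 4),
        noise_sd=4.0,
    ),
    "MUC": dict(
        base_color=(172, 196, 216),
        element_color=(155, 185, 210),
        accent_color=(192, 212, 228),
        element_density=8,
        element_size_px=(20, 35),
        noise_sd=3.0,
    ),
    "MUS": dict(
        base_color=(206, 148, 168),
        element_color=(168, 92, 118),
        element_density=22,  # stripe count over the tile height
        element_size_px=(4, 6),
        noise_sd=5.0,
    ),
    "NORM": dict(
        base_color=(204, 174, 190),
        element_color=(218, 196, 208),
        accent_color=(150, 88, 130),
        element_density=12,
        element_size_px=(14, 24),
        noise_sd=4.0,
    ),
    "STR": dict(
        base_color=(214, 182, 200),
        element_color=(188, 128, 164),
        element_density=18,  # diagonal stripe count
        element_size_px=(5, 8),
        noise_sd=5.0,
    ),
    "TUM": dict(
        base_color=(150, 105, 155),
        element_color=(92, 48, 112),
        element_density=90,
        element_size_px=(4, 9),
        noise_sd=6.0,
    ),
}


def default_texture(class_label: str, seed: int = 0) -> TextureParams:
    """Default :class:`TextureParams` for a class, with the given seed."""
    check_label(class_label)
    return TextureParams(class_label=class_label, seed=seed, **_DEFAULTS[class_label])


def _jitter_color(rng: np.random.Generator, color: RGB, amount: int = 8) -> np.ndarray:
    c = np.asarray(color, dtype=float) + rng.uniform(-amount, amount, size=3)
    return np.clip(c, 0, 255)


def _draw_disks(
    img: np.ndarray,
    rng: np.random.Generator,
    n: int,
    radii: tuple[int, int],
    color: RGB,
    jitter: int = 8,
) -> None:
    h, w = img.shape[:2]
    for _ in range(n):
        r = rng.integers(radii[0], radii[1] + 1)
        cy, cx = rng.integers(0, h), rng.integers(0, w)
        rr, cc = disk((cy, cx), r, shape=(h, w))
        img[rr, cc] = _jitter_color(rng, color, jitter)


def _draw_stripes(
    img: np.ndarray,
    rng: np.random.Generator,
    n_stripes: int,
    width: tuple[int, int],
    color: RGB,
    diagonal: bool,
) -> None:
    """Oriented fibers: horizontal bands, or 45-degree bands if diagonal."""
    h, w = img.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    coord = (yy + xx) if diagonal else yy
    span = int(coord.max()) + 1
    period = max(span // max(n_stripes, 1), 2)
    for k in range(0, span, period):
        wdt = int(rng.integers(width[0], width[1] + 1))
        off = int(rng.integers(0, max(period - wdt, 1)))
        mask = (coord >= k + off) & (coord < k + off + wdt)
        img[mask] = _jitter_color(rng, color, 10)


def _draw_rings(
    img: np.ndarray,
    rng: np.random.Generator,
    n: int,
    radii: tuple[int, int],
    fill: RGB,
    outline: RGB,
    thickness: int = 3,
) -> None:
    h, w = img.shape[:2]
    for _ in range(n):
        r = int(rng.integers(radii[0], radii[1] + 1))
        cy, cx = rng.integers(0, h), rng.integers(0, w)
        rr, cc = disk((cy, cx), r, shape=(h, w))
        img[rr, cc] = _jitter_color(rng, outline, 6)
        rr, cc = disk((cy, cx), max(r - thickness, 1), shape=(h, w))
        img[rr, cc] = _jitter_color(rng, fill, 6)


def _draw_ellipses(
    img: np.ndarray,
    rng: np.random.Generator,
    n: int,
    radii: tuple[int, int],
    color: RGB,
) -> None:
    h, w = img.shape[:2]
    for _ in range(n):
        ra = rng.integers(radii[0], radii[1] + 1)
        rb = rng.integers(radii[0], radii[1] + 1)
        cy, cx = rng.integers(0, h), rng.integers(0, w)
        rot = rng.uniform(0, np.pi)
        rr, cc = ellipse(cy, cx, ra, rb, shape=(h, w), rotation=rot)
        img[rr, cc] = _jitter_color(rng, color, 10)


def generate_tile(params: TextureParams) -> np.ndarray:
    """Render one 224x224x3 8-bit tile from a texture recipe.

    Deterministic: the same ``params`` (including ``seed``) always yields
    a bit-identical array.
    """
    rng = np.random.default_rng(np.random.SeedSequence([0x7113, params.seed & 0x7FFFFFFF]))
    img = np.empty((TILE_PX, TILE_PX, 3), dtype=float)
    img[:] = params.base_color

    label = params.class_label
    dens = params.element_density
    size = params.element_size_px
    if label == "ADI":
        # white vacuoles drawn as accent disk (border) + smaller white fill
        h = w = TILE_PX
        for _ in range(dens):
            r = int(rng.integers(size[0], size[1] + 1))
            cy, cx = rng.integers(0, h), rng.integers(0, w)
            rr, cc = disk((cy, cx), r, shape=(h, w))
            img[rr, cc] = _jitter_color(rng, params.accent_color, 6)
            rr, cc = disk((cy, cx), max(r - 2, 1), shape=(h, w))
            img[rr, cc] = _jitter_color(rng, params.element_color, 3)
    elif label == "BACK":
        pass
    elif label == "DEB":
        # alternating dark/light speckles on top of heavy pixel noise
        half = dens // 2
        _draw_disks(img, rng, half, size, params.element_color, jitter=14)
        _draw_disks(img, rng, dens - half, size, params.accent_color, jitter=14)
    elif label == "LYM":
        _draw_disks(img, rng, dens, size, params.element_color, jitter=12)
    elif label == "MUC":
        _draw_disks(img, rng, dens, size, params.element_color, jitter=6)
        _draw_disks(img, rng, dens // 2, size, params.accent_color, jitter=6)
    elif label == "MUS":
        _draw_stripes(img, rng, dens, size, params.element_color, diagonal=False)
    elif label == "NORM":
        _draw_rings(img, rng, dens, size, params.element_color, params.accent_color)
    elif label == "STR":
        _draw_stripes(img, rng, dens, size, params.element_color, diagonal=True)
    elif label == "TUM":
        _draw_ellipses(img, rng, dens, size, params.element_color)

    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)
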