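"""Slide tiling, Otsu tissue segmentation, tile filtering and augmentation.

A slide is cut into a non-overlapping grid of square tiles (partial edge
tiles dropped).  Each tile is converted to grayscale, an Otsu threshold is
computed on the tile's own histogram, pixels strictly below the threshold
count as tissue, and tiles with tissue fraction strictly greater than the
cutoff (default 50%) are kept.  Training-time augmentation applies, each
with probability 0.5: 90°-multiple rotation, horizontal/vertical flips,
hue shift, gamma correction and additive Gaussian noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.color import hsv2rgb, rgb2gray, rgb2hsv
from skimage.filters import threshold_otsu

__all__ = ["Tile", "tile_slide", "tissue_mask", "add_tissue_fractions",
           "filter_tiles", "augment", "write_tile_cache", "read_tile_cache"]

# augmentation magnitudes (mild, label-preserving)
HUE_SHIFT_MAX = 0.05          # fractional hue
GAMMA_RANGE = (0.8, 1.25)
NOISE_SIGMA = 5.0             # gray levels out of 255


@dataclass
class Tile:
    tile_id: str
    slide_id: str
    origin: tuple            # (row, col) pixel offset, 0-based top-left
    pixels: np.ndarray       # (ts, ts, 3) uint8
    tissue_fraction: float | None = None
    flags: dict = field(default_factory=dict)


def tile_slide(image_or_record, tile_size: int = 256, slide_id: str | None = None):
    """Cut a slide into its non-overlapping grid of full tiles.

    Accepts a :class:`~hypomil.synthetic.SlideRecord` or a raw (H, W, 3)
    array.  Partial edge tiles are dropped, so the count is
    ``floor(H/ts) * floor(W/ts)``; a slide smaller than one tile yields an
    empty list with a warning.
    """
    if hasattr(image_or_record, "image"):
        image = image_or_record.image
        slide_id = slide_id or image_or_record.sample_id
    else:
        image = np.asarray(image_or_record)
        slide_id = slide_id or "slide"
    h, w = image.shape[:2]
    n_rows, n_cols = h // tile_size, w // tile_size
    if n_rows == 0 or n_cols == 0:
        warnings.warn(f"slide {slide_id!r} ({h}×{w}) smaller than one "
                      f"{tile_size}px tile; no tiles produced")
        return []
    tiles = []
    for r in range(n_rows):
        for c in range(n_cols):
            y, x = r * tile_size, c * tile_size
            tiles.append(Tile(
                tile_id=f"{slide_id}_r{r}_c{c}",
                slide_id=slide_id,
                origin=(y, x),
                pixels=image[y:y + tile_size, x:x + tile_size],
            ))
    return tiles


def tissue_mask(tile_or_pixels):
    """Per-tile Otsu tissue segmentation.

    Returns ``(mask, tissue_fraction, flagged)``: the boolean mask of pixels
    strictly below the tile's own Otsu threshold on its grayscale image, the
    fraction of such pixels, and a flag marking constant-intensity tiles
    (threshold undefined → fraction 0).
    """
    pixels = tile_or_pixels.pixels if isinstance(tile_or_pixels, Tile) \
        else np.asarray(tile_or_pixels)
    gray = rgb2gray(pixels)  # luminance weighting 0.2125/0.7154/0.0721
    if gray.max() == gray.min():
        return np.zeros(gray.shape, dtype=bool), 0.0, True
    thr = threshold_otsu(gray)
    mask = gray < thr
    return mask, float(mask.mean()), False


def add_tissue_fractions(tiles):
    """Populate ``tissue_fraction`` (and constant-tile flags) in place."""
    for tile in tiles:
        _, frac, flagged = tissue_mask(tile)
        tile.tissue_fraction = frac
        if flagged:
            tile.flags["constant_intensity"] = True
    return tiles


def filter_tiles(tiles, min_fraction: float = 0.5):
    """Keep tiles whose tissue fraction is strictly greater than the cutoff.

    Order is preserved; the output is a subsequence of the input.  An empty
    result is returned as-is — the caller decides whether the sample is
    unusable.
    """
    for tile in tiles:
        if tile.tissue_fraction is None:
            raise ValueError(f"tile {tile.tile_id!r} has no tissue_fraction; "
                             f"run add_tissue_fractions first")
    return [t for t in tiles if t.tissue_fraction > min_fraction]


def augment(tile, rng: np.random.Generator, p: float = 0.5):
    """Random geometric + spectral augmentation of one tile.

    Each transform fires independently with probability ``p``: rotation by a
    random multiple of 90°, horizontal flip, vertical flip, hue shift
    (uniform ±0.05), gamma correction (uniform in [0.8, 1.25]) and additive
    Gaussian noise (σ = 5 gray levels).  Output stays uint8 in [0, 255];
    the weak label is untouched.  ``p=0`` is the identity.
    """
    pixels = tile.pixels if isinstance(tile, Tile) else np.asarray(tile)
    out = pixels.astype(np.float32)

    if rng.uniform() < p:
        out = np.rot90(out, k=int(rng.integers(1, 4)), axes=(0, 1))
    if rng.uniform() < p:
        out = out[:, ::-1]
    if rng.uniform() < p:
        out = out[::-1]
    if rng.uniform() < p:
        hsv = rgb2hsv(np.clip(out, 0, 255) / 255.0)
        hsv[..., 0] = (hsv[..., 0] + rng.uniform(-HUE_SHIFT_MAX, HUE_SHIFT_MAX)) % 1.0
        out = hsv2rgb(hsv) * 255.0
    if rng.uniform() < p:
        gamma = rng.uniform(*GAMMA_RANGE)
        out = (np.clip(out, 0, 255) / 255.0) ** gamma * 255.0
    if rng.uniform() < p:
        out = out + rng.normal(0.0, NOISE_SIGMA, out.shape)

    out = np.clip(out, 0, 255).astype(np.uint8)
    if isinstance(tile, Tile):
        return Tile(tile_id=tile.tile_id, slide_id=tile.slide_id,
                    origin=tile.origin, pixels=np.ascontiguousarray(out),
                    tissue_fraction=None, flags=dict(tile.flags))
    return np.ascontiguousarray(out)


def write_tile_cache(tiles, out_dir):
    """Cache tiles as PNG plus a CSV manifest
    (tile_id, slide_id, row, col, tissue_fraction)."""
    import csv
    from pathlib import Path

    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "tiles.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["tile_id", "slide_id", "row", "col",
                         "tissue_fraction"])
        for t in tiles:
            iio.imwrite(out / f"{t.tile_id}.png", t.pixels)
            writer.writerow([t.tile_id, t.slide_id, t.origin[0], t.origin[1],
                             "" if t.tissue_fraction is None
                             else f"{t.tissue_fraction:.10g}"])
    return out / "tiles.csv"


def read_tile_cache(cache_dir):
    """Re-read a tile cache written by :func:`write_tile_cache`."""
    import csv
    from pathlib import Path

    import imageio.v3 as iio

    out = Path(cache_dir)
    tiles = []
    with open(out / "tiles.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            tiles.append(Tile(
                tile_id=row["tile_id"], slide_id=row["slide_id"],
                origin=(int(row["row"]), int(row["col"])),
                pixels=iio.imread(out / f"{row['tile_id']}.png"),
                tissue_fraction=(float(row["tissue_fraction"])
                                 if row["tissue_fraction"] else None),
            ))
    return tiles
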