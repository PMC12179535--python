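"""GLCM texture features and binary-mask shape descriptors.

Texture: a tile is converted to 8-bit grayscale and a normalized gray-level
co-occurrence matrix P is built at distance 1 for each of the four angles
0°, 45°, 90° and 135° (pairs counted in one direction per angle).  From P,

    homogeneity = Σ_ij P(i,j) / (1 + (i−j)²)
    energy      = Σ_ij P(i,j)²
    correlation = Σ_ij (i−μ_i)(j−μ_j) P(i,j) / (σ_i σ_j)

plus contrast and dissimilarity as extras; each feature is the average over
the four angles.  Correlation is undefined on constant tiles (zero marginal
variance) and returned as NaN with a flag.

Shape: from a single-connected-component binary mask,

    eccentricity = √(1 − b²/a²)      (a ≥ b: moment-ellipse axis lengths)
    circularity  = 4π·Area / Perimeter²
    extent       = A_object / A_BBox

together with area, perimeter (Crofton projection estimator, chosen so the
circularity of rasterized disks lands near 1), solidity (area /
convex-hull area) and equivalent (area-derived) diameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import graycomatrix
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.util import img_as_ubyte

logger = logging.getLogger(__name__)

__all__ = [
    "GLCMFeatures", "ShapeDescriptors",
    "glcm", "texture_features", "tile_texture_features",
    "eccentricity_from_axes", "circularity", "extent_ratio",
    "shape_descriptors", "select_high_confidence",
]

GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
N_LEVELS = 256
DISTANCE = 1


@dataclass
class GLCMFeatures:
    tile_id: str
    homogeneity: float
    energy: float
    correlation: float  # NaN when undefined (constant tile)
    contrast: float
    dissimilarity: float
    correlation_defined: bool = True


@dataclass
class ShapeDescriptors:
    cell_id: int
    cell_type: str
    area: float
    perimeter: float
    equivalent_diameter: float
    eccentricity: float
    circularity: float
    extent: float
    solidity: float
    major_axis_length: float
    minor_axis_length: float


# ------------------------------------------------------------------- texture

def _to_gray_levels(image) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 3:
        image = img_as_ubyte(rgb2gray(image))
    if image.dtype != np.uint8:
        if image.max() >= N_LEVELS or image.min() < 0:
            raise ValueError(f"integer image values must lie in [0, {N_LEVELS})")
        image = image.astype(np.uint8)
    return image


def glcm(image, distance: int = DISTANCE, angle: float = 0.0,
         n_levels: int = N_LEVELS) -> np.ndarray:
    """Normalized co-occurrence matrix P for one (distance, angle) offset.

    The pixel offset is (round(d·sinθ), round(d·cosθ)); pairs are counted in
    that direction only (symmetric=False) and P sums to 1.
    """
    image = _to_gray_levels(image)
    dr = int(round(np.sin(angle) * distance))
    dc = int(round(np.cos(angle) * distance))
    if image.shape[0] <= abs(dr) or image.shape[1] <= abs(dc):
        raise ValueError(
            f"image {image.shape} smaller than offset ({dr}, {dc})"
        )
    P = graycomatrix(image, [distance], [angle], levels=n_levels,
                     symmetric=False, normed=True)[:, :, 0, 0]
    return P.astype(np.float64)


def texture_features(P: np.ndarray, tile_id: str = "") -> GLCMFeatures:
    """Texture statistics of one normalized co-occurrence matrix."""
    P = np.asarray(P, dtype=np.float64)
    n = P.shape[0]
    i = np.arange(n, dtype=np.float64)[:, None]
    j = np.arange(n, dtype=np.float64)[None, :]
    diff = i - j
    homogeneity = float((P / (1.0 + diff ** 2)).sum())
    energy = float((P ** 2).sum())
    contrast = float((P * diff ** 2).sum())
    dissimilarity = float((P * np.abs(diff)).sum())
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = float((np.arange(n) * pi).sum())
    mu_j = float((np.arange(n) * pj).sum())
    var_i = float(((np.arange(n) - mu_i) ** 2 * pi).sum())
    var_j = float(((np.arange(n) - mu_j) ** 2 * pj).sum())
    if var_i <= 0 or var_j <= 0:
        logger.warning("tile %s: zero marginal variance; correlation undefined",
                       tile_id or "<anon>")
        return GLCMFeatures(tile_id, homogeneity, energy, float("nan"),
                            contrast, dissimilarity, correlation_defined=False)
    corr = float((((i - mu_i) * (j - mu_j)) * P).sum()
                 / (np.sqrt(var_i) * np.sqrt(var_j)))
    return GLCMFeatures(tile_id, homogeneity, energy, corr,
                        contrast, dissimilarity)


def tile_texture_features(image, tile_id: str = "",
                          distance: int = DISTANCE,
                          angles=GLCM_ANGLES,
                          n_levels: int = N_LEVELS) -> GLCMFeatures:
    """Four-angle averaged texture features of one tile."""
    per_angle = [texture_features(glcm(image, distance, a, n_levels), tile_id)
                 for a in angles]
    defined = all(f.correlation_defined for f in per_angle)
    mean = lambda attr: float(np.mean([getattr(f, attr) for f in per_angle]))
    return GLCMFeatures(
        tile_id=tile_id,
        homogeneity=mean("homogeneity"),
        energy=mean("energy"),
        correlation=mean("correlation") if defined else float("nan"),
        contrast=mean("contrast"),
        dissimilarity=mean("dissimilarity"),
        correlation_defined=defined,
    )


# --------------------------------------------------------------------- shape

def eccentricity_from_axes(a: float, b: float) -> float:
    """√(1 − b²/a²) for major axis a ≥ minor axis b > 0.

    0 for a circle (b = a), approaching 1 in the elongated limit b/a → 0.
    """
    if not (a >= b > 0):
        raise ValueError(f"need major >= minor > 0, got a={a}, b={b}")
    return float(np.sqrt(1.0 - (b * b) / (a * a)))


def circularity(area: float, perimeter: float) -> float:
    """4π·Area / Perimeter²; exactly 1 for a perfect circle."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return float(4.0 * np.pi * area / (perimeter * perimeter))


def extent_ratio(area_object: float, area_bbox: float) -> float:
    """A_object / A_BBox ∈ (0, 1]."""
    if area_bbox <= 0:
        raise ValueError("bounding-box area must be positive")
    return float(area_object / area_bbox)


def shape_descriptors(mask: np.ndarray, cell_id: int = 0,
                      cell_type: str = "") -> ShapeDescriptors:
    """Binary shape descriptors of a single-cell mask.

    The mask must contain exactly one connected component of at least 8
    pixels.  Axis lengths come from the normalized second central moments
    (moment-ellipse convention); the perimeter uses the Crofton projection
    estimator, so rasterized disks land near circularity 1.
    """
    mask = np.asarray(mask).astype(bool)
    n_components = cc_label(mask).max()
    if n_components == 0:
        raise ValueError("empty mask")
    if n_components > 1:
        raise ValueError(f"mask has {n_components} connected components; "
                         f"expected a single cell")
    if mask.sum() < 8:
        raise ValueError(f"mask has {int(mask.sum())} pixels; minimum is 8")
    props = regionprops(mask.astype(np.uint8))[0]
    a = float(props.axis_major_length)
    b = float(props.axis_minor_length)
    area = float(props.area)
    perim = float(props.perimeter_crofton)
    return ShapeDescriptors(
        cell_id=cell_id,
        cell_type=cell_type,
        area=area,
        perimeter=perim,
        equivalent_diameter=float(np.sqrt(4.0 * area / np.pi)),
        eccentricity=eccentricity_from_axes(a, b) if b > 0 else 1.0,
        circularity=circularity(area, perim),
        extent=extent_ratio(area, float(props.area_bbox)),
        solidity=float(props.solidity),
        major_axis_length=a,
        minor_axis_length=b,
    )


# ------------------------------------------------------- high-confidence set

def select_high_confidence(tiles_by_sample: dict, model, cutoff: float = 0.9,
                           per_sample: int = 10,
                           rng: np.random.Generator | None = None,
                           calibration: str | None = None) -> dict:
    """Sample tiles per sample, score each as a one-tile bag, and keep only
    high-confidence calls, partitioned by predicted class.

    Parameters
    ----------
    tiles_by_sample : dict of sample_id → (n_i, H, W, 3) array
    model : fitted :class:`~hypomil.mil.HypoxiaMILClassifier`
    cutoff : float
        A tile is retained when its winning-class probability exceeds this
        value (strictly).
    per_sample : int
        Number of tiles randomly drawn per sample before scoring.
    calibration : {None, 'median'}
        With ``'median'``, tile scores are recentred so the cohort median
        hypoxic-probability sits at 0.5 before the argmax/cutoff semantics
        are applied.  Briefly trained desk-scale models rank tiles well but
        compress probabilities into a narrow band around a small constant
        offset, which otherwise sends every tile to the same class; for a
        calibrated fully trained model the recentering is a near no-op.

    Returns
    -------
    dict with keys ``'hypoxic'`` and ``'normoxic'``, each a list of
    ``(sample_id, tile_index, tile, probability)`` tuples.
    """
    if calibration not in (None, "median"):
        raise ValueError(f"unknown calibration {calibration!r}")
    rng = np.random.default_rng(0) if rng is None else rng
    scored = []
    for sample_id, tiles in tiles_by_sample.items():
        tiles = np.asarray(tiles)
        if len(tiles) == 0:
            continue
        take = min(per_sample, len(tiles))
        idx = rng.choice(len(tiles), size=take, replace=False)
        for ti in idx:
            p_hyp = float(model.score_tile(tiles[ti])[1])
            scored.append((sample_id, int(ti), tiles[ti], p_hyp))
    if calibration == "median" and scored:
        med = float(np.median([s[-1] for s in scored]))
        scored = [(sid, ti, tile, float(np.clip(0.5 + p - med, 0.0, 1.0)))
                  for sid, ti, tile, p in scored]
    out = {"hypoxic": [], "normoxic": []}
    for sample_id, ti, tile, p_hyp in scored:
        cls = "hypoxic" if p_hyp > 0.5 else "normoxic"
        p = max(p_hyp, 1.0 - p_hyp)
        if p > cutoff:
            out[cls].append((sample_id, ti, tile, p))
    for cls, items in out.items():
        if not items:
            logger.warning("no tiles retained for class %r at cutoff %.2f; "
                           "downstream comparison will be skipped", cls, cutoff)
    return out
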