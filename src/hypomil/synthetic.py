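"""Seeded synthetic histology-like data with planted, recoverable signal.

Three generators emulate the inputs the analysis expects, so the whole
pipeline is testable without any downloads:

* :func:`generate_slides` — large RGB "slides" mixing near-white background
  with a tissue disc rendered as smoothed noise in an H&E-like pink, bright
  lumen/vacuole speckle, and darker elliptical nuclei.  The two classes
  differ in texture correlation length (Gaussian blur radius of the noise)
  and in nucleus axis ratio.
* :func:`generate_expression` — a nonnegative genes × samples matrix in
  which a designated signature-gene subset is shifted upward (in log2
  space) in the "hypoxic" samples.
* :func:`generate_annotated_tiles` — MoNuSaC-style tiles with per-cell
  elliptical nucleus masks for epithelial-like and macrophage-like cells.

Every output is a pure function of the configuration (including its seed):
independent numpy Generator substreams are derived per artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

logger = logging.getLogger(__name__)

CLASSES = ("normoxic", "hypoxic")
CELL_TYPES = ("epithelial", "macrophage")

# H&E-like rendering constants (RGB); grayscale luminances are chosen so a
# per-tile Otsu split lands between the bright (background/lumen) mode and
# the tissue, not between nuclei and cytoplasm.
CYTOPLASM_RGB = np.array([225.0, 150.0, 200.0])  # eosin pink, luminance ~170
NUCLEUS_RGB = np.array([150.0, 110.0, 185.0])    # hematoxylin purple, ~124


def _default_granularity():
    return {"normoxic": 1.5, "hypoxic": 5.0}


def _default_axes():
    return {
        "normoxic": {"epithelial": (16.0, 16.0), "macrophage": (12.0, 12.0)},
        "hypoxic": {"epithelial": (22.0, 11.0), "macrophage": (16.0, 8.0)},
    }


def _default_signature():
    return [f"HYPOX{i:03d}" for i in range(1, 53)]


@dataclass
class SynthConfig:
    """Knobs of the synthetic cohort; the defaults are the study conditions.

    ``texture_granularity`` is the Gaussian blur sigma (pixels) applied to
    the tissue noise field per class; ``nucleus_axes`` maps class → cell
    type → (major, minor) full axis lengths in pixels; ``signature_shift``
    is the log2 up-shift of signature genes in hypoxic samples (2.5 log2
    units = 5 within-class SDs at ``expression_sigma`` 0.5).

    ``stain_gain_sd`` / ``stain_offset_sd`` control per-sample stain and
    illumination variation (a multiplicative gain and per-channel gray-level
    offsets drawn once per slide), mimicking the slide-to-slide staining
    differences of real H&E cohorts.  This class-independent variation is
    what keeps a label-permuted model honest: it offers sample-level
    features that carry no class information.
    """

    seed: int = 0
    n_samples_per_class: int = 40
    slide_size_px: tuple = (1024, 1024)
    tile_size_px: int = 256
    background_level: int = 245
    background_noise: float = 1.5
    texture_granularity: dict = field(default_factory=_default_granularity)
    texture_amplitude: float = 18.0
    tissue_radius_frac: float = 0.42
    stain_gain_sd: float = 0.04
    stain_offset_sd: float = 4.0
    vacuole_fraction: float = 0.10
    vacuole_radius: tuple = (6.0, 14.0)
    nuclei_per_slide: int = 250
    nucleus_axes: dict = field(default_factory=_default_axes)
    nucleus_axis_jitter: float = 0.10
    annotated_tiles_per_class: int = 10
    cells_per_tile: int = 10
    signature_genes: list = field(default_factory=_default_signature)
    n_background_genes: int = 200
    signature_shift: float = 2.5
    expression_sigma: float = 0.5

    def validate(self):
        h, w = self.slide_size_px
        if h < self.tile_size_px or w < self.tile_size_px:
            raise ValueError(
                f"degenerate config: slide {self.slide_size_px} smaller than "
                f"one {self.tile_size_px}px tile"
            )
        if self.n_samples_per_class < 1:
            raise ValueError("n_samples_per_class must be >= 1")
        for cls in CLASSES:
            if cls not in self.texture_granularity:
                raise ValueError(f"texture_granularity missing class {cls!r}")
            for ctype, (a, b) in self.nucleus_axes[cls].items():
                if not (a >= b > 0):
                    raise ValueError(
                        f"nucleus_axes[{cls!r}][{ctype!r}] needs major >= minor > 0"
                    )
        if not self.signature_genes:
            raise ValueError("signature_genes must be nonempty")
        if len(set(self.signature_genes)) != len(self.signature_genes):
            raise ValueError("duplicate gene identifiers in signature_genes")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        return self


@dataclass
class SlideRecord:
    """One sample's slide image plus ground truth and metadata."""

    sample_id: str
    image: np.ndarray  # (H, W, 3) uint8
    true_class: str    # generator ground truth; not shown to the model
    metadata: dict = field(default_factory=dict)


@dataclass
class CellAnnotation:
    cell_id: int
    cell_type: str
    mask: np.ndarray  # boolean, tile-sized
    tile_id: str


@dataclass
class AnnotatedTile:
    tile_id: str
    image: np.ndarray  # (ts, ts, 3) uint8
    true_class: str
    cells: list


def sample_sheet(cfg: SynthConfig) -> pd.DataFrame:
    """Deterministic sample_id ↔ true class mapping shared by all generators."""
    n = cfg.n_samples_per_class
    ids = [f"S{i:04d}" for i in range(2 * n)]
    classes = ["normoxic"] * n + ["hypoxic"] * n
    return pd.DataFrame({"sample_id": ids, "true_class": classes})


# --------------------------------------------------------------------- slides

def _render_tissue_texture(shape, granularity, amplitude, rng):
    noise = rng.standard_normal(shape)
    smooth = gaussian_filter(noise, sigma=granularity)
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd  # keep amplitude comparable across granularities
    return smooth * amplitude


def _paint_nucleus(img, rng, center, axes, color=NUCLEUS_RGB):
    # centers snap to the pixel grid: an off-grid circle rasterizes with a
    # broken 4-fold symmetry and picks up a spurious moment eccentricity
    # of ~0.1 that never decays with size
    major, minor = axes
    rr, cc = draw_ellipse(round(center[0]), round(center[1]),
                          minor / 2.0, major / 2.0,
                          shape=img.shape[:2],
                          rotation=rng.uniform(0, np.pi))
    img[rr, cc] = color + rng.normal(0, 4, (len(rr), 3))
    return rr, cc


def _jittered_axes(axes, jitter, rng):
    scale = max(1.0 + jitter * rng.standard_normal(), 0.3)
    return axes[0] * scale, axes[1] * scale


def render_slide(cfg: SynthConfig, rng: np.random.Generator,
                 true_class: str) -> np.ndarray:
    """Render one synthetic slide image for the given class."""
    h, w = cfg.slide_size_px
    img = np.full((h, w, 3), float(cfg.background_level))
    if cfg.background_noise > 0:
        img += rng.normal(0, cfg.background_noise, (h, w, 3))

    yy, xx = np.mgrid[0:h, 0:w]
    radius = cfg.tissue_radius_frac * min(h, w)
    cy, cx = h / 2.0, w / 2.0
    tissue = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
    if radius <= 0:
        tissue[:] = False
    if not tissue.any():  # zero tissue area: background only
        return np.clip(img, 0, 255).astype(np.uint8)

    tex = _render_tissue_texture((h, w), cfg.texture_granularity[true_class],
                                 cfg.texture_amplitude, rng)
    for ch in range(3):
        img[..., ch][tissue] = CYTOPLASM_RGB[ch] + tex[tissue]

    # bright lumen/vacuole speckle: gives every all-tissue tile a bright
    # minority mode so the per-tile Otsu split separates background-like
    # pixels from tissue (as in real H&E with lumina and fat)
    target = cfg.vacuole_fraction * tissue.sum()
    covered = 0
    while covered < target:
        rv = rng.uniform(*cfg.vacuole_radius)
        ang = rng.uniform(0, 2 * np.pi)
        rad = radius * np.sqrt(rng.uniform())
        center = (cy + rad * np.sin(ang), cx + rad * np.cos(ang))
        rr, cc = draw_disk(center, rv, shape=(h, w))
        img[rr, cc] = cfg.background_level + rng.normal(0, 1.5, (len(rr), 3))
        covered += len(rr)

    axes_by_type = cfg.nucleus_axes[true_class]
    for _ in range(cfg.nuclei_per_slide):
        ctype = CELL_TYPES[int(rng.uniform() < 0.3)]
        axes = _jittered_axes(axes_by_type[ctype], cfg.nucleus_axis_jitter, rng)
        ang = rng.uniform(0, 2 * np.pi)
        rad = radius * np.sqrt(rng.uniform())
        center = (cy + rad * np.sin(ang), cx + rad * np.cos(ang))
        _paint_nucleus(img, rng, center, axes)

    # per-slide stain/illumination jitter, independent of class
    gain = 1.0 + cfg.stain_gain_sd * rng.standard_normal()
    offset = cfg.stain_offset_sd * rng.standard_normal(3)
    img = img * gain + offset

    return np.clip(img, 0, 255).astype(np.uint8)


def generate_slides(cfg: SynthConfig) -> list:
    """Generate the full two-class cohort of slides (seed-deterministic)."""
    cfg.validate()
    sheet = sample_sheet(cfg)
    slides = []
    for idx, row in sheet.iterrows():
        rng = np.random.default_rng([cfg.seed, 1, int(idx)])
        image = render_slide(cfg, rng, row.true_class)
        slides.append(SlideRecord(
            sample_id=row.sample_id, image=image, true_class=row.true_class,
            metadata={"granularity": cfg.texture_granularity[row.true_class]},
        ))
    return slides


# ----------------------------------------------------------------- expression

def generate_expression(cfg: SynthConfig):
    """Genes × samples nonnegative expression matrix with planted shift.

    Returns ``(expr, truth)``: a DataFrame (genes in rows, sample IDs as
    columns) and a Series mapping sample_id → true class.  Per-gene values
    are log-normal; signature genes gain ``signature_shift`` log2 units in
    hypoxic samples; background genes are exchangeable between classes.
    """
    cfg.validate()
    genes = list(cfg.signature_genes) + [
        f"BG{i:04d}" for i in range(cfg.n_background_genes)
    ]
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene identifiers")
    sheet = sample_sheet(cfg)
    rng = np.random.default_rng([cfg.seed, 2])
    mu = rng.uniform(3.0, 8.0, size=len(genes))
    log2 = rng.normal(mu[:, None], cfg.expression_sigma,
                      size=(len(genes), len(sheet)))
    hyp = (sheet.true_class == "hypoxic").to_numpy()
    log2[: len(cfg.signature_genes), hyp] += cfg.signature_shift
    expr = pd.DataFrame(2.0 ** log2, index=genes,
                        columns=sheet.sample_id.tolist())
    truth = pd.Series(sheet.true_class.to_numpy(),
                      index=sheet.sample_id.tolist(), name="true_class")
    return expr, truth


# ------------------------------------------------------------ annotated tiles

def render_annotated_tile(cfg: SynthConfig, rng: np.random.Generator,
                          true_class: str, tile_id: str,
                          n_cells: int | None = None) -> AnnotatedTile:
    """One tile of class texture with non-overlapping elliptical nuclei."""
    ts = cfg.tile_size_px
    img = np.empty((ts, ts, 3))
    tex = _render_tissue_texture((ts, ts), cfg.texture_granularity[true_class],
                                 cfg.texture_amplitude, rng)
    for ch in range(3):
        img[..., ch] = CYTOPLASM_RGB[ch] + tex
    occupied = np.zeros((ts, ts), dtype=bool)
    cells = []
    n_cells = cfg.cells_per_tile if n_cells is None else n_cells
    axes_by_type = cfg.nucleus_axes[true_class]
    for j in range(n_cells):
        ctype = CELL_TYPES[j % len(CELL_TYPES)]
        placed = False
        for _ in range(40):
            axes = _jittered_axes(axes_by_type[ctype],
                                  cfg.nucleus_axis_jitter, rng)
            margin = axes[0] / 2.0 + 2
            if 2 * margin >= ts:
                break
            center = (round(rng.uniform(margin, ts - margin)),
                      round(rng.uniform(margin, ts - margin)))
            rr, cc = draw_ellipse(center[0], center[1],
                                  axes[1] / 2.0, axes[0] / 2.0,
                                  shape=(ts, ts),
                                  rotation=rng.uniform(0, np.pi))
            if len(rr) < 8 or occupied[rr, cc].any():
                continue
            img[rr, cc] = NUCLEUS_RGB + rng.normal(0, 4, (len(rr), 3))
            mask = np.zeros((ts, ts), dtype=bool)
            mask[rr, cc] = True
            occupied |= mask
            cells.append(CellAnnotation(cell_id=len(cells) + 1,
                                        cell_type=ctype, mask=mask,
                                        tile_id=tile_id))
            placed = True
            break
        if not placed:
            logger.warning("tile %s: could not place nucleus %d without "
                           "overlap; emitting fewer cells", tile_id, j + 1)
    gain = 1.0 + cfg.stain_gain_sd * rng.standard_normal()
    offset = cfg.stain_offset_sd * rng.standard_normal(3)
    img = img * gain + offset
    return AnnotatedTile(tile_id=tile_id,
                         image=np.clip(img, 0, 255).astype(np.uint8),
                         true_class=true_class, cells=cells)


def generate_annotated_tiles(cfg: SynthConfig) -> list:
    """MoNuSaC-style annotated tiles for both classes (seed-deterministic)."""
    cfg.validate()
    tiles = []
    for c_idx, cls in enumerate(CLASSES):
        for k in range(cfg.annotated_tiles_per_class):
            tile_id = f"{cls[:3]}_tile_{k:03d}"
            rng = np.random.default_rng([cfg.seed, 3, c_idx, k])
            tiles.append(render_annotated_tile(cfg, rng, cls, tile_id))
    return tiles


# ------------------------------------------------------------------ output IO

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_dataset(cfg: SynthConfig, out_dir) -> dict:
    """Write slides (TIFF), annotated tiles + 16-bit label masks (PNG),
    expression (TSV), ground truth (CSV) and a manifest JSON.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    (out / "slides").mkdir(parents=True, exist_ok=True)
    (out / "tiles").mkdir(exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)

    files = {}
    slides = generate_slides(cfg)
    for rec in slides:
        p = out / "slides" / f"{rec.sample_id}.tiff"
        tifffile.imwrite(p, rec.image)
        files[str(p.relative_to(out))] = _sha256(p)

    expr, truth = generate_expression(cfg)
    p = out / "expression.tsv"
    expr.to_csv(p, sep="\t")
    files[str(p.relative_to(out))] = _sha256(p)
    p = out / "ground_truth.csv"
    truth.rename_axis("sample_id").to_frame().to_csv(p)
    files[str(p.relative_to(out))] = _sha256(p)

    rows = []
    for tile in generate_annotated_tiles(cfg):
        p = out / "tiles" / f"{tile.tile_id}.png"
        iio.imwrite(p, tile.image)
        files[str(p.relative_to(out))] = _sha256(p)
        label = np.zeros(tile.image.shape[:2], dtype=np.uint16)
        for cell in tile.cells:
            label[cell.mask] = cell.cell_id
            rr, cc = np.nonzero(cell.mask)
            rows.append({"tile_id": tile.tile_id, "cell_id": cell.cell_id,
                         "cell_type": cell.cell_type,
                         "true_class": tile.true_class,
                         "bbox_min_row": int(rr.min()),
                         "bbox_min_col": int(cc.min()),
                         "bbox_max_row": int(rr.max()),
                         "bbox_max_col": int(cc.max())})
        p = out / "masks" / f"{tile.tile_id}_mask.png"
        iio.imwrite(p, label)
        files[str(p.relative_to(out))] = _sha256(p)
    p = out / "annotations.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    files[str(p.relative_to(out))] = _sha256(p)

    manifest = {"config": dataclasses.asdict(cfg), "files": files}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
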