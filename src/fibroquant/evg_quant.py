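"""Automated fiber quantification of Elastica van Gieson-stained liver sections.

The measurement chain mirrors routine digital-pathology practice for
proportional-area morphometry: a whole-slide RGB image with known physical
resolution is color-calibrated against the glass background, every pixel is
classified into one of five classes (collagen fiber, elastin fiber, nucleus,
cytoplasm, glass), the section is compartmented into 1 mm² tiles, the
collagen and elastin proportional areas (CPA/EPA, percent of the four tissue
classes) are computed per tile, and the section-level summary is the median
over tiles.  The median makes the summary insensitive to large vascular
(glass-dominated) areas, which simply fall below the tissue floor and drop
out of the tile set.

Pixel classification is a quadratic discriminant with equal priors in a
fixed linear opponent color space: each pixel is assigned the class whose
mean/covariance minimizes the squared Mahalanobis distance.  Ties are broken
by a fixed class order (glass < cytoplasm < nucleus < collagen < elastin),
so a tie never invents fiber.  The built-in color model is derived from an
EvG reference palette; :func:`train_color_model` fits a model from labeled
swatches instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import CalibrationError, NoTissueError, StageError

# ---------------------------------------------------------------------------
# Class codes, palette and working color space
# ---------------------------------------------------------------------------

#: Integer label codes.  The ordering doubles as the classification
#: tie-break order: np.argmin returns the lowest index on exact ties, so a
#: pixel equidistant between fiber and non-fiber classes is never called fiber.
GLASS, CYTOPLASM, NUCLEUS, COLLAGEN, ELASTIN = 0, 1, 2, 3, 4

CLASS_NAMES = ("glass", "cytoplasm", "nucleus", "collagen", "elastin")
CLASS_CODES = {name: code for code, name in enumerate(CLASS_NAMES)}
TISSUE_CLASSES = (CYTOPLASM, NUCLEUS, COLLAGEN, ELASTIN)

#: Reference EvG appearance, 8-bit RGB: collagen stains red (van Gieson acid
#: fuchsin), elastin near-black violet (resorcin-fuchsin), cytoplasm yellow
#: (picric acid), nuclei gray-violet, glass near-white.
DEFAULT_PALETTE: dict[str, tuple[int, int, int]] = {
    "glass": (245, 245, 245),
    "cytoplasm": (225, 200, 130),
    "nucleus": (105, 85, 115),
    "collagen": (195, 80, 95),
    "elastin": (50, 40, 60),
}

#: Fixed opponent transform (rows: luminance, red–green, yellow–blue).
#: Any fixed full-rank linear map works; opponent axes keep the stain
#: contrasts (red fuchsin vs yellow picric vs violet elastin) near-axis-aligned.
OPPONENT_MATRIX = np.array(
    [
        [0.30, 0.59, 0.11],
        [0.50, -0.50, 0.00],
        [0.25, 0.25, -0.50],
    ]
)

REFERENCE_WHITE = np.array(DEFAULT_PALETTE["glass"], dtype=float)


def rgb_to_working(rgb: np.ndarray) -> np.ndarray:
    """Map an (..., 3) RGB array into the working opponent space."""
    return np.asarray(rgb, dtype=float) @ OPPONENT_MATRIX.T


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SectionImage:
    """An RGB section raster with physical resolution (μm per pixel)."""

    pixels: np.ndarray  # (H, W, 3) uint8
    resolution_um_per_px: float

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be a non-empty (H, W, 3) array")
        if not self.resolution_um_per_px > 0:
            raise ValueError("resolution must be positive")
        object.__setattr__(self, "pixels", px.astype(np.uint8, copy=False))


@dataclass(frozen=True)
class ColorModel:
    """Per-class Gaussian color model in the working space.

    ``means`` is (5, 3) and ``covariances`` (5, 3, 3), indexed by the class
    codes above; covariances must be symmetric positive-definite.
    """

    means: np.ndarray
    covariances: np.ndarray
    working_space: str = "opponent"
    reference_white: np.ndarray = field(default_factory=lambda: REFERENCE_WHITE.copy())

    def __post_init__(self):
        means = np.asarray(self.means, dtype=float)
        covs = np.asarray(self.covariances, dtype=float)
        if means.shape != (5, 3) or covs.shape != (5, 3, 3):
            raise ValueError("model must cover exactly the five classes in 3 channels")
        for k in range(5):
            if not np.allclose(covs[k], covs[k].T):
                raise ValueError(f"covariance for class {CLASS_NAMES[k]} not symmetric")
            if np.linalg.eigvalsh(covs[k]).min() <= 0:
                raise ValueError(f"covariance for class {CLASS_NAMES[k]} not positive-definite")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "covariances", covs)

    @property
    def precisions(self) -> np.ndarray:
        return np.linalg.inv(self.covariances)


@dataclass(frozen=True)
class ClassMap:
    """Per-pixel class labels for one section."""

    labels: np.ndarray  # (H, W) uint8 with codes 0..4

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be 2-D")
        if lab.size and (lab.min() < 0 or lab.max() > 4):
            raise ValueError("labels must use codes 0..4")
        object.__setattr__(self, "labels", lab.astype(np.uint8, copy=False))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass(frozen=True)
class TileQuant:
    """Class pixel counts and fiber proportional areas for one grid tile."""

    tile_row: int
    tile_col: int
    class_counts: tuple[int, int, int, int, int]  # indexed by class code
    included: bool

    @property
    def tile_pixels(self) -> int:
        return int(sum(self.class_counts))

    @property
    def tissue_pixels(self) -> int:
        return int(sum(self.class_counts[c] for c in TISSUE_CLASSES))

    def _pct(self, code: int) -> float:
        t = self.tissue_pixels
        return 100.0 * self.class_counts[code] / t if t else float("nan")

    @property
    def cpa(self) -> float:
        return self._pct(COLLAGEN)

    @property
    def epa(self) -> float:
        return self._pct(ELASTIN)


@dataclass(frozen=True)
class FiberQuantResult:
    """Per-tile quantification plus section-level medians."""

    tiles: tuple[TileQuant, ...]
    tile_side_px: int
    median_cpa: float
    median_epa: float

    @property
    def n_tiles_included(self) -> int:
        return sum(t.included for t in self.tiles)


def default_color_model(noise_sd: float = 8.0, ridge: float = 1.0) -> ColorModel:
    """Built-in model: palette means plus isotropic RGB noise pushed through
    the opponent transform, with a diagonal ridge for strict positive-definiteness."""
    means = rgb_to_working(np.array([DEFAULT_PALETTE[n] for n in CLASS_NAMES], float))
    base = OPPONENT_MATRIX @ OPPONENT_MATRIX.T * noise_sd**2 + ridge * np.eye(3)
    covs = np.repeat(base[None, :, :], 5, axis=0)
    return ColorModel(means=means, covariances=covs)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

_GAIN_BOUNDS = (0.5, 2.0)
_WHITE_TOLERANCE = 30.0  # max per-channel distance from reference white


def calibrate_colors(image: SectionImage, model: ColorModel | None = None) -> SectionImage:
    """Automatic color calibration against the glass background.

    The glass color is estimated per channel as a robust high percentile of
    the image, and a per-channel linear gain maps it onto the model's
    reference white.  Idempotent within one intensity level once calibrated.

    Raises :class:`CalibrationError` when no plausible background exists
    (required gain outside bounds, or no near-white pixel after gain).
    """
    model = model or default_color_model()
    ref = np.asarray(model.reference_white, dtype=float)
    px = image.pixels.astype(float)
    est = np.percentile(px.reshape(-1, 3), 99.5, axis=0)
    if np.any(est <= 0):
        raise CalibrationError("image too dark: no background detectable")
    gain = ref / est
    if np.any(gain < _GAIN_BOUNDS[0]) or np.any(gain > _GAIN_BOUNDS[1]):
        raise CalibrationError(
            f"estimated background {est.round(1).tolist()} needs per-channel gain "
            f"{gain.round(3).tolist()} outside bounds {_GAIN_BOUNDS}"
        )
    out = np.clip(np.round(px * gain), 0, 255).astype(np.uint8)
    near_white = np.all(np.abs(out.astype(float) - ref) <= _WHITE_TOLERANCE, axis=-1)
    if not near_white.any():
        raise CalibrationError("no pixel near reference white after calibration")
    return SectionImage(pixels=out, resolution_um_per_px=image.resolution_um_per_px)


def train_color_model(
    swatches: dict[str, np.ndarray],
    ridge: float = 1.0,
    reference_white: np.ndarray | None = None,
) -> ColorModel:
    """Fit a per-class Gaussian color model from labeled RGB swatches.

    ``swatches`` maps each of the five class names to an (n, 3) uint8/float
    RGB sample with n ≥ 50.  Covariances get a diagonal ridge so single-color
    swatches still yield a positive-definite model.
    """
    missing = [n for n in CLASS_NAMES if n not in swatches]
    if missing:
        raise ValueError(f"missing swatches for classes: {missing}")
    small = [n for n in CLASS_NAMES if np.asarray(swatches[n]).reshape(-1, 3).shape[0] < 50]
    if small:
        raise ValueError(f"need at least 50 sample pixels per class; too few for: {small}")
    means = np.empty((5, 3))
    covs = np.empty((5, 3, 3))
    for code, name in enumerate(CLASS_NAMES):
        w = rgb_to_working(np.asarray(swatches[name], float).reshape(-1, 3))
        means[code] = w.mean(axis=0)
        centered = w - means[code]
        covs[code] = centered.T @ centered / len(w) + ridge * np.eye(3)
    white = REFERENCE_WHITE if reference_white is None else np.asarray(reference_white, float)
    return ColorModel(means=means, covariances=covs, reference_white=white)


def classify_pixels(image: SectionImage, model: ColorModel | None = None) -> ClassMap:
    """Assign every pixel the class minimizing squared Mahalanobis distance.

    Equal priors; deterministic; exact ties resolve to the lowest class code
    (glass < cytoplasm < nucleus < collagen < elastin).
    """
    model = model or default_color_model()
    h, w, _ = image.pixels.shape
    x = rgb_to_working(image.pixels).reshape(-1, 3)
    prec = model.precisions
    d2 = np.empty((x.shape[0], 5))
    for k in range(5):
        diff = x - model.means[k]
        d2[:, k] = np.einsum("ij,jk,ik->i", diff, prec[k], diff)
    labels = np.argmin(d2, axis=1).astype(np.uint8).reshape(h, w)
    return ClassMap(labels=labels)


def tile_side_for_area(resolution_um_per_px: float, tile_area_mm2: float = 1.0) -> int:
    """Side length in pixels of a square tile of the given physical area.

    floor(sqrt(area_mm²) × 1000 / resolution); at 0.46 μm/px a 1 mm² tile is
    2173 px on a side (2173² = 4,721,929 px).
    """
    if not resolution_um_per_px > 0 or not tile_area_mm2 > 0:
        raise ValueError("resolution and tile area must be positive")
    return int(np.floor(np.sqrt(tile_area_mm2) * 1000.0 / resolution_um_per_px))


def quantify_section(
    class_map: ClassMap,
    tile_side_px: int,
    min_tissue_fraction: float = 0.01,
) -> FiberQuantResult:
    """Tile the class map, compute per-tile CPA/EPA, aggregate by the median.

    Tiles are half-open, row-major, anchored at the top-left pixel; partial
    edge tiles are kept (proportional areas are scale-free).  A tile enters
    the median iff its tissue fraction (four tissue classes over all tile
    pixels) is at least ``min_tissue_fraction`` — glass-dominated vascular
    lumina drop out, which is what makes the median robust to vessels.
    CPA/EPA denominators are tissue pixels only; glass never counts.
    """
    labels = class_map.labels
    if labels.size == 0:
        raise NoTissueError("empty class map")
    if tile_side_px < 1:
        raise ValueError("tile side must be >= 1 px")
    h, w = labels.shape
    tiles: list[TileQuant] = []
    for tr, r0 in enumerate(range(0, h, tile_side_px)):
        for tc, c0 in enumerate(range(0, w, tile_side_px)):
            block = labels[r0 : r0 + tile_side_px, c0 : c0 + tile_side_px]
            counts = np.bincount(block.ravel(), minlength=5)
            tissue = int(counts[list(TISSUE_CLASSES)].sum())
            included = tissue / block.size >= min_tissue_fraction and tissue > 0
            tiles.append(
                TileQuant(
                    tile_row=tr,
                    tile_col=tc,
                    class_counts=tuple(int(c) for c in counts),
                    included=included,
                )
            )
    incl = [t for t in tiles if t.included]
    if not incl:
        raise NoTissueError("no tile reached the minimum tissue fraction")
    # even tile count -> mean of the two middle values (np.median convention)
    median_cpa = float(np.median([t.cpa for t in incl]))
    median_epa = float(np.median([t.epa for t in incl]))
    return FiberQuantResult(
        tiles=tuple(tiles),
        tile_side_px=int(tile_side_px),
        median_cpa=median_cpa,
        median_epa=median_epa,
    )


def quantify_image(
    image: SectionImage,
    model: ColorModel | None = None,
    tile_area_mm2: float = 1.0,
    min_tissue_fraction: float = 0.01,
) -> tuple[FiberQuantResult, ClassMap]:
    """Calibrate → classify → tile → quantify, in memory."""
    model = model or default_color_model()
    stages = (
        ("calibrate", lambda im: calibrate_colors(im, model)),
        ("classify", lambda im: classify_pixels(im, model)),
    )
    obj = image
    for name, fn in stages:
        try:
            obj = fn(obj)
        except Exception as exc:  # noqa: BLE001 - stage name must be attached
            raise StageError(name, exc) from exc
    try:
        side = tile_side_for_area(image.resolution_um_per_px, tile_area_mm2)
        result = quantify_section(obj, side, min_tissue_fraction)
    except Exception as exc:
        raise StageError("quantify", exc) from exc
    return result, obj


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

OVERLAY_COLORS = np.array(
    [
        (255, 255, 255),  # glass: white
        (210, 210, 210),  # cytoplasm: light gray
        (110, 110, 110),  # nucleus: dark gray
        (220, 40, 40),  # collagen: red
        (40, 60, 220),  # elastin: blue
    ],
    dtype=np.uint8,
)


def sidecar_path(image_path: str | Path) -> Path:
    return Path(image_path).with_suffix(".json")


def read_section_image(
    image_path: str | Path, resolution_um_per_px: float | None = None
) -> tuple[SectionImage, dict]:
    """Read a PNG/TIFF section and its JSON sidecar (resolution, patient id).

    An explicit ``resolution_um_per_px`` overrides the sidecar; one of the
    two must provide the resolution.
    """
    path = Path(image_path)
    meta: dict = {}
    sc = sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    res = resolution_um_per_px if resolution_um_per_px is not None else meta.get("resolution_um_per_px")
    if res is None:
        raise ValueError(f"no resolution for {path}: pass one or provide a JSON sidecar")
    pixels = np.asarray(Image.open(path).convert("RGB"))
    return SectionImage(pixels=pixels, resolution_um_per_px=float(res)), meta


def write_section_image(image: SectionImage, image_path: str | Path, **metadata) -> Path:
    """Write the RGB raster plus a JSON sidecar with resolution and metadata."""
    path = Path(image_path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(image.pixels).save(path)
    meta = {"resolution_um_per_px": image.resolution_um_per_px, **metadata}
    sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def write_quant_outputs(
    result: FiberQuantResult,
    class_map: ClassMap,
    out_dir: str | Path,
    stem: str,
    write_overlay: bool = False,
) -> dict[str, Path]:
    """Write the per-tile CSV, the JSON summary, and optionally the
    color-mapping overlay (collagen red, elastin blue)."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "tile_row": t.tile_row,
            "tile_col": t.tile_col,
            **{f"{n}_px": t.class_counts[c] for c, n in enumerate(CLASS_NAMES)},
            "tissue_px": t.tissue_pixels,
            "cpa": t.cpa,
            "epa": t.epa,
            "included": t.included,
        }
        for t in result.tiles
    ]
    paths = {"tiles": out / f"{stem}_tiles.csv", "summary": out / f"{stem}_summary.json"}
    pd.DataFrame(rows).to_csv(paths["tiles"], index=False, float_format="%.6f")
    paths["summary"].write_text(
        json.dumps(
            {
                "median_cpa": result.median_cpa,
                "median_epa": result.median_epa,
                "tile_side_px": result.tile_side_px,
                "n_tiles_included": result.n_tiles_included,
            },
            indent=1,
            sort_keys=True,
        )
    )
    if write_overlay:
        paths["overlay"] = out / f"{stem}_overlay.png"
        Image.fromarray(OVERLAY_COLORS[class_map.labels]).save(paths["overlay"])
    return paths


def run_quantification(
    image_path: str | Path,
    model: ColorModel | None = None,
    *,
    resolution_um_per_px: float | None = None,
    tile_area_mm2: float = 1.0,
    min_tissue_fraction: float = 0.01,
    out_dir: str | Path | None = None,
    write_overlay: bool = False,
) -> FiberQuantResult:
    """Full single-section pipeline from an image file to the median summary.

    Composes read → calibrate → classify → tile → quantify and, when
    ``out_dir`` is given, writes the per-tile CSV / JSON summary / optional
    overlay.  Errors carry the failing stage's name.
    """
    try:
        image, _meta = read_section_image(image_path, resolution_um_per_px)
    except Exception as exc:
        raise StageError("read", exc) from exc
    result, class_map = quantify_image(
        image, model, tile_area_mm2=tile_area_mm2, min_tissue_fraction=min_tissue_fraction
    )
    if out_dir is not None:
        write_quant_outputs(result, class_map, out_dir, Path(image_path).stem, write_overlay)
    return result
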