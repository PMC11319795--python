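"""Quantification of B-mode muscle ultrasound images.

Implements the three measurement families used in age-related muscle
composition studies:

* **Echo-intensity (EI)** — mean gray level (0–255) of the pixels inside a
  manually outlined muscle cross-section polygon.  Higher EI indicates more
  intramuscular fat / connective tissue.
* **Thicknesses** — muscle thickness (MT) and subcutaneous adipose tissue
  thickness (SAT), vertical distances between tissue interfaces on the
  image's central scan line, converted to cm with the pixel spacing.
* **GLCM texture** — gray-level co-occurrence matrices at a one-pixel offset
  in four directions (0°, 90°, 180°, 270°), averaged, and summarized with
  five Haralick features: angular second moment (ASM), contrast, correlation,
  inverse difference moment (IDM) and entropy.

Coordinates are 0-based ``(row, col)`` with row increasing downward.  A pixel
belongs to a polygon ROI when its center lies inside or on the boundary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
from PIL import Image
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "GrayImage",
    "PolygonROI",
    "RectROI",
    "LandmarkSet",
    "MuscleMeasures",
    "GLCMConfig",
    "GLCMFeatures",
    "compute_ei",
    "measure_thickness",
    "compute_glcm",
    "haralick_features",
    "glcm_features",
    "average_replicates",
    "read_image",
    "write_image",
    "read_sidecar",
    "write_sidecar",
    "FEATURE_COLUMNS",
]

#: canonical column order for per-image / per-subject feature tables
FEATURE_COLUMNS = ["MT_cm", "SAT_cm", "EI", "ASM", "Contrast", "Correlation", "IDM", "Entropy"]

#: sentinel returned for GLCM correlation when a marginal SD is zero
CORRELATION_UNDEFINED = float("nan")

# direction -> (drow, dcol) pixel offset at unit distance; 0° points right
# (increasing column), 90° up (decreasing row), matching the usual image
# convention of a y-axis growing downward.
_DIRECTION_OFFSETS = {0: (0, 1), 90: (-1, 0), 180: (0, -1), 270: (1, 0)}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrayImage:
    """8-bit grayscale image with isotropic pixel spacing in cm/pixel."""

    pixels: np.ndarray
    pixel_spacing: float = 0.01
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("GrayImage requires a 2-D grid of at least 2x2 pixels")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8))
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class PolygonROI:
    """Simple polygon in (row, col) pixel coordinates; >= 3 vertices."""

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        verts = tuple((float(r), float(c)) for r, c in self.vertices)
        if len(verts) < 3:
            raise ValueError("polygon ROI needs at least 3 vertices")
        poly = _ShapelyPolygon([(c, r) for r, c in verts])  # shapely is (x, y)
        if not poly.is_valid:
            raise ValueError("polygon ROI is self-intersecting or degenerate")
        object.__setattr__(self, "vertices", verts)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of pixels whose centers are inside or on the boundary."""
        rows, cols = shape
        rmin = max(0, int(math.floor(min(r for r, _ in self.vertices))))
        rmax = min(rows - 1, int(math.ceil(max(r for r, _ in self.vertices))))
        cmin = max(0, int(math.floor(min(c for _, c in self.vertices))))
        cmax = min(cols - 1, int(math.ceil(max(c for _, c in self.vertices))))
        mask = np.zeros(shape, dtype=bool)
        if rmax < rmin or cmax < cmin:
            return mask
        rr, cc = np.meshgrid(np.arange(rmin, rmax + 1), np.arange(cmin, cmax + 1), indexing="ij")
        poly = _ShapelyPolygon([(c, r) for r, c in self.vertices])
        pts = shapely.points(cc.ravel().astype(float), rr.ravel().astype(float))
        inside = shapely.covers(poly, pts).reshape(rr.shape)
        mask[rmin : rmax + 1, cmin : cmax + 1] = inside
        return mask


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangle: top-left pixel plus extent, all in pixels."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 2 or self.width < 2:
            raise ValueError("rectangle ROI must be at least 2 pixels in each dimension")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("rectangle ROI origin must be non-negative")

    def extract(self, image: GrayImage) -> np.ndarray:
        rows, cols = image.shape
        if self.row0 + self.height > rows or self.col0 + self.width > cols:
            raise ValueError("rectangle ROI extends outside the image")
        return image.pixels[self.row0 : self.row0 + self.height, self.col0 : self.col0 + self.width]


@dataclass(frozen=True)
class LandmarkSet:
    """Tissue-interface depths (pixels) on the image's central vertical line.

    ``skin_depth`` marks the skin surface, ``superficial_apo_depth`` the
    superficial aponeurosis border and ``deep_boundary_depth`` the deep
    aponeurosis (or bone) border.
    """

    skin_depth: float
    superficial_apo_depth: float
    deep_boundary_depth: float

    def __post_init__(self) -> None:
        if not (self.skin_depth <= self.superficial_apo_depth <= self.deep_boundary_depth):
            raise ValueError(
                "landmark depths must satisfy skin <= superficial aponeurosis <= deep boundary"
            )


@dataclass(frozen=True)
class MuscleMeasures:
    """Conventional per-image measures: thicknesses in cm, EI in gray levels."""

    MT_cm: float
    SAT_cm: float
    EI: float

    def __post_init__(self) -> None:
        if self.MT_cm < 0 or self.SAT_cm < 0:
            raise ValueError("thicknesses must be non-negative")
        if not (0 <= self.EI <= 255):
            raise ValueError("EI must lie in [0, 255]")


@dataclass(frozen=True)
class GLCMConfig:
    """Settings for co-occurrence texture analysis.

    ``levels`` gray levels (8-bit default, no requantization), ``distance``
    in pixels, ``directions`` in degrees.  ``log_base`` selects the entropy
    logarithm.  ``correlation_variant`` chooses between the standard
    normalized correlation (range [-1, 1]) and a plugin-compatible variant
    that divides the co-occurrence covariance by the variance product, which
    reproduces the ~1e-3 magnitudes reported by the common ImageJ texture
    plugin.
    """

    levels: int = 256
    distance: int = 1
    directions: tuple[int, ...] = (0, 90, 180, 270)
    log_base: float = math.e
    correlation_variant: str = "standard"

    def __post_init__(self) -> None:
        if not (2 <= self.levels <= 256):
            raise ValueError("levels must be in 2..256")
        if self.distance < 1:
            raise ValueError("distance must be >= 1 pixel")
        if not self.directions:
            raise ValueError("at least one direction required")
        for d in self.directions:
            if d % 360 not in _DIRECTION_OFFSETS:
                raise ValueError(f"unsupported direction {d}; use multiples of 90 degrees")
        if self.correlation_variant not in ("standard", "plugin_compatible"):
            raise ValueError("correlation_variant must be 'standard' or 'plugin_compatible'")


@dataclass(frozen=True)
class GLCMFeatures:
    """The five Haralick summaries of a normalized co-occurrence matrix."""

    ASM: float
    Contrast: float
    Correlation: float
    IDM: float
    Entropy: float


# ---------------------------------------------------------------------------
# echo-intensity and thickness
# ---------------------------------------------------------------------------

def compute_ei(image: GrayImage, roi: PolygonROI) -> float:
    """Mean pixel intensity inside the polygon ROI (boundary pixels included)."""
    mask = roi.mask(image.shape)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"polygon ROI {roi.vertices[:3]}... encloses no pixel centers")
    return float(image.pixels[mask].mean())


def measure_thickness(lm: LandmarkSet, pixel_spacing: float) -> tuple[float, float]:
    """(MT, SAT) in cm from interface depths and the pixel spacing.

    SAT is the skin-to-superficial-aponeurosis distance; MT the superficial-
    to-deep-boundary distance.  A zero MT (coincident interfaces) is allowed
    but flagged with a warning-level message via ValueError suppression: the
    caller receives 0.0.
    """
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be positive")
    sat = (lm.superficial_apo_depth - lm.skin_depth) * pixel_spacing
    mt = (lm.deep_boundary_depth - lm.superficial_apo_depth) * pixel_spacing
    return float(mt), float(sat)


# ---------------------------------------------------------------------------
# GLCM and Haralick features
# ---------------------------------------------------------------------------

def compute_glcm(
    image: GrayImage, roi: RectROI, cfg: GLCMConfig = GLCMConfig()
) -> tuple[dict[int, np.ndarray], np.ndarray]:
    """Normalized co-occurrence matrices per direction plus their average.

    For each direction the matrix counts ordered pixel pairs
    ``(patch[r, c], patch[r + dr*d, c + dc*d])`` over all positions where
    both pixels fall inside the rectangular ROI, then normalizes to sum 1.
    The averaged matrix is the element-wise mean over directions (which, for
    the default opposite-direction set, equals the symmetrized matrix).
    """
    patch = roi.extract(image)
    if cfg.levels < 256 and patch.max() >= cfg.levels:
        raise ValueError(f"pixel value {patch.max()} exceeds levels={cfg.levels}")
    d = cfg.distance
    per_direction: dict[int, np.ndarray] = {}
    for ang in cfg.directions:
        dr, dc = _DIRECTION_OFFSETS[ang % 360]
        dr, dc = dr * d, dc * d
        h, w = patch.shape
        if h - abs(dr) < 1 or w - abs(dc) < 1 or (h - abs(dr)) * (w - abs(dc)) == 0:
            raise ValueError(f"ROI ({h}x{w}) too thin for distance {d} at {ang} degrees")
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        ref = patch[r0:r1, c0:c1].ravel().astype(np.intp)
        nbr = patch[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel().astype(np.intp)
        if ref.size == 0:
            raise ValueError(f"ROI too thin for distance {d} at {ang} degrees")
        counts = np.bincount(ref * cfg.levels + nbr, minlength=cfg.levels**2)
        glcm = counts.reshape(cfg.levels, cfg.levels).astype(float)
        per_direction[ang] = glcm / glcm.sum()
    averaged = np.mean(list(per_direction.values()), axis=0)
    return per_direction, averaged


def haralick_features(glcm_avg: np.ndarray, cfg: GLCMConfig = GLCMConfig()) -> GLCMFeatures:
    """Five Haralick features of a normalized GLCM.

    ASM = Σ p²; Contrast = Σ (i−j)² p; IDM = Σ p / (1+(i−j)²);
    Entropy = −Σ p log p (base ``cfg.log_base``); Correlation (standard) =
    Σ (i−μ_i)(j−μ_j) p / (σ_i σ_j).  With a single occupied gray level the
    marginal SDs vanish and correlation is returned as NaN rather than
    dividing by zero.
    """
    p = np.asarray(glcm_avg, dtype=float)
    total = p.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"GLCM must be normalized to sum 1 (got {total!r})")
    n = p.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    asm = float((p**2).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    idm = float((p / (1.0 + (i - j) ** 2)).sum())
    pos = p[p > 0]
    entropy = float(-(pos * (np.log(pos) / math.log(cfg.log_base))).sum())
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((np.arange(n) * pi).sum())
    mu_j = float((np.arange(n) * pj).sum())
    var_i = float(((np.arange(n) - mu_i) ** 2 * pi).sum())
    var_j = float(((np.arange(n) - mu_j) ** 2 * pj).sum())
    cov = float(((i - mu_i) * (j - mu_j) * p).sum())
    if var_i <= 0 or var_j <= 0:
        corr = CORRELATION_UNDEFINED
    elif cfg.correlation_variant == "plugin_compatible":
        corr = cov / (var_i * var_j)
    else:
        corr = cov / math.sqrt(var_i * var_j)
    return GLCMFeatures(ASM=asm, Contrast=contrast, Correlation=corr, IDM=idm, Entropy=entropy)


def glcm_features(image: GrayImage, roi: RectROI, cfg: GLCMConfig = GLCMConfig()) -> GLCMFeatures:
    """Convenience: direction-averaged GLCM followed by Haralick features."""
    _, averaged = compute_glcm(image, roi, cfg)
    return haralick_features(averaged, cfg)


# ---------------------------------------------------------------------------
# replicate averaging
# ---------------------------------------------------------------------------

def average_replicates(records: Sequence):
    """Element-wise mean of replicate MuscleMeasures or GLCMFeatures records.

    Returns ``(averaged_record, n_replicates)``.  NaN fields (e.g. an
    undefined correlation) propagate via nanmean so one degenerate replicate
    does not poison the average.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot average an empty replicate list")
    cls = type(records[0])
    if any(type(r) is not cls for r in records):
        raise ValueError("replicates must all be the same record type")
    names = [f.name for f in fields(cls)]
    values = {}
    for name in names:
        col = np.array([getattr(r, name) for r in records], dtype=float)
        values[name] = float(np.nanmean(col)) if np.isnan(col).any() else float(col.mean())
    return cls(**values), len(records)


# ---------------------------------------------------------------------------
# file formats: 8-bit PNG/JPEG images and JSON ROI/landmark sidecars
# ---------------------------------------------------------------------------

def read_image(path: str | Path, pixel_spacing: float = 0.01) -> GrayImage:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return GrayImage(pixels=arr, pixel_spacing=pixel_spacing, id=Path(path).stem)


def write_image(image: GrayImage, path: str | Path) -> None:
    Image.fromarray(image.pixels, mode="L").save(path)


def write_sidecar(
    path: str | Path,
    landmarks: LandmarkSet,
    polygon: PolygonROI,
    rect: RectROI,
    pixel_spacing: float,
) -> None:
    """JSON sidecar with 0-based (row, col) coordinates, row growing downward."""
    payload = {
        "coordinate_convention": "0-based (row, col); row increases downward",
        "pixel_spacing_cm_per_px": pixel_spacing,
        "landmarks_px": {
            "skin_depth": landmarks.skin_depth,
            "superficial_apo_depth": landmarks.superficial_apo_depth,
            "deep_boundary_depth": landmarks.deep_boundary_depth,
        },
        "polygon_roi_vertices": [[r, c] for r, c in polygon.vertices],
        "rect_roi": {"row0": rect.row0, "col0": rect.col0, "rows": rect.height, "cols": rect.width},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_sidecar(path: str | Path) -> tuple[LandmarkSet, PolygonROI, RectROI, float]:
    data = json.loads(Path(path).read_text())
    lm = LandmarkSet(**data["landmarks_px"])
    poly = PolygonROI(vertices=tuple((r, c) for r, c in data["polygon_roi_vertices"]))
    rect = RectROI(
        row0=data["rect_roi"]["row0"],
        col0=data["rect_roi"]["col0"],
        height=data["rect_roi"]["rows"],
        width=data["rect_roi"]["cols"],
    )
    return lm, poly, rect, float(data["pixel_spacing_cm_per_px"])
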