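"""Particle segmentation and 2-D shape factors.

Micrographs show dispersed powder particles as dark blobs on a bright
background (or the inverse, configurable).  Segmentation binarizes with a
global Otsu threshold, labels connected components, drops border-touching
regions and small debris, and extracts one sub-pixel boundary polygon per
particle.  Nine shape factors are then computed from exact polygon
geometry:

* area ``A`` (shoelace), perimeter ``P``, equivalent diameter ``sqrt(4A/pi)``
* maximum / minimum Feret diameter (rotating calipers on the convex hull)
* elongation ``minFeret / maxFeret`` (1 = equant)
* solidity ``A / hull area``, convexity ``hull perimeter / P``
* circularity ``4 pi A / P**2``

Ratio factors are clamped to [0, 1]: contour smoothing can push the
perimeter marginally below the hull perimeter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from skimage import measure, segmentation
from skimage.filters import threshold_otsu

#: canonical order of the nine shape factors, used for table columns
FACTOR_NAMES = [
    "area",
    "perimeter",
    "equivalent_diameter",
    "max_feret",
    "min_feret",
    "elongation",
    "solidity",
    "convexity",
    "circularity",
]


@dataclass(frozen=True)
class ParticleShape:
    """Nine 2-D shape factors of a single particle outline.

    Lengths are in pixels and areas in px**2 unless a micrometre scale is
    applied downstream.  ``elongation``, ``solidity``, ``convexity`` and
    ``circularity`` are dimensionless in (0, 1].
    """

    area: float
    perimeter: float
    equivalent_diameter: float
    max_feret: float
    min_feret: float
    elongation: float
    solidity: float
    convexity: float
    circularity: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass
class SegmentationConfig:
    """Settings for :func:`segment_particles`.

    threshold
        ``"otsu"`` for an automatic global threshold, or a float in the
        image's intensity range.
    dark_particles
        Polarity: True if particles are darker than the background.
    min_area
        Regions below this area (px**2) are discarded as debris.
    smooth_window
        Circular moving-average window (vertices) applied to each contour;
        1 disables smoothing.  Light smoothing removes the pixel staircase
        that biases perimeter high and circularity low.
    um_per_px
        Physical pixel pitch; recorded for downstream unit conversion only.
    """

    threshold: str | float = "otsu"
    dark_particles: bool = True
    min_area: float = 50.0
    smooth_window: int = 7
    um_per_px: float = 2.0


# ---------------------------------------------------------------------------
# polygon geometry
# ---------------------------------------------------------------------------

def polygon_area(polygon: np.ndarray) -> float:
    """Shoelace area of a simple polygon given as an (n, 2) vertex array."""
    p = np.asarray(polygon, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_perimeter(polygon: np.ndarray) -> float:
    p = np.asarray(polygon, dtype=float)
    return float(np.sum(np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1)))


def feret_diameters(polygon: np.ndarray) -> tuple[float, float]:
    """Maximum and minimum Feret (caliper) diameters of a simple polygon.

    Both extremes are attained on the convex hull: the maximum over
    antipodal vertex pairs, the minimum over hull-edge orientations (the
    width of the hull normal to some edge).  Both are computed exactly at
    hull vertices/edges, not on a sampled angular grid.

    Raises
    ------
    ValueError
        If the polygon is degenerate (fewer than 3 vertices or collinear).
    """
    p = np.asarray(polygon, dtype=float)
    if p.ndim != 2 or p.shape[0] < 3:
        raise ValueError("polygon needs at least 3 vertices")
    try:
        hull = ConvexHull(p)
    except QhullError as exc:  # collinear input
        raise ValueError(f"degenerate polygon: {exc}") from exc
    hv = p[hull.vertices]

    diff = hv[:, None, :] - hv[None, :, :]
    max_feret = float(np.sqrt((diff ** 2).sum(-1)).max())

    edges = np.roll(hv, -1, axis=0) - hv
    lengths = np.linalg.norm(edges, axis=1)
    normals = np.column_stack([-edges[:, 1], edges[:, 0]]) / lengths[:, None]
    # width normal to each edge = spread of vertex projections on the normal
    proj = normals @ hv.T
    widths = proj.max(axis=1) - proj.min(axis=1)
    min_feret = float(widths.min())
    return max_feret, min_feret


def shape_factors(polygon: np.ndarray) -> ParticleShape:
    """Compute all nine shape factors from a simple closed polygon.

    The vertex array must not repeat the first vertex at the end; closure
    is implicit.

    Raises
    ------
    ValueError
        For degenerate (zero-area or collinear) polygons.
    """
    p = np.asarray(polygon, dtype=float)
    area = polygon_area(p)
    if area <= 0.0:
        raise ValueError("zero-area polygon")
    perimeter = polygon_perimeter(p)
    max_f, min_f = feret_diameters(p)

    hull = ConvexHull(p)
    hull_pts = p[hull.vertices]
    hull_area = polygon_area(hull_pts)
    hull_perimeter = polygon_perimeter(hull_pts)

    return ParticleShape(
        area=area,
        perimeter=perimeter,
        equivalent_diameter=float(np.sqrt(4.0 * area / np.pi)),
        max_feret=max_f,
        min_feret=min_f,
        elongation=min(min_f / max_f, 1.0),
        solidity=min(area / hull_area, 1.0),
        convexity=min(hull_perimeter / perimeter, 1.0),
        circularity=min(4.0 * np.pi * area / perimeter ** 2, 1.0),
    )


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _smooth_closed(contour: np.ndarray, window: int) -> np.ndarray:
    """Circular moving average along a closed contour."""
    if window <= 1 or len(contour) < 2 * window:
        return contour
    kernel = np.ones(window) / window
    pad = window // 2
    ext = np.vstack([contour[-pad:], contour, contour[:pad]])
    sm = np.column_stack(
        [np.convolve(ext[:, i], kernel, mode="same") for i in range(2)]
    )
    return sm[pad : pad + len(contour)]


def segment_particles(
    image: np.ndarray, config: SegmentationConfig | None = None
) -> list[np.ndarray]:
    """Extract one boundary polygon per particle from a grayscale image.

    Returns polygons as (n, 2) arrays in (x, y) = (col, row) pixel
    coordinates, origin top-left.  Border-touching regions and regions
    below ``config.min_area`` are excluded.  A blank or constant image
    yields an empty list.
    """
    config = config or SegmentationConfig()
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    img = img.astype(float)

    if img.max() == img.min():
        return []
    if config.threshold == "otsu":
        thr = threshold_otsu(img)
    else:
        thr = float(config.threshold)
    mask = img < thr if config.dark_particles else img > thr
    mask = segmentation.clear_border(mask)

    labels = measure.label(mask, connectivity=2)
    polygons: list[np.ndarray] = []
    for region in measure.regionprops(labels):
        if region.area < config.min_area:
            continue
        # sub-pixel contour on the padded region mask, at the 0.5 level
        rmask = np.pad(region.image.astype(float), 1)
        contours = measure.find_contours(rmask, 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)
        if np.allclose(contour[0], contour[-1]):
            contour = contour[:-1]
        contour = _smooth_closed(contour, config.smooth_window)
        r0, c0 = region.bbox[0], region.bbox[1]
        rows = contour[:, 0] + r0 - 1.0
        cols = contour[:, 1] + c0 - 1.0
        poly = np.column_stack([cols, rows])
        if len(poly) >= 3 and polygon_area(poly) >= config.min_area:
            polygons.append(poly)
    return polygons


def to_micrometres(table: pd.DataFrame, um_per_px: float) -> pd.DataFrame:
    """Convert a particle table's pixel units to micrometres (area to um^2)."""
    out = table.copy()
    out["area"] *= um_per_px ** 2
    for col in ("perimeter", "equivalent_diameter", "max_feret", "min_feret"):
        out[col] *= um_per_px
    return out


def process_micrographs(
    images: list[tuple[dict, np.ndarray]],
    config: SegmentationConfig | None = None,
) -> pd.DataFrame:
    """Segment a batch of micrographs into a pooled per-particle table.

    Parameters
    ----------
    images
        List of ``(tags, image)`` pairs, ``tags`` a dict with at least
        ``sample_id``, ``size_class``, ``slide`` and ``image_id`` keys.
    config
        Shared segmentation settings.

    Returns
    -------
    DataFrame with one row per particle: the tag columns followed by the
    nine shape-factor columns.  Particles are pooled, never averaged,
    across photos and slides within a (sample, size class) group; a group
    whose images yield no particles is flagged with a warning.
    """
    rows: list[dict] = []
    seen_groups: set[tuple] = set()
    hit_groups: set[tuple] = set()
    for tags, image in images:
        group = (tags.get("sample_id"), tags.get("size_class"))
        seen_groups.add(group)
        for poly in segment_particles(image, config):
            rec = dict(tags)
            rec.update(shape_factors(poly).as_dict())
            rows.append(rec)
            hit_groups.add(group)

    tag_cols = ["sample_id", "size_class", "slide", "image_id"]
    table = pd.DataFrame(rows, columns=tag_cols + FACTOR_NAMES)
    for group in sorted(seen_groups - hit_groups, key=str):
        warnings.warn(f"no particles detected in group {group}", stacklevel=2)
    return table
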