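"""Synthetic micrograph and bulk-density study generator.

Physical powders are replaced by a stated, fully seeded world: four
powder "brands", each with three sieve-size classes (fine < 180 um,
medium 180-355 um, coarse > 355 um) whose particle outlines follow
brand- and class-specific distributions of size (maximum Feret
diameter), aspect ratio, boundary roughness and agglomerate lobes.
Fine particles are drawn nearly spherical and smooth; coarse particles
large, elongated and irregular — the qualitative morphology gradient of
agglomerated whole milk powder.

A particle outline is a star-convex radial profile (an ellipse modulated
by low-order Fourier roughness) unioned with a few offset circular
lobes, then rescaled so its maximum Feret diameter equals the drawn
size.  Scenes place outlines without overlap, away from the image
border, and render them dark on a bright background with Gaussian
intensity noise; every rendered particle's polygon-exact shape factors
are recorded as ground truth.

The true bulk-density response is linear in the 27 fraction-weighted
composite features (three deciles each of maximum Feret diameter,
circularity and elongation per size class) plus Gaussian noise, with
negative weights on size and positive weights on circularity and
elongation, so that rounder, finer powders pack denser.  Coefficients
are calibrated so that true densities of the default study span roughly
the 330-650 kg/m3 band reported for instant whole milk powder.

The default pixel scale is 1 px = 2 um, mapping the sieve cutoffs
(180 um, 355 um) to 90 px and 177.5 px.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from . import mixture
from .featurize import DECILES, ecdf_deciles, feature_name
from .imaging import FACTOR_NAMES, ParticleShape, feret_diameters, shape_factors

SIZE_CLASSES = mixture.COMPONENTS  # ("coarse", "medium", "fine")
UM_PER_PX = 2.0

#: per-class particle count per rendered image (defaults keep scenes
#: placeable without overlap at 1024 px)
PARTICLES_PER_IMAGE = {"coarse": 6, "medium": 15, "fine": 40}


@dataclass(frozen=True)
class ShapeDistribution:
    """Distribution of one size class's particle outlines.

    mean_max_feret / feret_cv
        Mean and coefficient of variation of the maximum Feret diameter
        draw, px.
    aspect_ratio_mean / aspect_ratio_sd
        Mean and sd of the min/max Feret aspect-ratio draw, in (0, 1].
    roughness
        Amplitude in [0, 0.5) of the radial Fourier boundary
        perturbation; 0 gives a smooth ellipse.
    lobes
        Number of offset sub-blob protrusions modelling agglomeration.
    """

    mean_max_feret: float
    feret_cv: float
    aspect_ratio_mean: float
    aspect_ratio_sd: float
    roughness: float
    lobes: int

    def __post_init__(self):
        if self.mean_max_feret <= 0:
            raise ValueError("mean_max_feret must be positive")
        if not (0 < self.aspect_ratio_mean <= 1):
            raise ValueError("aspect_ratio_mean must be in (0, 1]")
        if not (0 <= self.roughness < 0.5):
            raise ValueError("roughness must be in [0, 0.5)")
        if self.lobes < 0:
            raise ValueError("lobes must be >= 0")


@dataclass(frozen=True)
class BrandArchetype:
    """A powder brand: one ShapeDistribution per size class."""

    name: str
    per_class: dict[str, ShapeDistribution]

    def __post_init__(self):
        if set(self.per_class) != set(SIZE_CLASSES):
            raise ValueError(
                f"archetype {self.name!r} must define exactly the classes "
                f"{SIZE_CLASSES}, got {sorted(self.per_class)}"
            )


@dataclass
class SceneTruth:
    """Ground truth of one rendered scene."""

    image_id: str
    size_class: str
    particles: list[dict] = field(default_factory=list)
    # each particle dict: center (x, y), polygon (n, 2), shape: ParticleShape


@dataclass
class DensityModelSpec:
    """Linear ground-truth density response over composite features, kg/m3."""

    intercept: float
    coefficients: dict[str, float]
    noise_sd: float
    response: str  # "loose" | "tapped"

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def evaluate(self, composite: pd.Series, rng: np.random.Generator) -> float:
        value = self.intercept
        for name, coef in self.coefficients.items():
            value += coef * float(composite[name])
        if self.noise_sd > 0:
            value += float(rng.normal(0.0, self.noise_sd))
        return float(value)


# ---------------------------------------------------------------------------
# default stated world
# ---------------------------------------------------------------------------

_CLASS_BASES = {
    # class: (mean_max_feret px, cv, aspect mean, aspect sd, roughness, lobes)
    "fine": (60.0, 0.22, 0.85, 0.05, 0.04, 0),
    "medium": (130.0, 0.12, 0.75, 0.06, 0.10, 2),
    "coarse": (225.0, 0.12, 0.65, 0.06, 0.18, 4),
}

# brand modifiers: (size multiplier, aspect-ratio shift, roughness multiplier)
_BRAND_MODS = {
    "brand1": (1.06, -0.06, 1.25),
    "brand2": (1.00, 0.00, 1.00),
    "brand3": (0.95, +0.05, 0.75),
    "brand4": (1.00, +0.01, 1.05),
}


def default_archetypes() -> list[BrandArchetype]:
    """Four brand archetypes spanning smooth/round to large/irregular."""
    brands = []
    for name, (smul, ashift, rmul) in _BRAND_MODS.items():
        per_class = {}
        for cls, (mf, cv, am, asd, rough, lobes) in _CLASS_BASES.items():
            per_class[cls] = ShapeDistribution(
                mean_max_feret=mf * smul,
                feret_cv=cv,
                aspect_ratio_mean=min(am + ashift, 1.0),
                aspect_ratio_sd=asd,
                roughness=min(rough * rmul, 0.45),
                lobes=lobes,
            )
        brands.append(BrandArchetype(name=name, per_class=per_class))
    return brands


#: per-class composite-feature names of the nine retained ECDF variables
def composite_names() -> list[str]:
    from .selection import PAPER9

    return [f"{cls}_{v}" for cls in SIZE_CLASSES for v in PAPER9]


def default_density_specs(noise_sd: float = 5.0) -> dict[str, DensityModelSpec]:
    """Loose and tapped ground-truth responses.

    Negative weight on every maximum-Feret decile (larger particles pack
    looser), positive weight on every circularity and elongation decile
    (rounder particles pack denser); intercepts place the default study
    inside the published 330-650 kg/m3 band, tapped above loose.
    """
    specs = {}
    for response, (intercept, c_feret, c_circ, c_elong) in {
        "loose": (264.0, -0.30, 80.0, 55.0),
        "tapped": (307.0, -0.30, 90.0, 60.0),
    }.items():
        coefficients = {}
        for name in composite_names():
            if "maxferet" in name:
                coefficients[name] = c_feret
            elif "circularity" in name:
                coefficients[name] = c_circ
            else:  # elongation
                coefficients[name] = c_elong
        specs[response] = DensityModelSpec(
            intercept=intercept,
            coefficients=coefficients,
            noise_sd=noise_sd,
            response=response,
        )
    return specs


# ---------------------------------------------------------------------------
# particle outlines
# ---------------------------------------------------------------------------

_N_THETA = 128
_MAX_REDRAWS = 50


def _dist_entropy(dist: ShapeDistribution) -> int:
    """Stable 63-bit entropy derived from a ShapeDistribution's parameters."""
    import hashlib

    payload = np.array(
        [
            dist.mean_max_feret,
            dist.feret_cv,
            dist.aspect_ratio_mean,
            dist.aspect_ratio_sd,
            dist.roughness,
            float(dist.lobes),
        ],
        dtype=np.float64,
    ).tobytes()
    return int.from_bytes(hashlib.sha256(payload).digest()[:8], "big") % (2 ** 63)


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def sample_outline(dist: ShapeDistribution, rng_seed) -> np.ndarray:
    """Draw one particle outline as a simple closed polygon, (n, 2) px.

    The polygon's maximum Feret diameter equals the size draw exactly
    (the shape is rescaled after construction); aspect ratio is matched
    by the underlying ellipse and perturbed by roughness and lobes.
    Degenerate draws are rejected and redrawn up to a retry limit.
    """
    rng = _as_rng(rng_seed)

    target = -1.0
    for _ in range(_MAX_REDRAWS):
        target = float(rng.normal(dist.mean_max_feret, dist.feret_cv * dist.mean_max_feret))
        if target > 2.0:  # at least a couple of pixels
            break
    else:
        raise RuntimeError("sample_outline: size draw retry limit exceeded")

    aspect = 0.0
    for _ in range(_MAX_REDRAWS):
        aspect = float(rng.normal(dist.aspect_ratio_mean, dist.aspect_ratio_sd))
        if 0.05 < aspect <= 1.0:
            break
    else:
        raise RuntimeError("sample_outline: aspect-ratio draw retry limit exceeded")

    theta = np.linspace(0.0, 2.0 * np.pi, _N_THETA, endpoint=False)
    a, b = 1.0, aspect
    radius = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)

    if dist.roughness > 0:
        modes = np.arange(2, 7)
        coef_c = rng.normal(0.0, 1.0 / modes)
        coef_s = rng.normal(0.0, 1.0 / modes)
        pert = coef_c @ np.cos(np.outer(modes, theta)) + coef_s @ np.sin(
            np.outer(modes, theta)
        )
        peak = np.abs(pert).max()
        if peak > 0:
            radius = radius * (1.0 + dist.roughness * pert / peak)

    poly = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])

    if dist.lobes > 0:
        shape = Polygon(poly)
        blobs = [shape]
        for _ in range(dist.lobes):
            ang = rng.uniform(0.0, 2.0 * np.pi)
            r_at = float(np.interp(ang % (2 * np.pi), theta, radius, period=2 * np.pi))
            lobe_r = rng.uniform(0.2, 0.35) * np.sqrt(a * b)
            cx, cy = 0.95 * r_at * np.cos(ang), 0.95 * r_at * np.sin(ang)
            blobs.append(shapely.Point(cx, cy).buffer(lobe_r, quad_segs=12))
        merged = shapely.unary_union(blobs)
        if merged.geom_type == "MultiPolygon":
            merged = max(merged.geoms, key=lambda g: g.area)
        poly = np.asarray(merged.exterior.coords)[:-1]

    # random orientation, then rescale so max Feret hits the size draw
    rot = rng.uniform(0.0, 2.0 * np.pi)
    R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
    poly = poly @ R.T
    max_f, _ = feret_diameters(poly)
    poly = poly * (target / max_f)
    return poly - poly.mean(axis=0)


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

def render_scene(
    outlines: list[np.ndarray],
    image_size: int = 1024,
    intensity_noise: float = 0.02,
    rng_seed=0,
    image_id: str = "img0",
    size_class: str = "",
    background: float = 0.85,
    foreground: float = 0.15,
    margin: float = 4.0,
    clearance: float = 3.0,
    max_tries: int = 300,
) -> tuple[np.ndarray, SceneTruth]:
    """Place outlines without overlap and render an 8-bit grayscale image.

    Particles are dark on a bright background by default, kept ``margin``
    px clear of the border and ``clearance`` px clear of each other.
    Ground truth records each placed polygon and its polygon-exact shape
    factors.  Raises ``RuntimeError`` naming the number placed if a
    non-overlapping placement cannot be found.
    """
    from skimage.draw import polygon as draw_polygon

    rng = _as_rng(rng_seed)
    truth = SceneTruth(image_id=image_id, size_class=size_class)
    img = np.full((image_size, image_size), background, dtype=float)

    placed: list[Polygon] = []
    for k, outline in enumerate(outlines):
        outline = np.asarray(outline, dtype=float)
        half_w = np.ptp(outline[:, 0]) / 2.0
        half_h = np.ptp(outline[:, 1]) / 2.0
        lo_x, hi_x = margin + half_w, image_size - margin - half_w
        lo_y, hi_y = margin + half_h, image_size - margin - half_h
        if lo_x >= hi_x or lo_y >= hi_y:
            raise RuntimeError(
                f"render_scene: outline {k} larger than the image; placed {k} "
                f"of {len(outlines)}"
            )
        ok = False
        for _ in range(max_tries):
            cx = rng.uniform(lo_x, hi_x)
            cy = rng.uniform(lo_y, hi_y)
            shifted = outline + [cx, cy]
            candidate = Polygon(shifted).buffer(clearance / 2.0)
            if all(not candidate.intersects(p) for p in placed):
                placed.append(candidate)
                truth.particles.append(
                    {
                        "center": (cx, cy),
                        "polygon": shifted,
                        "shape": shape_factors(shifted),
                    }
                )
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"render_scene: could not place particle {k}; placed "
                f"{len(placed)} of {len(outlines)} without overlap"
            )

    for rec in truth.particles:
        poly = rec["polygon"]
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=img.shape)
        img[rr, cc] = foreground
    if intensity_noise > 0:
        img = img + rng.normal(0.0, intensity_noise, img.shape)
    img8 = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    return img8, truth


# ---------------------------------------------------------------------------
# whole-study simulation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """Everything one simulated study produced.

    ``samples`` holds one row per (brand, design point) with fractions,
    role and true loose/tapped densities; ``truth_table`` pools the true
    shape factors of every rendered particle; ``class_features`` are the
    true per-(brand, size class) nine-variable ECDF vectors the density
    response was evaluated on.
    """

    archetypes: list[BrandArchetype]
    design: list[mixture.MixturePoint]
    images: dict  # (brand, size_class) -> list[np.ndarray]
    truths: dict  # (brand, size_class) -> list[SceneTruth]
    truth_table: pd.DataFrame
    class_features: dict  # (brand, size_class) -> pd.Series over PAPER9 names
    samples: pd.DataFrame
    density_specs: dict[str, DensityModelSpec]
    rng_seed: int


def true_class_features(truths: list[SceneTruth]) -> pd.Series:
    """Nine-variable ECDF vector from pooled ground-truth particles."""
    from .selection import PAPER9

    factors = {f: [] for f in FACTOR_NAMES}
    for truth in truths:
        for rec in truth.particles:
            for f, v in rec["shape"].as_dict().items():
                factors[f].append(v)
    values = {}
    for f in ("max_feret", "circularity", "elongation"):
        dec = ecdf_deciles(factors[f])
        for p, v in zip(DECILES, dec):
            values[feature_name(f, p)] = v
    return pd.Series({v: values[v] for v in PAPER9})


def simulate_study(
    archetypes: list[BrandArchetype] | None = None,
    design: list[mixture.MixturePoint] | None = None,
    density_specs: dict[str, DensityModelSpec] | None = None,
    images_per_sample: int = 3,
    particles_per_image: dict[str, int] | None = None,
    image_size: int = 1024,
    intensity_noise: float = 0.02,
    rng_seed: int = 0,
) -> SyntheticStudy:
    """Simulate the full 4-brand x 10-design-point study.

    For every (brand, size class), ``images_per_sample`` scenes are
    rendered (one slide each) and their ground-truth shape factors
    pooled; for every (brand, design point), the true loose and tapped
    densities are the linear density response evaluated on the
    fraction-weighted composite of the brand's true class features, plus
    Gaussian noise.  All randomness derives from ``rng_seed``.
    """
    archetypes = archetypes if archetypes is not None else default_archetypes()
    design = design if design is not None else mixture.constrained_design()
    density_specs = density_specs if density_specs is not None else default_density_specs()
    particles_per_image = particles_per_image or dict(PARTICLES_PER_IMAGE)

    for arch in archetypes:  # validated in __post_init__, re-checked for dicts built by hand
        if set(arch.per_class) != set(SIZE_CLASSES):
            raise ValueError(f"archetype {arch.name!r} missing a size class")

    noise_rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 0xD51]))

    images: dict = {}
    truths: dict = {}
    class_features: dict = {}
    truth_rows: list[dict] = []
    for arch in archetypes:
        for ci, cls in enumerate(SIZE_CLASSES):
            # the scene seed depends on the generating distribution, not the
            # brand label: identical archetypes reproduce identical scenes
            rng = np.random.default_rng(
                np.random.SeedSequence([rng_seed, ci, _dist_entropy(arch.per_class[cls])])
            )
            dist = arch.per_class[cls]
            imgs, trs = [], []
            for i in range(images_per_sample):
                outlines = [
                    sample_outline(dist, rng)
                    for _ in range(particles_per_image[cls])
                ]
                img, truth = render_scene(
                    outlines,
                    image_size=image_size,
                    intensity_noise=intensity_noise,
                    rng_seed=rng,
                    image_id=f"{arch.name}_{cls}_{i}",
                    size_class=cls,
                )
                imgs.append(img)
                trs.append(truth)
                for rec in truth.particles:
                    row = {
                        "sample_id": arch.name,
                        "size_class": cls,
                        "slide": i,
                        "image_id": truth.image_id,
                    }
                    row.update(rec["shape"].as_dict())
                    truth_rows.append(row)
            images[(arch.name, cls)] = imgs
            truths[(arch.name, cls)] = trs
            class_features[(arch.name, cls)] = true_class_features(trs)

    sample_rows = []
    for arch in archetypes:
        group = {cls: class_features[(arch.name, cls)] for cls in SIZE_CLASSES}
        for i, point in enumerate(design):
            composite = mixture.composite_features(group, point)
            row = {
                "brand": arch.name,
                "sample": i + 1,
                "role": point.role,
                **{f"frac_{c}": point.fractions[c] for c in SIZE_CLASSES},
            }
            for response, spec in density_specs.items():
                row[f"true_{response}"] = spec.evaluate(composite, noise_rng)
            sample_rows.append(row)

    return SyntheticStudy(
        archetypes=archetypes,
        design=design,
        images=images,
        truths=truths,
        truth_table=pd.DataFrame(truth_rows),
        class_features=class_features,
        samples=pd.DataFrame(sample_rows),
        density_specs=density_specs,
        rng_seed=rng_seed,
    )
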