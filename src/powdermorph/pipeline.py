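"""End-to-end orchestration: simulate -> segment -> featurize -> select ->
composite -> fit -> report.

A run is fully described by a :class:`RunConfig`; a single seed fans out
to per-stage seeds through ``numpy.random.SeedSequence`` spawning, so
re-running the same config reproduces every output bit-identically.  All
artifacts are plain text (CSV/JSON) plus PNG images.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import featurize, imaging, mixture, models, selection, synthetic

log = logging.getLogger("powdermorph")


class FeatureCSVError(ValueError):
    """Malformed feature-table CSV."""


def write_feature_csv(table: pd.DataFrame, path) -> None:
    """Write a (sample_id, size_class)-indexed feature table as CSV."""
    table.to_csv(path, index=True)


def read_feature_csv(path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_csv`.

    Raises :class:`FeatureCSVError` naming the missing column and line
    number on a malformed header.
    """
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    for col in ("sample_id", "size_class"):
        if col not in header:
            raise FeatureCSVError(f"{path}: line 1: missing column {col!r}")
    return pd.read_csv(path, index_col=["sample_id", "size_class"])


@dataclass
class RunConfig:
    """Settings for one reproducible pipeline run."""

    seed: int = 0
    outdir: str = "powdermorph_run"
    # synthetic study
    images_per_sample: int = 3
    image_size: int = 1024
    intensity_noise: float = 0.02
    noise_sd: float = 5.0  # density noise, kg/m3
    particles_per_image: dict = field(
        default_factory=lambda: dict(synthetic.PARTICLES_PER_IMAGE)
    )
    write_images: bool = False
    # segmentation
    segmentation: imaging.SegmentationConfig = field(
        default_factory=imaging.SegmentationConfig
    )
    # featurization / selection
    percentiles: tuple = featurize.DECILES
    selection_mode: str = "paper9"  # "paper9" | "rule"
    n_selected: int = 9
    # ECDF deciles of one factor are strongly correlated by construction;
    # only near-duplicates are filtered
    redundancy_threshold: float = 0.995
    # mixture design
    bounds: mixture.ComponentBounds = field(default_factory=mixture.ComponentBounds.default)
    # models
    max_components: int = 8
    ncomp_rule: str = "parsimonious"
    ncomp_tolerance: float = 0.02
    ann_hidden: int = 10
    ann_split: tuple = (0.70, 0.15, 0.15)
    ann_max_epochs: int = 200
    ann_patience: int = 6

    def settings_dict(self) -> dict:
        d = asdict(self)
        d["segmentation"] = asdict(self.segmentation)
        d["bounds"] = {"lower": self.bounds.lower, "upper": self.bounds.upper}
        return d


def stage_seeds(seed: int) -> dict[str, int]:
    """Fan a single run seed out to per-stage integer seeds (< 2**31)."""
    children = np.random.SeedSequence(seed).spawn(3)
    names = ("simulate", "cv_folds", "ann")
    return {
        name: int(c.generate_state(1)[0] % (2 ** 31))
        for name, c in zip(names, children)
    }


def run(config: RunConfig) -> dict:
    """Execute the whole pipeline and return (and write) the run report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)

    # --- stage 1: synthetic study -------------------------------------
    log.info("simulating study (seed %d)", seeds["simulate"])
    design = mixture.constrained_design(config.bounds)
    study = synthetic.simulate_study(
        design=design,
        density_specs=synthetic.default_density_specs(config.noise_sd),
        images_per_sample=config.images_per_sample,
        particles_per_image=config.particles_per_image,
        image_size=config.image_size,
        intensity_noise=config.intensity_noise,
        rng_seed=seeds["simulate"],
    )
    mixture.design_table(design).to_csv(out / "design.csv", index=False)
    study.samples.to_csv(out / "samples.csv", index=False)
    study.truth_table.to_csv(out / "truth_particles.csv", index=False)
    if config.write_images:
        import imageio.v3 as iio

        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for (brand, cls), imgs in study.images.items():
            for i, img in enumerate(imgs):
                iio.imwrite(img_dir / f"{brand}_{cls}_{i}.png", img)

    # --- stage 2: segmentation ----------------------------------------
    log.info("segmenting %d scenes", sum(len(v) for v in study.images.values()))
    batches = []
    for (brand, cls), imgs in sorted(study.images.items()):
        for i, img in enumerate(imgs):
            tags = {
                "sample_id": brand,
                "size_class": cls,
                "slide": i,
                "image_id": f"{brand}_{cls}_{i}",
            }
            batches.append((tags, img))
    particles = imaging.process_micrographs(batches, config.segmentation)
    particles.to_csv(out / "particles.csv", index=False)

    # --- stage 3: featurization + selection ---------------------------
    full = featurize.feature_matrix(particles, percentiles=config.percentiles)
    full.to_csv(out / "features_90.csv")
    if config.selection_mode == "paper9":
        selected_names = list(selection.PAPER9)
        stage1 = list(selection.STAGE1_FACTORS)
    elif config.selection_mode == "rule":
        stage1_pca = selection.pca(full)
        stage1_short = selection.select_factors(stage1_pca, 3)
        stage1 = [featurize.LONG_NAMES.get(s, s) for s in stage1_short]
        reduced = featurize.feature_matrix(
            particles, factors=stage1, percentiles=config.percentiles
        )
        idx = selection.select_variables(
            selection.pca(reduced), config.n_selected, config.redundancy_threshold
        )
        selected_names = [reduced.columns[j] for j in sorted(idx)]
    else:
        raise ValueError(f"unknown selection mode {config.selection_mode!r}")
    log.info("selected variables: %s", selected_names)
    selected = featurize.feature_matrix(
        particles, factors=stage1, percentiles=config.percentiles
    )[selected_names]
    selected.to_csv(out / "features_selected.csv")

    # --- stage 4: compositing -----------------------------------------
    brands = sorted({b for b, _ in study.class_features})
    X_rows, labels = [], []
    for brand in brands:
        group = {
            cls: selected.loc[(brand, cls)] for cls in mixture.COMPONENTS
        }
        for i, point in enumerate(design):
            comp = mixture.composite_features(group, point)
            X_rows.append(comp)
            labels.append((brand, i + 1))
    X = pd.DataFrame(X_rows, index=pd.MultiIndex.from_tuples(labels, names=["brand", "sample"]))
    X.to_csv(out / "composites.csv")

    y_tables = study.samples.set_index(["brand", "sample"])
    metrics: dict = {}
    for response in ("loose", "tapped"):
        y = y_tables.loc[X.index, f"true_{response}"].to_numpy()
        report = models.crossval(
            X.to_numpy(), y, config.max_components, folds=5, rng_seed=seeds["cv_folds"]
        )
        ncomp = models.select_ncomp(report, config.ncomp_rule, config.ncomp_tolerance)
        fit = models.pls_fit(X.to_numpy(), y, ncomp)
        ann = models.ann_fit(
            X.to_numpy(),
            y,
            hidden=config.ann_hidden,
            split=config.ann_split,
            max_epochs=config.ann_max_epochs,
            rng_seed=seeds["ann"],
            patience=config.ann_patience,
        )
        metrics[response] = {
            "pls": {
                "n_components": ncomp,
                "r2": fit.r2,
                "q2": float(report.q2[ncomp - 1]),
                "mse": fit.mse,
                "q2_by_ncomp": report.q2.tolist(),
                "r2_by_ncomp": report.r2.tolist(),
            },
            "ann": {
                "split_sizes": list(ann.split_sizes),
                "stopping_epoch": ann.stopping_epoch,
                "mse": ann.mse,
                "r2": ann.r2,
            },
        }
        coef = pd.Series(fit.coef, index=X.columns, name=f"coef_{response}")
        coef.to_csv(out / f"pls_coefficients_{response}.csv")

    report_obj = {
        "n_samples": int(len(X)),
        "n_composite_variables": int(X.shape[1]),
        "n_brands": len(brands),
        "n_design_points": len(design),
        "selected_variables": selected_names,
        "metrics": metrics,
        "seeds": seeds,
        "settings": config.settings_dict(),
    }
    text = json.dumps(report_obj, indent=2, sort_keys=True, default=str)
    (out / "report.json").write_text(text)
    # hash the scientific content only: the output path is not part of it
    hashable = json.loads(text)
    hashable["settings"].pop("outdir", None)
    report_obj["report_sha256"] = hashlib.sha256(
        json.dumps(hashable, sort_keys=True).encode()
    ).hexdigest()
    return report_obj
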