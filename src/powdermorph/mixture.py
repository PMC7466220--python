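"""Bounds-constrained simplex-centroid mixture design and feature compositing.

A powder sample is a blend of three sieve-size fractions (coarse > 355 um,
medium 180-355 um, fine < 180 um) whose percentages sum to 100.  The design
comprises the three pure fractions plus the seven points of a 3-component
simplex-centroid design (3 vertices, 3 edge midpoints, 1 centroid) mapped
into the feasible region by the pseudo-component transform

    x_i = L_i + p_i * (100 - sum(L)),

where ``L`` are the lower bounds and ``p`` the canonical simplex
proportions.  Ten design points per powder brand.

Per-sample predictors are built by scaling each size class's feature
vector by its fraction (as a proportion, /100) and concatenating the
three blocks, so nine features per class yield 27 composite variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: fixed component order: matches the design's sample numbering
#: (sample 1 = pure coarse, 2 = pure medium, 3 = pure fine)
COMPONENTS = ("coarse", "medium", "fine")

#: sieving bounds (percent) of the three fractions in instant whole milk
#: powder: fine 20-40, medium 50-70, coarse 10-30
DEFAULT_BOUNDS_PCT = {"coarse": (10.0, 30.0), "medium": (50.0, 70.0), "fine": (20.0, 40.0)}


@dataclass(frozen=True)
class ComponentBounds:
    """Lower/upper percentage bounds per size-class component."""

    lower: dict[str, float]
    upper: dict[str, float]

    def __post_init__(self):
        for comp in COMPONENTS:
            if comp not in self.lower or comp not in self.upper:
                raise ValueError(f"bounds missing component {comp!r}")
            if not self.lower[comp] < self.upper[comp]:
                raise ValueError(f"lower >= upper for component {comp!r}")
        lo, hi = sum(self.lower.values()), sum(self.upper.values())
        if not (lo <= 100.0 <= hi):
            raise ValueError(f"infeasible bounds: sum(lower)={lo}, sum(upper)={hi}")

    @classmethod
    def default(cls) -> "ComponentBounds":
        return cls(
            lower={c: DEFAULT_BOUNDS_PCT[c][0] for c in COMPONENTS},
            upper={c: DEFAULT_BOUNDS_PCT[c][1] for c in COMPONENTS},
        )


@dataclass(frozen=True)
class MixturePoint:
    """One designed sample: percentage per component plus its design role."""

    fractions: dict[str, float]
    role: str  # pure | vertex | edge_midpoint | centroid

    def __post_init__(self):
        total = sum(self.fractions.values())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, not 100")
        if self.role == "pure" and not any(
            abs(v - 100.0) < 1e-9 for v in self.fractions.values()
        ):
            raise ValueError("pure point must have one component at 100%")

    def as_array(self) -> np.ndarray:
        return np.array([self.fractions[c] for c in COMPONENTS])


def scd_canonical(q: int = 3) -> list[tuple[tuple[float, ...], str]]:
    """Canonical 3-component simplex-centroid design in proportions.

    Returns 7 ``(proportions, role)`` pairs: the 3 vertices, the 3 edge
    midpoints, then the overall centroid.  Only ``q = 3`` is supported.
    """
    if q != 3:
        raise ValueError(f"scd_canonical: only q=3 supported, got q={q}")
    pts: list[tuple[tuple[float, ...], str]] = []
    eye = np.eye(3)
    for i in range(3):
        pts.append((tuple(eye[i]), "vertex"))
    for i, j in [(0, 1), (0, 2), (1, 2)]:
        pts.append((tuple((eye[i] + eye[j]) / 2.0), "edge_midpoint"))
    pts.append(((1 / 3, 1 / 3, 1 / 3), "centroid"))
    return pts


def constrained_design(bounds: ComponentBounds | None = None) -> list[MixturePoint]:
    """The ten-point design: 3 pure fractions + 7 bounds-transformed SCD points.

    The pure points deliberately sit outside the bounded region; the SCD
    points are mapped by the pseudo-component transform and always satisfy
    the bounds.
    """
    bounds = bounds or ComponentBounds.default()
    L = np.array([bounds.lower[c] for c in COMPONENTS])
    slack = 100.0 - L.sum()
    points: list[MixturePoint] = []
    for comp in COMPONENTS:
        points.append(
            MixturePoint(
                fractions={c: (100.0 if c == comp else 0.0) for c in COMPONENTS},
                role="pure",
            )
        )
    for proportions, role in scd_canonical(3):
        x = L + np.asarray(proportions) * slack
        for c, v in zip(COMPONENTS, x):
            if v > bounds.upper[c] + 1e-9:
                raise ValueError(
                    f"infeasible bounds: transformed point exceeds upper bound on {c!r}"
                )
        points.append(
            MixturePoint(fractions=dict(zip(COMPONENTS, map(float, x))), role=role)
        )
    return points


def design_table(points: list[MixturePoint]) -> pd.DataFrame:
    """Design as a DataFrame: sample number, role, one percent column per class."""
    return pd.DataFrame(
        [
            {"sample": i + 1, "role": p.role, **{c: p.fractions[c] for c in COMPONENTS}}
            for i, p in enumerate(points)
        ]
    )


def composite_features(
    group_features: dict[str, "pd.Series | np.ndarray"],
    point: MixturePoint,
) -> pd.Series:
    """Fraction-weighted, class-blocked composite feature vector.

    Each size class's feature vector is multiplied by that class's
    fraction (as a proportion) and the blocks are concatenated in
    ``COMPONENTS`` order; labels become ``<class>_<feature>``.  Pure
    samples therefore reproduce one class's raw features with the other
    blocks zero.
    """
    lengths = set()
    blocks, labels = [], []
    for comp in COMPONENTS:
        if comp not in group_features:
            raise KeyError(f"composite_features: missing size class {comp!r}")
        vec = group_features[comp]
        vals = np.asarray(vec, dtype=float)
        lengths.add(vals.size)
        names = (
            list(vec.index)
            if isinstance(vec, pd.Series)
            else [f"f{i}" for i in range(vals.size)]
        )
        blocks.append(vals * (point.fractions[comp] / 100.0))
        labels.extend(f"{comp}_{n}" for n in names)
    if len(lengths) != 1:
        raise ValueError("composite_features: unequal feature-vector lengths")
    return pd.Series(np.concatenate(blocks), index=labels)
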