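"""PCA-based variable reduction.

The reduction runs in two stages: a PCA over all 90 ECDF variables guides
the choice of three shape factors (maximum Feret diameter, circularity,
elongation), and a second PCA over the remaining 30 variables guides the
choice of nine ECDF points.  The published choice of nine variables is
shipped as the ``PAPER9`` preset; :func:`select_variables` additionally
provides a reproducible rule (loading-norm ranking on PC1-PC2 with a
redundancy filter) for data where a manual read of the loading plot is
not available.

PCA is computed by SVD of the autoscaled (zero-mean, unit-sd) matrix, i.e.
correlation-matrix PCA.  Each loading column is sign-flipped so that its
largest-magnitude entry is positive, making loadings deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: the nine ECDF variables retained in the published two-stage reduction:
#: three deciles each of maximum Feret diameter, circularity and elongation
PAPER9 = (
    "maxferet_p30",
    "maxferet_p70",
    "maxferet_p100",
    "circularity_p30",
    "circularity_p70",
    "circularity_p90",
    "elongation_p20",
    "elongation_p30",
    "elongation_p70",
)

#: the three shape factors the first-stage reduction keeps
STAGE1_FACTORS = ("max_feret", "circularity", "elongation")


def autoscale(matrix, ddof: int = 1):
    """Column-standardize to mean 0, sd 1.

    Returns ``(scaled, means, sds)``.  A zero-variance column is an error
    naming the column, since it cannot be scaled.
    """
    X = np.asarray(matrix, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        names = list(matrix.columns[bad]) if hasattr(matrix, "columns") else bad.tolist()
        raise ValueError(f"autoscale: zero-variance column(s) {names}")
    return (X - means) / sds, means, sds


@dataclass
class PCAResult:
    """Correlation-matrix PCA of a samples x variables matrix.

    ``loadings`` columns are orthonormal; ``scores = scaled @ loadings``;
    ``explained_fraction`` is non-increasing and sums to <= 1 when
    truncated.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_fraction: np.ndarray
    scaled: np.ndarray
    columns: list[str]


def pca(matrix, n_components: int | None = None) -> PCAResult:
    """PCA by SVD of the autoscaled matrix.

    Components are ordered by explained variance.  Requires at least two
    samples and two variables with finite entries.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("pca: need at least a 2 x 2 matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("pca: non-finite entries")
    columns = (
        list(matrix.columns)
        if hasattr(matrix, "columns")
        else [f"v{i}" for i in range(X.shape[1])]
    )
    Xs, _, _ = autoscale(matrix)
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    if n_components is not None:
        U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    # sign convention: largest-|entry| of each loading column is positive
    for i in range(Vt.shape[0]):
        j = np.abs(Vt[i]).argmax()
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    return PCAResult(
        scores=U * s,
        loadings=Vt.T,
        explained_fraction=s ** 2 / (np.linalg.norm(Xs) ** 2),
        scaled=Xs,
        columns=columns,
    )


def select_variables(
    result: PCAResult,
    k: int,
    redundancy_threshold: float = 0.95,
) -> list[int]:
    """Pick ``k`` variables by descending PC1-PC2 loading norm.

    Candidates are ranked by the Euclidean norm of their first two
    loadings (ties broken by column order) and accepted greedily, skipping
    any whose absolute Pearson correlation with an already-accepted
    variable exceeds ``redundancy_threshold``.  If fewer than ``k``
    survive, the shorter list is returned with a warning.
    """
    n_vars = result.loadings.shape[0]
    if k > n_vars:
        raise ValueError(f"select_variables: k={k} exceeds {n_vars} variables")
    ncomp = min(2, result.loadings.shape[1])
    norms = np.linalg.norm(result.loadings[:, :ncomp], axis=1)
    order = sorted(range(n_vars), key=lambda j: (-norms[j], j))

    n = result.scaled.shape[0]
    corr = (result.scaled.T @ result.scaled) / np.outer(
        np.linalg.norm(result.scaled, axis=0), np.linalg.norm(result.scaled, axis=0)
    )
    chosen: list[int] = []
    for j in order:
        if len(chosen) == k:
            break
        if any(abs(corr[j, c]) > redundancy_threshold for c in chosen):
            continue
        chosen.append(j)
    if len(chosen) < k:
        warnings.warn(
            f"select_variables: only {len(chosen)} of {k} variables satisfy "
            f"the redundancy threshold {redundancy_threshold}",
            stacklevel=2,
        )
    return chosen


def select_factors(result: PCAResult, n_factors: int = 3) -> list[str]:
    """First-stage reduction: rank whole shape factors by loading strength.

    Aggregates the variance-weighted PC1-PC2 loading norms of each
    factor's decile columns (mean over the factor's columns, column label
    prefix before ``_p``) and returns the top ``n_factors`` factor
    prefixes.  Weighting each loading column by the square root of its
    explained-variance fraction keeps low-variance noise components from
    outranking the dominant morphology axis.
    """
    ncomp = min(2, result.loadings.shape[1])
    weights = np.sqrt(result.explained_fraction[:ncomp])
    norms = np.linalg.norm(result.loadings[:, :ncomp] * weights, axis=1)
    by_factor: dict[str, list[float]] = {}
    for name, w in zip(result.columns, norms):
        prefix = name.rsplit("_p", 1)[0]
        by_factor.setdefault(prefix, []).append(w)
    ranked = sorted(by_factor, key=lambda f: -float(np.mean(by_factor[f])))
    return ranked[:n_factors]
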