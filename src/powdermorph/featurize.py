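"""Per-sample ECDF-decile features from pooled particle shape factors.

Each shape factor's distribution within a (sample, size class) group is
summarized by the inverse empirical CDF evaluated at the ten percentiles
10%, 20%, ..., 100%.  With the default type-1 (right-continuous inverse
ECDF) convention, decile k is the ceil(k*n/10)-th order statistic, so the
100% point is exactly the maximum.  Nine factors x ten deciles gives 90
features per group; restricting to three factors gives 30.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .imaging import FACTOR_NAMES

#: default percentile grid (percent)
DECILES = tuple(range(10, 101, 10))

#: compact factor names used in feature-column labels, e.g. ``maxferet_p30``
SHORT_NAMES = {
    "area": "area",
    "perimeter": "perimeter",
    "equivalent_diameter": "eqdiameter",
    "max_feret": "maxferet",
    "min_feret": "minferet",
    "elongation": "elongation",
    "solidity": "solidity",
    "convexity": "convexity",
    "circularity": "circularity",
}
LONG_NAMES = {v: k for k, v in SHORT_NAMES.items()}


def feature_name(factor: str, percentile: int) -> str:
    """Column label for one (factor, percentile) feature, e.g. ``circularity_p90``."""
    return f"{SHORT_NAMES.get(factor, factor)}_p{int(percentile)}"


def ecdf_deciles(
    values,
    percentiles: tuple[int, ...] = DECILES,
    method: str = "inverted_cdf",
) -> np.ndarray:
    """Inverse-ECDF values at the requested percentiles.

    Parameters
    ----------
    values
        At least one finite number.
    percentiles
        Percent points in (0, 100].
    method
        Quantile convention, passed to :func:`numpy.quantile`.  The
        default ``"inverted_cdf"`` (type 1) returns exact order
        statistics.

    Raises
    ------
    ValueError
        On empty input or non-finite values.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("ecdf_deciles: empty input")
    if not np.all(np.isfinite(v)):
        raise ValueError("ecdf_deciles: non-finite values")
    q = np.asarray(percentiles, dtype=float) / 100.0
    return np.quantile(v, q, method=method)


def feature_matrix(
    table: pd.DataFrame,
    factors: list[str] | None = None,
    percentiles: tuple[int, ...] = DECILES,
    require_groups: list[tuple[str, str]] | None = None,
    method: str = "inverted_cdf",
) -> pd.DataFrame:
    """Build the (groups x features) ECDF-decile matrix from a particle table.

    Rows are (sample_id, size_class) groups in sorted order; columns are
    ``factor_pNN`` labels, factor-major.  ``require_groups`` lists groups
    that must be present and non-empty; a missing one raises ``KeyError``
    naming it.
    """
    factors = list(factors) if factors is not None else list(FACTOR_NAMES)
    groups = {key: sub for key, sub in table.groupby(["sample_id", "size_class"], sort=True)}
    if require_groups is not None:
        for g in require_groups:
            if tuple(g) not in groups:
                raise KeyError(f"feature_matrix: empty or missing group {tuple(g)}")

    columns = [feature_name(f, p) for f in factors for p in percentiles]
    rows, index = [], []
    for key in sorted(groups):
        sub = groups[key]
        vec = np.concatenate(
            [ecdf_deciles(sub[f].to_numpy(), percentiles, method) for f in factors]
        )
        rows.append(vec)
        index.append(key)
    out = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["sample_id", "size_class"]),
        columns=columns,
    )
    return out
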