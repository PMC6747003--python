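"""Expression-matrix preprocessing: missingness filter, rank-based
inverse-normal transform, and removal of leading principal components.

The downstream likelihood model assumes traits on a standard-normal
scale, so :func:`normalize_expression` maps each gene's values through
``Phi^-1((rank - 0.5) / m)`` and then standardizes the row exactly
(mean 0, SD 1 over non-missing entries).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .exceptions import DegenerateDataError, ParameterError


def filter_by_missingness(
    matrix: ExpressionMatrix, min_fraction: float = 0.5
) -> ExpressionMatrix:
    """Keep genes quantified in at least ``min_fraction`` of samples.

    Row order is preserved.  An empty result is returned with a warning
    rather than raised.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ParameterError("min_fraction must be in (0, 1]")
    frac = matrix.values.notna().mean(axis=1)
    keep = frac >= min_fraction
    if not keep.any():
        warnings.warn("missingness filter removed every gene", stacklevel=2)
    return ExpressionMatrix(matrix.values.loc[keep].copy(), scale=matrix.scale)


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform, missing entries untouched.

    Non-missing entries are replaced by ``Phi^-1((rank - 0.5) / m)``
    where ``m`` is the non-missing count and ties get average ranks.
    """
    x = np.asarray(values, dtype=float)
    obs = ~np.isnan(x)
    m = int(obs.sum())
    if m < 3:
        raise DegenerateDataError(f"need >= 3 non-missing values, got {m}")
    ranks = stats.rankdata(x[obs], method="average")
    out = np.full_like(x, np.nan)
    out[obs] = stats.norm.ppf((ranks - 0.5) / m)
    return out


def standardize(values: np.ndarray) -> np.ndarray:
    """Center and scale to unit SD (ddof=1) over non-missing entries."""
    x = np.asarray(values, dtype=float)
    obs = ~np.isnan(x)
    mu = x[obs].mean()
    sd = x[obs].std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("constant vector cannot be standardized")
    out = np.full_like(x, np.nan)
    out[obs] = (x[obs] - mu) / sd
    return out


def normalize_expression(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Inverse-normal transform then exact standardization, per gene."""
    values = matrix.values.copy()
    arr = values.to_numpy(dtype=float)
    for i in range(arr.shape[0]):
        arr[i] = standardize(inverse_normal_transform(arr[i]))
    values.iloc[:, :] = arr
    return ExpressionMatrix(values, scale="normalized")


def remove_principal_components(
    matrix: ExpressionMatrix, k: int
) -> ExpressionMatrix:
    """Project out the top-``k`` sample-space principal components.

    Components are the leading right singular vectors of the
    gene-centered matrix.  ``k = 0`` is the identity.  Missing entries
    are mean-imputed for the decomposition and restored to missing in
    the output.
    """
    n_samples = matrix.values.shape[1]
    if k < 0 or k >= n_samples:
        raise ParameterError(f"k must satisfy 0 <= k < n_samples ({n_samples})")
    if k == 0:
        return ExpressionMatrix(matrix.values.copy(), scale=matrix.scale)

    arr = matrix.values.to_numpy(dtype=float)
    missing = np.isnan(arr)
    row_means = np.nanmean(arr, axis=1, keepdims=True)
    filled = np.where(missing, row_means, arr)
    centered = filled - filled.mean(axis=1, keepdims=True)

    # right singular vectors span sample space
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    v_k = vt[:k].T  # samples x k
    residual = centered - centered @ v_k @ v_k.T
    residual[missing] = np.nan

    out = pd.DataFrame(
        residual, index=matrix.values.index, columns=matrix.values.columns
    )
    return ExpressionMatrix(out, scale=matrix.scale)
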