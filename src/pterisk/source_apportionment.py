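"""PCA source apportionment with Kaiser retention and varimax rotation.

Concentrations are standardised per element (correlation-matrix PCA, since
element scales span orders of magnitude), components with eigenvalue > 1
are retained, retained loadings are varimax-rotated for interpretability,
and each element's contribution to each source is the squared rotated
loading normalised across retained components, so rows of the contribution
matrix M sum to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import rotate_factors

from .core_io import Medium

__all__ = ["SourceModel", "standardize", "pca_kaiser", "element_source_contributions"]


@dataclass
class SourceModel:
    """Retained principal components of one medium's concentration matrix."""

    medium: Optional[Medium]
    eigenvalues: np.ndarray  # all, descending
    retained_k: int
    cumulative_variance: float  # percent explained by retained components
    loadings: pd.DataFrame  # element × retained component (rotated)
    scores: pd.DataFrame  # site × retained component
    m_matrix: Optional[pd.DataFrame] = None  # element × source contribution


def standardize(values: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores (mean 0, SD 1 with the n−1 convention)."""
    if len(values.index) < 3:
        raise ValueError("standardisation requires at least 3 sites")
    sd = values.std(ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant columns cannot be standardised: {constant}")
    return (values - values.mean()) / sd


def _varimax(loadings: np.ndarray) -> np.ndarray:
    rotated, _ = rotate_factors(loadings, "varimax")
    return rotated


def pca_kaiser(
    z: pd.DataFrame,
    rotation: str = "varimax",
    retention: int | str = "kaiser",
    medium: Medium | str | None = None,
) -> SourceModel:
    """Correlation-matrix PCA with Kaiser retention on a standardised matrix.

    ``retention`` is ``"kaiser"`` (strictly eigenvalue > 1; at least one
    component is always kept) or a fixed integer count. ``rotation`` is
    ``"varimax"`` or ``"none"``. Loading signs are normalised so each
    component's largest-magnitude loading is positive. Scores are
    standardised component scores of the (rotated) solution.
    """
    n, m = z.shape
    if n < m:
        warnings.warn(
            f"fewer sites ({n}) than elements ({m}): correlation matrix is rank deficient",
            stacklevel=2,
        )
    corr = np.asarray(z, dtype=float)
    corr = corr.T @ corr / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)

    if retention == "kaiser":
        k = max(1, int(np.sum(eigval > 1.0)))
    else:
        k = int(retention)
        if not 1 <= k <= m:
            raise ValueError(f"fixed retention k={k} outside [1, {m}]")

    load = eigvec[:, :k] * np.sqrt(eigval[:k])
    if rotation == "varimax" and k > 1:
        load = _varimax(load)
    elif rotation not in ("varimax", "none"):
        raise ValueError(f"unknown rotation {rotation!r}")

    # sign convention: dominant loading of each component is positive
    for j in range(load.shape[1]):
        if load[np.argmax(np.abs(load[:, j])), j] < 0:
            load[:, j] = -load[:, j]

    # order rotated components by explained variance (sum of squared loadings)
    ssl = (load**2).sum(axis=0)
    load = load[:, np.argsort(ssl)[::-1]]

    cols = [f"PC{j + 1}" for j in range(k)]
    loadings = pd.DataFrame(load, index=z.columns, columns=cols)
    # standardised regression scores: F = Z L (L'L)^-1, exact for the
    # unrotated solution and rotation-equivariant
    scores_mat = np.asarray(z) @ load @ np.linalg.pinv(load.T @ load)
    scores = pd.DataFrame(scores_mat, index=z.index, columns=cols)

    return SourceModel(
        medium=None if medium is None else Medium(medium),
        eigenvalues=eigval,
        retained_k=k,
        cumulative_variance=float(100.0 * eigval[:k].sum() / eigval.sum()),
        loadings=loadings,
        scores=scores,
    )


def element_source_contributions(model: SourceModel) -> pd.DataFrame:
    """Contribution rate M of each element to each retained source.

    M_{i,k} = L_{i,k}² / Σ_{k'} L_{i,k'}² over retained components; rows sum
    to 1 and the result is invariant to loading signs and component order.
    The model's ``m_matrix`` field is filled in place and returned.
    """
    sq = model.loadings**2
    denom = sq.sum(axis=1)
    dead = denom.index[denom == 0].tolist()
    if dead:
        raise ValueError(f"elements with all-zero retained loadings: {dead}")
    m = sq.div(denom, axis=0)
    model.m_matrix = m
    return m
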