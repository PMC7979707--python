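"""Continuous diet trait from semi-quantitative diet categories.

Species are scored on ten diet categories; a Gower distance matrix over
those scores is embedded by principal coordinates analysis (classical
metric scaling) and the first axis (optionally the first two) serves as a
continuous synthetic diet trait. The leading axis is oriented so that it
correlates positively with the invertebrate category, removing the sign
arbitrariness of eigenvectors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    values: np.ndarray      # n x n symmetric, zero diagonal
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have zero diagonal")


def gower_distance(diet: pd.DataFrame) -> DistanceMatrix:
    """Range-normalised mean absolute difference over diet categories.

    d(i, j) = mean_c |x_ic - x_jc| / range_c, so every entry lies in [0, 1].
    Categories with zero range across species carry no information for this
    metric and are dropped with a warning.
    """
    if len(diet) < 2:
        raise ValueError("need at least 2 species")
    X = diet.to_numpy(float)
    ranges = X.max(axis=0) - X.min(axis=0)
    keep = ranges > 0
    if not keep.any():
        raise ValueError("all diet categories are constant; Gower distance undefined")
    dropped = [c for c, k in zip(diet.columns, keep) if not k]
    if dropped:
        log.warning("dropping zero-range diet categories: %s", dropped)
    Xn = X[:, keep] / ranges[keep]
    D = np.abs(Xn[:, None, :] - Xn[None, :, :]).mean(axis=2)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(values=D, ids=tuple(str(s) for s in diet.index))


@dataclass
class PcoaResult:
    scores: pd.DataFrame             # n x k, species-indexed
    eigenvalues: np.ndarray          # k positive eigenvalues, descending
    variance_fractions: np.ndarray   # lambda_i / sum of positive lambdas
    loadings: pd.DataFrame | None    # category-axis Pearson r (if raw data given)
    scaled_loadings: pd.DataFrame | None  # r * sqrt(variance fraction)


def pcoa(d: DistanceMatrix, k: int, raw: pd.DataFrame | None = None) -> PcoaResult:
    """Classical metric scaling of a distance matrix.

    Double-centres -d^2/2, eigendecomposes, keeps the positive spectrum, and
    returns scores eigenvector * sqrt(eigenvalue). Variance fractions are
    computed over positive eigenvalues only; negative eigenvalues (possible
    for Gower matrices) are discarded without correction. When ``raw``
    category data are supplied, per-category loadings are reported both as
    plain category-axis Pearson correlations and scaled by
    sqrt(variance fraction).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D = d.values
    n = D.shape[0]
    B = -0.5 * D**2
    B = B - B.mean(axis=0, keepdims=True) - B.mean(axis=1, keepdims=True) + B.mean()
    evals, evecs = eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(np.abs(evals).max(), 1.0) * 1e-10
    pos = evals > tol
    if k > pos.sum():
        raise ValueError(
            f"requested {k} axes but only {int(pos.sum())} positive eigenvalues"
        )
    lam = evals[pos][:k]
    scores = evecs[:, pos][:, :k] * np.sqrt(lam)
    fractions = lam / evals[pos].sum()
    scores_df = pd.DataFrame(
        scores, index=list(d.ids), columns=[f"axis_{i+1}" for i in range(k)]
    )
    loadings = scaled = None
    if raw is not None:
        scores_df = _orient(scores_df, raw)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # constant categories
            r = np.array(
                [
                    [
                        _pearson(raw[c].to_numpy(float), scores_df.iloc[:, a].to_numpy())
                        for a in range(k)
                    ]
                    for c in raw.columns
                ]
            )
        loadings = pd.DataFrame(r, index=raw.columns, columns=scores_df.columns)
        scaled = loadings * np.sqrt(fractions)
    return PcoaResult(
        scores=scores_df,
        eigenvalues=lam,
        variance_fractions=fractions,
        loadings=loadings,
        scaled_loadings=scaled,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


_INVERT_HINTS = ("invert", "inv")


def _orient(scores: pd.DataFrame, raw: pd.DataFrame) -> pd.DataFrame:
    """Flip axis 1 so it correlates positively with the invertebrate category.

    If no category name suggests invertebrates, the first category is used as
    the anchor; orientation is a reporting convention only.
    """
    anchor = next(
        (c for c in raw.columns if any(h in str(c).lower() for h in _INVERT_HINTS)),
        raw.columns[0],
    )
    r = _pearson(raw[anchor].to_numpy(float), scores.iloc[:, 0].to_numpy())
    if np.isfinite(r) and r < 0:
        scores = scores.copy()
        scores.iloc[:, 0] = -scores.iloc[:, 0]
    return scores


def diet_trait(p: PcoaResult, use_axes: int = 1) -> pd.DataFrame:
    """Per-species synthetic diet trait: PCoA axis 1, or axes 1-2."""
    if use_axes not in (1, 2):
        raise ValueError("use_axes must be 1 or 2")
    if p.scores.shape[1] < use_axes:
        raise ValueError(f"PCoA result has fewer than {use_axes} axes")
    return p.scores.iloc[:, :use_axes].copy()
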