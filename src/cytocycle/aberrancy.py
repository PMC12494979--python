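"""Per-cell deviation scores from a reference population.

Three complementary scores:

* :func:`nn_aberrancy` — mean distance of each query cell to its k nearest
  reference (untreated) cells; with :func:`aberrancy_threshold`, a
  reference-quantile cutoff turns scores into canonical/aberrant flags.
* :func:`mahalanobis_by_group` — multivariate distance of each cell from its
  own group's centroid under the group covariance (e.g. phase-wise deviation).
* :func:`knn_condition_score` — a simplified kNN label-enrichment score:
  the fraction of a cell's k nearest neighbors carrying a condition label,
  normalized by that label's global prevalence (~1 under exchangeability).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .errors import ParameterError
from .matrix import ExpressionMatrix


@dataclass
class AberrancyParams:
    k: int = 10
    metric: str = "euclidean"
    threshold_quantile: float = 0.95
    feature_set: Optional[Sequence[str]] = None  # None = all channels

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError("k must be >= 1")
        if self.metric not in ("euclidean", "cosine"):
            raise ParameterError(f"unsupported metric {self.metric!r}")
        if not 0 < self.threshold_quantile < 1:
            raise ParameterError("threshold_quantile must be in (0, 1)")


@dataclass
class AberrancyScores:
    score: np.ndarray
    aberrant: Optional[np.ndarray] = None
    threshold_used: Optional[float] = None
    reference_id: str = "reference"
    params: AberrancyParams = field(default_factory=AberrancyParams)


def _features(m: ExpressionMatrix, feature_set) -> np.ndarray:
    if feature_set is None:
        return m.values
    return m.subset_channels(list(feature_set))


def nn_aberrancy(query: ExpressionMatrix, reference: ExpressionMatrix,
                 params: AberrancyParams | None = None,
                 reference_id: str = "reference") -> AberrancyScores:
    """Mean distance of each query cell to its k nearest reference cells.

    Exact (brute-force-equivalent) neighbor search.
    """
    params = params or AberrancyParams()
    xq = _features(query, params.feature_set)
    xr = _features(reference, params.feature_set)
    if xq.shape[1] != xr.shape[1]:
        raise ParameterError("query and reference feature sets differ")
    if params.k > xr.shape[0]:
        raise ParameterError(
            f"k={params.k} exceeds reference size {xr.shape[0]}"
        )
    nn = NearestNeighbors(n_neighbors=params.k, metric=params.metric)
    nn.fit(xr)
    dist, _ = nn.kneighbors(xq)
    return AberrancyScores(
        score=dist.mean(axis=1), reference_id=reference_id, params=params
    )


def reference_self_scores(reference: ExpressionMatrix,
                          params: AberrancyParams | None = None) -> np.ndarray:
    """Leave-self-out NN scores of reference cells against each other.

    Each reference cell is scored against the remaining reference cells
    (avoids the zero-inflation of scoring a cell against itself).
    """
    params = params or AberrancyParams()
    xr = _features(reference, params.feature_set)
    if params.k + 1 > xr.shape[0]:
        raise ParameterError("reference too small for leave-self-out scoring")
    nn = NearestNeighbors(n_neighbors=params.k + 1, metric=params.metric)
    nn.fit(xr)
    dist, _ = nn.kneighbors(xr)
    return dist[:, 1:].mean(axis=1)  # drop self (distance 0)


def aberrancy_threshold(reference_self: np.ndarray, alpha: float = 0.95) -> float:
    """alpha-quantile of the reference's own score distribution."""
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    return float(np.quantile(np.asarray(reference_self, dtype=float), alpha))


def classify(scores: AberrancyScores, threshold: float) -> AberrancyScores:
    """Flag cells whose score exceeds the threshold."""
    scores.aberrant = scores.score > threshold
    scores.threshold_used = float(threshold)
    return scores


def mahalanobis_by_group(m: ExpressionMatrix, groups: np.ndarray,
                         regularization: float = 1e-6,
                         feature_set: Optional[Sequence[str]] = None
                         ) -> np.ndarray:
    """Mahalanobis distance of each cell from its own group's centroid.

    ``sqrt((x - mu_g)' (Sigma_g + lambda I)^{-1} (x - mu_g))`` with mu_g and
    Sigma_g estimated from all cells of the group (canonical and noncanonical
    pooled). A small ridge lambda keeps near-singular covariances invertible.
    """
    x = _features(m, feature_set)
    groups = np.asarray(groups)
    if len(groups) != x.shape[0]:
        raise ParameterError("group labels do not align with the matrix")
    n_feat = x.shape[1]
    out = np.empty(x.shape[0])
    for g in pd.unique(groups):
        mask = groups == g
        xg = x[mask]
        if regularization <= 0 and xg.shape[0] < n_feat + 2:
            raise ParameterError(
                f"group {g!r} too small for a stable covariance; "
                "set regularization > 0"
            )
        mu = xg.mean(axis=0)
        cov = np.cov(xg, rowvar=False) if xg.shape[0] > 1 else np.zeros((n_feat, n_feat))
        cov = np.atleast_2d(cov) + regularization * np.eye(n_feat)
        try:
            prec = np.linalg.inv(cov)
        except np.linalg.LinAlgError as exc:
            raise ParameterError(
                f"singular covariance in group {g!r}; increase regularization"
            ) from exc
        centered = xg - mu
        out[mask] = np.sqrt(np.einsum("ij,jk,ik->i", centered, prec, centered))
    return out


def knn_condition_score(m: ExpressionMatrix, conditions: np.ndarray,
                        k: int = 10, metric: str = "euclidean",
                        feature_set: Optional[Sequence[str]] = None
                        ) -> pd.DataFrame:
    """Prevalence-normalized kNN label enrichment per cell and condition.

    ``score(cell, c)`` = fraction of the cell's k nearest neighbors (pooled
    data, leave-self-out) labeled ``c``, divided by the global prevalence of
    ``c``. Under exchangeable labels scores concentrate near 1. A simplified,
    documented stand-in for graph-signal perturbation-likelihood scoring.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    conditions = np.asarray(conditions)
    x = _features(m, feature_set)
    if len(conditions) != x.shape[0]:
        raise ParameterError("condition labels do not align with the matrix")
    levels = pd.unique(conditions)
    if len(levels) < 2:
        raise ParameterError("need >= 2 conditions")
    prevalence = {c: (conditions == c).mean() for c in levels}
    for c, p in prevalence.items():
        if p == 0:
            raise ParameterError(f"condition {c!r} has no cells")
    if k + 1 > x.shape[0]:
        raise ParameterError("k exceeds the number of other cells")

    nn = NearestNeighbors(n_neighbors=k + 1, metric=metric)
    nn.fit(x)
    _, idx = nn.kneighbors(x)
    neighbor_labels = conditions[idx[:, 1:]]  # leave self out
    scores = {
        str(c): (neighbor_labels == c).mean(axis=1) / prevalence[c]
        for c in levels
    }
    return pd.DataFrame(scores)
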