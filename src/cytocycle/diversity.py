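"""Graph-connectivity cell-state diversity.

Cells are nodes; an edge joins two cells whose cosine distance on a feature
subset crosses a fixed threshold (default 0.5); edge density (edges over all
C(n, 2) pairs) summarizes how spread-out the population is in marker space.
Sweeping all subsets of a feature pool and averaging density per subset size
yields the mean-connectivity-vs-feature-count diversity curve.

Under the default *dissimilarity* convention an edge means the pair is
well-separated (d >= tau), so denser graphs mean more diverse cell states.
The similarity convention (edge when d < tau) is retained as an option.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ParameterError
from .matrix import ExpressionMatrix
from .panels import DIVERSITY_FEATURES


@dataclass
class DiversityParams:
    threshold: float = 0.5
    n_cells_subsample: int = 2000
    feature_pool: Sequence[str] = field(default_factory=lambda: list(DIVERSITY_FEATURES))
    max_subsets_per_size: Optional[int] = 500  # None = exhaustive
    edge_convention: str = "dissimilarity"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 2:
            raise ParameterError("threshold must be in (0, 2)")
        if self.n_cells_subsample < 2:
            raise ParameterError("n_cells_subsample must be >= 2")
        if self.edge_convention not in ("dissimilarity", "similarity"):
            raise ParameterError(
                f"unknown edge convention {self.edge_convention!r}"
            )
        if not self.feature_pool:
            raise ParameterError("feature pool is empty")


@dataclass
class DiversityCurve:
    """Per-subset densities plus per-size means."""

    records: pd.DataFrame  # columns: subset, size, density, n_cells_used
    edge_convention: str

    @property
    def per_size_mean(self) -> pd.Series:
        return self.records.groupby("size")["density"].mean()


def cosine_distance_matrix(m: ExpressionMatrix | np.ndarray,
                           subset: Sequence[str] | None = None
                           ) -> tuple[np.ndarray, int]:
    """Pairwise cosine distances on a feature subset.

    Zero-norm cells (all-zero on the subset) are excluded; the count of
    excluded cells is returned alongside the symmetric, zero-diagonal matrix.
    """
    if isinstance(m, ExpressionMatrix):
        x = m.subset_channels(list(subset)) if subset is not None else m.values
    else:
        x = np.asarray(m, dtype=float)
    norms = np.linalg.norm(x, axis=1)
    usable = norms > 0
    n_dropped = int((~usable).sum())
    if n_dropped:
        warnings.warn(
            f"excluding {n_dropped} zero-norm cells from cosine distances",
            stacklevel=2,
        )
        x = x[usable]
    if x.shape[0] < 2:
        raise ParameterError("need >= 2 cells with nonzero norm")
    d = squareform(pdist(x, metric="cosine"))
    np.fill_diagonal(d, 0.0)
    return d, n_dropped


def graph_density(d: np.ndarray, threshold: float = 0.5,
                  convention: str = "dissimilarity") -> float:
    """Edge density of the thresholded adjacency graph.

    ``dissimilarity``: edge iff d(i, j) >= threshold; ``similarity``: edge iff
    d(i, j) < threshold. Density = edges / C(n, 2).
    """
    d = np.asarray(d)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ParameterError("distance matrix must be square")
    n = d.shape[0]
    if n < 2:
        raise ParameterError("need >= 2 cells")
    if convention not in ("dissimilarity", "similarity"):
        raise ParameterError(f"unknown edge convention {convention!r}")
    iu = np.triu_indices(n, k=1)
    upper = d[iu]
    edges = int((upper >= threshold).sum() if convention == "dissimilarity"
                else (upper < threshold).sum())
    return edges / (n * (n - 1) // 2)


def _sample_subsets(pool: list[str], size: int, cap: Optional[int],
                    rng: np.random.Generator) -> list[tuple[str, ...]]:
    total = math.comb(len(pool), size)
    if cap is None or total <= cap:
        return list(combinations(pool, size))
    # Seeded uniform sampling of distinct subsets; cap << total in practice.
    chosen: set[tuple[int, ...]] = set()
    while len(chosen) < cap:
        idx = tuple(sorted(rng.choice(len(pool), size=size, replace=False)))
        chosen.add(idx)
    return [tuple(pool[i] for i in idx) for idx in sorted(chosen)]


def diversity_curve(m: ExpressionMatrix, params: DiversityParams
                    ) -> DiversityCurve:
    """Edge density over feature subsets of every size in the pool.

    Cells are subsampled once per run (seeded); for each subset size all
    C(|pool|, s) subsets are enumerated, or a seeded uniform sample of
    ``max_subsets_per_size``. Exhaustive enumeration is seed-independent.
    """
    pool = list(params.feature_pool)
    m.require_channels(pool)
    rng = np.random.default_rng(params.seed)

    if m.n_cells > params.n_cells_subsample:
        idx = rng.choice(m.n_cells, size=params.n_cells_subsample, replace=False)
        x_all = m.values[np.sort(idx)]
    else:
        x_all = m.values
    col = {name: m.channel_index(name) for name in pool}

    rows = []
    for size in range(1, len(pool) + 1):
        for subset in _sample_subsets(pool, size, params.max_subsets_per_size, rng):
            x = x_all[:, [col[f] for f in subset]]
            d, _ = cosine_distance_matrix(x)
            dens = graph_density(d, params.threshold, params.edge_convention)
            rows.append(
                {
                    "subset": "+".join(subset),
                    "size": size,
                    "density": dens,
                    "n_cells_used": d.shape[0],
                }
            )
    return DiversityCurve(pd.DataFrame(rows), params.edge_convention)
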