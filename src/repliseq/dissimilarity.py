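"""Beta-diversity statistics: Bray-Curtis, Jaccard, and silhouette scores.

Bray-Curtis dissimilarity operates on relative abundances,
``sum|x - y| / sum(x + y)``; Jaccard on presence/absence,
``1 - |intersection| / |union|``.  Both are 0 for identical communities
and 1 for disjoint ones.  Silhouette scores, computed on a precomputed
Bray-Curtis matrix with sample-of-origin labels, measure how well
replicates cluster by the sample they came from: per point
``s = (b - a) / max(a, b)`` with ``a`` the mean dissimilarity to the own
cluster and ``b`` the smallest mean dissimilarity to another cluster.
The full [-1, 1] range is kept (well-separated data land in [0, 1]);
points in singleton clusters score 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_samples

from .otu_table import OTUTable, relative_abundances

logger = logging.getLogger(__name__)

__all__ = [
    "DissimilarityMatrix",
    "SilhouetteResult",
    "bray_curtis",
    "jaccard",
    "distance_matrix",
    "mean_within_sample_dissimilarity",
    "silhouette",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric dissimilarity matrix over dataset ids, values in [0, 1]."""

    ids: list
    values: np.ndarray
    metric: str = "bray_curtis"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.ids)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix must be symmetric")
        if (self.values < -1e-12).any() or (self.values > 1 + 1e-12).any():
            raise ValueError("dissimilarities must lie in [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def submatrix(self, ids) -> "DissimilarityMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DissimilarityMatrix(
            list(ids), self.values[np.ix_(idx, idx)], self.metric
        )


@dataclass
class SilhouetteResult:
    scores: pd.Series
    mean: float
    labels: dict = field(default_factory=dict)


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) of two abundance vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must share the OTU index")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be nonnegative")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def jaccard(x, y) -> float:
    """Jaccard dissimilarity 1 - |intersection|/|union| of two presence sets.

    Accepts sets of OTU ids or abundance vectors (presence = count > 0).
    """
    if isinstance(x, (set, frozenset)) or isinstance(y, (set, frozenset)):
        xs, ys = set(x), set(y)
    else:
        x = np.asarray(x)
        y = np.asarray(y)
        if x.shape != y.shape:
            raise ValueError("vectors must share the OTU index")
        xs = set(np.flatnonzero(x > 0))
        ys = set(np.flatnonzero(y > 0))
    union = xs | ys
    if not union:
        raise ValueError("Jaccard undefined for two empty sets")
    return 1.0 - len(xs & ys) / len(union)


def matrix_from_columns(columns: pd.DataFrame, metric: str) -> DissimilarityMatrix:
    """Pairwise dissimilarity over the columns of an abundance DataFrame.

    Bray-Curtis is computed on column-normalised relative abundances,
    Jaccard on presence/absence.
    """
    ids = list(columns.columns)
    if len(ids) < 2:
        raise ValueError("need at least 2 datasets")
    arr = columns.to_numpy(dtype=float).T  # datasets x OTUs
    sums = arr.sum(axis=1)
    if (sums == 0).any():
        bad = [ids[i] for i in np.flatnonzero(sums == 0)]
        raise ValueError(f"zero-depth datasets: {bad}")
    if metric == "bray_curtis":
        rel = arr / sums[:, None]
        vals = squareform(pdist(rel, metric="braycurtis"))
    elif metric == "jaccard":
        vals = squareform(pdist(arr > 0, metric="jaccard"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DissimilarityMatrix(ids, vals, metric)


def distance_matrix(table: OTUTable, metric: str = "bray_curtis") -> DissimilarityMatrix:
    """Pairwise Bray-Curtis (on relative abundances) or Jaccard (presence)
    dissimilarity matrix over a table's datasets."""
    rel = relative_abundances(table)
    if rel.zero_depth:
        raise ValueError(f"zero-depth datasets: {rel.zero_depth}")
    return matrix_from_columns(table.counts, metric)


def mean_within_sample_dissimilarity(
    dm: DissimilarityMatrix, labels: Mapping
) -> dict:
    """Mean dissimilarity over unordered within-sample replicate pairs.

    Samples with fewer than 2 members are omitted with a log notice.
    """
    by_sample: dict = {}
    for i, d in enumerate(dm.ids):
        by_sample.setdefault(labels[d], []).append(i)
    out = {}
    for sample, idx in by_sample.items():
        if len(idx) < 2:
            logger.info(
                "mean_within_sample_dissimilarity: sample %r has <2 members, omitted",
                sample,
            )
            continue
        sub = dm.values[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        out[sample] = float(sub[iu].mean())
    return out


def silhouette(dm: DissimilarityMatrix, labels: Mapping) -> SilhouetteResult:
    """Mean silhouette score of datasets clustered by their sample label."""
    missing = [d for d in dm.ids if d not in labels]
    if missing:
        raise ValueError(f"labels missing for datasets: {missing}")
    lab = np.asarray([labels[d] for d in dm.ids])
    if len(set(lab)) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    scores = silhouette_samples(dm.values, lab, metric="precomputed")
    series = pd.Series(scores, index=dm.ids)
    return SilhouetteResult(series, float(series.mean()), dict(zip(dm.ids, lab)))
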