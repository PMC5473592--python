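"""Alpha-diversity machinery.

Rarefied (expected) OTU richness in a random subsample of ``n`` reads drawn
without replacement, following Hurlbert:

    E[S_n] = sum_i [ 1 - C(N - N_i, n) / C(N, n) ]

where ``N_i`` is the read count of OTU ``i`` and ``N`` the dataset depth.
The exact sampling variance of ``S_n`` (Heck et al.) follows from the
pairwise joint-absence probabilities:

    Var[S_n] = sum_i q_i (1 - q_i) + 2 sum_{i<j} (q_ij - q_i q_j)

with ``q_i = C(N-N_i, n)/C(N, n)`` the probability OTU ``i`` is absent from
the subsample and ``q_ij = C(N-N_i-N_j, n)/C(N, n)`` the joint absence
probability.  Binomial ratios are evaluated in log-space (log-gamma) so
tables with 10^5-10^6 reads do not overflow.

Shannon diversity (natural log) under a given depth is estimated by
repeated random subsampling without replacement (multivariate
hypergeometric draws), mirroring the rrarefy-style procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from ._rng import derive_rng

logger = logging.getLogger(__name__)

__all__ = [
    "SubsampleSpec",
    "RarefactionCurve",
    "expected_richness",
    "richness_variance_heck",
    "subsample_counts",
    "shannon",
    "rarefaction_curve",
    "mean_curve_across_replicates",
    "rarefaction_slope",
    "relative_gain",
]


@dataclass
class SubsampleSpec:
    """Repeated-subsampling parameters: iteration count and top-level seed."""

    iterations: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class RarefactionCurve:
    """Mean diversity (richness or Shannon) over a grid of depths, with SE."""

    dataset: str
    sample: str | None
    depths: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    metric: str = "richness"
    se_kind: str = "analytic_heck"

    def __post_init__(self):
        self.depths = np.asarray(self.depths)
        self.mean = np.asarray(self.mean, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if not (len(self.depths) == len(self.mean) == len(self.se)):
            raise ValueError("depths, mean and se must have equal length")


# ---------------------------------------------------------------------------
# exact rarefaction
# ---------------------------------------------------------------------------


def _validate_counts_n(counts, n):
    counts = np.asarray(counts)
    if counts.size and not np.issubdtype(counts.dtype, np.integer):
        rounded = np.round(counts)
        if not np.allclose(counts, rounded):
            raise ValueError("counts must be integral")
        counts = rounded.astype(np.int64)
    counts = counts.astype(np.int64)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    if n != int(n):
        raise ValueError("subsample size n must be an integer")
    n = int(n)
    N = int(counts.sum())
    if n < 0:
        raise ValueError("n must be >= 0")
    if n > N:
        raise ValueError(f"cannot rarefy to n={n} > total reads N={N} (no extrapolation)")
    return counts, n, N


def _log_choose(a, b):
    # valid for a >= b >= 0 elementwise
    return gammaln(a + 1.0) - gammaln(b + 1.0) - gammaln(a - b + 1.0)


def _absence_prob(u, n, N, log_cnn):
    """P(all reads of a count-u OTU missed) = C(N-u, n)/C(N, n), vectorised."""
    u = np.asarray(u, dtype=np.int64)
    q = np.zeros(u.shape, dtype=float)
    ok = (N - u) >= n
    if ok.any():
        q[ok] = np.exp(_log_choose((N - u[ok]).astype(float), float(n)) - log_cnn)
    return np.clip(q, 0.0, 1.0)


def expected_richness(counts, n) -> float:
    """Expected OTU richness in a random subsample of ``n`` reads (Hurlbert)."""
    counts, n, N = _validate_counts_n(counts, n)
    counts = counts[counts > 0]
    if n == 0 or counts.size == 0:
        return 0.0
    log_cnn = _log_choose(float(N), float(n))
    q = _absence_prob(counts, n, N, log_cnn)
    return float(np.sum(1.0 - q))


def richness_variance_heck(counts, n) -> float:
    """Exact variance of subsample richness (Heck et al. pairwise formula).

    Computed over groups of OTUs with equal counts, so cost is quadratic in
    the number of *distinct* abundances rather than the number of OTUs.
    """
    counts, n, N = _validate_counts_n(counts, n)
    counts = counts[counts > 0]
    if n == 0 or n == N or counts.size == 0:
        return 0.0
    u, m = np.unique(counts, return_counts=True)
    log_cnn = _log_choose(float(N), float(n))
    q = _absence_prob(u, n, N, log_cnn)
    var = float(np.sum(m * q * (1.0 - q)))
    # pairwise joint-absence over distinct count values
    qq = _absence_prob(u[:, None] + u[None, :], n, N, log_cnn)
    cov = qq - q[:, None] * q[None, :]
    weights = m[:, None] * m[None, :] - np.diag(m)  # ordered pairs i != j
    var += float(np.sum(weights * cov))
    return max(var, 0.0)


def subsample_counts(counts, n, seed_or_rng=0) -> np.ndarray:
    """Draw ``n`` reads without replacement (multivariate hypergeometric)."""
    counts, n, N = _validate_counts_n(counts, n)
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    return rng.multivariate_hypergeometric(counts, n)


def shannon(x) -> float:
    """Shannon diversity H = -sum p ln p (natural log) of counts or fractions."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = x.sum()
    if total == 0:
        raise ValueError("cannot compute Shannon diversity of an all-zero vector")
    p = x[x > 0] / total
    return float(-np.sum(p * np.log(p)))


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------


def rarefaction_curve(
    table,
    dataset,
    grid: Sequence[int],
    metric: str = "richness",
    spec: SubsampleSpec | None = None,
    se_kind: str | None = None,
) -> RarefactionCurve:
    """Rarefaction curve for one dataset over a depth grid.

    Richness is analytic (Hurlbert expectation, Heck SE); Shannon is the
    mean over ``spec.iterations`` random subsamples with the empirical
    standard error of that mean.  Grid depths exceeding the dataset's total
    reads are skipped with a log notice, never extrapolated.
    """
    counts = table.column(dataset)
    N = int(counts.sum())
    grid = list(grid)
    if any(g != int(g) for g in grid):
        raise ValueError("grid depths must be integers")
    usable = [int(g) for g in grid if g <= N]
    skipped = [int(g) for g in grid if g > N]
    if skipped:
        logger.info(
            "rarefaction_curve(%s): skipping depths beyond total reads (%d): %s",
            dataset, N, skipped,
        )
    if not usable:
        raise ValueError(f"no usable grid depths for dataset {dataset!r} (N={N})")
    sample = table.sample_of.get(dataset)
    if metric == "richness":
        mean = [expected_richness(counts, g) for g in usable]
        se = [np.sqrt(richness_variance_heck(counts, g)) for g in usable]
        return RarefactionCurve(
            dataset, sample, usable, mean, se, metric, se_kind or "analytic_heck"
        )
    if metric == "shannon":
        if spec is None:
            spec = SubsampleSpec()
        mean, se = [], []
        for g in usable:
            vals = np.empty(spec.iterations)
            for i in range(spec.iterations):
                rng = derive_rng(spec.seed, "sub", dataset, g, i)
                vals[i] = shannon(subsample_counts(counts, g, rng))
            mean.append(vals.mean())
            se.append(
                vals.std(ddof=1) / np.sqrt(spec.iterations)
                if spec.iterations > 1
                else 0.0
            )
        return RarefactionCurve(
            dataset, sample, usable, mean, se, metric, se_kind or "empirical"
        )
    raise ValueError(f"unknown metric {metric!r}")


def mean_curve_across_replicates(
    curves: Sequence[RarefactionCurve], mode: str = "per_depth"
) -> RarefactionCurve:
    """Average replicate curves; SE is the standard error of the mean.

    ``mode='per_depth'`` (default): at each depth, replicates whose grid
    covers that depth contribute; shallower replicates are excluded at that
    depth only.  ``mode='global'``: only depths present in every replicate
    are kept.  Depths with fewer than 2 contributing replicates get SE NaN.
    """
    if not curves:
        raise ValueError("no curves given")
    metric = curves[0].metric
    by_depth: dict = {}
    for c in curves:
        for d, v in zip(c.depths, c.mean):
            by_depth.setdefault(int(d), []).append(float(v))
    depths = sorted(by_depth)
    if mode == "global":
        depths = [d for d in depths if len(by_depth[d]) == len(curves)]
    elif mode != "per_depth":
        raise ValueError(f"unknown mode {mode!r}")
    if not depths:
        raise ValueError("no common depths across replicate curves")
    mean, se = [], []
    for d in depths:
        vals = np.asarray(by_depth[d])
        mean.append(vals.mean())
        se.append(
            vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
        )
    samples = {c.sample for c in curves}
    sample = samples.pop() if len(samples) == 1 else None
    return RarefactionCurve(
        "mean", sample, depths, mean, se, metric, "across_replicates"
    )


def rarefaction_slope(curve: RarefactionCurve, at_depth) -> float:
    """Finite-difference slope (diversity units per read) of a curve at a depth."""
    d = np.asarray(curve.depths, dtype=float)
    if not (d.min() <= at_depth <= d.max()):
        raise ValueError(
            f"depth {at_depth} outside curve grid [{d.min():.0f}, {d.max():.0f}]"
        )
    if len(d) < 2:
        raise ValueError("curve needs at least 2 grid points for a slope")
    hi = int(np.searchsorted(d, at_depth, side="right"))
    hi = min(max(hi, 1), len(d) - 1)
    return float((curve.mean[hi] - curve.mean[hi - 1]) / (d[hi] - d[hi - 1]))


def relative_gain(pooled_value: float, replicate_mean: float) -> float:
    """Pooled diversity divided by the mean single-replicate diversity."""
    if replicate_mean <= 0:
        raise ValueError("replicate mean must be > 0")
    return float(pooled_value) / float(replicate_mean)
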