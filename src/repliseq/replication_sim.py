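"""Resampling simulations linking sequencing depth and DNA-extraction
replication to alpha-diversity and sample separability.

Four procedures, all based on repeated random subsampling without
replacement from an OTU count table:

``alpha_vs_depth``
    Per replicate and depth: subsample all OTUs to the depth, *then* filter
    to a taxonomic category, then compute richness and Shannon diversity.
    Filtering after subsampling estimates the effect of total read depth
    obtained with universal eukaryote primers while targeting a subset.

``pooled_alpha_vs_n``
    Constant-depth pooling: for each number of replicates ``n``, draw ``n``
    distinct replicates at random, subsample ``r = floor(total_depth/n)``
    reads from each, merge, filter, and compute diversity; total merged
    depth stays ~constant (default 15,000 reads) so the effect of
    replication is separated from the effect of depth.

``divergence_vs_depth`` / ``silhouette_vs_depth``
    Per depth: subsample every retained replicate, then compute mean
    within-sample Bray-Curtis/Jaccard dissimilarity, or the mean silhouette
    score of the Bray-Curtis matrix with sample-of-origin labels.

``silhouette_vs_replication``
    Per ``n``: partition each sample's replicates into ``floor(R/n)``
    disjoint pseudo-replicates of ``n`` members (leftovers discarded), each
    member subsampled to ``r = floor(total_depth/n)`` reads and merged;
    silhouette over all pseudo-replicates.

Randomness contract: every subsample draw for (dataset, depth, iteration)
comes from a stream derived from (seed, "sub", dataset, depth, iteration),
shared across procedures.  Hence the ``n = 1`` pooling simulations reduce
bit-identically to the corresponding single-replicate depth simulations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from ._rng import derive_rng
from .diversity import SubsampleSpec, shannon, subsample_counts
from .dissimilarity import DissimilarityMatrix, matrix_from_columns, silhouette
from .otu_table import OTUTable, TaxonomyMap

logger = logging.getLogger(__name__)

__all__ = [
    "PoolingDesign",
    "SimulationResult",
    "alpha_vs_depth",
    "pooled_alpha_vs_n",
    "divergence_vs_depth",
    "silhouette_vs_depth",
    "silhouette_vs_replication",
    "depth_richness_correlation",
]


@dataclass
class PoolingDesign:
    """Constant-total-depth pooling scheme.

    For ``n`` pooled replicates each contributes ``r = floor(total_depth/n)``
    reads, so the merged depth is ``n * r`` (within n-1 reads of
    ``total_depth`` when n does not divide it).
    """

    n_values: Sequence[int] = tuple(range(1, 11))
    total_depth: int = 15000
    iterations: int = 100
    seed: int = 0

    def __post_init__(self):
        self.n_values = tuple(int(n) for n in self.n_values)
        if any(n < 1 for n in self.n_values):
            raise ValueError("replicate numbers must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    def reads_per_replicate(self, n: int) -> int:
        return self.total_depth // n


@dataclass
class SimulationResult:
    """Mean +/- SE of a statistic over a simulation grid.

    ``mean`` and ``se`` are DataFrames indexed by the grid (depth or number
    of pooled replicates) with one column per series (sample, replicate, or
    'all').  ``raw`` keeps the per-iteration values, keyed by
    ``(series, grid_value)``; the SE is the across-iteration standard
    deviation divided by sqrt(iterations) (the Monte-Carlo error of the
    reported mean), with the raw values available for any other summary.
    """

    axis: str
    grid: np.ndarray
    statistic: str
    category: str
    mean: pd.DataFrame
    se: pd.DataFrame
    raw: dict = field(default_factory=dict, repr=False)
    extras: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if (np.diff(self.grid) <= 0).any():
            raise ValueError("grid must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: axis value, series, mean, se."""
        rows = []
        for series in self.mean.columns:
            for g in self.grid:
                rows.append(
                    {
                        self.axis: g,
                        "series": series,
                        "statistic": self.statistic,
                        "category": self.category,
                        "mean": self.mean.at[g, series],
                        "se": self.se.at[g, series],
                    }
                )
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    def to_json(self) -> str:
        return json.dumps(
            {
                "axis": self.axis,
                "grid": [int(g) for g in self.grid],
                "statistic": self.statistic,
                "category": self.category,
                "mean": {c: list(self.mean[c]) for c in self.mean.columns},
                "se": {c: list(self.se[c]) for c in self.se.columns},
            }
        )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _category_mask(table: OTUTable, tax: TaxonomyMap | None, category: str):
    if category == "all":
        return np.ones(len(table.counts.index), dtype=bool)
    if tax is None:
        raise ValueError("taxonomy required for category filtering")
    return tax.category_mask(table.counts.index, category)


def _alpha_stats(sub: np.ndarray, mask: np.ndarray):
    """Richness and Shannon diversity of a (filtered) subsample vector."""
    filtered = sub[mask]
    richness = int((filtered > 0).sum())
    h = shannon(filtered) if filtered.sum() > 0 else np.nan
    return richness, h

def _draw(counts, dataset, depth, iteration, seed):
    """The shared subsample draw for (dataset, depth, iteration)."""
    return subsample_counts(counts, depth, derive_rng(seed, "sub", dataset, depth, iteration))


def merge_subsamples(
    table: OTUTable, datasets: Sequence, r: int, seed: int, iteration: int
) -> np.ndarray:
    """Subsample ``min(r, depth)`` reads from each dataset and sum the draws.

    When every member is at least ``r`` reads deep the merged vector totals
    exactly ``len(datasets) * r`` reads; a shallower member contributes all
    of its reads (the rrarefy convention).
    """
    merged = None
    for d in datasets:
        counts = table.column(d)
        sub = _draw(counts, d, min(r, int(counts.sum())), iteration, seed)
        merged = sub if merged is None else merged + sub
    return merged


def _mean_se(values: np.ndarray):
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    n = len(values)
    if n == 0:
        return float("nan"), float("nan")
    se = values.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
    return float(values.mean()), float(se)


def _assemble(axis, grid, statistic, category, raw, series_order, extras=None):
    mean = pd.DataFrame(index=pd.Index(grid, name=axis), columns=series_order, dtype=float)
    se = mean.copy()
    for (series, g), vals in raw.items():
        m, s = _mean_se(vals)
        mean.at[g, series] = m
        se.at[g, series] = s
    return SimulationResult(
        axis, grid, statistic, category, mean, se, raw, extras or {}
    )


# ---------------------------------------------------------------------------
# simulations
# ---------------------------------------------------------------------------


def alpha_vs_depth(
    table: OTUTable,
    tax: TaxonomyMap | None,
    category: str,
    grid: Sequence[int],
    spec: SubsampleSpec,
) -> dict:
    """Richness and Shannon vs depth, per replicate (subsample-then-filter).

    Replicates shallower than the deepest grid point are excluded entirely
    (the constant-depth exclusion rule), so every replicate contributes at
    every depth.  Returns ``{'richness': SimulationResult, 'shannon': ...}``
    with one column per retained replicate.
    """
    grid = sorted(int(g) for g in grid)
    if not grid:
        raise ValueError("empty depth grid")
    depths = table.depths()
    retained = [d for d in table.dataset_ids if depths[d] >= grid[-1]]
    excluded = [d for d in table.dataset_ids if depths[d] < grid[-1]]
    if excluded:
        logger.info("alpha_vs_depth: excluding %s (depth < %d)", excluded, grid[-1])
    if not retained:
        raise ValueError(f"no replicates reach the deepest grid point {grid[-1]}")
    mask = _category_mask(table, tax, category)
    raw_rich: dict = {}
    raw_shan: dict = {}
    for d in retained:
        counts = table.column(d)
        for g in grid:
            rich = np.empty(spec.iterations)
            shan = np.empty(spec.iterations)
            for i in range(spec.iterations):
                sub = _draw(counts, d, g, i, spec.seed)
                rich[i], shan[i] = _alpha_stats(sub, mask)
            raw_rich[(d, g)] = rich
            raw_shan[(d, g)] = shan
    return {
        "richness": _assemble("depth", grid, "richness", category, raw_rich, retained),
        "shannon": _assemble("depth", grid, "shannon", category, raw_shan, retained),
    }


def pooled_alpha_vs_n(
    table: OTUTable,
    tax: TaxonomyMap | None,
    category: str,
    design: PoolingDesign,
    samples: Sequence | None = None,
    shallow: str = "exclude",
) -> dict:
    """Richness and Shannon vs number of pooled replicates at constant depth.

    Per iteration and sample: choose ``n`` distinct replicates uniformly
    (among those deep enough to supply ``r = floor(total_depth/n)`` reads),
    subsample ``r`` reads from each, merge, filter to the category, and
    compute diversity.  Returns ``{'richness': ..., 'shannon': ...}`` with
    one column per sample; chosen replicate ids are kept in
    ``extras['selected']``.

    ``shallow`` governs replicates with depth < r: ``'exclude'`` (default)
    removes them from the selection pool, ``'all_reads'`` keeps them with
    every read contributed (rrarefy convention).
    """
    if shallow not in ("exclude", "all_reads"):
        raise ValueError(f"unknown shallow policy {shallow!r}")
    samples = list(samples) if samples is not None else table.samples
    mask = _category_mask(table, tax, category)
    depths = table.depths()
    grid = sorted(design.n_values)
    raw_rich: dict = {}
    raw_shan: dict = {}
    selected: dict = {}
    for s in samples:
        members = table.datasets_of_sample(s)
        for n in grid:
            r = design.reads_per_replicate(n)
            if shallow == "exclude":
                avail = [d for d in members if depths[d] >= r]
            else:
                avail = list(members)
            if len(avail) < n:
                raise ValueError(
                    f"sample {s!r}: only {len(avail)} usable replicates "
                    f"(depth >= {r}), cannot pool n={n}"
                )
            rich = np.empty(design.iterations)
            shan = np.empty(design.iterations)
            chosen_log = []
            for i in range(design.iterations):
                sel = derive_rng(design.seed, "sel", s, n, i)
                chosen = list(sel.choice(np.asarray(avail, dtype=object), n, replace=False))
                merged = merge_subsamples(table, chosen, r, design.seed, i)
                rich[i], shan[i] = _alpha_stats(merged, mask)
                chosen_log.append(chosen)
            raw_rich[(s, n)] = rich
            raw_shan[(s, n)] = shan
            selected[(s, n)] = chosen_log
    extras = {"selected": selected, "reads_per_replicate": {n: design.reads_per_replicate(n) for n in grid}}
    return {
        "richness": _assemble("n_replicates", grid, "richness", category, raw_rich, samples, extras),
        "shannon": _assemble("n_replicates", grid, "shannon", category, raw_shan, samples, extras),
    }


def _retained_at_depth(table: OTUTable, g: int) -> list:
    depths = table.depths()
    return sorted(d for d in table.dataset_ids if depths[d] >= g)


def divergence_vs_depth(
    table: OTUTable,
    grid: Sequence[int],
    spec: SubsampleSpec,
    tax: TaxonomyMap | None = None,
    category: str = "all",
) -> dict:
    """Mean within-sample Bray-Curtis and Jaccard dissimilarity vs depth.

    Per iteration and depth every replicate deep enough is subsampled (then
    filtered to the category, if given); dissimilarities are computed on the
    subsample's relative abundances (Bray-Curtis) or presence/absence
    (Jaccard).  Samples with fewer than 2 retained replicates at a depth
    are omitted at that depth.
    """
    grid = sorted(int(g) for g in grid)
    if not grid:
        raise ValueError("empty depth grid")
    mask = _category_mask(table, tax, category)
    samples = table.samples
    raw_bc: dict = {}
    raw_jc: dict = {}
    for g in grid:
        retained = _retained_at_depth(table, g)
        by_sample = {
            s: [d for d in retained if table.sample_of[d] == s] for s in samples
        }
        usable = {s: ds for s, ds in by_sample.items() if len(ds) >= 2}
        for s in samples:
            if s not in usable:
                logger.info(
                    "divergence_vs_depth: sample %r has <2 replicates at depth %d, omitted",
                    s, g,
                )
        if not usable:
            continue
        acc = {s: {"bc": np.empty(spec.iterations), "jc": np.empty(spec.iterations)} for s in usable}
        for i in range(spec.iterations):
            subs = {
                d: _draw(table.column(d), d, g, i, spec.seed)[mask]
                for ds in usable.values()
                for d in ds
            }
            for s, ds in usable.items():
                # a replicate whose subsample holds no reads of the target
                # category cannot enter a dissimilarity; drop it this iteration
                nonzero = [d for d in ds if subs[d].sum() > 0]
                if len(nonzero) < 2:
                    acc[s]["bc"][i] = np.nan
                    acc[s]["jc"][i] = np.nan
                    continue
                cols = pd.DataFrame({d: subs[d] for d in nonzero})
                bc = matrix_from_columns(cols, "bray_curtis")
                jc = matrix_from_columns(cols, "jaccard")
                iu = np.triu_indices(len(nonzero), k=1)
                acc[s]["bc"][i] = bc.values[iu].mean()
                acc[s]["jc"][i] = jc.values[iu].mean()
        for s in usable:
            raw_bc[(s, g)] = acc[s]["bc"]
            raw_jc[(s, g)] = acc[s]["jc"]
    if not raw_bc:
        raise ValueError("no sample has >= 2 replicates at any grid depth")
    return {
        "bray_curtis": _assemble("depth", grid, "bray_curtis", category, raw_bc, samples),
        "jaccard": _assemble("depth", grid, "jaccard", category, raw_jc, samples),
    }


def _silhouette_of_columns(cols: pd.DataFrame, labels: dict) -> float:
    # columns whose (filtered) subsample holds no reads cannot enter a
    # Bray-Curtis matrix; drop them, and give up on the iteration if fewer
    # than 2 clusters remain
    keep = [c for c in cols.columns if cols[c].sum() > 0]
    n_clusters = len({labels[c] for c in keep})
    # silhouette needs 2..len(keep)-1 clusters (all-singleton clusterings
    # are undefined)
    if len(keep) < 3 or not (2 <= n_clusters <= len(keep) - 1):
        return np.nan
    dm = matrix_from_columns(cols[keep], "bray_curtis")
    return silhouette(dm, {c: labels[c] for c in keep}).mean


def silhouette_vs_depth(
    table: OTUTable,
    tax: TaxonomyMap | None,
    category: str,
    grid: Sequence[int],
    spec: SubsampleSpec,
) -> SimulationResult:
    """Mean silhouette score (Bray-Curtis, sample-of-origin clusters) vs depth."""
    grid = sorted(int(g) for g in grid)
    if not grid:
        raise ValueError("empty depth grid")
    mask = _category_mask(table, tax, category)
    raw: dict = {}
    for g in grid:
        # columns ordered by (sample, dataset) so the n=1 pooling reduction
        # produces an identically ordered matrix
        retained = sorted(
            _retained_at_depth(table, g), key=lambda d: (str(table.sample_of[d]), str(d))
        )
        labels = {d: table.sample_of[d] for d in retained}
        if len(set(labels.values())) < 2:
            raise ValueError(f"fewer than 2 samples represented at depth {g}")
        vals = np.empty(spec.iterations)
        for i in range(spec.iterations):
            cols = pd.DataFrame(
                {d: _draw(table.column(d), d, g, i, spec.seed)[mask] for d in retained}
            )
            vals[i] = _silhouette_of_columns(cols, labels)
        raw[("all", g)] = vals
    return _assemble("depth", grid, "silhouette", category, raw, ["all"])


def silhouette_vs_replication(
    table: OTUTable,
    tax: TaxonomyMap | None,
    category: str,
    design: PoolingDesign,
    shallow: str = "all_reads",
) -> SimulationResult:
    """Mean silhouette score vs number of replicates pooled per pseudo-replicate.

    Per iteration each sample's replicates are randomly partitioned into
    ``floor(R/n)`` disjoint pseudo-replicates of ``n`` members (leftovers
    discarded); members are subsampled to ``r = floor(total_depth/n)``
    reads and merged.  Every sample must yield at least 2
    pseudo-replicates.

    ``shallow='all_reads'`` (default) keeps replicates shallower than
    ``r`` in the partition, contributing every read they have (rrarefy
    convention; this preserves the fixed floor(R/n)-pool structure);
    ``shallow='exclude'`` removes them first, which makes the ``n = 1``
    case coincide exactly with the depth simulation at ``total_depth``.
    """
    if shallow not in ("exclude", "all_reads"):
        raise ValueError(f"unknown shallow policy {shallow!r}")
    mask = _category_mask(table, tax, category)
    depths = table.depths()
    samples = sorted(table.samples, key=str)
    if len(samples) < 2:
        raise ValueError("need >= 2 samples")
    grid = sorted(design.n_values)
    raw: dict = {}
    n_pools: dict = {}
    for n in grid:
        r = design.reads_per_replicate(n)
        avail = {
            s: sorted(
                d
                for d in table.datasets_of_sample(s)
                if shallow == "all_reads" or depths[d] >= r
            )
            for s in samples
        }
        pools_per_sample = {s: len(ds) // n for s, ds in avail.items()}
        short = [s for s, k in pools_per_sample.items() if k < 2]
        if short:
            raise ValueError(
                f"n={n} yields <2 pseudo-replicates for samples {short} "
                f"(need 2n replicates with depth >= {r})"
            )
        n_pools[n] = pools_per_sample
        vals = np.empty(design.iterations)
        for i in range(design.iterations):
            pseudo_cols = {}
            labels = {}
            for s in samples:
                part = derive_rng(design.seed, "part", s, n, i)
                order = list(part.permutation(np.asarray(avail[s], dtype=object)))
                k = pools_per_sample[s]
                groups = [sorted(order[j * n : (j + 1) * n]) for j in range(k)]
                groups.sort()  # deterministic pseudo-replicate order
                for j, members in enumerate(groups):
                    pid = f"{s}|pool{j}"
                    pseudo_cols[pid] = merge_subsamples(table, members, r, design.seed, i)[mask]
                    labels[pid] = s
            cols = pd.DataFrame(pseudo_cols)
            vals[i] = _silhouette_of_columns(cols, labels)
        raw[("all", n)] = vals
    extras = {"n_pools": n_pools, "reads_per_replicate": {n: design.reads_per_replicate(n) for n in grid}}
    return _assemble("n_replicates", grid, "silhouette", category, raw, ["all"], extras)


def depth_richness_correlation(table: OTUTable):
    """Pearson correlation between observed richness and depth across replicates."""
    depths = table.depths().to_numpy(dtype=float)
    richness = table.observed_richness().to_numpy(dtype=float)
    if len(depths) < 3:
        raise ValueError("need >= 3 replicate datasets")
    if depths.std() == 0:
        raise ValueError("depths have zero variance")
    if richness.std() == 0:
        return 0.0, 1.0
    r, p = sstats.pearsonr(depths, richness)
    return float(r), float(p)
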