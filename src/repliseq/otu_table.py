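"""OTU count tables, taxonomy categories, and table-level operations.

The central object is :class:`OTUTable`: a nonnegative integer matrix of
read counts (rows = OTUs, columns = sequencing datasets, typically one per
DNA-extraction replicate) together with a mapping from each dataset to its
sample of origin.  :class:`TaxonomyMap` carries the taxonomic lineage of
each OTU and its coarse category -- ``protist`` (classified eukaryote that
is neither metazoan, fungal nor Viridiplantae), ``metazoa``, or ``other``.

Operations cover I/O (plain TSV), in-silico pooling of replicate columns,
category filtering, relative abundances, singleton statistics and
depth-based dataset exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = ("protist", "metazoa", "other")

#: tokens accepted in taxonomy files, normalised to the canonical categories
_CATEGORY_ALIASES = {
    "protist": "protist",
    "protists": "protist",
    "metazoa": "metazoa",
    "metazoan": "metazoa",
    "other": "other",
    "unknown": "other",
    "unclassified": "other",
    "": "other",
}


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class OTUTable:
    """Integer OTU x dataset count matrix with sample-of-origin labels.

    Parameters
    ----------
    counts
        DataFrame of nonnegative integer read counts; index = OTU ids,
        columns = dataset ids.
    sample_of
        Mapping dataset id -> sample id; must cover every column.
    """

    counts: pd.DataFrame
    sample_of: dict = field(default_factory=dict)

    def __post_init__(self):
        counts = self.counts
        if counts.index.has_duplicates:
            raise ValueError("duplicate OTU ids in table")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate dataset ids in table")
        arr = counts.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    raise ValueError("counts must be integral")
                counts = counts.round().astype(np.int64)
            if (counts.to_numpy() < 0).any():
                raise ValueError("counts must be nonnegative")
        self.counts = counts.astype(np.int64) if counts.size else counts
        self.sample_of = dict(self.sample_of)
        missing = [d for d in self.counts.columns if d not in self.sample_of]
        if missing:
            raise ValueError(f"datasets missing from sample map: {missing}")

    # -- descriptive accessors ------------------------------------------------

    @property
    def otu_ids(self) -> list:
        return list(self.counts.index)

    @property
    def dataset_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def samples(self) -> list:
        seen: dict = {}
        for d in self.counts.columns:
            seen.setdefault(self.sample_of[d], None)
        return list(seen)

    def depths(self) -> pd.Series:
        """Total reads (sequence depth) per dataset."""
        return self.counts.sum(axis=0)

    def observed_richness(self) -> pd.Series:
        """Number of OTUs with at least one read, per dataset."""
        return (self.counts > 0).sum(axis=0)

    def datasets_of_sample(self, sample) -> list:
        return [d for d in self.counts.columns if self.sample_of[d] == sample]

    def column(self, dataset) -> np.ndarray:
        return self.counts[dataset].to_numpy()


@dataclass
class TaxonomyMap:
    """OTU id -> lineage string and coarse category."""

    lineage: pd.Series
    category: pd.Series

    def __post_init__(self):
        self.lineage = pd.Series(self.lineage, dtype=object)
        self.category = pd.Series(self.category, dtype=object)
        bad = set(self.category.unique()) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories: {sorted(bad)}")

    def category_mask(self, otu_ids: Iterable, category: str) -> np.ndarray:
        """Boolean mask over ``otu_ids`` selecting the given category.

        ``category='all'`` selects everything.
        """
        otu_ids = pd.Index(otu_ids)
        if category == "all":
            return np.ones(len(otu_ids), dtype=bool)
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        cats = self.category.reindex(otu_ids)
        if cats.isna().any():
            missing = list(otu_ids[cats.isna()][:5])
            raise ValueError(f"taxonomy does not cover OTUs {missing}...")
        return (cats == category).to_numpy()


@dataclass
class RelAbundanceTable:
    """Per-dataset OTU read fractions; columns sum to 1 when depth > 0."""

    fractions: pd.DataFrame
    zero_depth: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_otu_table(path, sample_map: Mapping) -> OTUTable:
    """Read a tab-separated OTU table (first column OTU id, header = datasets)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    parsed = {}
    for col in df.columns:
        try:
            parsed[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ParseError(
                f"{path}: malformed numeric cell at OTU {row!r}, dataset {col!r}"
            ) from None
    counts = pd.DataFrame(parsed, index=df.index)
    missing = [d for d in counts.columns if d not in sample_map]
    if missing:
        raise ValueError(
            f"datasets {missing} not present in sample map (configuration error)"
        )
    return OTUTable(counts, {d: sample_map[d] for d in counts.columns})


def write_otu_table(table: OTUTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="otu_id")


def read_sample_map(path) -> dict:
    """Read a dataset->sample map from TSV with columns dataset, sample[, replicate]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: sample map needs >= 2 columns (dataset, sample)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_taxonomy(path) -> TaxonomyMap:
    """Read a TSV taxonomy file with columns OTU id, lineage, category.

    Category tokens are normalised: unknown/unclassified/blank map to
    ``other``; anything unrecognised is an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ParseError(f"{path}: taxonomy needs 3 columns (otu, lineage, category)")
    otus = df.iloc[:, 0]
    if otus.duplicated().any():
        dups = list(otus[otus.duplicated()].unique()[:5])
        raise ParseError(f"{path}: duplicate OTU ids {dups}")
    raw = df.iloc[:, 2].str.strip().str.lower()
    unknown = sorted(set(raw) - set(_CATEGORY_ALIASES))
    if unknown:
        raise ParseError(f"{path}: unknown category tokens {unknown}")
    cats = raw.map(_CATEGORY_ALIASES)
    return TaxonomyMap(
        lineage=pd.Series(df.iloc[:, 1].to_numpy(), index=otus.to_numpy()),
        category=pd.Series(cats.to_numpy(), index=otus.to_numpy()),
    )


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    pd.DataFrame(
        {"lineage": tax.lineage, "category": tax.category}
    ).to_csv(path, sep="\t", index_label="otu_id")


def category_from_lineage(lineage: str) -> str:
    """Coarse category from a semicolon-separated lineage string.

    A protist is operationally any classified eukaryote that is not
    metazoan, fungal or Viridiplantae.
    """
    ranks = [r.strip().lower() for r in str(lineage).split(";")]
    if "metazoa" in ranks:
        return "metazoa"
    if "eukaryota" in ranks and not ({"fungi", "viridiplantae"} & set(ranks)):
        return "protist"
    return "other"


# ---------------------------------------------------------------------------
# table operations
# ---------------------------------------------------------------------------


def pool_replicates(table: OTUTable, grouping: Mapping) -> OTUTable:
    """Sum replicate columns in-silico according to ``grouping`` (dataset -> group).

    Every dataset must be assigned to exactly one group; read counts are
    summed with integer arithmetic so totals are conserved exactly.  The
    pooled column inherits the sample label when all members share one,
    otherwise the group id itself is used.
    """
    unassigned = [d for d in table.dataset_ids if d not in grouping]
    if unassigned:
        raise ValueError(f"datasets not assigned to any group: {unassigned}")
    groups: dict = {}
    for d in table.dataset_ids:
        groups.setdefault(grouping[d], []).append(d)
    for g, members in groups.items():
        if not members:
            raise ValueError(f"empty group {g!r}")
    pooled = pd.DataFrame(
        {g: table.counts[members].sum(axis=1) for g, members in groups.items()},
        index=table.counts.index,
    )
    sample_of = {}
    for g, members in groups.items():
        member_samples = {table.sample_of[d] for d in members}
        sample_of[g] = member_samples.pop() if len(member_samples) == 1 else g
    return OTUTable(pooled, sample_of)


def pool_by_sample(table: OTUTable) -> OTUTable:
    """Pool all replicates of each sample into one column per sample."""
    return pool_replicates(table, dict(table.sample_of))


def filter_category(table: OTUTable, tax: TaxonomyMap, category: str) -> OTUTable:
    """Restrict rows to one taxonomic category (``all`` = no filtering)."""
    if category == "all":
        return OTUTable(table.counts.copy(), table.sample_of)
    mask = tax.category_mask(table.counts.index, category)
    return OTUTable(table.counts.loc[mask], table.sample_of)


def relative_abundances(table: OTUTable) -> RelAbundanceTable:
    """Per-dataset OTU read fractions (counts divided by dataset depth)."""
    depths = table.depths()
    zero = [d for d in table.dataset_ids if depths[d] == 0]
    safe = depths.replace(0, 1)
    return RelAbundanceTable(table.counts / safe, zero_depth=zero)


@dataclass
class SingletonStats:
    n_singletons: int
    otu_fraction: float
    read_fraction: float


def singleton_stats(table: OTUTable, scope: str = "global"):
    """Singleton OTU count and fractions of OTUs / reads.

    ``scope='global'``: a singleton is an OTU with exactly one read across
    all datasets (the study-wide definition).  ``scope='per_dataset'``
    returns a DataFrame with the same statistics per column.  OTU fractions
    are relative to OTUs with at least one read in scope.
    """
    if scope == "global":
        totals = table.counts.sum(axis=1)
        n_single = int((totals == 1).sum())
        n_present = int((totals > 0).sum())
        total_reads = int(totals.sum())
        return SingletonStats(
            n_single,
            n_single / n_present if n_present else 0.0,
            n_single / total_reads if total_reads else 0.0,
        )
    if scope == "per_dataset":
        rows = {}
        for d in table.dataset_ids:
            col = table.counts[d]
            n_single = int((col == 1).sum())
            n_present = int((col > 0).sum())
            depth = int(col.sum())
            rows[d] = {
                "n_singletons": n_single,
                "otu_fraction": n_single / n_present if n_present else 0.0,
                "read_fraction": n_single / depth if depth else 0.0,
            }
        return pd.DataFrame(rows).T
    raise ValueError(f"unknown scope {scope!r}")


def remove_singletons(table: OTUTable, scope: str = "global") -> OTUTable:
    """Drop singleton OTUs (for the singleton-sensitivity analysis only;
    the default pipeline retains them)."""
    if scope == "global":
        keep = table.counts.sum(axis=1) != 1
        return OTUTable(table.counts.loc[keep], table.sample_of)
    if scope == "per_dataset":
        counts = table.counts.mask(table.counts == 1, 0)
        return OTUTable(counts, table.sample_of)
    raise ValueError(f"unknown scope {scope!r}")


def depth_filter(table: OTUTable, min_depth: int) -> OTUTable:
    """Drop datasets with depth below ``min_depth`` (the standard
    15,000-read exclusion rule); excluded datasets are logged."""
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    depths = table.depths()
    keep = [d for d in table.dataset_ids if depths[d] >= min_depth]
    excluded = [d for d in table.dataset_ids if depths[d] < min_depth]
    if excluded:
        logger.info(
            "depth_filter: excluding %d datasets below %d reads: %s",
            len(excluded), min_depth, excluded,
        )
    if not keep:
        raise ValueError(
            f"all datasets have depth < {min_depth}; lower the threshold"
        )
    return OTUTable(
        table.counts[keep], {d: table.sample_of[d] for d in keep}
    )


def summarize_datasets(table: OTUTable, tax: TaxonomyMap | None = None) -> pd.DataFrame:
    """Per-dataset overview: depth, observed richness, Shannon diversity,
    singleton count, and (with taxonomy) category read/OTU fractions."""
    from .diversity import shannon

    depths = table.depths()
    rows = {}
    for d in table.dataset_ids:
        col = table.column(d)
        row = {
            "sample": table.sample_of[d],
            "depth": int(depths[d]),
            "richness": int((col > 0).sum()),
            "shannon": shannon(col) if col.sum() else np.nan,
            "n_singletons": int((col == 1).sum()),
        }
        if tax is not None:
            for cat in ("protist", "metazoa"):
                mask = tax.category_mask(table.counts.index, cat)
                sub = col[mask]
                row[f"{cat}_read_fraction"] = (
                    sub.sum() / col.sum() if col.sum() else np.nan
                )
                row[f"{cat}_otu_fraction"] = (
                    (sub > 0).sum() / (col > 0).sum() if (col > 0).sum() else np.nan
                )
        rows[d] = row
    return pd.DataFrame(rows).T
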