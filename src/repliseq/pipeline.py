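"""End-to-end orchestration: from an OTU table + taxonomy (or a synthetic
preset) to a results directory with one TSV/JSON pair per analysis stage
and a manifest recording config, seed, versions and output checksums."""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .diversity import (
    SubsampleSpec,
    mean_curve_across_replicates,
    rarefaction_curve,
    relative_gain,
)
from .otu_table import (
    OTUTable,
    TaxonomyMap,
    depth_filter,
    pool_by_sample,
    read_otu_table,
    read_sample_map,
    read_taxonomy,
    remove_singletons,
    singleton_stats,
    summarize_datasets,
)
from .replication_sim import (
    PoolingDesign,
    divergence_vs_depth,
    pooled_alpha_vs_n,
    silhouette_vs_depth,
    silhouette_vs_replication,
)
from .synthetic_data import preset_study

logger = logging.getLogger(__name__)


def _pkg_version() -> str:
    from . import __version__

    return __version__


STAGES = (
    "describe",
    "rarefaction",
    "alpha_pooling",
    "divergence_depth",
    "silhouette_depth",
    "silhouette_pooling",
    "singleton_sensitivity",
)


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Either ``otu_table``/``taxonomy``/``sample_map`` paths or a synthetic
    ``preset`` name must be given.  Defaults follow the standard analysis:
    datasets below 15,000 reads excluded, total pooled depth 15,000 reads,
    100 iterations per simulation.
    """

    otu_table: str | None = None
    taxonomy: str | None = None
    sample_map: str | None = None
    preset: str | None = None
    categories: tuple = ("all", "protist", "metazoa")
    grid_start: int = 500
    grid_step: int = 500
    grid_max: int = 15000
    total_depth: int = 15000
    min_depth: int = 15000
    iterations: int = 100
    n_values: tuple = tuple(range(1, 11))
    silhouette_n_values: tuple = (1, 2, 3, 4, 5)
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.grid_start < 1 or self.grid_step < 1 or self.grid_max < self.grid_start:
            raise ValueError("invalid depth grid")
        if (self.preset is None) == (self.otu_table is None):
            raise ValueError("give either input paths or a synthetic preset")

    @property
    def grid(self) -> list:
        return list(range(self.grid_start, self.grid_max + 1, self.grid_step))

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        for key in ("categories", "n_values", "silhouette_n_values"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def for_preset(cls, name: str, seed: int = 0, out_dir: str = "results", **overrides) -> "RunConfig":
        """Config with sensible scales for a synthetic preset (the ``tiny``
        preset gets a shallow grid and few iterations for smoke runs)."""
        base = dict(preset=name, seed=seed, out_dir=out_dir)
        if name == "tiny":
            base.update(
                grid_start=100, grid_step=200, grid_max=500,
                total_depth=500, min_depth=500, iterations=5,
                n_values=(1, 2, 3), silhouette_n_values=(1,),
            )
        base.update(overrides)
        return cls(**base)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(config: RunConfig):
    if config.preset is not None:
        study = preset_study(config.preset, seed=config.seed)
        return study.table, study.taxonomy
    sample_map = read_sample_map(config.sample_map)
    table = read_otu_table(config.otu_table, sample_map)
    tax = read_taxonomy(config.taxonomy) if config.taxonomy else None
    return table, tax


def _stage_describe(table, tax, config, out):
    df = summarize_datasets(table, tax)
    df.to_csv(out / "describe.tsv", sep="\t", index_label="dataset")
    stats = singleton_stats(table, scope="global")
    (out / "describe.json").write_text(
        json.dumps(
            {
                "n_otus": int((table.counts.sum(axis=1) > 0).sum()),
                "n_datasets": len(table.dataset_ids),
                "total_reads": int(table.depths().sum()),
                "singletons": {
                    "count": stats.n_singletons,
                    "otu_fraction": stats.otu_fraction,
                    "read_fraction": stats.read_fraction,
                },
            },
            indent=2,
        )
    )


def _rarefaction_frame(table, filtered, pooled, config):
    spec = SubsampleSpec(iterations=config.iterations, seed=config.seed)
    rows = []

    def add(curve, kind):
        for d, m, s in zip(curve.depths, curve.mean, curve.se):
            rows.append(
                {
                    "kind": kind,
                    "dataset": curve.dataset,
                    "sample": curve.sample,
                    "metric": curve.metric,
                    "depth": int(d),
                    "mean": m,
                    "se": s,
                    "se_kind": curve.se_kind,
                }
            )

    for metric in ("richness", "shannon"):
        per_sample_curves: dict = {}
        for d in filtered.dataset_ids:
            c = rarefaction_curve(filtered, d, config.grid, metric, spec)
            add(c, "replicate")
            per_sample_curves.setdefault(filtered.sample_of[d], []).append(c)
        for s, curves in per_sample_curves.items():
            m = mean_curve_across_replicates(curves)
            m = type(m)(f"mean[{s}]", s, m.depths, m.mean, m.se, m.metric, m.se_kind)
            add(m, "replicate_mean")
        for g in pooled.dataset_ids:
            c = rarefaction_curve(pooled, g, config.grid, metric, spec)
            add(c, "pooled")
    return pd.DataFrame(rows)


def _stage_rarefaction(table, tax, config, out):
    filtered = depth_filter(table, config.min_depth)
    pooled = pool_by_sample(table)
    df = _rarefaction_frame(table, filtered, pooled, config)
    df.to_csv(out / "rarefaction_curves.tsv", sep="\t", index=False, float_format="%.10g")
    # relative gain at the deepest grid point, per sample
    top = config.grid[-1]
    gains = {}
    for metric in ("richness", "shannon"):
        sub = df[(df.metric == metric) & (df.depth == top)]
        for s in pooled.dataset_ids:
            pooled_val = sub[(sub.kind == "pooled") & (sub.dataset == s)]["mean"]
            rep_mean = sub[(sub.kind == "replicate_mean") & (sub["sample"] == s)]["mean"]
            if len(pooled_val) and len(rep_mean):
                gains.setdefault(metric, {})[str(s)] = relative_gain(
                    float(pooled_val.iloc[0]), float(rep_mean.iloc[0])
                )
    (out / "rarefaction_gain.json").write_text(json.dumps({"depth": top, "gain": gains}, indent=2))


def _stage_alpha_pooling(table, tax, config, out):
    design = PoolingDesign(
        n_values=config.n_values,
        total_depth=config.total_depth,
        iterations=config.iterations,
        seed=config.seed,
    )
    frames = []
    for cat in config.categories:
        res = pooled_alpha_vs_n(table, tax, cat, design)
        frames.extend(r.to_frame() for r in res.values())
    pd.concat(frames).to_csv(
        out / "alpha_vs_replication.tsv", sep="\t", index=False, float_format="%.10g"
    )


def _stage_divergence_depth(table, tax, config, out):
    spec = SubsampleSpec(iterations=config.iterations, seed=config.seed)
    filtered = depth_filter(table, config.min_depth)
    res = divergence_vs_depth(filtered, config.grid, spec)
    pd.concat([r.to_frame() for r in res.values()]).to_csv(
        out / "divergence_vs_depth.tsv", sep="\t", index=False, float_format="%.10g"
    )


def _stage_silhouette_depth(table, tax, config, out):
    spec = SubsampleSpec(iterations=config.iterations, seed=config.seed)
    filtered = depth_filter(table, config.min_depth)
    frames = []
    for cat in config.categories:
        if cat != "all" and tax is None:
            continue
        frames.append(silhouette_vs_depth(filtered, tax, cat, config.grid, spec).to_frame())
    pd.concat(frames).to_csv(
        out / "silhouette_vs_depth.tsv", sep="\t", index=False, float_format="%.10g"
    )


def _stage_silhouette_pooling(table, tax, config, out):
    design = PoolingDesign(
        n_values=config.silhouette_n_values,
        total_depth=config.total_depth,
        iterations=config.iterations,
        seed=config.seed,
    )
    frames = []
    for cat in config.categories:
        if cat != "all" and tax is None:
            continue
        frames.append(silhouette_vs_replication(table, tax, cat, design).to_frame())
    pd.concat(frames).to_csv(
        out / "silhouette_vs_replication.tsv", sep="\t", index=False, float_format="%.10g"
    )


def _stage_singleton_sensitivity(table, tax, config, out):
    """Pooled rarefaction with singletons retained vs removed."""
    pooled = pool_by_sample(table)
    pooled_no_single = pool_by_sample(remove_singletons(table, scope="global"))
    rows = []
    for kind, tbl in (("retained", pooled), ("removed", pooled_no_single)):
        for g in tbl.dataset_ids:
            c = rarefaction_curve(tbl, g, config.grid, "richness")
            for d, m, s in zip(c.depths, c.mean, c.se):
                rows.append(
                    {"singletons": kind, "sample": g, "depth": int(d), "mean": m, "se": s}
                )
    pd.DataFrame(rows).to_csv(
        out / "singleton_sensitivity.tsv", sep="\t", index=False, float_format="%.10g"
    )


_STAGE_FUNCS = {
    "describe": _stage_describe,
    "rarefaction": _stage_rarefaction,
    "alpha_pooling": _stage_alpha_pooling,
    "divergence_depth": _stage_divergence_depth,
    "silhouette_depth": _stage_silhouette_depth,
    "silhouette_pooling": _stage_silhouette_pooling,
    "singleton_sensitivity": _stage_singleton_sensitivity,
}


def run_all(config: RunConfig) -> Path:
    """Run every analysis stage; returns the output directory.

    A stage failure writes a ``FAILED`` marker naming the stage and
    re-raises; completed stage outputs are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, tax = _load_inputs(config)
    logger.info(
        "run_all: %d OTUs x %d datasets, seed=%d", len(table.otu_ids),
        len(table.dataset_ids), config.seed,
    )
    for stage in STAGES:
        logger.info("stage %s", stage)
        try:
            _STAGE_FUNCS[stage](table, tax, config, out)
        except Exception as exc:
            (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "versions": {
            "repliseq": _pkg_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
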