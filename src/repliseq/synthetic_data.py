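"""Synthetic replicate OTU tables with controlled spatial heterogeneity.

The generator emulates a sediment metabarcoding study: a few bulk samples,
each represented by several DNA-extraction replicates sequenced to uneven
depths.  The community model is compound Dirichlet-multinomial:

* a long-tailed base abundance distribution (log-normal, normalised);
* per-sample composition = base abundances perturbed by a log-normal
  multiplicative shift (between-sample structure);
* per-replicate composition drawn from a Dirichlet centred on the sample
  composition, with per-OTU concentration ``min(theta_c * p_i, kappa_c)``
  where ``theta_c`` is the category's concentration (lower = patchier) and
  ``kappa_c`` its *dominance cap*: even the most abundant OTUs of a
  category keep at least CV ~ 1/sqrt(kappa_c) of replicate-to-replicate
  variation.  Metazoa default to both a lower concentration and a much
  lower cap than protists: large animals enter a 0.5 g sediment scoop as
  individuals, so even dominant metazoan taxa swap identity between
  replicates, while abundant protists are well mixed;
* reads drawn multinomially at the replicate's depth (sequencing noise).

The Dirichlet layer separates patchiness from sequencing noise: with the
concentration pushed to infinity and the sample shift to zero the model
collapses to repeated multinomial sampling from one community (the null
study used to calibrate silhouette ~ 0 and pooling gain ~ 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import derive_rng
from .otu_table import CATEGORIES, OTUTable, TaxonomyMap

__all__ = [
    "CommunityModel",
    "SyntheticStudy",
    "generate_study",
    "null_study",
    "heterogeneity_recovery",
    "preset_model",
    "preset_study",
    "PRESETS",
]

#: lineage strings attached to synthetic OTUs, per category
_LINEAGES = {
    "protist": "Eukaryota;SAR;Stramenopiles",
    "metazoa": "Eukaryota;Opisthokonta;Metazoa;Annelida",
    "other": "Eukaryota;Opisthokonta;Fungi",
}


@dataclass
class CommunityModel:
    """Ground-truth community parameters.

    ``base_abundance`` sums to 1; ``concentration`` maps each category to a
    Dirichlet concentration scale (per-OTU alpha = concentration *
    sample-level abundance), so lower values yield patchier replicate
    compositions.  ``dominance_cap`` bounds the per-OTU alpha from above,
    keeping abundant OTUs of a patchy category volatile across replicates.
    ``sample_shift_sigma`` is the SD of the log-normal per-OTU multiplier
    distinguishing samples (0 = identical samples).
    """

    base_abundance: np.ndarray
    category_of: np.ndarray
    concentration: dict
    dominance_cap: dict | None = None
    sample_shift_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.base_abundance = np.asarray(self.base_abundance, dtype=float)
        if not np.isclose(self.base_abundance.sum(), 1.0):
            raise ValueError("base abundances must sum to 1")
        if (self.base_abundance <= 0).any():
            raise ValueError("base abundances must be positive")
        self.category_of = np.asarray(self.category_of, dtype=object)
        if len(self.category_of) != len(self.base_abundance):
            raise ValueError("category_of and base_abundance length mismatch")
        for c in CATEGORIES:
            if self.concentration.get(c, 0) <= 0:
                raise ValueError(f"concentration for {c!r} must be > 0")
        if self.dominance_cap is None:
            self.dominance_cap = {c: float("inf") for c in CATEGORIES}
        for c in CATEGORIES:
            if self.dominance_cap.get(c, 0) <= 0:
                raise ValueError(f"dominance cap for {c!r} must be > 0")

    @property
    def n_otus(self) -> int:
        return len(self.base_abundance)

    @classmethod
    def create(
        cls,
        n_otus: int = 50000,
        abundance_sigma: float = 3.0,
        category_fractions: Mapping | None = None,
        concentration: Mapping | None = None,
        dominance_cap: Mapping | None = None,
        sample_shift_sigma: float = 1.0,
        seed: int = 0,
    ) -> "CommunityModel":
        """Draw a model: log-normal base abundances and exact-proportion
        category assignment (protist-majority, small metazoan fraction)."""
        fracs = dict(category_fractions or {"protist": 0.64, "metazoa": 0.08, "other": 0.28})
        if not np.isclose(sum(fracs.values()), 1.0):
            raise ValueError("category fractions must sum to 1")
        conc = dict(concentration or {"protist": 3000.0, "metazoa": 300.0, "other": 3000.0})
        cap = dict(dominance_cap or {"protist": 50.0, "metazoa": 0.2, "other": 50.0})
        rng = derive_rng(seed, "model")
        base = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=n_otus)
        base /= base.sum()
        # exact allocation keeps realised fractions on target for any n_otus
        n_by_cat = {c: int(round(fracs[c] * n_otus)) for c in CATEGORIES}
        drift = n_otus - sum(n_by_cat.values())
        n_by_cat["other"] += drift
        cats = np.repeat(
            np.array(CATEGORIES, dtype=object),
            [n_by_cat[c] for c in CATEGORIES],
        )
        rng.shuffle(cats)
        return cls(base, cats, conc, cap, sample_shift_sigma, seed)


@dataclass
class SyntheticStudy:
    """A generated study: OTU table, taxonomy, and the ground truth behind it."""

    table: OTUTable
    taxonomy: TaxonomyMap
    ground_truth: dict = field(default_factory=dict)


def generate_study(
    model: CommunityModel,
    n_samples: int = 3,
    n_replicates: int = 10,
    depth_range: tuple = (2500, 37000),
    seed: int = 0,
    sample_names: Sequence | None = None,
) -> SyntheticStudy:
    """Generate a replicate study from a community model.

    Per-replicate depths are uniform over ``depth_range``; replicate
    compositions follow the compound Dirichlet-multinomial described in the
    module docstring.  Deterministic for a fixed ``seed``.
    """
    if sample_names is None:
        sample_names = [f"S{k + 1}" for k in range(n_samples)]
    otu_ids = [f"OTU_{k + 1:05d}" for k in range(model.n_otus)]
    alpha_scale = np.array(
        [model.concentration[c] for c in model.category_of], dtype=float
    )
    alpha_cap = np.array(
        [model.dominance_cap[c] for c in model.category_of], dtype=float
    )
    columns = {}
    sample_of = {}
    truth_comp = {}
    lo, hi = depth_range
    for s in sample_names:
        shift_rng = derive_rng(seed, "shift", s)
        if model.sample_shift_sigma > 0:
            shift = shift_rng.lognormal(0.0, model.sample_shift_sigma, model.n_otus)
        else:
            shift = np.ones(model.n_otus)
        comp = model.base_abundance * shift
        comp /= comp.sum()
        truth_comp[s] = comp
        for j in range(n_replicates):
            rng = derive_rng(seed, "rep", s, j)
            depth = int(rng.integers(lo, hi + 1))
            alpha = np.minimum(alpha_scale * comp, alpha_cap)
            alpha = np.maximum(alpha, 1e-300)
            # gamma draws rescaled to mean comp_i, so each OTU keeps its
            # sample-level expected abundance while the relative variance is
            # 1/alpha_i: patchiness differs by category without biasing the
            # mean composition
            g = comp * rng.gamma(alpha) / alpha
            total = g.sum()
            q = g / total if total > 0 else comp
            counts = rng.multinomial(depth, q / q.sum())
            name = f"{s}_r{j + 1:02d}"
            columns[name] = counts
            sample_of[name] = s
    table = OTUTable(pd.DataFrame(columns, index=otu_ids), sample_of)
    tax = TaxonomyMap(
        lineage=pd.Series(
            [_LINEAGES[c] for c in model.category_of], index=otu_ids
        ),
        category=pd.Series(model.category_of, index=otu_ids),
    )
    truth = {
        "sample_composition": truth_comp,
        "concentration": dict(model.concentration),
        "dominance_cap": dict(model.dominance_cap),
        "sample_shift_sigma": model.sample_shift_sigma,
        "depth_range": tuple(depth_range),
        "seed": seed,
    }
    return SyntheticStudy(table, tax, truth)


def null_study(model: CommunityModel, **kwargs) -> SyntheticStudy:
    """Study with no between-sample structure and no patchiness.

    Sample shift is removed and all concentrations pushed to 1e9, so
    replicates are plain multinomial samples from one shared community.
    Used to calibrate the null expectations: pooling gain ~ 1, mean
    silhouette ~ 0, no category divergence ordering.
    """
    flat = replace(
        model,
        sample_shift_sigma=0.0,
        concentration={c: 1e9 for c in CATEGORIES},
        dominance_cap={c: 1e9 for c in CATEGORIES},
    )
    return generate_study(flat, **kwargs)


@dataclass
class HeterogeneityCheck:
    metazoa_divergence: float
    protist_divergence: float
    effect_size: float  # metazoa minus protist mean within-sample Bray-Curtis
    passed: bool


def heterogeneity_recovery(
    study: SyntheticStudy,
    depth: int = 5000,
    iterations: int = 25,
    seed: int = 0,
) -> HeterogeneityCheck:
    """Check that metazoan intra-sample divergence exceeds protist divergence.

    Computes the mean within-sample Bray-Curtis dissimilarity at a common
    subsampling depth (subsample-then-filter) for the metazoan and protist
    OTU subsets and compares them; the expected ordering holds when the
    generating model gave metazoa a lower Dirichlet concentration.
    """
    from .diversity import SubsampleSpec
    from .replication_sim import divergence_vs_depth

    spec = SubsampleSpec(iterations=iterations, seed=seed)
    div = {}
    for cat in ("metazoa", "protist"):
        res = divergence_vs_depth(
            study.table, [depth], spec, tax=study.taxonomy, category=cat
        )["bray_curtis"]
        div[cat] = float(res.mean.loc[depth].mean())
    effect = div["metazoa"] - div["protist"]
    return HeterogeneityCheck(div["metazoa"], div["protist"], effect, effect > 0)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

#: study shapes used throughout tests and the pipeline
PRESETS = {
    # mirrors the real study's design envelope: 3 samples x 10 replicates,
    # uneven depths (2,500-37,000 reads), a large long-tailed OTU pool
    # (~7,000 OTUs observed, ~20% singletons at these depths),
    # protist-majority community, metazoa 10x patchier than protists
    "paperlike": dict(
        model=dict(
            n_otus=50000,
            abundance_sigma=3.0,
            concentration={"protist": 3000.0, "metazoa": 300.0, "other": 3000.0},
            dominance_cap={"protist": 50.0, "metazoa": 0.2, "other": 50.0},
            sample_shift_sigma=1.0,
        ),
        study=dict(n_samples=3, n_replicates=10, depth_range=(2500, 37000)),
    ),
    "null": dict(
        model=dict(
            n_otus=50000,
            abundance_sigma=3.0,
            concentration={"protist": 3000.0, "metazoa": 300.0, "other": 3000.0},
            dominance_cap={"protist": 50.0, "metazoa": 0.2, "other": 50.0},
            sample_shift_sigma=1.0,
        ),
        study=dict(n_samples=3, n_replicates=10, depth_range=(2500, 37000)),
    ),
    # small and shallow, for fast smoke tests
    "tiny": dict(
        model=dict(
            n_otus=200,
            abundance_sigma=1.5,
            concentration={"protist": 30.0, "metazoa": 3.0, "other": 30.0},
            dominance_cap={"protist": 50.0, "metazoa": 0.2, "other": 50.0},
            sample_shift_sigma=1.0,
        ),
        study=dict(n_samples=3, n_replicates=3, depth_range=(500, 2000)),
    ),
}


def preset_model(name: str, seed: int = 0) -> CommunityModel:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return CommunityModel.create(seed=seed, **PRESETS[name]["model"])


def preset_study(name: str, seed: int = 0) -> SyntheticStudy:
    """Generate one of the named study presets (``paperlike``, ``null``, ``tiny``)."""
    model = preset_model(name, seed=seed)
    kwargs = dict(PRESETS[name]["study"], seed=seed)
    if name == "null":
        return null_study(model, **kwargs)
    return generate_study(model, **kwargs)
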