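import numpy as np
import pandas as pd
import pytest

from repliseq.diversity import SubsampleSpec, expected_richness
from repliseq.otu_table import OTUTable, TaxonomyMap, filter_category
from repliseq.replication_sim import (
    PoolingDesign,
    alpha_vs_depth,
    depth_richness_correlation,
    divergence_vs_depth,
    merge_subsamples,
    pooled_alpha_vs_n,
    silhouette_vs_depth,
    silhouette_vs_replication,
)


@pytest.fixture(scope="module")
def study(tiny_study):
    return tiny_study


def spec(iters=10, seed=3):
    return SubsampleSpec(iterations=iters, seed=seed)


class TestMergeSubsamples:
    def test_read_conservation(self, study):
        table = study.table
        ds = table.dataset_ids[:3]
        merged = merge_subsamples(table, ds, 200, seed=1, iteration=0)
        assert merged.sum() == 3 * 200
        assert (merged <= table.counts[ds].sum(axis=1).to_numpy()).all()

    def test_shallow_member_contributes_all_reads(self, study):
        table = study.table
        d = min(table.dataset_ids, key=lambda d: table.depths()[d])
        depth = int(table.depths()[d])
        merged = merge_subsamples(table, [d], depth + 500, seed=1, iteration=0)
        assert merged.sum() == depth


class TestAlphaVsDepth:
    def test_full_depth_equals_observed_filtered_richness(self, study):
        table, tax = study.table, study.taxonomy
        dmin = int(table.depths().min())
        res = alpha_vs_depth(table, tax, "protist", [dmin], spec(5))
        for d in res["richness"].mean.columns:
            sub = table.counts[table.counts[d] > 0]
            if table.depths()[d] == dmin:
                observed = (
                    filter_category(table, tax, "protist").counts[d] > 0
                ).sum()
                assert res["richness"].mean.loc[dmin, d] == observed

    def test_matches_analytic_expectation(self, study):
        table = study.table
        res = alpha_vs_depth(table, None, "all", [300], spec(60, seed=9))
        for d in res["richness"].mean.columns:
            analytic = expected_richness(table.column(d), 300)
            raw = res["richness"].raw[(d, 300)]
            se = raw.std(ddof=1) / np.sqrt(len(raw))
            assert res["richness"].mean.loc[300, d] == pytest.approx(
                analytic, abs=3 * se + 1e-9
            )

    def test_subsample_then_filter_differs_from_filter_then_subsample(self, study):
        # the pipeline subsamples the full community first; filtering first
        # concentrates the depth budget on the category and yields more
        # category OTUs -- the orders must not be interchangeable
        table, tax = study.table, study.taxonomy
        sub_first = alpha_vs_depth(table, tax, "protist", [300], spec(20))
        filt_first = alpha_vs_depth(
            filter_category(table, tax, "protist"), None, "all", [300], spec(20)
        )
        a = sub_first["richness"].mean.loc[300]
        b = filt_first["richness"].mean.loc[300]
        common = a.index.intersection(b.index)
        assert (b[common] > a[common]).all()

    def test_determinism(self, study):
        r1 = alpha_vs_depth(study.table, None, "all", [200, 400], spec(5))
        r2 = alpha_vs_depth(study.table, None, "all", [200, 400], spec(5))
        for key in r1["richness"].raw:
            assert (r1["richness"].raw[key] == r2["richness"].raw[key]).all()


class TestPooledAlpha:
    def test_n1_reduces_to_single_replicate_subsampling(self, study):
        """The n=1 pooling draw must be bit-identical to the depth draw of
        the selected replicate (shared RNG stream contract)."""
        table = study.table
        design = PoolingDesign(n_values=(1,), total_depth=500, iterations=8, seed=5)
        pooled = pooled_alpha_vs_n(table, None, "all", design)
        depth_sim = alpha_vs_depth(table, None, "all", [500], spec(8, seed=5))
        for s in table.samples:
            chosen = pooled["richness"].extras["selected"][(s, 1)]
            for i in range(8):
                d = chosen[i][0]
                for stat in ("richness", "shannon"):
                    assert (
                        pooled[stat].raw[(s, 1)][i]
                        == depth_sim[stat].raw[(d, 500)][i]
                    )

    def test_too_few_replicates_rejected(self, study):
        design = PoolingDesign(n_values=(7,), total_depth=500, iterations=2, seed=0)
        with pytest.raises(ValueError, match="cannot pool"):
            pooled_alpha_vs_n(study.table, None, "all", design)

    def test_homogeneous_replicates_flat_in_n(self):
        # identical replicate columns: pooling cannot add richness
        col = np.array([40, 25, 10, 5, 5, 5, 4, 3, 2, 1])
        counts = pd.DataFrame({f"d{i}": col for i in range(4)}, index=range(10))
        t = OTUTable(counts, {f"d{i}": "s" for i in range(4)})
        design = PoolingDesign(n_values=(1, 2, 4), total_depth=80, iterations=40, seed=2)
        res = pooled_alpha_vs_n(t, None, "all", design)
        rich = res["richness"].mean["s"]
        se = max(
            res["richness"].raw[("s", n)].std(ddof=1) / np.sqrt(40) for n in (1, 2, 4)
        )
        assert abs(rich[4] - rich[1]) <= 4 * se + 0.3


class TestDivergence:
    def test_identical_replicates_zero_divergence_at_full_depth(self):
        col = np.array([10, 6, 4])
        counts = pd.DataFrame(
            {"a1": col, "a2": col, "b1": col * 2, "b2": col * 2}, index=range(3)
        )
        t = OTUTable(counts, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        res = divergence_vs_depth(t, [20], spec(4))
        assert res["bray_curtis"].mean.loc[20, "A"] == pytest.approx(0.0)
        assert res["jaccard"].mean.loc[20, "A"] == pytest.approx(0.0)

    def test_nonnegative_and_decreasing_with_depth(self, study):
        res = divergence_vs_depth(study.table, [50, 150, 500], spec(15))
        for metric in ("bray_curtis", "jaccard"):
            mean = res[metric].mean
            assert (mean.fillna(0).to_numpy() >= 0).all()
            overall = mean.mean(axis=1)
            assert overall[500] < overall[50]


class TestSilhouetteSims:
    def test_disjoint_samples_score_near_one(self):
        rng = np.random.default_rng(1)
        cols = {}
        sof = {}
        for k, s in enumerate("ABC"):
            base = np.zeros(30, dtype=int)
            base[10 * k : 10 * (k + 1)] = rng.integers(20, 60, 10)
            for j in range(3):
                cols[f"{s}{j}"] = base + rng.integers(0, 3, 30) * (base > 0)
                sof[f"{s}{j}"] = s
        t = OTUTable(pd.DataFrame(cols), sof)
        # at a depth deep enough that subsampling noise is small, disjoint
        # OTU sets give between-sample distance 1 and near-perfect scores
        res = silhouette_vs_depth(t, None, "all", [300], spec(5))
        assert res.mean.loc[300, "all"] > 0.85

    def test_identical_compositions_score_near_zero(self):
        col = np.array([30, 20, 10, 5, 5])
        counts = pd.DataFrame(
            {f"{s}{j}": col for s in "AB" for j in range(3)}, index=range(5)
        )
        t = OTUTable(counts, {f"{s}{j}": s for s in "AB" for j in range(3)})
        res = silhouette_vs_depth(t, None, "all", [40], spec(20, seed=4))
        assert abs(res.mean.loc[40, "all"]) < 0.15

    def test_n1_reduces_to_depth_simulation(self, study):
        table = study.table
        design = PoolingDesign(n_values=(1,), total_depth=500, iterations=6, seed=5)
        pooled = silhouette_vs_replication(
            table, None, "all", design, shallow="exclude"
        )
        depth_sim = silhouette_vs_depth(table, None, "all", [500], spec(6, seed=5))
        assert (
            pooled.raw[("all", 1)] == depth_sim.raw[("all", 500)]
        ).all()

    def test_leftover_replicates_discarded(self, study):
        # 3 replicates per sample, n=2 -> floor(3/2) = 1 pool: too few
        design = PoolingDesign(n_values=(2,), total_depth=200, iterations=2, seed=0)
        with pytest.raises(ValueError, match="<2 pseudo-replicates"):
            silhouette_vs_replication(study.table, None, "all", design)

    def test_pool_counts_follow_floor_rule(self):
        rng = np.random.default_rng(6)
        cols = {
            f"{s}{j}": rng.integers(0, 20, 40) for s in "AB" for j in range(10)
        }
        t = OTUTable(pd.DataFrame(cols), {f"{s}{j}": s for s in "AB" for j in range(10)})
        design = PoolingDesign(n_values=(3,), total_depth=90, iterations=2, seed=0)
        res = silhouette_vs_replication(t, None, "all", design)
        assert res.extras["n_pools"][3] == {"A": 3, "B": 3}  # floor(10/3)


class TestDepthRichnessCorrelation:
    def test_collinear(self):
        cols = {}
        for i, depth in enumerate((10, 20, 30)):
            col = np.zeros(40, dtype=int)
            col[:depth] = 1
            cols[f"d{i}"] = col
        t = OTUTable(pd.DataFrame(cols), {f"d{i}": "s" for i in range(3)})
        r, p = depth_richness_correlation(t)
        assert r == pytest.approx(1.0)

    def test_constant_richness_gives_zero(self):
        cols = {"d0": [5, 5], "d1": [9, 1], "d2": [3, 4]}
        t = OTUTable(pd.DataFrame(cols, index=["a", "b"]), {f"d{i}": "s" for i in range(3)})
        r, p = depth_richness_correlation(t)
        assert r == 0.0

    def test_positive_on_unsaturated_synthetic_study(self):
        # richness tracks depth only while sampling is far from exhaustive,
        # so use a large OTU pool relative to the replicate depths
        from repliseq.synthetic_data import CommunityModel, generate_study

        model = CommunityModel.create(n_otus=3000, abundance_sigma=2.0, seed=12)
        st = generate_study(
            model, n_samples=1, n_replicates=12, depth_range=(500, 8000), seed=12
        )
        r, p = depth_richness_correlation(st.table)
        assert r > 0.5
        assert p < 0.05
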