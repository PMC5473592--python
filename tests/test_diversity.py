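import math
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from repliseq.diversity import (
    RarefactionCurve,
    SubsampleSpec,
    expected_richness,
    mean_curve_across_replicates,
    rarefaction_curve,
    rarefaction_slope,
    relative_gain,
    richness_variance_heck,
    shannon,
    subsample_counts,
)

from _oracles import enumerate_subsample_richness

small_counts = st.lists(st.integers(0, 5), min_size=1, max_size=6).filter(
    lambda c: sum(c) > 0
)


class TestExpectedRichness:
    @pytest.mark.parametrize(
        "counts, n, expected",
        [
            ((5, 3, 2), 10, 3.0),  # census returns observed richness
            ((2, 1, 1), 1, 1.0),  # one read is always one OTU
            ((2, 1, 1), 2, 11 / 6),  # enumeration over the 6 read pairs
            ((7,), 3, 1.0),
            ((4, 4), 0, 0.0),
        ],
    )
    def test_known_values(self, counts, n, expected):
        assert expected_richness(counts, n) == pytest.approx(expected, abs=1e-9)

    def test_no_extrapolation(self):
        with pytest.raises(ValueError, match="extrapolation"):
            expected_richness((2, 1), 4)

    @given(counts=small_counts)
    @settings(max_examples=50, deadline=None)
    def test_nondecreasing_and_concave_in_n(self, counts):
        values = [expected_richness(counts, n) for n in range(sum(counts) + 1)]
        diffs = np.diff(values)
        assert (diffs >= -1e-9).all()
        assert (np.diff(diffs) <= 1e-9).all()

    def test_large_counts_no_overflow(self):
        # log-gamma evaluation must survive 10^5-read OTUs
        val = expected_richness((10**5, 10**5, 1), 10**5)
        assert 2.0 < val <= 3.0


class TestHeckVariance:
    def test_census_has_zero_variance(self):
        assert richness_variance_heck((4, 3, 2), 9) == 0.0
        assert richness_variance_heck((4, 3, 2), 0) == 0.0

    @pytest.mark.parametrize("counts", [(2, 1, 1), (3, 2), (2, 2, 2), (5, 1)])
    def test_matches_enumeration(self, counts):
        for n in range(sum(counts) + 1):
            _, var = enumerate_subsample_richness(counts, n)
            assert richness_variance_heck(counts, n) == pytest.approx(var, abs=1e-9)

    def test_matches_monte_carlo_on_large_table(self):
        counts = np.array([10**5, 10**5])
        n = 10**5
        rng = np.random.default_rng(2024)
        draws = rng.multivariate_hypergeometric(counts, n, size=10**4)
        rich = (draws > 0).sum(axis=1)
        mc_var = rich.var(ddof=1)
        # variance of the sample variance approximated via normal theory
        se_var = mc_var * math.sqrt(2.0 / (10**4 - 1))
        assert richness_variance_heck(counts, n) == pytest.approx(
            mc_var, abs=3 * se_var + 1e-12
        )

    def test_vegan_rarefy_agrees(self, tmp_path):
        """Cross-check expectation and SE against R vegan's rarefy."""
        rscript = shutil.which("Rscript")
        assert rscript, "Rscript expected on PATH"
        script = tmp_path / "check.R"
        script.write_text(
            "suppressMessages(library(vegan))\n"
            "x <- c(50, 25, 10, 5, 3, 1, 1)\n"
            "for (n in c(10, 40, 80)) {\n"
            "  r <- rarefy(x, n, se=TRUE)\n"
            '  cat(sprintf("%d %.10f %.10f\\n", n, r[1], r[2]))\n'
            "}\n"
        )
        out = subprocess.run(
            [rscript, str(script)], capture_output=True, text=True, check=True
        ).stdout
        x = (50, 25, 10, 5, 3, 1, 1)
        for line in out.strip().splitlines():
            n, mean, se = line.split()
            assert expected_richness(x, int(n)) == pytest.approx(float(mean), abs=1e-8)
            assert math.sqrt(richness_variance_heck(x, int(n))) == pytest.approx(
                float(se), abs=1e-8
            )


class TestSubsampleCounts:
    def test_edge_depths(self):
        counts = np.array([4, 0, 3])
        assert (subsample_counts(counts, 7, 0) == counts).all()
        assert subsample_counts(counts, 0, 0).sum() == 0

    def test_totals_and_bounds(self):
        counts = np.array([8, 2, 5])
        rng = np.random.default_rng(3)
        for _ in range(50):
            sub = subsample_counts(counts, 6, rng)
            assert sub.sum() == 6
            assert (sub <= counts).all()

    def test_marginal_means_match_hypergeometric(self):
        counts = np.array([8, 2])
        rng = np.random.default_rng(11)
        draws = np.array([subsample_counts(counts, 5, rng)[0] for _ in range(4000)])
        # mean 5 * 8/10 = 4, sd from the hypergeometric variance
        var = 5 * 0.8 * 0.2 * (10 - 5) / (10 - 1)
        assert draws.mean() == pytest.approx(4.0, abs=4 * math.sqrt(var / 4000))


class TestShannon:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ((1, 1, 1, 1), math.log(4)),
            ((7, 0, 0), 0.0),
            ((1, 2, 3), -sum(p * math.log(p) for p in (1 / 6, 1 / 3, 1 / 2))),
        ],
    )
    def test_known_values(self, x, expected):
        assert shannon(x) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon((0, 0))

    @given(counts=small_counts, scale=st.integers(2, 9))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_permutation_and_scaling(self, counts, scale):
        base = shannon(counts)
        assert shannon(counts[::-1]) == pytest.approx(base, abs=1e-12)
        assert shannon([scale * c for c in counts]) == pytest.approx(base, abs=1e-12)


class TestCurves:
    def test_richness_curve_full_depth(self, toy_table):
        c = rarefaction_curve(toy_table, "A_r1", [3, 9], "richness")
        assert c.mean[-1] == pytest.approx(3.0)  # observed richness of A_r1
        assert c.se[-1] == pytest.approx(0.0, abs=1e-9)
        assert c.se_kind == "analytic_heck"

    def test_depths_beyond_total_skipped(self, toy_table):
        c = rarefaction_curve(toy_table, "A_r1", [5, 500], "richness")
        assert list(c.depths) == [5]
        with pytest.raises(ValueError, match="no usable"):
            rarefaction_curve(toy_table, "A_r1", [500], "richness")

    def test_shannon_curve_deterministic(self, toy_table):
        spec = SubsampleSpec(iterations=10, seed=42)
        c1 = rarefaction_curve(toy_table, "B_r1", [4, 8], "shannon", spec)
        c2 = rarefaction_curve(toy_table, "B_r1", [4, 8], "shannon", spec)
        assert (c1.mean == c2.mean).all() and (c1.se == c2.se).all()

    def test_richness_curve_matches_monte_carlo(self, tiny_study):
        table = tiny_study.table
        d = table.dataset_ids[0]
        counts = table.column(d)
        c = rarefaction_curve(table, d, [100, 300], "richness")
        rng = np.random.default_rng(5)
        for depth, mean in zip(c.depths, c.mean):
            draws = rng.multivariate_hypergeometric(counts, depth, size=4000)
            rich = (draws > 0).sum(axis=1)
            se = rich.std(ddof=1) / math.sqrt(4000)
            assert mean == pytest.approx(rich.mean(), abs=3 * se)


class TestMeanCurveAndSlope:
    def _curve(self, depths, values, dataset="d", sample="s"):
        return RarefactionCurve(dataset, sample, depths, values, [0] * len(depths))

    def test_identical_curves_zero_se(self):
        c = self._curve([10, 20], [3, 5])
        m = mean_curve_across_replicates([c, c])
        assert list(m.mean) == [3, 5]
        assert list(m.se) == [0, 0]
        assert m.se_kind == "across_replicates"

    def test_two_value_sem(self):
        m = mean_curve_across_replicates(
            [self._curve([10], [1]), self._curve([10], [3])]
        )
        assert m.mean[0] == pytest.approx(2.0)
        assert m.se[0] == pytest.approx(1.0)  # SEM of {1, 3}

    def test_per_depth_vs_global_mode(self):
        short = self._curve([10], [1])
        long = self._curve([10, 20], [1, 4])
        per = mean_curve_across_replicates([short, long], mode="per_depth")
        assert list(per.depths) == [10, 20]
        glob = mean_curve_across_replicates([short, long], mode="global")
        assert list(glob.depths) == [10]

    def test_slope(self):
        linear = self._curve([0, 1000, 2000], [0, 5, 10])
        assert rarefaction_slope(linear, 1500) == pytest.approx(0.005)
        flat = self._curve([0, 1000], [7, 7])
        assert rarefaction_slope(flat, 500) == 0.0
        with pytest.raises(ValueError, match="outside"):
            rarefaction_slope(linear, 9999)


def test_relative_gain():
    assert relative_gain(180, 100) == pytest.approx(1.8)
    assert relative_gain(7.5, 7.5) == 1.0
    with pytest.raises(ValueError):
        relative_gain(1.0, 0.0)
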