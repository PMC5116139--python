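"""Cytosine-report parsing, 5mC/5hmC estimation, coverage filtering,
aggregation and group comparison."""

import numpy as np
import pytest
from scipy import stats

from retroepi.genome_annotation import GenomicInterval
from retroepi import methylome as me
from retroepi import synthetic_data as sd
import pandas as pd


def _counts(chem, n, k, chrom="chr1", pos=100):
    return me.CpGSiteCounts(chrom, pos, chem, n, k)


class TestCytosineReport:
    def test_format_semantics(self, tmp_path):
        p = tmp_path / "rep.txt"
        p.write_text("chr1\t6\t+\t7\t3\tCG\tCGA\n")
        (site,) = me.parse_cytosine_report(p, "BS", merge_strands=False)
        assert site.pos == 5 and site.n_reads == 10 and site.n_unconverted == 7

    def test_dyad_merge_sums_counts(self, tmp_path):
        p = tmp_path / "rep.txt"
        p.write_text("chr1\t6\t+\t7\t3\tCG\tCGA\nchr1\t7\t-\t5\t5\tCG\tCGT\n")
        (site,) = me.parse_cytosine_report(p, "BS", merge_strands=True)
        assert site.pos == 5 and site.n_reads == 20 and site.n_unconverted == 12

    def test_non_cg_lines_excluded(self, tmp_path):
        p = tmp_path / "rep.txt"
        p.write_text(
            "chr1\t6\t+\t7\t3\tCG\tCGA\n"
            "chr1\t9\t+\t1\t9\tCHH\tCTA\n"
            "chr1\t12\t+\t2\t8\tCHG\tCAG\n"
        )
        sites = me.parse_cytosine_report(p, "BS")
        assert len(sites) == 1

    def test_bad_context_and_negative_counts_error_with_line(self, tmp_path):
        p = tmp_path / "rep.txt"
        p.write_text("chr1\t6\t+\t7\t3\tZZ\tCGA\n")
        with pytest.raises(ValueError, match=":1:"):
            me.parse_cytosine_report(p, "BS")
        p.write_text("chr1\t6\t+\t7\t3\tCG\tCGA\nchr1\t9\t+\t-1\t3\tCG\tCGA\n")
        with pytest.raises(ValueError, match=":2:"):
            me.parse_cytosine_report(p, "BS")

    def test_report_roundtrip(self, tmp_path):
        sites = [
            me.CpGSiteCounts("chr1", 5, "oxBS", 100, 60),
            me.CpGSiteCounts("chr1", 40, "oxBS", 80, 10),
        ]
        p = tmp_path / "rt.txt"
        me.write_cytosine_report(sites, p)
        back = me.parse_cytosine_report(p, "oxBS", merge_strands=False)
        assert [(s.pos, s.n_reads, s.n_unconverted) for s in back] == [
            (5, 100, 60),
            (40, 80, 10),
        ]


class TestEstimators:
    def test_subtraction_definition(self):
        est = me.estimate_from_bs_oxbs(_counts("BS", 100, 80), _counts("oxBS", 100, 60))
        assert est.level_5mC == pytest.approx(0.60)
        assert est.level_5hmC == pytest.approx(0.20)
        assert est.level_modified == pytest.approx(0.80)

    def test_negative_subtraction_clamped_with_diagnostic(self):
        est = me.estimate_from_bs_oxbs(_counts("BS", 100, 20), _counts("oxBS", 100, 25))
        assert est.level_5hmC == 0.0
        assert est.level_5mC == pytest.approx(0.25)
        assert est.level_5hmC_raw == pytest.approx(-0.05)

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            me.estimate_from_bs_oxbs(_counts("BS", 0, 0), _counts("oxBS", 100, 10))
        with pytest.raises(ValueError):
            me.estimate_from_tab(_counts("TAB", 0, 0))

    def test_tab_direct_and_paired(self):
        assert me.estimate_from_tab(_counts("TAB", 100, 20)).level_5hmC == 0.20
        assert me.estimate_from_tab(_counts("TAB", 100, 0)).level_5hmC == 0.0
        est = me.estimate_from_tab(_counts("TAB", 100, 20), bs=_counts("BS", 100, 80))
        assert est.level_5mC == pytest.approx(0.60)

    def test_site_mismatch_rejected(self):
        with pytest.raises(ValueError):
            me.estimate_from_bs_oxbs(
                _counts("BS", 100, 80, pos=100), _counts("oxBS", 100, 60, pos=200)
            )

    def test_high_depth_estimates_near_truth(self):
        truth = pd.DataFrame(
            {"chrom": ["amp"], "pos": [10], "p_c": [0.2], "p_5mc": [0.6], "p_5hmc": [0.2]}
        )
        counts = sd.simulate_bisulfite_counts(
            truth, sd.ChemistrySpec.ideal(), mean_depth=10_000, seed=1
        )
        est = me.estimate_from_bs_oxbs(counts["BS"][0], counts["oxBS"][0])
        assert abs(est.level_5mC - 0.6) < 0.02 and abs(est.level_5hmC - 0.2) < 0.02

    def test_invariant_levels_ordered(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n1, n2 = rng.integers(1, 200, size=2)
            est = me.estimate_from_bs_oxbs(
                _counts("BS", int(n1), int(rng.integers(0, n1 + 1))),
                _counts("oxBS", int(n2), int(rng.integers(0, n2 + 1))),
                ci=False,
            )
            assert 0 <= est.level_5hmC <= 1 and 0 <= est.level_5mC <= 1
            assert est.level_5mC + est.level_5hmC <= max(est.level_modified, est.level_5mC) + 1e-9


class TestCoverageFilter:
    def test_joint_filter_drops_shallow_chemistry(self):
        d = {
            "BS": [_counts("BS", 99, 50)],
            "oxBS": [_counts("oxBS", 150, 50)],
        }
        out = me.filter_min_coverage(d, min_reads=100)
        assert out["BS"] == [] and out["oxBS"] == []

    def test_boundary_is_inclusive(self):
        d = {"BS": [_counts("BS", 100, 50)], "oxBS": [_counts("oxBS", 100, 50)]}
        out = me.filter_min_coverage(d, min_reads=100)
        assert len(out["BS"]) == 1 and len(out["oxBS"]) == 1

    def test_per_chemistry_mode(self):
        d = {"BS": [_counts("BS", 99, 50)], "oxBS": [_counts("oxBS", 150, 50)]}
        out = me.filter_min_coverage(d, min_reads=100, joint=False)
        assert out["BS"] == [] and len(out["oxBS"]) == 1

    def test_idempotent_and_never_grows(self):
        rng = np.random.default_rng(2)
        sites = {
            chem: [
                me.CpGSiteCounts("amp", int(p), chem, int(n), int(rng.integers(0, n + 1)))
                for p, n in zip(range(50), rng.poisson(120, size=50) + 1)
            ]
            for chem in ("BS", "oxBS")
        }
        once = me.filter_min_coverage(sites, 100)
        twice = me.filter_min_coverage(once, 100)
        assert once == twice
        assert all(len(once[c]) <= len(sites[c]) for c in sites)


class TestReplicateAverage:
    def _est(self, pos, mc, hmc):
        return me.ModEstimate("amp", pos, mc, hmc, mc + hmc, 100)

    def test_mean_of_three(self):
        reps = [[self._est(5, v, v / 2)] for v in (0.1, 0.2, 0.3)]
        out = me.replicate_average(reps)
        assert out.loc[0, "level_5mC"] == pytest.approx(0.2)
        assert out.loc[0, "n_replicates"] == 3

    def test_single_replicate_identity(self):
        out = me.replicate_average([[self._est(5, 0.4, 0.1)]])
        assert out.loc[0, "level_5mC"] == pytest.approx(0.4)

    def test_missing_replicate_averaged_over_present(self):
        reps = [
            [self._est(5, 0.1, 0.0), self._est(9, 0.5, 0.0)],
            [self._est(5, 0.3, 0.0)],
        ]
        out = me.replicate_average(reps).set_index("pos")
        assert out.loc[5, "level_5mC"] == pytest.approx(0.2)
        assert out.loc[9, "n_replicates"] == 1


class TestRegionAggregation:
    def _est(self, pos, mc, hmc, depth):
        return me.ModEstimate("chr1", pos, mc, hmc, mc + hmc, depth)

    def test_coverage_weighted_mean(self):
        ests = [self._est(10, 0.5, 0.0, 100), self._est(20, 0.7, 0.0, 300)]
        out = me.aggregate_by_region(ests, [GenomicInterval("chr1", 0, 100)])
        assert out.loc[0, "level_5mC"] == pytest.approx(0.65)
        assert out.loc[0, "n_cpgs"] == 2

    def test_region_without_cpgs_missing(self):
        out = me.aggregate_by_region([], [GenomicInterval("chr1", 0, 100)])
        assert np.isnan(out.loc[0, "level_5mC"]) and out.loc[0, "n_cpgs"] == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        ests = [
            self._est(int(p), float(m), float(h), int(d))
            for p, m, h, d in zip(
                rng.integers(0, 10_000, 200),
                rng.random(200) * 0.8,
                rng.random(200) * 0.2,
                rng.integers(1, 500, 200),
            )
        ]
        regions = []
        for _ in range(30):
            s = int(rng.integers(0, 9500))
            regions.append(GenomicInterval("chr1", s, s + int(rng.integers(50, 500))))
        out = me.aggregate_by_region(ests, regions)
        for i, r in enumerate(regions):
            inside = [e for e in ests if r.start <= e.pos < r.end]
            if not inside:
                assert np.isnan(out.loc[i, "level_5mC"])
                continue
            w = np.array([e.n_reads_min for e in inside], dtype=float)
            expect = np.average([e.level_5mC for e in inside], weights=w)
            assert out.loc[i, "level_5mC"] == pytest.approx(expect)


class TestCompareGroups:
    def test_exact_ranksum_three_vs_three(self):
        stat, p = me.compare_groups([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)  # 2 of the 20 assignments as extreme

    def test_identical_groups_p_one(self):
        _, p = me.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            me.compare_groups([], [1.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_matches_scipy_on_tie_free_instances(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        pooled = rng.permutation(np.arange(1, na + nb + 1)).astype(float)
        a, b = pooled[:na], pooled[na:]
        stat, p = me.compare_groups(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue)
        assert stat == pytest.approx(ref.statistic)

    def test_large_sample_power_matches_normal_approximation(self):
        # shift of 1 SD at n=100/group: power of the rank-sum ~ Phi(z) with
        # z = sqrt(3/pi) * delta * sqrt(n/2) - z_{alpha/2}
        rng = np.random.default_rng(12)
        n, delta, alpha, n_sims = 100, 1.0, 0.05, 300
        rejections = 0
        for _ in range(n_sims):
            a = rng.normal(0, 1, n)
            b = rng.normal(delta, 1, n)
            _, p = me.compare_groups(a, b)
            rejections += p < alpha
        # with this effect size the approximation gives power ~ 1.0
        p_hat = stats.norm.cdf(
            np.sqrt(3 / np.pi) * delta * np.sqrt(n / 2) - stats.norm.ppf(1 - alpha / 2)
        )
        se = np.sqrt(max(p_hat * (1 - p_hat), 1e-4) / n_sims)
        assert abs(rejections / n_sims - p_hat) < 4 * se + 0.02

    def test_welch_t_mode(self):
        stat, p = me.compare_groups([1, 2, 3], [4, 5, 6], test="t")
        ref = stats.ttest_ind([1, 2, 3], [4, 5, 6], equal_var=False)
        assert stat == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)
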