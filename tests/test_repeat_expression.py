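"""Repeat-class pooling, median-of-ratios size factors, and TE-to-gene links."""

import numpy as np
import pandas as pd
import pytest

from retroepi.genome_annotation import GenomicInterval, TECopy
from retroepi.read_assignment import AssignedRead
from retroepi import repeat_expression as rx


def _copy(chrom, start, end, name="L1Md_T", cls="LINE"):
    return TECopy(GenomicInterval(chrom, start, end), name, name, cls, 1.0, False)


def _read(i, chrom, start, end):
    return AssignedRead(f"r{i}", GenomicInterval(chrom, start, end), "inclusive")


class TestPooling:
    def test_reads_inside_single_class(self):
        copies = [_copy("chr1", 100, 700)]
        reads = [_read(i, "chr1", 150 + i, 200 + i) for i in range(10)]
        counts = rx.pool_repeat_counts(reads, copies)
        assert counts["LINE"] == 10 and counts[rx.UNASSIGNED] == 0

    def test_read_outside_annotation_unassigned(self):
        counts = rx.pool_repeat_counts(
            [_read(0, "chr1", 5000, 5050)], [_copy("chr1", 100, 700)]
        )
        assert counts[rx.UNASSIGNED] == 1 and counts["LINE"] == 0

    def test_fractional_weighting_across_classes(self):
        copies = [
            _copy("chr1", 100, 200, cls="LINE"),
            _copy("chr1", 180, 300, name="RLTR13", cls="LTR"),
        ]
        counts = rx.pool_repeat_counts([_read(0, "chr1", 150, 250)], copies)
        assert counts["LINE"] == pytest.approx(0.5)
        assert counts["LTR"] == pytest.approx(0.5)

    def test_drop_mode_sends_ambiguous_to_unassigned(self):
        copies = [
            _copy("chr1", 100, 200, cls="LINE"),
            _copy("chr1", 180, 300, name="RLTR13", cls="LTR"),
        ]
        counts = rx.pool_repeat_counts(
            [_read(0, "chr1", 150, 250)], copies, ambiguous="drop"
        )
        assert counts[rx.UNASSIGNED] == 1

    @pytest.mark.parametrize("seed", range(4))
    def test_conservation_and_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        classes = ["LINE", "LTR", "SINE"]
        copies = []
        for i in range(40):
            s = int(rng.integers(0, 19_000))
            copies.append(
                _copy("chr1", s, s + int(rng.integers(100, 900)),
                      name=f"n{i}", cls=classes[int(rng.integers(3))])
            )
        reads = []
        for i in range(300):
            s = int(rng.integers(0, 19_900))
            reads.append(_read(i, "chr1", s, s + 50))
        counts = rx.pool_repeat_counts(reads, copies)
        assert counts.sum() == pytest.approx(len(reads))
        brute = {c: 0.0 for c in classes + [rx.UNASSIGNED]}
        for r in reads:
            hit = sorted(
                {c.te_class for c in copies if r.chosen.overlaps(c.interval)}
            )
            if not hit:
                brute[rx.UNASSIGNED] += 1
            else:
                for cls in hit:
                    brute[cls] += 1 / len(hit)
        for cls in brute:
            assert counts[cls] == pytest.approx(brute[cls])


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        t = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(rx.size_factors(t), 1.0)

    def test_doubling_scales_factor(self):
        t = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        f = rx.size_factors(t)
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_scale_equivariance_of_factor_ratios(self):
        # scaling one column by c scales its factor by c relative to the
        # others (absolute factors shift together via the geometric means)
        rng = np.random.default_rng(1)
        t = pd.DataFrame(rng.integers(1, 1000, size=(30, 3)), columns=list("abc"))
        f0 = rx.size_factors(t)
        t2 = t.copy()
        t2["b"] = t2["b"] * 7
        f1 = rx.size_factors(t2)
        assert (f1["b"] / f1["a"]) / (f0["b"] / f0["a"]) == pytest.approx(7.0)
        assert (f1["c"] / f1["a"]) == pytest.approx(f0["c"] / f0["a"])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_median_of_ratios(self, seed):
        rng = np.random.default_rng(seed)
        t = pd.DataFrame(rng.integers(0, 500, size=(50, 4)), columns=list("abcd"))
        t.iloc[0] = [10, 20, 30, 40]  # ensure one all-positive row
        f = rx.size_factors(t)
        arr = t.to_numpy(dtype=float)
        keep = arr[(arr > 0).all(axis=1)]
        geo = np.exp(np.log(keep).mean(axis=1))
        for j, col in enumerate(t.columns):
            assert f[col] == pytest.approx(float(np.median(keep[:, j] / geo)))

    def test_no_all_positive_row_errors(self):
        t = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudo-counts"):
            rx.size_factors(t)


class TestLinking:
    def _interactions(self, pairs):
        baits, genes, oes = [], [], []
        for gene, oe in pairs:
            baits.append(GenomicInterval("chr1", 0, 1000))
            genes.append(gene)
            oes.append(oe)
        return rx.interactions_from_bed_pair(baits, genes, oes)

    def test_copy_inside_other_end_links_gene(self):
        inter = self._interactions([("g1", GenomicInterval("chr1", 5000, 6000))])
        links = rx.link_tes_to_genes(inter, [_copy("chr1", 5200, 5400)])
        assert links[0] == {"g1"}

    def test_copy_without_other_end_empty(self):
        inter = self._interactions([("g1", GenomicInterval("chr1", 5000, 6000))])
        links = rx.link_tes_to_genes(inter, [_copy("chr1", 9000, 9400)])
        assert links[0] == set()

    def test_monotone_in_interactions(self):
        copies = [_copy("chr1", 5200, 5400)]
        small = self._interactions([("g1", GenomicInterval("chr1", 5000, 6000))])
        big = self._interactions(
            [
                ("g1", GenomicInterval("chr1", 5000, 6000)),
                ("g2", GenomicInterval("chr1", 5300, 5600)),
            ]
        )
        assert rx.link_tes_to_genes(small, copies)[0] <= rx.link_tes_to_genes(big, copies)[0]

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_all_pairs_join(self, seed):
        rng = np.random.default_rng(seed)
        copies = []
        for i in range(30):
            s = int(rng.integers(0, 50_000))
            copies.append(_copy("chr1", s, s + int(rng.integers(100, 2000)), name=f"c{i}"))
        pairs = []
        for g in range(40):
            s = int(rng.integers(0, 50_000))
            pairs.append((f"g{g}", GenomicInterval("chr1", s, s + int(rng.integers(200, 3000)))))
        links = rx.link_tes_to_genes(self._interactions(pairs), copies)
        for i, c in enumerate(copies):
            expect = {g for g, oe in pairs if c.interval.overlaps(oe)}
            assert links[i] == expect


class TestGroupedCompare:
    def test_identical_groups_p_one_exact(self):
        t2 = pd.DataFrame(
            {"s1": [5.0, 6.0, 7.0, 5.0, 6.0, 7.0]},
            index=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        out = rx.grouped_expression_compare(
            t2, {"a1", "a2", "a3"}, {"b1", "b2", "b3"}, test="wilcoxon_ranksum"
        )
        assert out["p"] == pytest.approx(1.0)

    def test_welch_t_matches_hand_formula(self):
        a, b = np.array([1.0, 2.0, 4.0]), np.array([2.0, 5.0, 9.0])
        t = pd.DataFrame({"s1": np.concatenate([a, b])},
                         index=[f"g{i}" for i in range(6)])
        out = rx.grouped_expression_compare(
            t, {"g0", "g1", "g2"}, {"g3", "g4", "g5"}, test="t"
        )
        se = np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        assert out["statistic"] == pytest.approx((a.mean() - b.mean()) / se)

    def test_planted_twofold_shift_detected(self):
        rng = np.random.default_rng(21)
        detections = 0
        for _ in range(100):
            base = rng.lognormal(mean=np.log(100), sigma=0.3, size=200)
            expr = base.copy()
            expr[:100] *= 2.0  # NOS+-linked genes
            t = pd.DataFrame({"s1": expr}, index=[f"g{i}" for i in range(200)])
            out = rx.grouped_expression_compare(
                t, {f"g{i}" for i in range(100)}, {f"g{i}" for i in range(100, 200)},
                test="t",
            )
            detections += out["p"] < 0.05 and out["mean_pos"] > out["mean_neg"]
        assert detections >= 90

    def test_empty_group_after_linking_rejected(self):
        t = pd.DataFrame({"s1": [1.0]}, index=["g1"])
        with pytest.raises(ValueError):
            rx.grouped_expression_compare(t, {"g1"}, {"gX"})


class TestInteractionIO:
    def test_tsv_roundtrip(self, tmp_path):
        inter = rx.interactions_from_bed_pair(
            [GenomicInterval("chr1", 0, 1000)],
            ["g1"],
            [GenomicInterval("chr1", 5000, 6000)],
            scores=[3.5],
        )
        p = tmp_path / "pairs.tsv"
        rx.write_interactions(inter, p)
        back = rx.read_interactions(p)
        assert len(back) == 1
        row = back.pairs.iloc[0]
        assert row["gene_id"] == "g1" and row["oe_start"] == 5000
        assert row["score"] == pytest.approx(3.5)

    def test_empty_gene_id_rejected(self):
        with pytest.raises(ValueError):
            rx.interactions_from_bed_pair(
                [GenomicInterval("chr1", 0, 10)], [""], [GenomicInterval("chr1", 20, 30)]
            )
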