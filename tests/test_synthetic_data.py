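"""The synthetic-data generator: determinism, planted truth, and the
conversion-chemistry matrix."""

import numpy as np
import pytest

from retroepi.genome_annotation import reverse_complement
from retroepi import read_assignment as ra
from retroepi import synthetic_data as sd
from retroepi import te_enrichment as te


class TestGenome:
    def test_same_seed_identical_output(self):
        cfg = sd.SimulationConfig(seed=42, genome_length=200_000, te_families=(
            sd.TEFamilySpec("L1Md_T", "LINE", 6000, 5, 2.0, truncation_prob=0.5),
            sd.TEFamilySpec("B1_Mus", "SINE", 150, 30, 8.0),
        ))
        a, b = sd.simulate_genome(cfg), sd.simulate_genome(cfg)
        assert a.genome == b.genome
        assert a.truth.equals(b.truth)

    def test_zero_divergence_zero_truncation_exact_consensus(self):
        cfg = sd.SimulationConfig(
            seed=3, genome_length=100_000,
            te_families=(sd.TEFamilySpec("fam", "LINE", 800, 10, 0.0),),
        )
        sim = sd.simulate_genome(cfg)
        cons = sim.consensus["fam"]
        for c in sim.copies:
            seq = sim.genome["chr1"][c.interval.start : c.interval.end]
            if c.interval.strand == "-":
                seq = reverse_complement(seq)
            assert seq == cons

    def test_realized_divergence_matches_configured(self):
        cfg = sd.SimulationConfig(
            seed=5, genome_length=1_200_000,
            te_families=(sd.TEFamilySpec("fam", "LINE", 3000, 60, 8.0),),
        )
        sim = sd.simulate_genome(cfg)
        cons = sim.consensus["fam"]
        divs = []
        for c, row in zip(sim.copies, sim.truth.itertuples()):
            seq = sim.genome["chr1"][c.interval.start : c.interval.end]
            if c.interval.strand == "-":
                seq = reverse_complement(seq)
            ref = cons[row.truncation_offset :]
            divs.append(np.mean([x != y for x, y in zip(seq, ref)]) * 100)
        assert abs(np.mean(divs) - 8.0) < 1.0

    def test_truncation_produces_length_dichotomy(self, sim):
        l1 = sim.truth[sim.truth.family == "L1Md_T"]
        lengths = l1.end - l1.start
        assert (lengths > 5000).any() and (lengths <= 5000).any()
        assert ((lengths > 5000) == l1.full_length).all()

    def test_excessive_te_content_rejected(self):
        cfg = sd.SimulationConfig(
            seed=1, genome_length=50_000,
            te_families=(sd.TEFamilySpec("fam", "LINE", 6000, 10, 0.0),),
        )
        with pytest.raises(ValueError, match="80%"):
            sd.simulate_genome(cfg)

    def test_copies_non_overlapping(self, sim):
        prev_end = -1
        for c in sim.copies:
            assert c.interval.start >= prev_end
            prev_end = c.interval.end


class TestChIP:
    def test_same_seed_identical(self, sim):
        a = sd.simulate_chip(sim, {"L1Md_T": 0.5}, seed=9)
        b = sd.simulate_chip(sim, {"L1Md_T": 0.5}, seed=9)
        assert a.peaks_inclusive == b.peaks_inclusive
        assert a.records == b.records

    def test_unique_peaks_subset_of_inclusive(self, chip):
        inclusive = {p.interval for p in chip.peaks_inclusive}
        assert all(p.interval in inclusive for p in chip.peaks_unique)

    def test_null_binding_gives_no_enrichment(self, sim, by_class):
        chip = sd.simulate_chip(sim, {}, n_background_peaks=1000, seed=13)
        res = te.enrichment_test(
            chip.peaks_inclusive, by_class, sim.chrom_sizes, n_reps=500, seed=14
        )
        for r in res:
            assert r.q_value > 0.05
            assert 0.6 < r.fold < 1.5

    def test_reads_from_identical_copies_multimap(self):
        cfg = sd.SimulationConfig(
            seed=8, genome_length=120_000, read_length=50,
            te_families=(sd.TEFamilySpec("fam", "LINE", 500, 10, 0.0),),
        )
        sim = sd.simulate_genome(cfg)
        chip = sd.simulate_chip(
            sim, {"fam": 1.0}, n_background_peaks=0, n_background_reads=200,
            five_prime_window=None, seed=10,
        )
        inside = {c.interval.start for c in sim.copies}
        copy_spans = [(c.interval.start, c.interval.end) for c in sim.copies]

        def in_copy(pos):
            return any(s <= pos and pos + 50 <= e for s, e in copy_spans)

        unique = ra.filter_unique(chip.records)
        kept_inside = [
            u for u in unique
            if in_copy(chip.read_truth.set_index("read_id").loc[u.read_id, "pos"])
        ]
        assert len(kept_inside) == 0  # 10 identical copies: nothing maps uniquely
        inclusive = ra.assign_inclusive(chip.records, seed=1)
        assert len(inclusive) == len(chip.records)


class TestChemistry:
    def test_ideal_matrix_values(self):
        ideal = sd.ChemistrySpec.ideal()
        assert sd.read_as_c_probability("BS", 0.2, 0.6, 0.2, ideal) == pytest.approx(0.8)
        assert sd.read_as_c_probability("oxBS", 0.2, 0.6, 0.2, ideal) == pytest.approx(0.6)
        assert sd.read_as_c_probability("TAB", 0.2, 0.6, 0.2, ideal) == pytest.approx(0.2)

    def test_unmodified_site_reads_at_conversion_failure_rate(self):
        spec = sd.ChemistrySpec(conversion=0.99, fail_bs=0, fail_oxbs=0, fail_tab=0)
        for chem in ("BS", "oxBS", "TAB"):
            assert sd.read_as_c_probability(chem, 1.0, 0.0, 0.0, spec) == pytest.approx(0.01)

    def test_probability_validity_for_legal_configs(self):
        rng = np.random.default_rng(0)
        spec = sd.ChemistrySpec()
        for _ in range(500):
            p = rng.dirichlet([1, 1, 1, 1])[:3]
            for chem in ("BS", "oxBS", "TAB"):
                v = sd.read_as_c_probability(chem, *p, spec)
                assert 0.0 <= v <= 1.0

    def test_invalid_state_probabilities_rejected(self):
        with pytest.raises(ValueError):
            sd.read_as_c_probability("BS", 0.5, 0.5, 0.5, sd.ChemistrySpec())


class TestBisulfiteSim:
    def test_determinism_and_truth_shape(self, sim):
        counts, truth = sd.simulate_bisulfite(sim, mean_depth=5, seed=2)
        counts2, _ = sd.simulate_bisulfite(sim, mean_depth=5, seed=2)
        assert counts["BS"] == counts2["BS"]
        assert set(counts) == {"BS", "oxBS", "TAB"}
        assert len(truth) == len(counts["BS"])

    def test_bound_copy_levels_override(self, sim):
        bound = {0, 1}
        truth = sd.methylome_truth(sim, bound_copy_indices=bound)
        c0 = sim.copies[0].interval
        inside = truth[(truth.pos >= c0.start) & (truth.pos < c0.end)]
        assert (inside.p_5mc == 0.25).all() and (inside.p_5hmc == 0.20).all()
        outside_all = truth[truth.pos < sim.copies[0].interval.start]
        if len(outside_all):
            assert (outside_all.p_5mc == 0.75).all()


class TestInteractionsAndCounts:
    def test_determinism_and_fold_truth(self, sim):
        pos = set(range(0, 10))
        neg = set(range(20, 30))
        a = sd.simulate_interactions_and_counts(sim, pos, neg, seed=4)
        b = sd.simulate_interactions_and_counts(sim, pos, neg, seed=4)
        assert a[1].equals(b[1])
        inter, counts, truth = a
        grouped = truth.groupby("group")["mu"].mean()
        assert grouped["nos_pos"] > 1.5 * grouped["nos_neg"]

    def test_null_fold_gives_alpha_level_rejections(self, sim):
        from retroepi import repeat_expression as rx

        rejections = 0
        n_trials = 40
        for s in range(n_trials):
            inter, counts, truth = sd.simulate_interactions_and_counts(
                sim, set(range(0, 30)), set(range(40, 70)), fold=1.0, seed=100 + s
            )
            norm = counts / rx.size_factors(counts + 1)
            gp = set(truth.index[truth.group == "nos_pos"])
            gn = set(truth.index[truth.group == "nos_neg"])
            out = rx.grouped_expression_compare(norm, gp, gn, test="t")
            rejections += out["p"] < 0.05
        assert rejections <= 8  # ~alpha * n_trials with slack


class TestFoldPlanting:
    def test_unreachable_fold_rejected(self, sim, by_class):
        ltr = [c.interval for c in by_class["LTR"]]
        with pytest.raises(ValueError, match="unreachable"):
            sd.simulate_peaks_with_fold(ltr, sim.chrom_sizes, 10, 300, 100.0, seed=0)

    def test_planted_overlap_rate(self, sim, by_class):
        from retroepi.genome_annotation import overlap_flags

        ltr = [c.interval for c in by_class["LTR"]]
        p0 = te.expected_overlap_probability(ltr, sim.chrom_sizes, 300)
        peaks = sd.simulate_peaks_with_fold(ltr, sim.chrom_sizes, 3000, 300, 2.0, seed=6)
        frac = overlap_flags([p.interval for p in peaks], ltr).mean()
        se = np.sqrt(2 * p0 * (1 - 2 * p0) / 3000)
        assert abs(frac - 2 * p0) < 4 * se
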