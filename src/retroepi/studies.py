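"""Canned end-to-end study scenarios on synthetic data.

Each function runs one self-contained experiment — calibration of the
enrichment test under its own null, recovery of planted enrichment folds,
family binding probabilities, methylation levels, mapping-policy behaviour
on a duplicated-block genome, consensus 5' geometry — and returns the
measured quantities together with the problem size.  They are the engine
behind the numbered analysis drivers and the acceptance checks, so every
reported number is recomputed from scratch from a seed.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import methylome as me
from . import read_assignment as ra
from . import synthetic_data as sd
from . import te_enrichment as te
from .genome_annotation import TECopy
from .meta_profiles import consensus_profile

__all__ = [
    "default_genome",
    "copies_by_class",
    "null_enrichment_calibration",
    "planted_fold_recovery",
    "family_binding_recovery",
    "chemistry_recovery",
    "clamping_sweep",
    "coverage_filter_equivalence",
    "mapping_policy_study",
    "consensus_geometry_study",
]


def default_genome(seed: int = 1) -> sd.SimulatedGenome:
    """The standard 2 Mb five-family synthetic genome."""
    return sd.simulate_genome(sd.SimulationConfig(seed=seed))


def copies_by_class(sim: sd.SimulatedGenome) -> dict[str, list[TECopy]]:
    out: dict[str, list[TECopy]] = {}
    for c in sim.copies:
        out.setdefault(c.te_class, []).append(c)
    return out


def null_enrichment_calibration(
    sim: sd.SimulatedGenome,
    n_trials: int = 500,
    n_peaks: int = 500,
    peak_length: int = 300,
    n_reps: int = 1000,
    alpha: float = 0.05,
    base_seed: int = 1,
) -> dict:
    """Type-I behaviour of the enrichment test under its own null.

    Each trial draws a peak set from the matched-random generator itself
    (so no class is enriched) and runs the full test; returns the fraction
    of (trial, class) empirical p-values at or below ``alpha``.
    """
    by_class = copies_by_class(sim)
    template = [
        te.Peak(te.GenomicInterval(sim.config.chrom_name, 0, peak_length))
        for _ in range(n_peaks)
    ]
    pvals = []
    for trial in range(n_trials):
        null_peaks = [
            te.Peak(iv)
            for iv in te.sample_matched_random(
                template, sim.chrom_sizes, seed=base_seed + trial
            )
        ]
        results = te.enrichment_test(
            null_peaks,
            by_class,
            sim.chrom_sizes,
            n_reps=n_reps,
            seed=100_000 + base_seed + trial,
        )
        pvals.extend(r.empirical_p for r in results)
    arr = np.asarray(pvals)
    return {
        "fraction_significant": float((arr <= alpha).mean()),
        "alpha": alpha,
        "n_pvalues": len(arr),
        "n_trials": n_trials,
        "pvals": arr,
    }


def planted_fold_recovery(
    sim: sd.SimulatedGenome,
    te_class: str = "LTR",
    fold: float = 3.0,
    n_peaks: int = 2000,
    n_reps: int = 1000,
    seed: int = 0,
) -> dict:
    """Plant peaks at an exact fold over the matched null on one TE class and
    re-estimate the fold with the enrichment test."""
    by_class = copies_by_class(sim)
    targets = [c.interval for c in by_class[te_class]]
    peaks = sd.simulate_peaks_with_fold(
        targets, sim.chrom_sizes, n_peaks, sim.config.peak_length, fold, seed=seed
    )
    results = te.enrichment_test(
        peaks, by_class, sim.chrom_sizes, n_reps=n_reps, seed=seed + 1_000_000
    )
    hit = next(r for r in results if r.te_class_or_name == te_class)
    return {
        "planted_fold": fold,
        "estimated_fold": hit.fold,
        "observed": hit.observed,
        "expected_mean": hit.expected_mean,
        "empirical_p": hit.empirical_p,
        "q_value": hit.q_value,
        "n_peaks": n_peaks,
    }


def family_binding_recovery(
    sim: sd.SimulatedGenome,
    binding: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Plant per-family binding probabilities on full-length L1 copies and
    recover them with the family-age overlap summary.

    No background peaks are planted, so the ambiguous overlap fraction of a
    family estimates its binding probability directly; the 95% CI column is
    the exact (Clopper-Pearson) binomial interval of the recovered count.
    """
    if binding is None:
        binding = {"L1Md_T": 0.8, "L1Md_A": 0.4, "L1Md_F2": 0.0}
    chip = sd.simulate_chip(
        sim, dict(binding), n_background_peaks=0, n_background_reads=0, seed=seed
    )
    age_order = sim.catalog.age_order["L1"]
    rows = te.family_age_summary(
        [c for c in sim.copies if c.family in age_order],
        chip.peaks_unique,
        chip.peaks_inclusive,
        age_order,
        full_length_only=True,
    )
    out = []
    for r in rows:
        planted = binding.get(r.family, 0.0)
        k = int(round(r.frac_ambiguous_peaks * r.n_copies)) if r.n_copies else 0
        if r.n_copies:
            ci = stats.binomtest(k, r.n_copies).proportion_ci(confidence_level=0.95)
            lo, hi = float(ci.low), float(ci.high)
        else:
            lo = hi = float("nan")
        out.append(
            {
                "family": r.family,
                "age_rank": r.age_rank,
                "planted": planted,
                "n_full_length": r.n_copies,
                "frac_unique": r.frac_unique_peaks,
                "frac_ambiguous": r.frac_ambiguous_peaks,
                "ci_low": lo,
                "ci_high": hi,
                "planted_in_ci": bool(lo <= planted <= hi) if r.n_copies else False,
            }
        )
    return pd.DataFrame(out)


def chemistry_recovery(
    truth_5mc: float = 0.6,
    truth_5hmc: float = 0.2,
    depth: float = 1000,
    n_sites: int = 200,
    tolerance: float = 0.03,
    seed: int = 0,
) -> dict:
    """Simulate BS/oxBS counts at replicate CpG sites with known truth under
    ideal chemistry and score the subtraction estimator per site."""
    truth = pd.DataFrame(
        {
            "chrom": "amp",
            "pos": np.arange(n_sites),
            "p_c": 1 - truth_5mc - truth_5hmc,
            "p_5mc": truth_5mc,
            "p_5hmc": truth_5hmc,
        }
    )
    counts = sd.simulate_bisulfite_counts(
        truth, sd.ChemistrySpec.ideal(), depth, seed=seed, chemistries=("BS", "oxBS")
    )
    ests = [
        me.estimate_from_bs_oxbs(b, o, ci=False)
        for b, o in zip(counts["BS"], counts["oxBS"])
    ]
    err_mc = np.array([e.level_5mC - truth_5mc for e in ests])
    err_hmc = np.array([e.level_5hmC - truth_5hmc for e in ests])
    return {
        "n_sites": n_sites,
        "depth": depth,
        "tolerance": tolerance,
        "frac_5mc_within": float((np.abs(err_mc) <= tolerance).mean()),
        "frac_5hmc_within": float((np.abs(err_hmc) <= tolerance).mean()),
        "mean_5mc": float(truth_5mc + err_mc.mean()),
        "mean_5hmc": float(truth_5hmc + err_hmc.mean()),
    }


def clamping_sweep(n_pairs: int = 1_000_000, seed: int = 0) -> dict:
    """Run the subtraction estimator over random BS/oxBS count pairs and
    check the clamping invariant 0 <= 5hmC <= 1 on every one."""
    rng = np.random.default_rng(seed)
    n_bs = rng.integers(1, 500, size=n_pairs)
    k_bs = rng.integers(0, n_bs + 1)
    n_ox = rng.integers(1, 500, size=n_pairs)
    k_ox = rng.integers(0, n_ox + 1)
    min_hmc, max_hmc = np.inf, -np.inf
    for i in range(n_pairs):
        est = me.estimate_from_bs_oxbs(
            me.CpGSiteCounts("c", 0, "BS", int(n_bs[i]), int(k_bs[i])),
            me.CpGSiteCounts("c", 0, "oxBS", int(n_ox[i]), int(k_ox[i])),
            ci=False,
        )
        if est.level_5hmC < min_hmc:
            min_hmc = est.level_5hmC
        if est.level_5hmC > max_hmc:
            max_hmc = est.level_5hmC
    return {"n_pairs": n_pairs, "min_5hmc": float(min_hmc), "max_5hmc": float(max_hmc)}


def coverage_filter_equivalence(
    n_seeds: int = 100,
    n_sites: int = 60,
    mean_depth: float = 120,
    threshold: int = 100,
    base_seed: int = 0,
) -> dict:
    """Compare the joint coverage filter with a brute-force recount on
    Poisson-depth amplicons across many seeds; returns agreement count."""
    agree = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(base_seed + s)
        sites = {
            chem: [
                me.CpGSiteCounts("amp", p, chem, int(n), int(rng.integers(0, n + 1)))
                for p, n in enumerate(rng.poisson(mean_depth, size=n_sites) + 1)
            ]
            for chem in ("BS", "oxBS")
        }
        kept = me.filter_min_coverage(sites, threshold)
        kept_pos = {s_.pos for s_ in kept["BS"]}
        brute = {
            p
            for p in range(n_sites)
            if all(
                any(x.pos == p and x.n_reads >= threshold for x in sites[c])
                for c in sites
            )
        }
        agree += kept_pos == brute and {s_.pos for s_ in kept["oxBS"]} == brute
    return {"n_seeds": n_seeds, "n_agree": agree}


def mapping_policy_study(
    flank: int = 2000,
    block: int = 1000,
    read_length: int = 50,
    n_flank_reads: int = 2000,
    n_tied_reads: int = 10_000,
    seed: int = 0,
) -> dict:
    """Unique/inclusive behaviour on the duplicated-block genome.

    Reads from inside the duplicated blocks are perfectly tied two-hit
    reads: the unique filter must drop them all, the inclusive policy must
    split them evenly (chi-square uniformity); reads from the unique flanks
    must survive the unique filter essentially completely.
    """
    genome, regions = sd.duplicated_block_genome(flank, block, seed=seed)
    rng = np.random.default_rng(seed + 1)

    flank_origins = []
    for name in ("flank1", "flank2", "flank3"):
        s, e = regions[name]
        starts = rng.integers(s, e - read_length, size=n_flank_reads // 3)
        flank_origins.extend(("chrD", int(x)) for x in starts)
    b1s, b1e = regions["block1"]
    block_origins = [
        ("chrD", int(x))
        for x in rng.integers(b1s, b1e - read_length + 1, size=n_tied_reads)
    ]

    records = sd.reads_with_hits(genome, flank_origins + block_origins, read_length)
    n_flank = len(flank_origins)
    flank_ids = {r.read_id for r in records[:n_flank]}
    unique = ra.filter_unique(records)
    unique_from_flanks = sum(1 for u in unique if u.read_id in flank_ids)
    unique_from_blocks = len(unique) - unique_from_flanks

    block_records = records[n_flank:]
    assigned = ra.assign_inclusive(block_records, seed=seed + 2)
    in_block1 = sum(1 for a in assigned if a.chosen.start < b1e)
    chi_p = float(stats.chisquare([in_block1, len(assigned) - in_block1]).pvalue)
    return {
        "n_flank_reads": n_flank,
        "n_tied_reads": len(block_records),
        "unique_from_blocks": unique_from_blocks,
        "flank_retention": unique_from_flanks / n_flank,
        "inclusive_retention": len(assigned) / len(block_records),
        "block1_assignments": in_block1,
        "chi2_uniformity_p": chi_p,
    }


def consensus_geometry_study(
    consensus_length: int = 6000,
    five_prime_window: int = 900,
    fold: float = 4.0,
    n_reads: int = 30_000,
    binsize: int = 100,
    seed: int = 0,
) -> dict:
    """Plant a 4x read-density excess in the 5' window of a consensus element
    and measure the recovered 5'/3' coverage ratio."""
    reads = sd.simulate_consensus_reads(
        consensus_length, n_reads, five_prime_window, fold, seed=seed
    )
    prof = consensus_profile(reads, consensus_length, binsize=binsize)
    n5 = five_prime_window // binsize
    read_len = 50
    last_full = (consensus_length - read_len) // binsize
    five = prof.ip_coverage[:n5].mean()
    three = prof.ip_coverage[n5:last_full].mean()
    return {
        "planted_fold": fold,
        "ratio_5p_3p": float(five / three),
        "n_reads": n_reads,
    }
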