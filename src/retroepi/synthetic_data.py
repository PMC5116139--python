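"""Synthetic inputs for the whole pipeline, with planted ground truth.

The generator emulates the structure of the real inputs — a genome with
transposable-element copies of several families and ages, ChIP peaks and
multi-hit reads concentrated at bound elements, bisulfite cytosine reports
under the three conversion chemistries, and promoter-interaction/count
tables — at desk scale (a ~2 Mb genome) so every downstream analysis can be
exercised and scored against the planted truth without any downloads.

Everything is a pure function of (config, seed): the same seed gives
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_annotation import (
    DEFAULT_FULL_LENGTH_BP,
    GenomicInterval,
    TECopy,
    TEClassCatalog,
)
from .read_assignment import AlignmentRecord
from .te_enrichment import Peak, PlacementSpace
from .repeat_expression import InteractionSet, interactions_from_bed_pair

__all__ = [
    "TEFamilySpec",
    "ChemistrySpec",
    "SimulationConfig",
    "SimulatedGenome",
    "ChIPSim",
    "simulate_genome",
    "simulate_chip",
    "read_as_c_probability",
    "simulate_bisulfite",
    "simulate_bisulfite_counts",
    "methylome_truth",
    "simulate_interactions_and_counts",
    "simulate_peaks_with_fold",
    "simulate_consensus_reads",
    "reads_with_hits",
    "duplicated_block_genome",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class TEFamilySpec:
    """One synthetic TE family: consensus length, copy number, divergence
    (mean % substitution from consensus, the age proxy) and the probability
    that a copy is 5'-truncated (truncation offsets are geometric with the
    given mean, mimicking the 5'-truncated LINE-1 insertion spectrum)."""

    name: str
    te_class: str
    consensus_length: int
    copy_number: int
    divergence: float  # percent
    truncation_prob: float = 0.0
    truncation_mean: int = 2000

    def __post_init__(self) -> None:
        if not (0 <= self.truncation_prob <= 1):
            raise ValueError("truncation_prob must be in [0, 1]")
        if self.copy_number < 0 or self.consensus_length < 1:
            raise ValueError("copy_number >= 0 and consensus_length >= 1 required")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")


@dataclass(frozen=True)
class ChemistrySpec:
    """Conversion-chemistry error model.

    ``conversion`` is the probability that a convertible (unprotected)
    cytosine is actually read as T; each ``fail_*`` is the probability that
    a base the chemistry should protect is nonetheless converted.  The
    probability of reading C at a site with true state probabilities
    (p_C, p_5mC, p_5hmC) is::

        BS   : (p_5mC + p_5hmC) * (1 - fail_bs)  + p_C * (1 - conversion)
        oxBS :  p_5mC * (1 - fail_oxbs) + (p_C + p_5hmC) * (1 - conversion)
        TAB  :  p_5hmC * (1 - fail_tab) + (p_C + p_5mC) * (1 - conversion)
    """

    conversion: float = 0.995
    fail_bs: float = 0.005
    fail_oxbs: float = 0.03
    fail_tab: float = 0.05

    def __post_init__(self) -> None:
        for v in (self.conversion, self.fail_bs, self.fail_oxbs, self.fail_tab):
            if not (0 <= v <= 1):
                raise ValueError("chemistry probabilities must be in [0, 1]")

    @classmethod
    def ideal(cls) -> "ChemistrySpec":
        return cls(conversion=1.0, fail_bs=0.0, fail_oxbs=0.0, fail_tab=0.0)


def read_as_c_probability(
    chemistry: str, p_c: float, p_5mc: float, p_5hmc: float, spec: ChemistrySpec
) -> float:
    """Probability a read reports C at a site under one chemistry."""
    if min(p_c, p_5mc, p_5hmc) < 0 or p_c + p_5mc + p_5hmc > 1 + 1e-9:
        raise ValueError("state probabilities must be >= 0 and sum to <= 1")
    miss = 1 - spec.conversion
    if chemistry == "BS":
        return (p_5mc + p_5hmc) * (1 - spec.fail_bs) + p_c * miss
    if chemistry == "oxBS":
        return p_5mc * (1 - spec.fail_oxbs) + (p_c + p_5hmc) * miss
    if chemistry == "TAB":
        return p_5hmc * (1 - spec.fail_tab) + (p_c + p_5mc) * miss
    raise ValueError(f"unknown chemistry {chemistry!r}")


_DEFAULT_FAMILIES = (
    # youngest -> oldest L1 families (divergence = age proxy), an
    # enhancer-like LTR family and a SINE to exercise multi-class logic
    TEFamilySpec("L1Md_T", "LINE", 6500, 60, 1.5, truncation_prob=0.5),
    TEFamilySpec("L1Md_A", "LINE", 6500, 60, 3.0, truncation_prob=0.5),
    TEFamilySpec("L1Md_F2", "LINE", 6500, 50, 10.0, truncation_prob=0.7),
    TEFamilySpec("RLTR13D6", "LTR", 600, 100, 5.0),
    TEFamilySpec("B1_Mus", "SINE", 150, 200, 8.0),
)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    genome_length: int = 2_000_000
    chrom_name: str = "chr1"
    te_families: tuple[TEFamilySpec, ...] = _DEFAULT_FAMILIES
    chemistry: ChemistrySpec = field(default_factory=ChemistrySpec)
    read_length: int = 50
    peak_length: int = 300
    full_length_threshold: int = DEFAULT_FULL_LENGTH_BP

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["te_families"] = tuple(TEFamilySpec(**f) for f in d.get("te_families", []))
        if "chemistry" in d:
            d["chemistry"] = ChemistrySpec(**d["chemistry"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

@dataclass
class SimulatedGenome:
    config: SimulationConfig
    genome: dict[str, str]
    copies: list[TECopy]
    consensus: dict[str, str]
    truth: pd.DataFrame  # chrom,start,end,strand,repeat_name,family,class,divergence,offset,full_length
    catalog: TEClassCatalog

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def simulate_genome(config: SimulationConfig, seed: int | None = None) -> SimulatedGenome:
    """Background i.i.d. sequence with TE copies inserted at uniform random
    non-overlapping positions.

    Each copy is its family consensus, 5'-truncated with the configured
    probability (geometric offset), substituted per-base at the family
    divergence rate, and reverse-complemented on minus-strand insertions.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    consensus = {
        fam.name: _random_seq(rng, fam.consensus_length) for fam in config.te_families
    }
    # draw every copy's sequence first, then place longest-first so uniform
    # non-overlapping placement cannot dead-end
    drawn: list[tuple[TEFamilySpec, int, str, str]] = []  # (family, offset, strand, seq)
    for fam in config.te_families:
        for _ in range(fam.copy_number):
            offset = 0
            if fam.truncation_prob > 0 and rng.random() < fam.truncation_prob:
                offset = int(rng.geometric(1.0 / fam.truncation_mean))
                offset = min(offset, max(fam.consensus_length - 100, 0))
            seq = _mutate(rng, consensus[fam.name][offset:], fam.divergence / 100.0)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                from .genome_annotation import reverse_complement

                seq = reverse_complement(seq)
            drawn.append((fam, offset, strand, seq))
    total_te = sum(len(s) for *_, s in drawn)
    if total_te > 0.8 * config.genome_length:
        raise ValueError(
            f"requested TE content ({total_te} bp) exceeds 80% of the "
            f"{config.genome_length} bp genome"
        )
    order = sorted(range(len(drawn)), key=lambda i: -len(drawn[i][3]))
    free: list[tuple[int, int]] = [(0, config.genome_length)]
    placements: list[tuple[int, int]] = [(0, 0)] * len(drawn)  # (start, idx)
    for i in order:
        length = len(drawn[i][3])
        weights = np.array([max(0, e - s - length + 1) for s, e in free], dtype=np.int64)
        total = int(weights.sum())
        if total == 0:
            raise ValueError("no room left to place a TE copy; lower copy numbers")
        u = int(rng.integers(total))
        block = int(np.searchsorted(np.cumsum(weights), u, side="right"))
        s, e = free[block]
        start = s + (u - (int(np.cumsum(weights)[block]) - int(weights[block])))
        placements[i] = (start, i)
        free[block : block + 1] = [
            iv for iv in [(s, start), (start + length, e)] if iv[1] > iv[0]
        ]
    background = np.frombuffer(_random_seq(rng, config.genome_length).encode(), dtype="S1").copy()
    copies: list[TECopy] = []
    rows = []
    for i, (fam, offset, strand, seq) in enumerate(drawn):
        start = placements[i][0]
        background[start : start + len(seq)] = np.frombuffer(seq.encode(), dtype="S1")
        iv = GenomicInterval(config.chrom_name, start, start + len(seq), strand)
        full = iv.length > config.full_length_threshold
        copies.append(
            TECopy(iv, fam.name, fam.name, fam.te_class, fam.divergence, full)
        )
        rows.append(
            (
                config.chrom_name,
                start,
                start + len(seq),
                strand,
                fam.name,
                fam.name,
                fam.te_class,
                fam.divergence,
                offset,
                full,
            )
        )
    copies.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    truth = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "strand", "repeat_name", "family",
            "te_class", "divergence", "truncation_offset", "full_length",
        ],
    ).sort_values(["chrom", "start"], ignore_index=True)
    catalog = TEClassCatalog(
        names={fam.name: (fam.name, fam.te_class) for fam in config.te_families},
        age_order={
            "L1": [f.name for f in sorted(
                (f for f in config.te_families if f.te_class == "LINE"),
                key=lambda f: f.divergence,
            )]
        },
    )
    return SimulatedGenome(
        config=config,
        genome={config.chrom_name: background.tobytes().decode()},
        copies=copies,
        consensus=consensus,
        truth=truth,
        catalog=catalog,
    )


# ---------------------------------------------------------------------------
# ChIP peaks and reads
# ---------------------------------------------------------------------------

@dataclass
class ChIPSim:
    peaks_inclusive: list[Peak]  # all planted + background ("ambiguous" set)
    peaks_unique: list[Peak]  # subset at copies with enough divergence to map
    records: list[AlignmentRecord]  # reads with full multi-hit sets
    truth: pd.DataFrame  # per planted peak: family, copy index, origin
    read_truth: pd.DataFrame  # per read: origin position, n_hits


def _kmer_index(genome: Mapping[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in genome.items():
        for p in range(len(seq) - k + 1):
            index.setdefault(seq[p : p + k], []).append((chrom, p))
    return index


def simulate_chip(
    sim: SimulatedGenome,
    binding: Mapping[str, float],
    n_background_peaks: int = 100,
    reads_per_peak: float = 20.0,
    n_background_reads: int = 2000,
    five_prime_window: int | None = 900,
    unique_divergence_threshold: float = 4.0,
    seed: int = 0,
    max_edit_distance: int = 0,
) -> ChIPSim:
    """Plant peaks in bound TE copies and emit reads with multi-hit sets.

    ``binding`` maps family name -> probability that a full-length copy is
    bound (short-consensus families treat every copy as eligible).  Bound
    copies get one peak, positioned inside the 5' window of the element when
    configured (strand-aware), plus ``n_background_peaks`` uniform decoys.
    The inclusive ("ambiguous") peak set contains all peaks; the unique set
    keeps planted peaks only at copies diverged beyond
    ``unique_divergence_threshold`` %, at which point a read is essentially
    certain to span a diagnostic substitution and map uniquely.

    Reads are uniform within each peak at Poisson(``reads_per_peak``) depth
    over a uniform genomic background; every read's hit set lists all exact
    occurrences of its sequence in the genome (``max_edit_distance`` > 0
    additionally admits nearby approximate matches, via edlib).
    """
    rng = np.random.default_rng(seed)
    cfg = sim.config
    chrom = cfg.chrom_name
    genome_seq = sim.genome[chrom]
    glen = len(genome_seq)
    peaks: list[Peak] = []
    unique_flags: list[bool] = []
    rows = []

    for ci, copy in enumerate(sim.copies):
        p_bind = binding.get(copy.family, binding.get(copy.te_class, 0.0))
        if p_bind <= 0:
            continue
        eligible = copy.full_length or (
            copy.length <= cfg.full_length_threshold
            and copy.length >= 0.9 * next(
                f.consensus_length for f in cfg.te_families if f.name == copy.family
            )
        )
        if not eligible or rng.random() >= p_bind:
            continue
        if five_prime_window is not None and copy.length > five_prime_window:
            off = int(rng.integers(five_prime_window))
            center = (
                copy.interval.start + off
                if copy.interval.strand != "-"
                else copy.interval.end - 1 - off
            )
        else:
            center = int(rng.integers(copy.interval.start, copy.interval.end))
        start = max(0, min(center - cfg.peak_length // 2, glen - cfg.peak_length))
        pk = Peak(
            GenomicInterval(chrom, start, start + cfg.peak_length),
            summit_offset=cfg.peak_length // 2,
            mode="inclusive",
        )
        peaks.append(pk)
        unique_flags.append(copy.divergence > unique_divergence_threshold)
        rows.append((len(peaks) - 1, ci, copy.family, copy.te_class, "planted"))

    space = PlacementSpace(sim.chrom_sizes)
    if n_background_peaks:
        starts = space.sample_starts(
            np.full(n_background_peaks, cfg.peak_length, dtype=np.int64), 1, rng
        )[0]
        for g in starts:
            c, local = space.to_local(int(g))
            peaks.append(
                Peak(
                    GenomicInterval(c, local, local + cfg.peak_length),
                    summit_offset=cfg.peak_length // 2,
                    mode="inclusive",
                )
            )
            unique_flags.append(True)
            rows.append((len(peaks) - 1, -1, "", "", "background"))

    peaks_unique = [
        Peak(p.interval, p.summit_offset, "unique")
        for p, u in zip(peaks, unique_flags)
        if u
    ]

    # reads: per-peak Poisson depth plus uniform background
    k = cfg.read_length
    origins: list[int] = []
    for p in peaks:
        n = int(rng.poisson(reads_per_peak))
        lo = p.interval.start
        hi = max(lo + 1, p.interval.end - k)
        origins.extend(int(x) for x in rng.integers(lo, hi, size=n))
    origins.extend(
        int(x) for x in rng.integers(0, glen - k + 1, size=n_background_reads)
    )
    index = _kmer_index(sim.genome, k)
    records = []
    read_rows = []
    for i, pos in enumerate(origins):
        seq = genome_seq[pos : pos + k]
        hit_positions = list(index.get(seq, []))
        if max_edit_distance > 0:
            hit_positions = _approx_hits(sim.genome, seq, max_edit_distance)
        hits = tuple(
            (GenomicInterval(c, p_, p_ + k), 60, 42 if len(hit_positions) == 1 else 0)
            for c, p_ in hit_positions
        )
        rid = f"read{i:07d}"
        records.append(AlignmentRecord(rid, hits))
        read_rows.append((rid, chrom, pos, len(hits)))
    truth = pd.DataFrame(
        rows, columns=["peak", "copy_index", "family", "te_class", "origin"]
    )
    read_truth = pd.DataFrame(read_rows, columns=["read_id", "chrom", "pos", "n_hits"])
    return ChIPSim(peaks, peaks_unique, records, truth, read_truth)


def _approx_hits(
    genome: Mapping[str, str], read: str, max_ed: int
) -> list[tuple[str, int]]:
    import edlib

    out = []
    for chrom, seq in genome.items():
        res = edlib.align(read, seq, mode="HW", task="locations", k=max_ed)
        if res["editDistance"] == -1:
            continue
        seen = set()
        for _, end in res["locations"]:
            start = end + 1 - len(read)
            if start >= 0 and start not in seen:
                seen.add(start)
                out.append((chrom, start))
    return sorted(out)


# ---------------------------------------------------------------------------
# Bisulfite
# ---------------------------------------------------------------------------

def methylome_truth(
    sim: SimulatedGenome,
    background: tuple[float, float] = (0.75, 0.02),
    per_class: Mapping[str, tuple[float, float]] | None = None,
    bound_copy_indices: set[int] | None = None,
    bound_levels: tuple[float, float] = (0.25, 0.20),
) -> pd.DataFrame:
    """True (p_C, p_5mC, p_5hmC) per genomic CpG cytosine.

    Defaults: heavily methylated background with a little 5hmC; per-class
    overrides; copies flagged as bound get hypomethylated, 5hmC-rich levels
    (the profile expected where an active demethylase sits).
    """
    chrom = sim.config.chrom_name
    seq = sim.genome[chrom]
    positions = np.array(
        [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"], dtype=np.int64
    )
    mc = np.full(len(positions), background[0])
    hmc = np.full(len(positions), background[1])
    for ci, copy in enumerate(sim.copies):
        levels = None
        if per_class is not None:
            levels = per_class.get(copy.family, per_class.get(copy.te_class))
        if bound_copy_indices is not None and ci in bound_copy_indices:
            levels = bound_levels
        if levels is None:
            continue
        sel = (positions >= copy.interval.start) & (positions < copy.interval.end)
        mc[sel], hmc[sel] = levels
    if np.any(mc + hmc > 1 + 1e-9):
        raise ValueError("p_5mC + p_5hmC > 1 at some site")
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "p_c": 1.0 - mc - hmc,
            "p_5mc": mc,
            "p_5hmc": hmc,
        }
    )


def simulate_bisulfite_counts(
    truth: pd.DataFrame,
    chemistry: ChemistrySpec,
    mean_depth: float,
    seed: int,
    chemistries: Sequence[str] = ("BS", "oxBS", "TAB"),
) -> dict[str, list["CpGSiteCounts"]]:
    """Draw per-CpG read counts for each chemistry.

    Depth is Poisson around ``mean_depth`` per site and chemistry; the
    unconverted count is binomial at the chemistry's read-as-C probability.
    """
    from .methylome import CpGSiteCounts

    if mean_depth < 1:
        raise ValueError("mean_depth must be >= 1")
    bad = truth["p_c"] + truth["p_5mc"] + truth["p_5hmc"]
    if np.any(bad > 1 + 1e-9) or np.any(truth[["p_c", "p_5mc", "p_5hmc"]] < -1e-12):
        raise ValueError("state probabilities must be >= 0 and sum to <= 1 per site")
    rng = np.random.default_rng(seed)
    out: dict[str, list[CpGSiteCounts]] = {}
    for chem in chemistries:
        p_read_c = np.array(
            [
                read_as_c_probability(chem, r.p_c, r.p_5mc, r.p_5hmc, chemistry)
                for r in truth.itertuples()
            ]
        )
        depth = rng.poisson(mean_depth, size=len(truth))
        unconv = rng.binomial(depth, p_read_c)
        out[chem] = [
            CpGSiteCounts(r.chrom, int(r.pos), chem, int(n), int(u))
            for r, n, u in zip(truth.itertuples(), depth, unconv)
        ]
    return out


def simulate_bisulfite(
    sim: SimulatedGenome,
    chemistry: ChemistrySpec | None = None,
    mean_depth: float = 30.0,
    seed: int = 0,
    **truth_kwargs,
) -> tuple[dict[str, list["CpGSiteCounts"]], pd.DataFrame]:
    """Genome-wide cytosine reports for BS/oxBS/TAB plus the truth table."""
    chemistry = chemistry or sim.config.chemistry
    truth = methylome_truth(sim, **truth_kwargs)
    counts = simulate_bisulfite_counts(truth, chemistry, mean_depth, seed)
    return counts, truth


# ---------------------------------------------------------------------------
# Interactions and expression counts
# ---------------------------------------------------------------------------

def simulate_interactions_and_counts(
    sim: SimulatedGenome,
    nos_pos_copy_indices: set[int],
    nos_neg_copy_indices: set[int],
    n_genes: int = 300,
    linked_fraction: float = 0.8,
    fold: float = 2.0,
    n_samples: int = 4,
    base_mean: float = 200.0,
    dispersion: float = 0.1,
    seed: int = 0,
) -> tuple[InteractionSet, pd.DataFrame, pd.DataFrame]:
    """Genes, promoter interactions to TE copies, and an expression table.

    A ``linked_fraction`` of NOS+ and NOS- copies each contact a distinct
    gene promoter; genes linked to NOS+ copies have negative-binomial means
    ``fold`` times the base mean.  Returns (interactions, counts, truth).
    """
    rng = np.random.default_rng(seed)
    glen = sim.config.genome_length
    chrom = sim.config.chrom_name
    promoters = []
    gene_ids = [f"gene{i:04d}" for i in range(n_genes)]
    starts = rng.integers(0, glen - 1000, size=n_genes)
    for s in starts:
        promoters.append(GenomicInterval(chrom, int(s), int(s) + 1000))

    baits, genes, other_ends = [], [], []
    gene_group = {g: "unlinked" for g in gene_ids}
    next_gene = iter(range(n_genes))

    def _link(copy_idx: int, group: str) -> None:
        try:
            gi = next(next_gene)
        except StopIteration:
            return
        g = gene_ids[gi]
        gene_group[g] = group
        iv = sim.copies[copy_idx].interval
        baits.append(promoters[gi])
        genes.append(g)
        other_ends.append(GenomicInterval(iv.chrom, iv.start, iv.end))

    for ci in sorted(nos_pos_copy_indices):
        if rng.random() < linked_fraction:
            _link(ci, "nos_pos")
    for ci in sorted(nos_neg_copy_indices):
        if rng.random() < linked_fraction:
            _link(ci, "nos_neg")

    interactions = interactions_from_bed_pair(baits, genes, other_ends)
    mu = np.full(n_genes, base_mean) * np.exp(
        rng.normal(0, 0.3, size=n_genes)
    )  # lognormal gene-to-gene spread
    for i, g in enumerate(gene_ids):
        if gene_group[g] == "nos_pos":
            mu[i] *= fold
    n_nb = 1.0 / dispersion
    counts = pd.DataFrame(
        {
            f"sample{j}": rng.negative_binomial(n_nb, n_nb / (n_nb + mu))
            for j in range(n_samples)
        },
        index=gene_ids,
    )
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "group": [gene_group[g] for g in gene_ids], "mu": mu}
    ).set_index("gene_id")
    return interactions, counts, truth


def simulate_peaks_with_fold(
    targets: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    n_peaks: int,
    peak_length: int,
    fold: float,
    seed: int = 0,
    mode: str = "inclusive",
) -> list[Peak]:
    """Peaks whose probability of overlapping ``targets`` is exactly ``fold``
    times the matched-random null probability.

    Each peak is, with probability ``fold * p0`` (p0 = the closed-form null
    overlap probability), placed uniformly among all placements that overlap
    a target, and otherwise uniformly among all placements that do not; the
    expected enrichment fold over the matched null is therefore ``fold``.
    """
    from .te_enrichment import expected_overlap_probability

    space = PlacementSpace(chrom_sizes)
    p0 = expected_overlap_probability(targets, chrom_sizes, peak_length)
    q = fold * p0
    if not (0 <= q <= 1):
        raise ValueError(f"fold {fold} is unreachable: fold * p0 = {q:.3f} not in [0,1]")
    merged = space.merged_global(targets)
    hit_spans, miss_spans = [], []
    for bs, be in zip(space.block_start, space.block_end):
        if be - bs < peak_length:
            continue
        v0, v1 = int(bs), int(be - peak_length + 1)  # valid starts, half-open
        inside: list[tuple[int, int]] = []
        for ms, me in merged:
            s = max(v0, int(ms) - peak_length + 1)
            e = min(v1, int(me))
            if s < e:
                if inside and s <= inside[-1][1]:
                    inside[-1] = (inside[-1][0], max(inside[-1][1], e))
                else:
                    inside.append((s, e))
        hit_spans.extend(inside)
        prev = v0
        for s, e in inside:
            if prev < s:
                miss_spans.append((prev, s))
            prev = e
        if prev < v1:
            miss_spans.append((prev, v1))

    rng = np.random.default_rng(seed)

    def _draw(spans: list[tuple[int, int]]) -> int:
        w = np.array([e - s for s, e in spans], dtype=np.int64)
        u = int(rng.integers(int(w.sum())))
        i = int(np.searchsorted(np.cumsum(w), u, side="right"))
        return spans[i][0] + (u - (int(np.cumsum(w)[i]) - int(w[i])))

    peaks = []
    for _ in range(n_peaks):
        g = _draw(hit_spans) if rng.random() < q else _draw(miss_spans)
        chrom, local = space.to_local(g)
        peaks.append(
            Peak(
                GenomicInterval(chrom, local, local + peak_length),
                summit_offset=peak_length // 2,
                mode=mode,
            )
        )
    return peaks


# ---------------------------------------------------------------------------
# Special-purpose fixtures
# ---------------------------------------------------------------------------

def simulate_consensus_reads(
    consensus_length: int,
    n_reads: int,
    five_prime_window: int,
    five_prime_fold: float,
    read_length: int = 50,
    seed: int = 0,
) -> list[GenomicInterval]:
    """Reads along a consensus element with density ``five_prime_fold`` times
    higher inside the first ``five_prime_window`` bp (the 5' UTR geometry)."""
    rng = np.random.default_rng(seed)
    span = consensus_length - read_length
    w = five_prime_window
    weight_5p = five_prime_fold * w
    weight_3p = float(span - w)
    out = []
    for _ in range(n_reads):
        if rng.random() < weight_5p / (weight_5p + weight_3p):
            start = int(rng.integers(0, w))
        else:
            start = int(rng.integers(w, span))
        out.append(GenomicInterval("consensus", start, start + read_length))
    return out


def reads_with_hits(
    genome: Mapping[str, str],
    origins: Sequence[tuple[str, int]],
    read_length: int,
) -> list[AlignmentRecord]:
    """Turn (chrom, start) read origins into alignment records whose hit sets
    list every exact occurrence of the read sequence in the genome."""
    index = _kmer_index(genome, read_length)
    records = []
    for i, (chrom, pos) in enumerate(origins):
        seq = genome[chrom][pos : pos + read_length]
        hits = tuple(
            (GenomicInterval(c, p, p + read_length), 60, 42 if len(index[seq]) == 1 else 0)
            for c, p in index[seq]
        )
        records.append(AlignmentRecord(f"read{i:07d}", hits))
    return records


def duplicated_block_genome(
    flank: int = 2000, block: int = 1000, seed: int = 0
) -> tuple[dict[str, str], dict[str, tuple[int, int]]]:
    """A genome with two identical blocks separated by unique flanks:
    flank - block - flank - block - flank.  Reads from inside a block map to
    both copies; flank reads map uniquely.  Returns (genome, regions)."""
    rng = np.random.default_rng(seed)
    f1, f2, f3 = (_random_seq(rng, flank) for _ in range(3))
    b = _random_seq(rng, block)
    seq = f1 + b + f2 + b + f3
    regions = {
        "flank1": (0, flank),
        "block1": (flank, flank + block),
        "flank2": (flank + block, 2 * flank + block),
        "block2": (2 * flank + block, 2 * flank + 2 * block),
        "flank3": (2 * flank + 2 * block, 3 * flank + 2 * block),
    }
    return {"chrD": seq}, regions
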