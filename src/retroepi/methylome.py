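"""BS / oxBS / TAB cytosine-modification arithmetic.

The three bisulfite chemistries read out different sets of modified
cytosines as unconverted C:

* BS     — 5mC + 5hmC (both resist conversion)
* oxBS   — 5mC only (KRuO4 first oxidises 5hmC, which then converts)
* TAB    — 5hmC only (TET-assisted protection of 5hmC, 5mC converts)

So 5hmC is obtained by subtraction: BS level - oxBS level (clamped at 0),
or directly from TAB.  Per-CpG counts come from Bismark-style cytosine
reports; amplicon analyses keep only CpGs with deep coverage (>= 100 reads
in every chemistry being combined, by default) and average replicates per
CpG.  Group comparisons use the two-sided Wilcoxon rank-sum (exact for
small groups) or Welch's t.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .genome_annotation import GenomicInterval, TECopy

__all__ = [
    "CpGSiteCounts",
    "ModEstimate",
    "parse_cytosine_report",
    "write_cytosine_report",
    "merge_dyads",
    "estimate_from_bs_oxbs",
    "estimate_from_tab",
    "filter_min_coverage",
    "replicate_average",
    "aggregate_by_region",
    "compare_groups",
    "estimates_frame",
]

CHEMISTRIES = ("BS", "oxBS", "TAB")


@dataclass(frozen=True)
class CpGSiteCounts:
    """Read counts at one CpG cytosine under one conversion chemistry."""

    chrom: str
    pos: int  # 0-based cytosine position (genome or consensus coordinate)
    chemistry: str
    n_reads: int
    n_unconverted: int  # reads reporting C (escaped conversion)
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.chemistry not in CHEMISTRIES:
            raise ValueError(f"unknown chemistry {self.chemistry!r}")
        if not (0 <= self.n_unconverted <= self.n_reads):
            raise ValueError("need 0 <= n_unconverted <= n_reads")

    @property
    def level(self) -> float:
        """Naive unconverted fraction (NaN at zero coverage)."""
        return self.n_unconverted / self.n_reads if self.n_reads else float("nan")


@dataclass(frozen=True)
class ModEstimate:
    """Estimated modification levels at a CpG or region.

    ``level_5hmC_raw`` keeps the unclamped subtraction as a diagnostic;
    ``level_5mC + level_5hmC <= level_modified`` holds after clamping.
    """

    chrom: str
    pos: int
    level_5mC: float
    level_5hmC: float
    level_modified: float
    n_reads_min: int
    level_5hmC_raw: float = float("nan")
    ci_5mC: tuple[float, float] | None = None
    ci_5hmC: tuple[float, float] | None = None


# ---------------------------------------------------------------------------
# Bismark cytosine report I/O
# ---------------------------------------------------------------------------

def parse_cytosine_report(
    path: str | Path,
    chemistry: str,
    merge_strands: bool = True,
) -> list[CpGSiteCounts]:
    """Parse a Bismark cytosine report, keeping CG-context lines.

    Columns: chrom, 1-based position, strand, count methylated (unconverted),
    count unmethylated, context, trinucleotide.  Positions are converted to
    0-based.  With ``merge_strands`` the +/- calls of one CpG dyad (minus
    strand cytosine at pos+1 of the plus one) are summed onto the plus-strand
    coordinate — the default for genome-scale data; amplicon analyses keep
    the sequenced strand (``merge_strands=False``).
    """
    sites: list[CpGSiteCounts] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.rstrip("\n")
            if not s or s.startswith("#"):
                continue
            f = s.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 tab-separated columns")
            chrom, pos1, strand, n_meth, n_unmeth, context = f[:6]
            if context not in ("CG", "CHG", "CHH", "CN", "Unknown"):
                raise ValueError(f"{path}:{lineno}: unknown context token {context!r}")
            if context != "CG":
                continue
            try:
                pos = int(pos1) - 1
                meth, unmeth = int(n_meth), int(n_unmeth)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer counts") from None
            if meth < 0 or unmeth < 0:
                raise ValueError(f"{path}:{lineno}: negative counts")
            sites.append(
                CpGSiteCounts(chrom, pos, chemistry, meth + unmeth, meth, strand)
            )
    return merge_dyads(sites) if merge_strands else sites


def merge_dyads(sites: Sequence[CpGSiteCounts]) -> list[CpGSiteCounts]:
    """Sum the two strand calls of each CpG dyad onto the plus-strand (C)
    coordinate; a minus-strand call at pos p belongs to the dyad at p-1."""
    acc: dict[tuple[str, int, str], list[int]] = {}
    for s in sites:
        pos = s.pos - 1 if s.strand == "-" else s.pos
        key = (s.chrom, pos, s.chemistry)
        if key in acc:
            acc[key][0] += s.n_reads
            acc[key][1] += s.n_unconverted
        else:
            acc[key] = [s.n_reads, s.n_unconverted]
    return [
        CpGSiteCounts(chrom, pos, chem, n, u)
        for (chrom, pos, chem), (n, u) in sorted(acc.items())
    ]


def write_cytosine_report(sites: Iterable[CpGSiteCounts], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.pos + 1}\t{s.strand}\t{s.n_unconverted}\t"
                f"{s.n_reads - s.n_unconverted}\tCG\tCGN\n"
            )


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

def _wilson(k: int, n: int) -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def estimate_from_bs_oxbs(
    bs: CpGSiteCounts, oxbs: CpGSiteCounts, ci: bool = True
) -> ModEstimate:
    """5mC from oxBS, total modification from BS, 5hmC by subtraction.

    Negative subtraction results are clamped to 0 (the raw value is kept in a
    diagnostic field).  Wilson 95% CIs per proportion (``ci=False`` skips
    them, for bulk scans); the 5hmC CI combines the two binomial variances by
    normal approximation.
    """
    if (bs.chrom, bs.pos) != (oxbs.chrom, oxbs.pos):
        raise ValueError("BS and oxBS counts are for different sites")
    if bs.chemistry != "BS" or oxbs.chemistry != "oxBS":
        raise ValueError("chemistry mismatch (need BS and oxBS)")
    if bs.n_reads == 0 or oxbs.n_reads == 0:
        raise ValueError("zero coverage in one chemistry; no estimate")
    modified = bs.level
    mc = oxbs.level
    raw_hmc = modified - mc
    hmc = max(0.0, raw_hmc)
    ci_mc = ci_hmc = None
    if ci:
        se = float(
            np.sqrt(
                modified * (1 - modified) / bs.n_reads + mc * (1 - mc) / oxbs.n_reads
            )
        )
        ci_hmc = (max(0.0, raw_hmc - 1.96 * se), min(1.0, raw_hmc + 1.96 * se))
        ci_mc = _wilson(oxbs.n_unconverted, oxbs.n_reads)
    return ModEstimate(
        bs.chrom,
        bs.pos,
        level_5mC=mc,
        level_5hmC=hmc,
        level_modified=modified,
        n_reads_min=min(bs.n_reads, oxbs.n_reads),
        level_5hmC_raw=raw_hmc,
        ci_5mC=ci_mc,
        ci_5hmC=ci_hmc,
    )


def estimate_from_tab(tab: CpGSiteCounts, bs: CpGSiteCounts | None = None) -> ModEstimate:
    """5hmC directly from TAB; 5mC only when a paired BS count is given
    (BS level - TAB level, clamped at 0)."""
    if tab.chemistry != "TAB":
        raise ValueError("chemistry mismatch (need TAB)")
    if tab.n_reads == 0:
        raise ValueError("zero TAB coverage; no estimate")
    hmc = tab.level
    if bs is None:
        return ModEstimate(
            tab.chrom,
            tab.pos,
            level_5mC=float("nan"),
            level_5hmC=hmc,
            level_modified=float("nan"),
            n_reads_min=tab.n_reads,
            ci_5hmC=_wilson(tab.n_unconverted, tab.n_reads),
        )
    if bs.n_reads == 0:
        raise ValueError("zero BS coverage; no estimate")
    mc = max(0.0, bs.level - hmc)
    return ModEstimate(
        tab.chrom,
        tab.pos,
        level_5mC=mc,
        level_5hmC=hmc,
        level_modified=bs.level,
        n_reads_min=min(tab.n_reads, bs.n_reads),
        ci_5mC=None,
        ci_5hmC=_wilson(tab.n_unconverted, tab.n_reads),
    )


def filter_min_coverage(
    counts_by_chemistry: Mapping[str, Sequence[CpGSiteCounts]],
    min_reads: int = 100,
    joint: bool = True,
) -> dict[str, list[CpGSiteCounts]]:
    """Keep CpG sites with ``n_reads >= min_reads``.

    In ``joint`` mode (the amplicon default) a site survives only when it is
    present and deep enough in *every* chemistry supplied — a subtraction
    needs both counts.  Per-chemistry mode filters each list independently.
    Idempotent; never increases the site count.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if not joint:
        return {
            chem: [s for s in sites if s.n_reads >= min_reads]
            for chem, sites in counts_by_chemistry.items()
        }
    depth: dict[tuple[str, int], dict[str, int]] = {}
    for chem, sites in counts_by_chemistry.items():
        for s in sites:
            depth.setdefault((s.chrom, s.pos), {})[chem] = s.n_reads
    chems = list(counts_by_chemistry)
    ok = {
        key
        for key, d in depth.items()
        if all(d.get(c, 0) >= min_reads for c in chems)
    }
    return {
        chem: [s for s in sites if (s.chrom, s.pos) in ok]
        for chem, sites in counts_by_chemistry.items()
    }


def replicate_average(replicates: Sequence[Sequence[ModEstimate]]) -> pd.DataFrame:
    """Unweighted per-CpG mean across biological replicates.

    A CpG missing from some replicates is averaged over those where it is
    present; the replicate count is reported per CpG.
    """
    if not replicates:
        raise ValueError("need >= 1 replicate")
    rows = []
    for rep_idx, rep in enumerate(replicates):
        for e in rep:
            rows.append(
                (e.chrom, e.pos, rep_idx, e.level_5mC, e.level_5hmC, e.level_modified)
            )
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "rep", "level_5mC", "level_5hmC", "level_modified"]
    )
    out = (
        df.groupby(["chrom", "pos"], sort=True)
        .agg(
            level_5mC=("level_5mC", "mean"),
            level_5hmC=("level_5hmC", "mean"),
            level_modified=("level_modified", "mean"),
            n_replicates=("rep", "nunique"),
        )
        .reset_index()
    )
    return out


def aggregate_by_region(
    estimates: Sequence[ModEstimate],
    regions: Sequence[TECopy] | Sequence[GenomicInterval],
) -> pd.DataFrame:
    """Coverage-weighted mean 5mC/5hmC over the CpGs inside each region.

    Regions containing no estimated CpG get NaN levels and n_cpgs = 0.
    """
    ivs = [r.interval if isinstance(r, TECopy) else r for r in regions]
    rows = []
    for i, iv in enumerate(ivs):
        inside = [
            e for e in estimates if e.chrom == iv.chrom and iv.start <= e.pos < iv.end
        ]
        if not inside:
            rows.append((i, iv.chrom, iv.start, iv.end, np.nan, np.nan, 0))
            continue
        w = np.array([max(e.n_reads_min, 1) for e in inside], dtype=float)
        mc = float(np.average([e.level_5mC for e in inside], weights=w))
        hmc = float(np.average([e.level_5hmC for e in inside], weights=w))
        rows.append((i, iv.chrom, iv.start, iv.end, mc, hmc, len(inside)))
    return pd.DataFrame(
        rows,
        columns=["region", "chrom", "start", "end", "level_5mC", "level_5hmC", "n_cpgs"],
    )


def compare_groups(
    levels_a: Sequence[float],
    levels_b: Sequence[float],
    test: str = "wilcoxon_ranksum",
) -> tuple[float, float]:
    """Two-sided comparison of two groups of levels.

    ``wilcoxon_ranksum`` uses the Mann-Whitney U statistic: for
    ``n_a + n_b <= 12`` the two-sided p is computed by full enumeration of
    the group assignments of the pooled (tie-averaged) ranks, which is exact
    even with ties; larger groups use the normal approximation with tie
    correction.  ``t`` is Welch's unequal-variance t.  Returns (statistic, p).
    """
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if test == "wilcoxon_ranksum":
        if a.size + b.size <= 12:
            return _exact_ranksum(a, b)
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    if test == "t":
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def _exact_ranksum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum p by enumerating every assignment of the
    pooled mid-ranks to group a.

    Two-sided p is twice the smaller tail (capped at 1), the standard
    convention; with ties the permutation distribution of U is asymmetric,
    so the tails are counted separately.
    """
    from itertools import combinations

    na, nb = a.size, b.size
    ranks = stats.rankdata(np.concatenate([a, b]))
    u_obs = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    total = n_le = n_ge = 0
    for idx in combinations(range(na + nb), na):
        u = float(ranks[list(idx)].sum() - na * (na + 1) / 2.0)
        n_le += u <= u_obs + 1e-12
        n_ge += u >= u_obs - 1e-12
        total += 1
    return u_obs, min(1.0, 2.0 * min(n_le, n_ge) / total)


def estimates_frame(estimates: Sequence[ModEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [e.chrom for e in estimates],
            "pos": [e.pos for e in estimates],
            "level_5mC": [e.level_5mC for e in estimates],
            "level_5hmC": [e.level_5hmC for e in estimates],
            "level_modified": [e.level_modified for e in estimates],
            "n_reads": [e.n_reads_min for e in estimates],
            "level_5hmC_raw": [e.level_5hmC_raw for e in estimates],
        }
    )
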