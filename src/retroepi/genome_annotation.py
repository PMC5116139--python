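"""Genomes, transposable-element annotations, and interval arithmetic.

All coordinates inside the package are 0-based half-open (BED convention).
RepeatMasker ``.out`` files and Bismark reports use 1-based inclusive
coordinates; they are converted at the I/O boundary and never afterwards.

The module also computes a desk-scale "uniqueome": the set of positions at
which a read of length *k* maps to exactly one place in the genome (both
strands considered), used to restrict matched-random null intervals for
uniquely mapped peak sets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "TECopy",
    "TEClassCatalog",
    "MappabilityTrack",
    "read_fasta",
    "write_fasta",
    "read_repeatmasker",
    "write_repeatmasker",
    "read_bed",
    "write_bed",
    "merge_intervals",
    "overlap_flags",
    "overlap_count",
    "classify_full_length",
    "build_mappability",
]

DEFAULT_FULL_LENGTH_BP = 5000  # "full-length" LINE-1 means strictly longer than this


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_bp


@dataclass(frozen=True)
class TECopy:
    """One annotated transposable-element instance.

    ``divergence`` is the percent substitution from the family consensus,
    the standard proxy for the copy's age.  ``full_length`` records whether
    the copy exceeds the full-length threshold (strict inequality; default
    5 kb, the L1 convention).
    """

    interval: GenomicInterval
    repeat_name: str
    family: str
    te_class: str
    divergence: float = 0.0
    full_length: bool = False

    def __post_init__(self) -> None:
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class TEClassCatalog:
    """Repeat-name resolution plus family age ordering.

    ``age_order`` maps a superfamily label to its families ordered youngest
    first.  When a superfamily has no explicit order, families are ranked by
    mean divergence across copies (younger = less diverged).
    """

    names: dict[str, tuple[str, str]] = field(default_factory=dict)  # name -> (family, class)
    age_order: dict[str, list[str]] = field(default_factory=dict)

    def resolve(self, repeat_name: str) -> tuple[str, str]:
        try:
            return self.names[repeat_name]
        except KeyError:
            raise KeyError(f"repeat name {repeat_name!r} not in catalog") from None

    def ordered_families(
        self, superfamily: str, copies: Sequence[TECopy] | None = None
    ) -> list[str]:
        if superfamily in self.age_order:
            order = self.age_order[superfamily]
            if len(set(order)) != len(order):
                raise ValueError(f"age order for {superfamily!r} is not a strict order")
            return list(order)
        if copies is None:
            raise KeyError(
                f"no age order for {superfamily!r} and no copies to rank by divergence"
            )
        div: dict[str, list[float]] = {}
        for c in copies:
            div.setdefault(c.family, []).append(c.divergence)
        return sorted(div, key=lambda fam: float(np.mean(div[fam])))


def classify_full_length(copy: TECopy, threshold: int = DEFAULT_FULL_LENGTH_BP) -> bool:
    """True iff the copy is strictly longer than ``threshold`` bp."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return copy.length > threshold


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# RepeatMasker / BED annotation I/O
# ---------------------------------------------------------------------------

_RM_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def read_repeatmasker(
    path: str | Path,
    full_length_threshold: int = DEFAULT_FULL_LENGTH_BP,
) -> list[TECopy]:
    """Parse a RepeatMasker ``.out`` file (or a BED6 fallback) into TE copies.

    The ``.out`` dialect: three header lines, whitespace-delimited records,
    1-based inclusive coordinates, strand ``C`` for the minus strand, and
    ``class/family`` in column 11.  A BED6 file is accepted when the name
    column encodes ``repeat_name:family:class[:divergence]``.
    Records are returned sorted by (chrom, start).
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    if _looks_like_bed(lines):
        return _read_bed_annotation(lines, path, full_length_threshold)

    copies: list[TECopy] = []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if lineno <= 3 and (stripped.startswith(("SW", "score")) or "perc" in stripped):
            continue
        fields = stripped.split()
        if len(fields) < 11:
            raise ValueError(f"{path}:{lineno}: malformed RepeatMasker line: {stripped!r}")
        try:
            divergence = float(fields[1])
            chrom = fields[4]
            begin = int(fields[5])
            end = int(fields[6])
            strand = fields[8]
            repeat_name = fields[9]
            class_family = fields[10]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed RepeatMasker line: {exc}") from None
        if strand == "C":
            strand = "-"
        elif strand != "+":
            raise ValueError(f"{path}:{lineno}: unknown strand token {strand!r}")
        te_class, _, family = class_family.partition("/")
        if not family:
            family = repeat_name
        interval = GenomicInterval(chrom, begin - 1, end, strand)
        copies.append(
            TECopy(
                interval=interval,
                repeat_name=repeat_name,
                family=family,
                te_class=te_class,
                divergence=divergence,
                full_length=interval.length > full_length_threshold,
            )
        )
    copies.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return copies


def _looks_like_bed(lines: list[str]) -> bool:
    for line in lines:
        s = line.strip()
        if not s or s.startswith(("#", "track", "browser")):
            continue
        fields = s.split("\t")
        return len(fields) >= 4 and fields[1].isdigit() and fields[2].isdigit()
    return False


def _read_bed_annotation(
    lines: list[str], path: Path, full_length_threshold: int
) -> list[TECopy]:
    copies = []
    for lineno, line in enumerate(lines, start=1):
        s = line.strip()
        if not s or s.startswith(("#", "track", "browser")):
            continue
        fields = s.split("\t")
        if len(fields) < 6:
            raise ValueError(f"{path}:{lineno}: BED annotation needs >= 6 columns")
        name_parts = fields[3].split(":")
        if len(name_parts) < 3:
            raise ValueError(
                f"{path}:{lineno}: BED name must encode repeat:family:class[:divergence]"
            )
        divergence = float(name_parts[3]) if len(name_parts) > 3 else 0.0
        interval = GenomicInterval(fields[0], int(fields[1]), int(fields[2]), fields[5])
        copies.append(
            TECopy(
                interval=interval,
                repeat_name=name_parts[0],
                family=name_parts[1],
                te_class=name_parts[2],
                divergence=divergence,
                full_length=interval.length > full_length_threshold,
            )
        )
    copies.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return copies


def write_repeatmasker(copies: Iterable[TECopy], path: str | Path) -> None:
    """Write TE copies in the RepeatMasker ``.out`` dialect read back by
    :func:`read_repeatmasker` (round-trip identity on the TECopy fields)."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, c in enumerate(copies, start=1):
            strand = "C" if c.interval.strand == "-" else "+"
            class_family = f"{c.te_class}/{c.family}"
            fh.write(
                f"  239 {c.divergence:5.1f}  0.0  0.0  {c.interval.chrom} "
                f"{c.interval.start + 1} {c.interval.end} (0) {strand} "
                f"{c.repeat_name} {class_family} 1 {c.interval.length} (0) {i}\n"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            f = s.split("\t")
            strand = f[5] if len(f) >= 6 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path, names=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, np.ndarray]:
    acc: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        acc.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {c: np.array(sorted(v), dtype=np.int64) for c, v in acc.items()}


def merge_intervals(intervals: Iterable[GenomicInterval]) -> dict[str, np.ndarray]:
    """Merge overlapping/adjacent intervals per chromosome.

    Returns ``{chrom: array of shape (n, 2)}`` with disjoint sorted rows.
    """
    merged: dict[str, np.ndarray] = {}
    for chrom, arr in _by_chrom(intervals).items():
        out: list[list[int]] = []
        for s, e in arr:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.array(out, dtype=np.int64)
    return merged


def _overlap_bp_merged(
    starts: np.ndarray, ends: np.ndarray, merged: np.ndarray
) -> np.ndarray:
    """Total overlap bp of each query ``[starts, ends)`` with disjoint sorted
    ``merged`` rows, via prefix sums (vectorised over queries)."""
    if merged.size == 0:
        return np.zeros(len(starts), dtype=np.int64)
    ms, me = merged[:, 0], merged[:, 1]
    lengths = me - ms
    prefix = np.concatenate([[0], np.cumsum(lengths)])
    # index of first merged interval with end > q.start, last with start < q.end
    lo = np.searchsorted(me, starts, side="right")
    hi = np.searchsorted(ms, ends, side="left")
    total = np.zeros(len(starts), dtype=np.int64)
    sel = hi > lo
    if np.any(sel):
        full = prefix[hi[sel]] - prefix[lo[sel]]
        # clip the two boundary intervals to the query span
        left_clip = np.maximum(starts[sel] - ms[lo[sel]], 0)
        right_clip = np.maximum(me[hi[sel] - 1] - ends[sel], 0)
        total[sel] = full - left_clip - right_clip
    return total


def overlap_flags(
    queries: Sequence[GenomicInterval],
    targets: Sequence[GenomicInterval],
    min_overlap_bp: int = 1,
) -> np.ndarray:
    """Boolean flag per query: does it share >= ``min_overlap_bp`` bp with the
    target set?

    Shared bp is counted against the *union* of the targets (half-open
    intersection with the merged target intervals), so two abutting targets
    each contributing part of the requirement still count.
    """
    flags = np.zeros(len(queries), dtype=bool)
    if not queries or not targets:
        return flags
    merged = merge_intervals(targets)
    by_chrom: dict[str, list[int]] = {}
    for i, q in enumerate(queries):
        by_chrom.setdefault(q.chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        if chrom not in merged:
            continue
        idx_arr = np.array(idx)
        starts = np.array([queries[i].start for i in idx], dtype=np.int64)
        ends = np.array([queries[i].end for i in idx], dtype=np.int64)
        bp = _overlap_bp_merged(starts, ends, merged[chrom])
        flags[idx_arr] = bp >= min_overlap_bp
    return flags


def overlap_count(
    queries: Sequence[GenomicInterval],
    targets: Sequence[GenomicInterval],
    min_overlap_bp: int = 1,
) -> tuple[int, np.ndarray]:
    """Number of queries overlapping >= 1 target, plus the per-query flags."""
    flags = overlap_flags(queries, targets, min_overlap_bp=min_overlap_bp)
    return int(flags.sum()), flags


# ---------------------------------------------------------------------------
# Mappability ("uniqueome")
# ---------------------------------------------------------------------------

@dataclass
class MappabilityTrack:
    """Per-chromosome sorted disjoint intervals of uniquely mappable read
    start positions, for reads of length ``read_length``."""

    intervals: dict[str, np.ndarray]
    read_length: int

    def __post_init__(self) -> None:
        for chrom, arr in self.intervals.items():
            if arr.size == 0:
                continue
            if np.any(arr[:, 0] >= arr[:, 1]):
                raise ValueError(f"{chrom}: empty/inverted mappability interval")
            if np.any(arr[1:, 0] < arr[:-1, 1]):
                raise ValueError(f"{chrom}: mappability intervals overlap or are unsorted")

    def to_intervals(self) -> list[GenomicInterval]:
        out = []
        for chrom in sorted(self.intervals):
            for s, e in self.intervals[chrom]:
                out.append(GenomicInterval(chrom, int(s), int(e)))
        return out

    def write_bed3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for iv in self.to_intervals():
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")

    @classmethod
    def read_bed3(cls, path: str | Path, read_length: int) -> "MappabilityTrack":
        acc: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                f = line.split()
                if len(f) >= 3:
                    acc.setdefault(f[0], []).append((int(f[1]), int(f[2])))
        return cls(
            {c: np.array(sorted(v), dtype=np.int64) for c, v in acc.items()}, read_length
        )


_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def build_mappability(genome: Mapping[str, str], k: int, step: int = 1) -> MappabilityTrack:
    """Exact-k-mer uniqueome: start position p is mappable iff the k-mer at p
    occurs exactly once in the union of the genome and its reverse complement.

    Desk-scale exact computation; intended for synthetic genomes (<= ~10 Mb).
    ``step`` subsamples candidate start positions (1 = every position).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter[str] = Counter()
    for seq in genome.values():
        for strand_seq in (seq, reverse_complement(seq)):
            for p in range(len(strand_seq) - k + 1):
                counts[strand_seq[p : p + k]] += 1
    intervals: dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        n = len(seq) - k + 1
        if n <= 0:
            intervals[chrom] = np.empty((0, 2), dtype=np.int64)
            continue
        mappable = np.zeros(n, dtype=bool)
        for p in range(0, n, step):
            mappable[p] = counts[seq[p : p + k]] == 1
        intervals[chrom] = _bool_to_intervals(mappable)
    return MappabilityTrack(intervals, read_length=k)


def _bool_to_intervals(mask: np.ndarray) -> np.ndarray:
    if not mask.any():
        return np.empty((0, 2), dtype=np.int64)
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return np.stack([starts, ends], axis=1).astype(np.int64)
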