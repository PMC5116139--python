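"""Unique vs inclusive assignment of multi-mapping reads.

Repeat-derived reads often align equally well to many near-identical copies.
Two policies are contrasted throughout the pipeline:

* **unique** — a read is kept only when exactly one hit attains its best
  alignment score; tied-best reads are discarded.  This mirrors filtering a
  SAM file down to unambiguous alignments.
* **inclusive** — every read is kept, and a tied-best read is assigned to
  one of its best-scoring hits uniformly at random (seeded, so reruns are
  byte-identical).  Signals at young, low-mappability repeat families are
  invisible to the unique policy and only recoverable inclusively.

"Equal mapping quality" is interpreted as a tied best alignment score; when
scores are absent, MAPQ ties are used; when both are absent every hit of a
multi-hit read is treated as tied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .genome_annotation import GenomicInterval

__all__ = [
    "AlignmentRecord",
    "AssignedRead",
    "filter_unique",
    "assign_inclusive",
    "reads_to_coverage",
    "read_sam_records",
    "write_sam_records",
    "read_hits_tsv",
    "write_hits_tsv",
    "write_assigned_bed",
]


@dataclass(frozen=True)
class AlignmentRecord:
    """All candidate alignments of one read: (interval, score, mapq) hits."""

    read_id: str
    hits: tuple[tuple[GenomicInterval, int | None, int | None], ...]

    def __post_init__(self) -> None:
        if not self.hits:
            raise ValueError(f"read {self.read_id!r} has no hits")

    def best_hits(self) -> list[GenomicInterval]:
        """Hits attaining the read's best score (score, else MAPQ, else all)."""
        scores = [h[1] for h in self.hits]
        if all(s is not None for s in scores):
            best = max(scores)
            return [h[0] for h in self.hits if h[1] == best]
        mapqs = [h[2] for h in self.hits]
        if all(m is not None for m in mapqs):
            best = max(mapqs)
            return [h[0] for h in self.hits if h[2] == best]
        return [h[0] for h in self.hits]


@dataclass(frozen=True)
class AssignedRead:
    read_id: str
    chosen: GenomicInterval
    mode: str  # "unique" | "inclusive"


def filter_unique(records: Iterable[AlignmentRecord]) -> list[AssignedRead]:
    """Keep a read iff exactly one hit attains its best score."""
    out = []
    for rec in records:
        best = rec.best_hits()
        if len(best) == 1:
            out.append(AssignedRead(rec.read_id, best[0], "unique"))
    return out


def assign_inclusive(records: Iterable[AlignmentRecord], seed: int) -> list[AssignedRead]:
    """Assign every read to one best-scoring hit, uniformly at random.

    One seeded generator is consumed in read-name-sorted order, so the same
    records and seed always give the same assignments.
    """
    rng = np.random.default_rng(seed)
    out = []
    for rec in sorted(records, key=lambda r: r.read_id):
        best = rec.best_hits()
        chosen = best[0] if len(best) == 1 else best[int(rng.integers(len(best)))]
        out.append(AssignedRead(rec.read_id, chosen, "inclusive"))
    return out


def reads_to_coverage(
    assigned: Sequence[AssignedRead],
    binsize: int,
    chrom_sizes: Mapping[str, int],
) -> dict[str, np.ndarray]:
    """Binned midpoint coverage: each read counted once in the bin holding its
    midpoint, so bin sums conserve the read count."""
    if binsize < 1:
        raise ValueError("binsize must be >= 1")
    cov = {
        chrom: np.zeros(-(-size // binsize), dtype=np.float64)
        for chrom, size in chrom_sizes.items()
    }
    for read in assigned:
        vec = cov.get(read.chosen.chrom)
        if vec is None:
            continue
        b = min(read.chosen.midpoint // binsize, len(vec) - 1)
        vec[b] += 1
    return cov


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_sam_records(path: str | Path) -> list[AlignmentRecord]:
    """Reconstruct per-read hit sets from a SAM/BAM file.

    Primary and secondary alignments are grouped by read name; the AS tag is
    used as the alignment score when present, MAPQ otherwise.
    """
    hits: dict[str, list[tuple[GenomicInterval, int | None, int | None]]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            strand = "-" if aln.is_reverse else "+"
            iv = GenomicInterval(
                aln.reference_name, aln.reference_start, aln.reference_end, strand
            )
            score = aln.get_tag("AS") if aln.has_tag("AS") else None
            hits.setdefault(aln.query_name, []).append((iv, score, aln.mapping_quality))
    return [AlignmentRecord(rid, tuple(h)) for rid, h in sorted(hits.items())]


def write_sam_records(
    records: Iterable[AlignmentRecord],
    chrom_sizes: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write hit sets as a headerful SAM file (first hit primary, rest
    secondary), with AS tags carrying the alignment scores."""
    chroms = list(chrom_sizes)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": c, "LN": int(chrom_sizes[c])} for c in chroms],
        }
    )
    tid = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            for i, (iv, score, mapq) in enumerate(rec.hits):
                a = pysam.AlignedSegment(header)
                a.query_name = rec.read_id
                a.reference_id = tid[iv.chrom]
                a.reference_start = iv.start
                a.mapping_quality = 0 if mapq is None else int(mapq)
                a.cigarstring = f"{iv.length}M"
                a.flag = (16 if iv.strand == "-" else 0) | (256 if i > 0 else 0)
                a.query_sequence = "*"
                if score is not None:
                    a.set_tag("AS", int(score))
                out.write(a)


def read_hits_tsv(path: str | Path) -> list[AlignmentRecord]:
    """Internal hit-list format: read_id, chrom, start, end, strand, score,
    mapq per line ('.' for missing score/mapq); testable without an aligner."""
    hits: dict[str, list[tuple[GenomicInterval, int | None, int | None]]] = {}
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            rid, chrom, start, end, strand, score, mapq = s.split("\t")
            hits.setdefault(rid, []).append(
                (
                    GenomicInterval(chrom, int(start), int(end), strand),
                    None if score == "." else int(score),
                    None if mapq == "." else int(mapq),
                )
            )
    return [AlignmentRecord(rid, tuple(h)) for rid, h in sorted(hits.items())]


def write_hits_tsv(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#read_id\tchrom\tstart\tend\tstrand\tscore\tmapq\n")
        for rec in records:
            for iv, score, mapq in rec.hits:
                fh.write(
                    f"{rec.read_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                    f"{'.' if score is None else score}\t{'.' if mapq is None else mapq}\n"
                )


def write_assigned_bed(assigned: Iterable[AssignedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in assigned:
            iv = r.chosen
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.read_id}\t0\t{iv.strand}\n")
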