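"""Strand-aware signal profiles: anchor meta-profiles, per-copy matrices,
and consensus-element coverage/ratio profiles.

Anchors (e.g. peak summits) contribute the window of signal around them,
minus-strand anchors reversed, so the averaged profile reads 5'-to-3'.
Consensus profiles bin reads mapped to one representative full-length
element (the way family-level LINE-1 5' UTR enrichment is shown), with an
optional input library and a pseudocount-protected IP/input ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_annotation import GenomicInterval, TECopy
from .read_assignment import AssignedRead

__all__ = [
    "SignalTrack",
    "MetaProfile",
    "ConsensusProfile",
    "anchor_profile",
    "consensus_profile",
    "per_copy_signal",
    "methylation_profile",
]


@dataclass
class SignalTrack:
    """Per-chromosome binned non-negative signal (e.g. read coverage)."""

    values: dict[str, np.ndarray]
    binsize: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.binsize < 1:
            raise ValueError("binsize must be >= 1")
        for chrom, v in self.values.items():
            if np.any(np.asarray(v) < 0):
                raise ValueError(f"{chrom}: negative signal values")

    @classmethod
    def from_coverage(
        cls, coverage: Mapping[str, np.ndarray], binsize: int, label: str = ""
    ) -> "SignalTrack":
        return cls({c: np.asarray(v, dtype=float) for c, v in coverage.items()}, binsize, label)

    def value_at(self, chrom: str, pos: int) -> float:
        vec = self.values[chrom]
        return float(vec[min(pos // self.binsize, len(vec) - 1)])

    def library_size(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def write_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.values):
                for b, v in enumerate(self.values[chrom]):
                    if v != 0:
                        fh.write(
                            f"{chrom}\t{b * self.binsize}\t{(b + 1) * self.binsize}\t{v:g}\n"
                        )


@dataclass
class MetaProfile:
    bins: int
    window: int  # bp each side of the anchor
    mean_signal: np.ndarray  # length == bins
    n_anchors: int
    n_dropped: int = 0  # anchors lost to chromosome edges

    def bin_centers(self) -> np.ndarray:
        w = 2 * self.window / self.bins
        return -self.window + (np.arange(self.bins) + 0.5) * w

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_center": self.bin_centers(), "mean_signal": self.mean_signal}
        )


@dataclass
class ConsensusProfile:
    element_name: str
    binsize: int
    ip_coverage: np.ndarray
    input_coverage: np.ndarray | None = None
    ratio: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d: dict[str, np.ndarray] = {
            "bin_start": np.arange(len(self.ip_coverage)) * self.binsize,
            "ip": self.ip_coverage,
        }
        if self.input_coverage is not None:
            d["input"] = self.input_coverage
            d["ratio"] = self.ratio
        return pd.DataFrame(d)


def anchor_profile(
    track: SignalTrack,
    anchors: Sequence[tuple[str, int, str]],
    window: int = 4000,
    bins: int = 80,
) -> MetaProfile:
    """Mean signal in ``bins`` bins across ``[-window, +window)`` around each
    anchor ``(chrom, position, strand)``.

    Minus-strand anchors contribute their window reversed, so the profile is
    oriented 5'-to-3'.  Anchors whose window leaves the chromosome are
    dropped (and counted); all anchors dropped is an error.
    """
    if window < 1 or bins < 1 or (2 * window) % bins != 0:
        raise ValueError("need window >= 1 and bins dividing 2*window")
    per_bin = 2 * window // bins
    acc = np.zeros(bins, dtype=float)
    used = dropped = 0
    for chrom, pos, strand in anchors:
        vec = track.values.get(chrom)
        chrom_len = len(vec) * track.binsize if vec is not None else 0
        if vec is None or pos - window < 0 or pos + window > chrom_len:
            dropped += 1
            continue
        bp_positions = np.arange(pos - window, pos + window)
        vals = vec[bp_positions // track.binsize]
        # bin in genomic orientation, then mirror the bins for minus-strand
        # anchors: the per-bin means are computed in one canonical order, so
        # flipping every strand reverses the profile exactly
        binned = vals.reshape(bins, per_bin).mean(axis=1)
        acc += binned[::-1] if strand == "-" else binned
        used += 1
    if used == 0:
        raise ValueError("no usable anchors (all out of bounds or on missing chromosomes)")
    return MetaProfile(bins, window, acc / used, used, dropped)


def consensus_profile(
    reads: Sequence[AssignedRead] | Sequence[GenomicInterval],
    consensus_length: int,
    element_name: str = "consensus",
    input_reads: Sequence[AssignedRead] | Sequence[GenomicInterval] | None = None,
    binsize: int = 100,
    pseudocount: float = 0.5,
) -> ConsensusProfile:
    """Binned midpoint coverage of reads along a consensus element.

    Each read counts once, in the bin of its midpoint, so total coverage
    equals the read count.  With an input library, ``ratio = (IP + eps) /
    (input_scaled + eps)`` per bin, where input is scaled to the IP library
    size and ``eps`` is the pseudocount (default 0.5 reads/bin).
    """
    if consensus_length < 1:
        raise ValueError("consensus length must be >= 1")
    nbins = -(-consensus_length // binsize)

    def _cover(rds) -> np.ndarray:
        cov = np.zeros(nbins, dtype=float)
        for r in rds:
            iv = r.chosen if isinstance(r, AssignedRead) else r
            cov[min(iv.midpoint // binsize, nbins - 1)] += 1
        return cov

    ip = _cover(reads)
    if input_reads is None:
        return ConsensusProfile(element_name, binsize, ip)
    inp = _cover(input_reads)
    scale = ip.sum() / inp.sum() if inp.sum() > 0 else 1.0
    ratio = (ip + pseudocount) / (inp * scale + pseudocount)
    return ConsensusProfile(element_name, binsize, ip, inp, ratio)


def per_copy_signal(
    tracks: Sequence[SignalTrack],
    copies: Sequence[TECopy],
    sort_by: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Length-normalised mean signal of each track over each copy.

    Returns a (copies x tracks) frame plus the row order sorting the primary
    track (``sort_by``) descending, stable on ties.  Copies extending past a
    track's coverage get a missing value, not 0.
    """
    if not copies:
        raise ValueError("copies must be non-empty")
    mat = np.full((len(copies), len(tracks)), np.nan)
    for j, track in enumerate(tracks):
        for i, copy in enumerate(copies):
            vec = track.values.get(copy.interval.chrom)
            if vec is None:
                continue
            chrom_len = len(vec) * track.binsize
            if copy.interval.end > chrom_len:
                continue
            b0 = copy.interval.start // track.binsize
            b1 = -(-copy.interval.end // track.binsize)
            mat[i, j] = float(vec[b0:b1].mean())
    labels = [t.label or f"track{j}" for j, t in enumerate(tracks)]
    frame = pd.DataFrame(mat, columns=labels)
    frame.insert(0, "copy", [c.repeat_name for c in copies])
    key = mat[:, sort_by]
    order = np.argsort(-np.where(np.isnan(key), -np.inf, key), kind="stable")
    return frame, order


def methylation_profile(
    estimates: pd.DataFrame,
    consensus_length: int,
    binsize: int = 100,
) -> pd.DataFrame:
    """Coverage-weighted mean 5mC/5hmC per bin along a consensus element.

    ``estimates`` needs columns ``pos`` (0-based CpG position), ``level_5mC``,
    ``level_5hmC`` and ``n_reads``.  Bins containing no covered CpG are NaN.
    """
    nbins = -(-consensus_length // binsize)
    out = pd.DataFrame(
        {
            "bin_start": np.arange(nbins) * binsize,
            "mean_5mC": np.nan,
            "mean_5hmC": np.nan,
            "n_cpgs": 0,
        }
    )
    if len(estimates) == 0:
        return out
    df = estimates.copy()
    df["bin"] = np.minimum(df["pos"] // binsize, nbins - 1).astype(int)
    for b, grp in df.groupby("bin"):
        w = grp["n_reads"].to_numpy(dtype=float)
        if w.sum() <= 0:
            continue
        out.loc[b, "mean_5mC"] = float(np.average(grp["level_5mC"], weights=w))
        out.loc[b, "mean_5hmC"] = float(np.average(grp["level_5hmC"], weights=w))
        out.loc[b, "n_cpgs"] = len(grp)
    return out
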