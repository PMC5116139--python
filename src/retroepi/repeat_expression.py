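"""Repeat-class expression pooling, size-factor normalisation, and linking
TE copies to genes through promoter-interaction lists.

Reads assigned to TE copies are pooled per repeat class (a read spanning
copies of k distinct classes contributes 1/k to each by default).  Samples
are normalised with median-of-ratios size factors.  Promoter-capture
interaction pairs link enhancer-like TE copies to the genes whose promoters
they contact, so expression of genes wired to pluripotency-factor-bound
(NOS+) TEs can be compared with genes wired to unbound (NOS-) TEs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_annotation import GenomicInterval, TECopy, TEClassCatalog, overlap_flags
from .read_assignment import AssignedRead
from . import methylome

__all__ = [
    "InteractionSet",
    "read_interactions",
    "write_interactions",
    "interactions_from_bed_pair",
    "pool_repeat_counts",
    "size_factors",
    "normalize_counts",
    "link_tes_to_genes",
    "grouped_expression_compare",
]

UNASSIGNED = "unassigned"

_INTERACTION_COLUMNS = [
    "bait_chrom",
    "bait_start",
    "bait_end",
    "gene_id",
    "oe_chrom",
    "oe_start",
    "oe_end",
    "score",
    "reserved1",
    "reserved2",
]


@dataclass
class InteractionSet:
    """Promoter-interaction pairs: a promoter (bait) interval with its gene
    id, and the distal other-end interval it contacts."""

    pairs: pd.DataFrame  # columns _INTERACTION_COLUMNS, 0-based half-open

    def __post_init__(self) -> None:
        missing = set(_INTERACTION_COLUMNS[:7]) - set(self.pairs.columns)
        if missing:
            raise ValueError(f"interaction table lacks columns: {sorted(missing)}")
        if (self.pairs["gene_id"].astype(str) == "").any():
            raise ValueError("empty gene id in interaction table")

    def __len__(self) -> int:
        return len(self.pairs)

    def other_ends(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.oe_chrom, int(r.oe_start), int(r.oe_end))
            for r in self.pairs.itertuples()
        ]


def read_interactions(path: str | Path) -> InteractionSet:
    """Read the 10-column interaction TSV dialect (0-based half-open):
    promoter chrom/start/end/gene, other-end chrom/start/end, score, and two
    reserved columns."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    df = df.iloc[:, : len(_INTERACTION_COLUMNS)]
    df.columns = _INTERACTION_COLUMNS[: df.shape[1]]
    for col in _INTERACTION_COLUMNS[df.shape[1] :]:
        df[col] = 0
    return InteractionSet(df)


def write_interactions(interactions: InteractionSet, path: str | Path) -> None:
    interactions.pairs.to_csv(path, sep="\t", header=False, index=False)


def interactions_from_bed_pair(
    bait_bed: Sequence[GenomicInterval],
    gene_ids: Sequence[str],
    other_end_bed: Sequence[GenomicInterval],
    scores: Sequence[float] | None = None,
) -> InteractionSet:
    """Converter from generic paired-BED input to the interaction dialect."""
    if not (len(bait_bed) == len(gene_ids) == len(other_end_bed)):
        raise ValueError("bait, gene and other-end lists must have equal length")
    df = pd.DataFrame(
        {
            "bait_chrom": [b.chrom for b in bait_bed],
            "bait_start": [b.start for b in bait_bed],
            "bait_end": [b.end for b in bait_bed],
            "gene_id": list(gene_ids),
            "oe_chrom": [o.chrom for o in other_end_bed],
            "oe_start": [o.start for o in other_end_bed],
            "oe_end": [o.end for o in other_end_bed],
            "score": list(scores) if scores is not None else 0.0,
            "reserved1": 0,
            "reserved2": 0,
        }
    )
    return InteractionSet(df)


# ---------------------------------------------------------------------------
# Pooling and normalisation
# ---------------------------------------------------------------------------

def pool_repeat_counts(
    assigned_reads: Sequence[AssignedRead],
    te_copies: Sequence[TECopy],
    catalog: TEClassCatalog | None = None,
    ambiguous: str = "fractional",
) -> pd.Series:
    """Pool read counts per repeat class.

    A read overlapping copies of exactly one class counts 1 for that class;
    a read overlapping k > 1 classes counts 1/k each (``ambiguous=
    "fractional"``) or is dropped to ``unassigned`` (``ambiguous="drop"``);
    a read overlapping no copy lands in ``unassigned``.  The series conserves
    reads: values sum to ``len(assigned_reads)``.
    """
    if ambiguous not in ("fractional", "drop"):
        raise ValueError("ambiguous must be 'fractional' or 'drop'")

    def class_of(c: TECopy) -> str:
        if catalog is not None and c.repeat_name in catalog.names:
            return catalog.names[c.repeat_name][1]
        return c.te_class

    classes = sorted({class_of(c) for c in te_copies})
    counts = {cls: 0.0 for cls in classes}
    counts[UNASSIGNED] = 0.0
    read_ivs = [r.chosen for r in assigned_reads]
    flags_by_class = {
        cls: overlap_flags(read_ivs, [c.interval for c in te_copies if class_of(c) == cls])
        for cls in classes
    }
    for i in range(len(assigned_reads)):
        hit = [cls for cls in classes if flags_by_class[cls][i]]
        if not hit:
            counts[UNASSIGNED] += 1.0
        elif len(hit) == 1 or ambiguous == "fractional":
            for cls in hit:
                counts[cls] += 1.0 / len(hit)
        else:
            counts[UNASSIGNED] += 1.0
    return pd.Series(counts, name="count")


def size_factors(table: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each feature with positive counts in every sample, compute the ratio
    of each sample's count to the feature's geometric mean; the per-sample
    median of those ratios is its size factor.
    """
    counts = table.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has positive counts in every sample; add pseudo-counts "
            "or more features"
        )
    sub = counts[positive]
    geo = np.exp(np.mean(np.log(sub), axis=1))
    factors = np.median(sub / geo[:, None], axis=0)
    return pd.Series(factors, index=table.columns, name="size_factor")


def normalize_counts(table: pd.DataFrame) -> pd.DataFrame:
    return table / size_factors(table)


# ---------------------------------------------------------------------------
# Interaction linking and group comparison
# ---------------------------------------------------------------------------

def link_tes_to_genes(
    interactions: InteractionSet,
    copies: Sequence[TECopy],
) -> dict[int, set[str]]:
    """Map copy index -> genes whose promoters contact an other-end interval
    the copy overlaps.  Monotone in the interaction list (adding pairs never
    removes links)."""
    links: dict[int, set[str]] = {i: set() for i in range(len(copies))}
    copy_ivs = [c.interval for c in copies]
    for row in interactions.pairs.itertuples():
        oe = GenomicInterval(row.oe_chrom, int(row.oe_start), int(row.oe_end))
        flags = overlap_flags(copy_ivs, [oe])
        for i in np.nonzero(flags)[0]:
            links[int(i)].add(str(row.gene_id))
    return links


def grouped_expression_compare(
    normalized: pd.DataFrame,
    genes_pos: set[str],
    genes_neg: set[str],
    test: str = "t",
    exclusive: bool = False,
) -> dict[str, float]:
    """Compare mean normalised expression of genes linked to bound (NOS+)
    TEs vs genes linked to unbound (NOS-) TEs.

    A gene linked to both groups counts as NOS+ by default (``exclusive``
    drops it from both).  Delegates the test to
    :func:`retroepi.methylome.compare_groups`.
    """
    both = genes_pos & genes_neg
    if exclusive:
        genes_pos = genes_pos - both
        genes_neg = genes_neg - both
    else:
        genes_neg = genes_neg - both
    expr_pos = normalized.loc[sorted(genes_pos & set(normalized.index))].mean(axis=1)
    expr_neg = normalized.loc[sorted(genes_neg & set(normalized.index))].mean(axis=1)
    if expr_pos.empty or expr_neg.empty:
        raise ValueError("a gene group is empty after linking")
    stat, p = methylome.compare_groups(expr_pos.to_numpy(), expr_neg.to_numpy(), test=test)
    return {
        "n_pos": float(len(expr_pos)),
        "n_neg": float(len(expr_neg)),
        "mean_pos": float(expr_pos.mean()),
        "mean_neg": float(expr_neg.mean()),
        "statistic": stat,
        "p": p,
    }
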