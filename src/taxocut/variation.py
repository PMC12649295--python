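"""Intra-group similarity statistics and taxon distribution tables.

For every taxonomic group with at least two sequences, the minimum and
median of its within-group pairwise similarities describe how variable the
marker is inside that group; the medians of those statistics across groups
summarise a whole rank.  Pairs absent from the sparse matrix (dropped at
build time) are valued at the matrix floor, which is all the information
retained about them.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Sequence

import pandas as pd

from .similarity import SimilarityMatrix
from .taxonomy import RANKS, RankPartition, TaxonomyTable


@dataclass(frozen=True)
class GroupVariation:
    """Within-group similarity minimum and median for one taxon (n >= 2)."""

    rank: str
    taxon: str
    n: int
    min_sim: float
    median_sim: float


@dataclass(frozen=True)
class RankVariationSummary:
    """Medians across groups of the per-group min and median similarity."""

    rank: str
    median_of_min: float
    median_of_median: float
    groups_evaluated: int


def group_variation(mat: SimilarityMatrix, truth: RankPartition) -> list[GroupVariation]:
    """Min/median within-group similarity for every group of >= 2 sequences.

    All C(n, 2) within-group pairs contribute; pairs missing from the
    sparse matrix count as the floor value.
    """
    if not truth.groups:
        raise ValueError("empty partition")
    out: list[GroupVariation] = []
    for taxon in sorted(truth.groups):
        members = sorted(truth.groups[taxon])
        if len(members) < 2:
            continue
        values: list[float] = []
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                values.append(mat.get(a, b, default=mat.floor))
        out.append(GroupVariation(rank=truth.rank, taxon=taxon, n=len(members),
                                  min_sim=min(values), median_sim=median(values)))
    return out


def rank_summary(variations: Iterable[GroupVariation], rank: str) -> RankVariationSummary:
    """Summarise one rank: medians across groups of min_sim and median_sim."""
    at_rank = [v for v in variations if v.rank == rank]
    if not at_rank:
        raise ValueError(f"no group variation records at rank {rank!r}")
    return RankVariationSummary(
        rank=rank,
        median_of_min=median(v.min_sim for v in at_rank),
        median_of_median=median(v.median_sim for v in at_rank),
        groups_evaluated=len(at_rank),
    )


def variation_table(mat: SimilarityMatrix, tax: TaxonomyTable,
                    ranks: Sequence[str] = ("species", "genus", "family",
                                            "order", "class")) -> pd.DataFrame:
    """Rank-by-rank variation summary over the matrix ids (one row per rank)."""
    from .taxonomy import partition_at_rank

    ids = [i for i in mat.ids if i in tax]
    rows = []
    for rank in ranks:
        part = partition_at_rank(tax, ids, rank)
        variations = group_variation(mat, part)
        if not variations:
            continue
        summary = rank_summary(variations, rank)
        rows.append({"rank": rank, "min_sim": summary.median_of_min,
                     "median_sim": summary.median_of_median,
                     "groups": summary.groups_evaluated})
    return pd.DataFrame(rows)


def taxon_distribution(tax: TaxonomyTable, ids: Iterable[str]) -> pd.DataFrame:
    """Sequence and subgroup counts per taxon per rank.

    Columns: rank, taxon, seq_no (sequences annotated with the taxon) and
    subgroup_no (distinct groups at the next lower rank inside the taxon).
    Use top_share() for the dominance of the largest taxa at a rank.
    """
    from .taxonomy import partition_at_rank

    ids = set(ids)
    unknown = ids - set(tax.rows)
    if unknown:
        raise KeyError(f"ids not in taxonomy table: {sorted(unknown)[:5]}")
    rows = []
    for idx, rank in enumerate(RANKS):
        part = partition_at_rank(tax, ids, rank)
        child_rank = RANKS[idx - 1] if idx > 0 else None
        for taxon in sorted(part.groups):
            members = part.groups[taxon]
            if child_rank is not None:
                child = partition_at_rank(tax, members, child_rank)
                n_child = child.n_groups()
            else:
                n_child = 0
            rows.append({"rank": rank, "taxon": taxon,
                         "seq_no": len(members), "subgroup_no": n_child})
    return pd.DataFrame(rows)


def top_share(distribution: pd.DataFrame, rank: str, k: int = 5) -> float:
    """Fraction of rank-annotated sequences held by the k largest taxa."""
    at_rank = distribution[distribution["rank"] == rank]
    if at_rank.empty:
        raise ValueError(f"no taxa at rank {rank!r}")
    counts = at_rank["seq_no"].sort_values(ascending=False)
    return float(counts.head(k).sum() / counts.sum())
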