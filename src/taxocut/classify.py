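"""Rank-wise classification of query sequences with taxon-specific cutoffs.

A query (for example a metabarcoding ASV) is aligned against a reference
barcode set; its best hit proposes a full taxonomy.  The assignment is then
gated rank by rank: walking from species up to phylum, the hit's similarity
must reach the cutoff applicable at that rank — looked up for the hit's
taxon via the highest-confidence ancestor-chain rule — and the accepted
taxonomy is truncated at the deepest rank that passes.  Classifications
against several reference sets are merged per query, preferring the deeper
assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .predict import GLOBAL_TAXON, CutoffEntry, CutoffTable
from .similarity import AlignmentParams, pair_similarity
from .taxonomy import NAMED_RANKS, BarcodeRecord, TaxonomyTable

#: classification walks these ranks deepest-first
CLASSIFIED_RANKS: tuple[str, ...] = tuple(NAMED_RANKS)  # species .. phylum


def rank_depth(rank: str | None) -> int:
    """Smaller is deeper; None (unclassified) is the shallowest."""
    if rank is None:
        return len(CLASSIFIED_RANKS)
    return CLASSIFIED_RANKS.index(rank)


@dataclass(frozen=True)
class Hit:
    """Best reference match for one query."""

    query_id: str
    ref_id: str
    score: float
    ref_taxonomy: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class ClassificationResult:
    """Accepted taxonomy of one query, truncated at the accepted rank."""

    query_id: str
    names: Mapping[str, str]        # rank -> name; blank below accepted_rank
    accepted_rank: str | None
    score: float
    cutoff_used: CutoffEntry | None = None
    source: str = ""
    ref_id: str = ""


def best_hit(query: BarcodeRecord, refs: Sequence[BarcodeRecord],
             params: AlignmentParams,
             tax: TaxonomyTable | None = None) -> Hit:
    """Reference with the highest adjusted similarity to the query.

    Ties go to the lexicographically smallest reference id.  A query with
    no positive-scoring alignment yields a Hit with score 0 and empty
    taxonomy.
    """
    if not refs:
        raise ValueError("reference set is empty")
    best_score = -1.0
    best_ref: BarcodeRecord | None = None
    for ref in sorted(refs, key=lambda r: r.id):
        pair = pair_similarity(query, ref, params)
        if pair.score > best_score:
            best_score = pair.score
            best_ref = ref
    if best_ref is None or best_score <= 0.0:
        return Hit(query.id, "", 0.0, {})
    taxonomy: dict[str, str] = {}
    if tax is not None and best_ref.id in tax:
        taxonomy = {rank: tax.name_at(best_ref.id, rank) for rank in CLASSIFIED_RANKS}
    return Hit(query.id, best_ref.id, best_score, taxonomy)


def _cutoff_for_rank(hit: Hit, level_rank: str,
                     cutoffs: CutoffTable) -> CutoffEntry | None:
    """Applicable cutoff at one rank: highest confidence along the chain of
    the hit's taxa at the ranks above, falling back to the global entry."""
    start = CLASSIFIED_RANKS.index(level_rank)
    candidates: list[CutoffEntry] = []
    for higher in CLASSIFIED_RANKS[start + 1:]:
        taxon = hit.ref_taxonomy.get(higher, "")
        if not taxon:
            continue
        entry = cutoffs.get(level_rank, taxon, higher) or cutoffs.get(level_rank, taxon)
        if entry is not None:
            candidates.append(entry)
    global_entry = cutoffs.get(level_rank, GLOBAL_TAXON)
    if global_entry is not None:
        candidates.append(global_entry)
    if not candidates:
        return None
    return max(candidates, key=lambda e: e.confidence)  # ties -> most specific


def assign(hit: Hit, cutoffs: CutoffTable, tax: TaxonomyTable | None = None,
           source: str = "") -> ClassificationResult:
    """Gate the hit's taxonomy rank by rank against the cutoff table.

    Walks species -> phylum and accepts the deepest rank whose applicable
    cutoff the hit's score reaches; names below the accepted rank are
    blanked.  A zero-score hit (or one passing no rank) is unclassified.
    """
    blank = {rank: "" for rank in CLASSIFIED_RANKS}
    if hit.score <= 0.0 or not hit.ref_taxonomy:
        return ClassificationResult(hit.query_id, blank, None, hit.score,
                                    source=source, ref_id=hit.ref_id)
    for rank in CLASSIFIED_RANKS:
        entry = _cutoff_for_rank(hit, rank, cutoffs)
        if entry is None:
            continue
        if hit.score >= entry.cutoff:
            depth = CLASSIFIED_RANKS.index(rank)
            names = {
                r: (hit.ref_taxonomy.get(r, "") if i >= depth else "")
                for i, r in enumerate(CLASSIFIED_RANKS)
            }
            return ClassificationResult(hit.query_id, names, rank, hit.score,
                                        cutoff_used=entry, source=source,
                                        ref_id=hit.ref_id)
    return ClassificationResult(hit.query_id, blank, None, hit.score,
                                source=source, ref_id=hit.ref_id)


def classify_queries(queries: Sequence[BarcodeRecord],
                     refs: Sequence[BarcodeRecord], tax: TaxonomyTable,
                     cutoffs: CutoffTable, params: AlignmentParams,
                     source: str = "") -> list[ClassificationResult]:
    """best_hit + assign for every query against one reference set."""
    results = []
    for query in queries:
        hit = best_hit(query, refs, params, tax)
        results.append(assign(hit, cutoffs, tax, source=source))
    return results


def merge_results(a: Iterable[ClassificationResult],
                  b: Iterable[ClassificationResult]) -> list[ClassificationResult]:
    """Merge per-query classifications from two reference sets.

    Per query the deeper accepted rank wins; at equal depth the higher
    score; still equal, the result whose source label sorts first.  Queries
    present in only one input are kept as-is.
    """
    def better(x: ClassificationResult, y: ClassificationResult) -> ClassificationResult:
        kx = (rank_depth(x.accepted_rank), -x.score, x.source)
        ky = (rank_depth(y.accepted_rank), -y.score, y.source)
        return x if kx <= ky else y

    merged: dict[str, ClassificationResult] = {}
    for result in list(a) + list(b):
        if result.query_id in merged:
            merged[result.query_id] = better(merged[result.query_id], result)
        else:
            merged[result.query_id] = result
    return list(merged.values())


def write_classification(results: Sequence[ClassificationResult],
                         path: str | Path) -> None:
    """Write classification results as TSV (one row per query)."""
    cols = ["query", "ref", "score", "cutoff", "accepted_rank",
            *CLASSIFIED_RANKS, "source"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in results:
            cutoff = f"{r.cutoff_used.cutoff:.3f}" if r.cutoff_used else ""
            fh.write("\t".join([
                r.query_id, r.ref_id, f"{r.score:.4f}", cutoff,
                r.accepted_rank or "unclassified",
                *[r.names.get(rank, "") for rank in CLASSIFIED_RANKS],
                r.source,
            ]) + "\n")


def abundance_table(results: Sequence[ClassificationResult], rank: str):
    """Per-taxon query counts at one rank (unclassified rows excluded)."""
    import pandas as pd

    counts: dict[str, int] = {}
    for r in results:
        name = r.names.get(rank, "")
        if name:
            counts[name] = counts.get(name, 0) + 1
    frame = pd.DataFrame(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
                         columns=["taxon", "count"])
    frame.insert(0, "rank", rank)
    return frame
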