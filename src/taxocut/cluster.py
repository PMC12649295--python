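"""Threshold clustering, the clustering F-measure, and species complexes.

Clustering at a similarity threshold t is single linkage: the clusters are
the connected components of the graph whose edges are the pairs scoring at
least t.  The clustering F-measure scores a clustering against a taxonomy
ground truth: each ground-truth class takes the best harmonic mean of
precision and recall over all clusters, and classes are weighted by size.

Species whose sequences co-cluster at 100% similarity cannot be told apart
by the marker at all; such sets are "indistinguishable species complexes"
and can be reduced to one representative species before cutoff prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .similarity import SimilarityMatrix
from .taxonomy import BarcodeRecord, RankPartition, TaxonomyTable


@dataclass(frozen=True)
class Clustering:
    """Single-linkage clustering at one threshold.

    Cluster ids are the lexicographically smallest member, which makes the
    clustering deterministic and stable under reordering.
    """

    threshold: float
    clusters: Mapping[str, frozenset[str]]

    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self) -> dict[str, str]:
        return {member: cid for cid, members in self.clusters.items()
                for member in members}


@dataclass(frozen=True)
class FMeasureReport:
    """Overall clustering F-measure and the per-class best F values."""

    value: float
    per_class: Mapping[str, tuple[int, float]]  # name -> (class size, best F)


@dataclass(frozen=True)
class SpeciesComplex:
    """Set of species indistinguishable by the marker (co-cluster at 1.0)."""

    members: frozenset[str]
    representative: str

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a species complex needs at least 2 members")
        if self.representative not in self.members:
            raise ValueError("representative must be a member of the complex")


def cluster_at(mat: SimilarityMatrix, ids: Iterable[str], t: float) -> Clustering:
    """Connected components of the >= t similarity graph over ``ids``."""
    ids = set(ids)
    if not ids:
        raise ValueError("cannot cluster an empty id set")
    missing = ids - set(mat.ids)
    if missing:
        raise KeyError(f"ids not in matrix: {sorted(missing)[:5]}")
    if t < mat.floor and t < 1.0:
        warnings.warn(
            f"threshold {t} is below the matrix floor {mat.floor}; pairs "
            "dropped at build time cannot contribute edges", stacklevel=2)
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    graph.add_edges_from(
        (a, b) for a, b, score in mat.edges(within=ids) if score >= t)
    clusters = {min(comp): frozenset(comp)
                for comp in nx.connected_components(graph)}
    return Clustering(threshold=t, clusters=clusters)


def fmeasure_from_labels(cluster_labels: Mapping[str, str],
                         class_labels: Mapping[str, str]) -> FMeasureReport:
    """Clustering F-measure from id -> cluster and id -> class maps.

    Evaluated over the ids present in ``class_labels`` (the ground truth);
    every such id must be clustered.  For class k of size n_k and cluster j
    of size n_j with overlap n_kj: P = n_kj/n_j, R = n_kj/n_k, and the class
    score is the maximum harmonic mean over j.  The overall value weights
    classes by n_k / n.
    """
    n = len(class_labels)
    if n == 0:
        raise ValueError("empty ground truth")
    cluster_sizes: dict[str, int] = {}
    overlap: dict[tuple[str, str], int] = {}
    class_sizes: dict[str, int] = {}
    for seq_id, cls in class_labels.items():
        cj = cluster_labels[seq_id]
        cluster_sizes[cj] = cluster_sizes.get(cj, 0) + 1
        overlap[(cls, cj)] = overlap.get((cls, cj), 0) + 1
        class_sizes[cls] = class_sizes.get(cls, 0) + 1
    best: dict[str, float] = {cls: 0.0 for cls in class_sizes}
    for (cls, cj), n_kj in overlap.items():
        f = 2.0 * n_kj / (cluster_sizes[cj] + class_sizes[cls])
        if f > best[cls]:
            best[cls] = f
    value = min(1.0, sum(class_sizes[cls] / n * best[cls] for cls in class_sizes))
    per_class = {cls: (class_sizes[cls], best[cls]) for cls in class_sizes}
    return FMeasureReport(value=value, per_class=per_class)


def clustering_fmeasure(clustering: Clustering, truth: RankPartition) -> FMeasureReport:
    """Score a clustering against a rank partition (covered ids only)."""
    if not truth.covered:
        raise ValueError("empty ground truth partition")
    cluster_labels = clustering.labels()
    missing = truth.covered - set(cluster_labels)
    if missing:
        raise KeyError(f"covered ids absent from clustering: {sorted(missing)[:5]}")
    # restrict cluster sizes to covered ids by relabelling on the subset
    restricted = {i: cluster_labels[i] for i in truth.covered}
    return fmeasure_from_labels(restricted, truth.labels())


def indistinguishable_complexes(mat: SimilarityMatrix,
                                species: RankPartition) -> list[SpeciesComplex]:
    """Species complexes: species co-clustering at 100% similarity.

    Clusters the species-annotated ids at threshold 1.0; every cluster whose
    sequences span two or more species yields a complex.  Complexes sharing
    a species (possible when a species' sequences split across clusters) are
    unioned.  Returned sorted by representative for determinism.
    """
    if species.rank != "species":
        raise ValueError("expected the species-rank partition")
    if not species.covered:
        return []
    clustering = cluster_at(mat, species.covered, 1.0)
    labels = species.labels()
    merged: list[set[str]] = []
    for members in clustering.clusters.values():
        names = {labels[i] for i in members}
        if len(names) < 2:
            continue
        absorbed = [grp for grp in merged if grp & names]
        for grp in absorbed:
            names |= grp
            merged.remove(grp)
        merged.append(names)
    return sorted(
        (SpeciesComplex(members=frozenset(grp), representative=min(grp))
         for grp in merged),
        key=lambda c: c.representative)


def deduplicate_species(records: Sequence[BarcodeRecord], tax: TaxonomyTable,
                        complexes: Iterable[SpeciesComplex],
                        representatives: Mapping[frozenset, str] | None = None,
                        ) -> list[BarcodeRecord]:
    """Drop sequences of all complex members except one representative.

    The representative defaults to the alphabetically first species of each
    complex; ``representatives`` (complex members -> species) overrides.
    Records outside any complex are retained unchanged, in order.
    """
    drop: set[str] = set()
    for cpx in complexes:
        rep = cpx.representative
        if representatives and cpx.members in representatives:
            rep = representatives[cpx.members]
            if rep not in cpx.members:
                raise ValueError(f"override {rep!r} not in complex {sorted(cpx.members)}")
        drop |= cpx.members - {rep}
    return [rec for rec in records
            if tax.name_at(rec.id, "species") not in drop]
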