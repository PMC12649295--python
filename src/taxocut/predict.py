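"""Similarity-cutoff prediction by threshold sweep.

The resolving power of a marker for delineating taxa at a rank is the
highest clustering F-measure attainable by any similarity threshold; the
similarity cutoff is the threshold attaining it.  A *global* cutoff is
predicted over a whole dataset, a *local* cutoff within one taxonomic group
(for example, species-level cutoffs within each genus).  Groups that are
too small, have too few subgroups, or are dominated by a single subgroup
give unreliable predictions and are filtered out.  When a taxon's own
prediction has low confidence, the *best* cutoff falls back to the entry on
its ancestor chain with the highest confidence.

The estimation is exposed both as plain functions (sweep_predict,
predict_local, best_cutoff) and as a CutoffModel whose fit() returns a
CutoffResults object carrying the entries, curves and a summary table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from decimal import Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cluster import fmeasure_from_labels
from .similarity import AlignmentParams, SimilarityMatrix, build_matrix
from .taxonomy import (NAMED_RANKS, BarcodeRecord, RankPartition,
                       TaxonomyTable, partition_at_rank)

logger = logging.getLogger(__name__)

GLOBAL_TAXON = "All"


@dataclass(frozen=True)
class SweepConfig:
    """Threshold grid and ground-truth rank for one sweep.

    The grid is {start, start+step, ..., end}; its resolution bounds the
    precision of every predicted cutoff.  Species-level sweeps default to
    0.70-1.00; at genus rank and above cutoffs can drop well below 0.7, so
    for_level() widens the start to 0.50 there.
    """

    start: float = 0.70
    end: float = 1.00
    step: float = 0.001
    level_rank: str = "species"
    scope_rank: str | None = None
    scope_taxon: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("start must be < end")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.level_rank not in NAMED_RANKS:
            raise ValueError(f"unknown rank {self.level_rank!r}")

    @classmethod
    def for_level(cls, level_rank: str, **overrides) -> "SweepConfig":
        start = 0.70 if level_rank == "species" else 0.50
        kwargs = {"start": start, "level_rank": level_rank, **overrides}
        return cls(**kwargs)

    def grid(self) -> list[float]:
        decimals = max(0, -Decimal(str(self.step)).as_tuple().exponent)
        n = int(round((self.end - self.start) / self.step))
        points = [round(self.start + i * self.step, decimals) for i in range(n + 1)]
        if points[-1] > self.end + 1e-12:
            points.pop()
        return points


@dataclass(frozen=True)
class EligibilityFilter:
    """Group filters for local prediction.

    A scope group is eligible when it has more than ``min_seq`` sequences
    (strict), at least ``min_groups`` distinct level-rank groups, and its
    largest level-rank group holds at most ``max_dominance`` of the
    sequences (groups dominated by a single subgroup are excluded).
    """

    min_seq: int = 30
    min_groups: int = 5
    max_dominance: float = 0.70

    def __post_init__(self) -> None:
        if self.min_seq <= 0 or self.min_groups <= 0 or self.max_dominance <= 0:
            raise ValueError("all eligibility thresholds must be positive")

    def check(self, n_seq: int, n_groups: int, dominance: float) -> str | None:
        """None when eligible, else the failed criterion."""
        if n_seq <= self.min_seq:
            return f"sequence count {n_seq} not > {self.min_seq}"
        if n_groups < self.min_groups:
            return f"group count {n_groups} < {self.min_groups}"
        if dominance > self.max_dominance:
            return f"dominant group holds {dominance:.0%} > {self.max_dominance:.0%}"
        return None


@dataclass(frozen=True)
class CutoffEntry:
    """One predicted cutoff with its confidence (the F-measure attained)."""

    rank: str                       # level rank being delineated
    taxon: str                      # scope taxon, "All" for global
    cutoff: float
    confidence: float
    seq_no: int
    group_no: int
    scope_rank: str | None = None   # rank of the scope taxon, None for global
    fallback_from: str | None = None

    def as_dict(self) -> dict:
        return {
            "cut-off": self.cutoff,
            "confidence": self.confidence,
            "sequence number": self.seq_no,
            "group number": self.group_no,
            "scope rank": self.scope_rank,
            "fallback from": self.fallback_from,
        }


@dataclass
class CutoffTable:
    """Predicted cutoffs keyed by (level rank, scope rank, scope taxon)."""

    entries: dict[tuple[str, str | None, str], CutoffEntry] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @staticmethod
    def _key(entry: CutoffEntry) -> tuple[str, str | None, str]:
        return (entry.rank, entry.scope_rank, entry.taxon)

    def add(self, entry: CutoffEntry) -> None:
        self.entries[self._key(entry)] = entry

    def get(self, level_rank: str, taxon: str,
            scope_rank: str | None = None) -> CutoffEntry | None:
        if scope_rank is not None:
            return self.entries.get((level_rank, scope_rank, taxon))
        for (rank, _, name), entry in self.entries.items():
            if rank == level_rank and name == taxon:
                return entry
        return None

    def at_level(self, level_rank: str) -> list[CutoffEntry]:
        return [e for (rank, _, _), e in self.entries.items() if rank == level_rank]

    def update(self, other: "CutoffTable") -> None:
        self.entries.update(other.entries)

    def to_json(self, path: str | Path | None = None) -> str:
        payload: dict = {"metadata": self.metadata}
        for entry in self.entries.values():
            payload.setdefault(entry.rank, {})[entry.taxon] = entry.as_dict()
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CutoffTable":
        """Read a cutoff table; accepts both {rank: {taxon: ...}} and
        {taxon: {rank: ...}} key orders."""
        if isinstance(source, Path):
            text = source.read_text()
        else:
            text = str(source)
            if "\n" not in text and len(text) < 4096 and Path(text).exists():
                text = Path(text).read_text()
        payload = json.loads(text)
        table = cls(metadata=payload.pop("metadata", {}))
        for outer, inner in payload.items():
            for key, raw in inner.items():
                rank, taxon = (outer, key) if outer in NAMED_RANKS else (key, outer)
                table.add(CutoffEntry(
                    rank=rank,
                    taxon=taxon,
                    cutoff=float(raw["cut-off"]),
                    confidence=float(raw["confidence"]),
                    seq_no=int(raw.get("sequence number", 0)),
                    group_no=int(raw.get("group number", 0)),
                    scope_rank=raw.get("scope rank"),
                    fallback_from=raw.get("fallback from"),
                ))
        return table


class _UnionFind:
    __slots__ = ("parent", "size")

    def __init__(self, items: Iterable[str]) -> None:
        self.parent = {i: i for i in items}
        self.size = {i: 1 for i in self.parent}

    def find(self, x: str) -> str:
        parent = self.parent
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]


def sweep_curve(mat: SimilarityMatrix, truth: RankPartition,
                grid: Sequence[float]) -> list[tuple[float, float]]:
    """F-measure at every grid threshold, via an incremental union-find.

    Thresholds are visited from high to low so each edge is merged exactly
    once; the returned curve is in ascending threshold order.
    """
    ids = truth.covered
    class_labels = truth.labels()
    edges = sorted(mat.edges(within=set(ids)), key=lambda e: -e[2])
    uf = _UnionFind(ids)
    curve: list[tuple[float, float]] = []
    idx = 0
    for t in sorted(grid, reverse=True):
        while idx < len(edges) and edges[idx][2] >= t:
            uf.union(edges[idx][0], edges[idx][1])
            idx += 1
        cluster_labels = {i: uf.find(i) for i in ids}
        report = fmeasure_from_labels(cluster_labels, class_labels)
        curve.append((t, report.value))
    curve.reverse()
    return curve


def sweep_predict(mat: SimilarityMatrix, truth: RankPartition,
                  cfg: SweepConfig) -> tuple[CutoffEntry, list[tuple[float, float]]]:
    """Predict the cutoff maximising the clustering F-measure.

    Returns the entry (cutoff = smallest grid threshold attaining the
    maximal F, confidence = that F) and the full (threshold, F) curve.
    """
    if not truth.covered:
        raise ValueError("empty ground truth")
    if truth.n_groups() == 1:
        raise ValueError("degenerate truth: all sequences share one group")
    grid = cfg.grid()
    curve = sweep_curve(mat, truth, grid)
    best_f = max(f for _, f in curve)
    cutoff = min(t for t, f in curve if f == best_f)
    entry = CutoffEntry(
        rank=cfg.level_rank,
        taxon=cfg.scope_taxon or GLOBAL_TAXON,
        cutoff=cutoff,
        confidence=best_f,
        seq_no=len(truth.covered),
        group_no=truth.n_groups(),
        scope_rank=cfg.scope_rank,
    )
    return entry, curve


def predict_global(mat: SimilarityMatrix, tax: TaxonomyTable,
                   cfg: SweepConfig) -> tuple[CutoffEntry, list[tuple[float, float]]]:
    """Global prediction over every matrix id annotated at the level rank."""
    truth = partition_at_rank(tax, [i for i in mat.ids if i in tax], cfg.level_rank)
    return sweep_predict(mat, truth, replace(cfg, scope_rank=None, scope_taxon=None))


def predict_local(mat: SimilarityMatrix, tax: TaxonomyTable, level_rank: str,
                  scope_rank: str, filt: EligibilityFilter | None = None,
                  cfg: SweepConfig | None = None,
                  ) -> tuple[CutoffTable, dict[str, list[tuple[float, float]]]]:
    """Predict one cutoff per eligible scope-rank group.

    For every group at ``scope_rank`` passing the eligibility filter, runs
    the sweep restricted to that group's sequences with ``level_rank``
    groups as ground truth.  Ineligible groups are skipped and logged with
    the failed criterion.  Returns the table and the per-taxon curves.
    """
    if NAMED_RANKS.index(scope_rank) <= NAMED_RANKS.index(level_rank):
        raise ValueError("scope_rank must be strictly above level_rank")
    filt = filt or EligibilityFilter()
    cfg = cfg or SweepConfig.for_level(level_rank)
    ids_in_tax = [i for i in mat.ids if i in tax]
    scope_part = partition_at_rank(tax, ids_in_tax, scope_rank)
    table = CutoffTable(metadata={"level": level_rank, "scope": scope_rank,
                                  "m": mat.m, "sweep": [cfg.start, cfg.end, cfg.step]})
    curves: dict[str, list[tuple[float, float]]] = {}
    for taxon in sorted(scope_part.groups):
        truth = partition_at_rank(tax, scope_part.groups[taxon], level_rank)
        n_seq = len(truth.covered)
        if n_seq == 0:
            logger.info("skipping %s %r: no sequences annotated at %s",
                        scope_rank, taxon, level_rank)
            continue
        dominance = max(len(g) for g in truth.groups.values()) / n_seq
        reason = filt.check(n_seq, truth.n_groups(), dominance)
        if reason is not None:
            logger.info("skipping %s %r: %s", scope_rank, taxon, reason)
            continue
        entry, curve = sweep_predict(
            mat, truth, replace(cfg, level_rank=level_rank,
                                scope_rank=scope_rank, scope_taxon=taxon))
        table.add(entry)
        curves[taxon] = curve
    return table, curves


def best_cutoff(taxon: str, level_rank: str, tables: CutoffTable,
                tax: TaxonomyTable, taxon_rank: str | None = None) -> CutoffEntry:
    """Cutoff for a taxon via the highest-confidence ancestor-chain entry.

    Candidates are the taxon's own entry (if predicted) and the entries of
    its ancestors up to the global one; the highest confidence wins, ties
    going to the most specific entry.  ``fallback_from`` records the source
    taxon whenever it is not the requested one.
    """
    if taxon_rank is None and taxon != GLOBAL_TAXON:
        taxon_rank = tax.rank_of(taxon)
    chain: list[tuple[str | None, str]] = []
    if taxon != GLOBAL_TAXON and taxon_rank is not None:
        chain.append((taxon_rank, taxon))
        chain.extend(tax.ancestors_of(taxon, taxon_rank))
    chain.append((None, GLOBAL_TAXON))
    candidates: list[CutoffEntry] = []
    for scope_rank, name in chain:
        entry = tables.get(level_rank, name, scope_rank)
        if entry is None and scope_rank is not None:
            entry = tables.get(level_rank, name)
        if entry is not None:
            candidates.append(entry)
    if not candidates:
        raise LookupError(
            f"no cutoff entry at level {level_rank!r} on the ancestor chain of {taxon!r}")
    chosen = max(candidates, key=lambda e: e.confidence)  # ties -> most specific
    if chosen.taxon != taxon:
        chosen = replace(chosen, fallback_from=chosen.taxon)
    return chosen


class CutoffModel:
    """Threshold-sweep estimator for similarity cutoffs.

    Built from a similarity matrix and a taxonomy table; fit() sweeps the
    threshold grid and returns a CutoffResults with the global entry and,
    when ``scope_rank`` is given, the local entries for every eligible
    group.
    """

    def __init__(self, matrix: SimilarityMatrix, taxonomy: TaxonomyTable,
                 level_rank: str = "species", config: SweepConfig | None = None,
                 marker: str = "") -> None:
        self.matrix = matrix
        self.taxonomy = taxonomy
        self.level_rank = level_rank
        self.config = config or SweepConfig.for_level(level_rank)
        self.marker = marker

    @classmethod
    def from_records(cls, records: Sequence[BarcodeRecord], taxonomy: TaxonomyTable,
                     params: AlignmentParams | None = None,
                     level_rank: str = "species",
                     config: SweepConfig | None = None) -> "CutoffModel":
        params = params or AlignmentParams()
        marker = records[0].marker if records else ""
        return cls(build_matrix(records, params), taxonomy,
                   level_rank=level_rank, config=config, marker=marker)

    def fit(self, scope_rank: str | None = None,
            eligibility: EligibilityFilter | None = None) -> "CutoffResults":
        entry, curve = predict_global(self.matrix, self.taxonomy,
                                      replace(self.config, level_rank=self.level_rank))
        table = CutoffTable(metadata={
            "marker": self.marker, "m": self.matrix.m,
            "level": self.level_rank,
            "sweep": [self.config.start, self.config.end, self.config.step],
        })
        table.add(entry)
        local_curves: dict[str, list[tuple[float, float]]] = {}
        if scope_rank is not None:
            local, local_curves = predict_local(
                self.matrix, self.taxonomy, self.level_rank, scope_rank,
                eligibility, self.config)
            table.update(local)
        return CutoffResults(model=self, table=table, global_entry=entry,
                             curve=curve, local_curves=local_curves)


@dataclass
class CutoffResults:
    """Fitted cutoffs: global entry, optional local entries, sweep curves."""

    model: CutoffModel
    table: CutoffTable
    global_entry: CutoffEntry
    curve: list[tuple[float, float]]
    local_curves: Mapping[str, list[tuple[float, float]]]

    @property
    def cutoff(self) -> float:
        return self.global_entry.cutoff

    @property
    def confidence(self) -> float:
        return self.global_entry.confidence

    def best(self, taxon: str) -> CutoffEntry:
        return best_cutoff(taxon, self.model.level_rank, self.table,
                           self.model.taxonomy)

    def as_frame(self) -> pd.DataFrame:
        rows = [{
            "level": e.rank, "scope_rank": e.scope_rank or "", "taxon": e.taxon,
            "cutoff": e.cutoff, "confidence": e.confidence,
            "seq_no": e.seq_no, "group_no": e.group_no,
        } for e in self.table.entries.values()]
        return pd.DataFrame(rows).sort_values(["level", "taxon"]).reset_index(drop=True)

    def summary(self) -> str:
        frame = self.as_frame()
        lines = [
            "Similarity cutoff prediction",
            f"  level rank: {self.model.level_rank}   "
            f"min alignment length m: {self.model.matrix.m}",
            f"  sweep grid: {self.model.config.start}-{self.model.config.end} "
            f"step {self.model.config.step}",
            f"  global cutoff: {self.cutoff:.3f}  "
            f"resolving power (F): {self.confidence:.4f}  "
            f"[{self.global_entry.seq_no} seqs / {self.global_entry.group_no} groups]",
            "",
            frame.to_string(index=False,
                            formatters={"cutoff": "{:.3f}".format,
                                        "confidence": "{:.4f}".format}),
        ]
        return "\n".join(lines)

    def curve_frame(self, taxon: str | None = None) -> pd.DataFrame:
        curve = self.curve if taxon is None else self.local_curves[taxon]
        return pd.DataFrame(curve, columns=["threshold", "fmeasure"])

    def plot(self, taxon: str | None = None, ax=None):
        """Plot the sweep curve with the predicted cutoff marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.curve_frame(taxon)
        ax.plot(frame["threshold"], frame["fmeasure"], lw=1.5)
        entry = self.global_entry if taxon is None else self.table.get(
            self.model.level_rank, taxon)
        ax.axvline(entry.cutoff, color="crimson", ls="--", lw=1)
        ax.set_xlabel("similarity threshold")
        ax.set_ylabel("clustering F-measure")
        ax.set_title(f"{taxon or GLOBAL_TAXON}: cutoff {entry.cutoff:.3f}, "
                     f"F {entry.confidence:.4f}")
        return ax
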