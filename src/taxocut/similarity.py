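"""Pairwise barcode similarity with a minimum-alignment-length adjustment.

The similarity between two barcodes is the percent identity ``s`` of their
best local alignment, taken as a fraction in [0, 1] with gap columns counted
in the denominator.  When the alignment spans fewer columns ``l`` than a
marker-specific minimum ``m`` (400 for full-length ITS/LSU, 50 for the short
ITS1/ITS2 sub-regions), the score is down-weighted to ``s * l / m``.  This
keeps short fragments from looking spuriously similar to everything.

Alignments are computed with Biopython's PairwiseAligner in local mode under
megablast-style scoring (match +2, mismatch -3, gap open 5, gap extend 2 by
default).  Ambiguity codes (N, R, Y, ...) score as mismatches.  Matrices of
precomputed searches in the standard 12-column tabular dialect can be
imported instead of realigning.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .taxonomy import BarcodeRecord

#: alphabet covered by the scoring matrix; anything else is rejected upstream
_ALPHABET = "ACGTURYSWKMBDHVN-"
_EXACT = frozenset("ACGTU")


@dataclass(frozen=True)
class AlignmentParams:
    """Alignment scoring and adjustment parameters.

    m is the minimum alignment length in bases; match/mismatch are the
    substitution scores and gap_open/gap_extend non-negative penalties.
    floor is the smallest adjusted score retained when building sparse
    matrices (pairs below it are dropped, bounding memory; every analysis
    here sweeps thresholds well above it).
    """

    m: int = 400
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    floor: float = 0.5

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("minimum alignment length m must be >= 1")
        if not 0.0 <= self.floor <= 1.0:
            raise ValueError("floor must lie in [0, 1]")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")


#: short-marker default (ITS1/ITS2-like fragments)
SHORT_MARKER_PARAMS = AlignmentParams(m=50)


@dataclass(frozen=True)
class ScoredPair:
    """Best-local-alignment identity s, alignment length l, adjusted score."""

    s: float
    l: int
    score: float


@functools.lru_cache(maxsize=8)
def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    n = len(_ALPHABET)
    data = np.full((n, n), float(params.mismatch))
    for i, ch in enumerate(_ALPHABET):
        if ch in _EXACT:
            data[i, i] = float(params.match)
    matrix = substitution_matrices.Array(alphabet=_ALPHABET, dims=2, data=data)
    aligner = Align.PairwiseAligner(
        mode="local",
        open_gap_score=-float(params.gap_open),
        extend_gap_score=-float(params.gap_extend),
    )
    aligner.substitution_matrix = matrix
    return aligner


def adjust_score(s: float, l: int, params: AlignmentParams | int) -> float:
    """Length-adjusted similarity: s when l >= m, else s * l / m.

    ``params`` may be an AlignmentParams or the bare minimum length m.
    Total function; the result is clamped to [0, 1].
    """
    m = params.m if isinstance(params, AlignmentParams) else int(params)
    if m < 1:
        raise ValueError("minimum alignment length m must be >= 1")
    if l <= 0:
        return 0.0
    value = s if l >= m else s * l / m
    return min(1.0, max(0.0, value))


def _identity_counts(alignment) -> tuple[int, int]:
    """(identities, alignment columns) of one local alignment."""
    counts = alignment.counts()
    identities = counts.identities
    columns = alignment.length
    return identities, columns


def pair_similarity(a: BarcodeRecord, b: BarcodeRecord,
                    params: AlignmentParams) -> ScoredPair:
    """Adjusted similarity of the best local alignment of two barcodes.

    Symmetric by construction: the two sequences are put in a canonical
    order before aligning, so pair_similarity(a, b) == pair_similarity(b, a)
    even when co-optimal alignments exist.
    """
    first, second = a.seq, b.seq
    if (second, b.id) < (first, a.id):
        first, second = second, first
    aligner = _aligner(params)
    alignments = aligner.align(first, second)
    try:
        best = alignments[0]
    except IndexError:
        return ScoredPair(0.0, 0, 0.0)
    if best.score <= 0:
        return ScoredPair(0.0, 0, 0.0)
    identities, columns = _identity_counts(best)
    if columns == 0:
        return ScoredPair(0.0, 0, 0.0)
    s = identities / columns
    return ScoredPair(s, columns, adjust_score(s, columns, params))


@dataclass
class SimilarityMatrix:
    """Sparse symmetric pairwise similarity scores in [0, 1].

    Entries are stored once per unordered pair under a sorted id tuple;
    self-similarity is defined as 1 and never stored.  Pairs scoring below
    ``floor`` are absent.  ``m`` records the minimum alignment length used.
    """

    ids: list[str]
    entries: dict[tuple[str, str], float] = field(default_factory=dict)
    m: int = 400
    floor: float = 0.5

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, score: float) -> None:
        if a == b:
            raise ValueError("self-similarity is implicit and never stored")
        self.entries[self._key(a, b)] = score

    def get(self, a: str, b: str, default: float | None = None) -> float | None:
        if a == b:
            return 1.0
        return self.entries.get(self._key(a, b), default)

    def edges(self, within: set[str] | None = None) -> Iterator[tuple[str, str, float]]:
        """Stored (id, id, score) triples, optionally restricted to a subset."""
        for (a, b), score in self.entries.items():
            if within is None or (a in within and b in within):
                yield a, b, score

    def subset(self, ids: Iterable[str]) -> "SimilarityMatrix":
        keep = set(ids)
        sub = SimilarityMatrix(ids=[i for i in self.ids if i in keep],
                               m=self.m, floor=self.floor)
        sub.entries = {k: v for k, v in self.entries.items()
                       if k[0] in keep and k[1] in keep}
        return sub

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# m={self.m}\tfloor={self.floor}\n")
            fh.write("id1\tid2\tscore\n")
            for (a, b), score in sorted(self.entries.items()):
                fh.write(f"{a}\t{b}\t{score:.6f}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, ids: Sequence[str] | None = None) -> "SimilarityMatrix":
        lines = Path(path).read_text().splitlines()
        if not lines or not lines[0].startswith("#"):
            raise ValueError(f"{path}: missing '# m=... floor=...' header line")
        meta = dict(tok.split("=", 1) for tok in lines[0][1:].split())
        mat = cls(ids=list(ids) if ids else [],
                  m=int(meta["m"]), floor=float(meta["floor"]))
        seen: list[str] = []
        seen_set: set[str] = set()
        for line in lines[2:]:
            if not line.strip():
                continue
            a, b, score = line.split("\t")
            mat.set(a, b, float(score))
            for i in (a, b):
                if i not in seen_set:
                    seen.append(i)
                    seen_set.add(i)
        if not mat.ids:
            mat.ids = seen
        return mat


def build_matrix(records: Sequence[BarcodeRecord],
                 params: AlignmentParams) -> SimilarityMatrix:
    """All-against-all adjusted similarities for a set of barcodes.

    Evaluates every unordered pair; entries below ``params.floor`` are
    dropped.  Duplicate record ids raise ValueError.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least 2 records to build a matrix")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate record ids: {dupes}")
    mat = SimilarityMatrix(ids=ids, m=params.m, floor=params.floor)
    for a, b in combinations(records, 2):
        pair = pair_similarity(a, b, params)
        if pair.score >= params.floor:
            mat.set(a.id, b.id, pair.score)
    return mat


def import_pairwise(path: str | Path, params: AlignmentParams) -> SimilarityMatrix:
    """Import a 12-column tabular pairwise search output as a matrix.

    Columns: query, subject, percent identity (0-100), alignment length,
    mismatches, gap opens, q.start, q.end, s.start, s.end, e-value, bit
    score.  Per direction the row with the highest bit score is kept; the
    two directions are then symmetrised by taking the maximum.  Self-pairs
    are dropped and the length adjustment is applied.
    """
    best: dict[tuple[str, str], tuple[float, float]] = {}  # (q,s) -> (bit, score)
    order: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}")
            try:
                query, subject = fields[0], fields[1]
                pident = float(fields[2])
                length = int(fields[3])
                bit = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
            for i in (query, subject):
                if i not in seen:
                    order.append(i)
                    seen.add(i)
            if query == subject:
                continue
            score = adjust_score(pident / 100.0, length, params)
            key = (query, subject)
            if key not in best or bit > best[key][0]:
                best[key] = (bit, score)
    mat = SimilarityMatrix(ids=order, m=params.m, floor=params.floor)
    for (query, subject), (_, score) in best.items():
        current = mat.entries.get(SimilarityMatrix._key(query, subject))
        if current is None or score > current:
            mat.set(query, subject, score)
    mat.entries = {k: v for k, v in mat.entries.items() if v >= params.floor}
    return mat
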