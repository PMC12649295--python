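"""Sequence and taxonomy I/O plus rank partitions.

A barcode dataset is a FASTA file of marker sequences together with a
delimited taxonomy table mapping each sequence id to names at seven ranks
(strain, species, genus, family, order, class, phylum).  Rank partitions —
the grouping of sequence ids by their name at one rank — are the ground
truth against which threshold clusterings are scored.

An empty rank value means "unannotated at this rank"; such ids are excluded
from partitions at that rank but kept everywhere else.  Placeholder names
("unidentified", a bare "sp." epithet, ...) are normalised to empty at read
time so that they never form spurious ground-truth groups.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

# Lowest to highest.  Kingdom and above are out of the rank vocabulary.
RANKS: tuple[str, ...] = (
    "strain", "species", "genus", "family", "order", "class", "phylum",
)

# Ranks that carry group names in a taxonomy table (strain is free-text).
NAMED_RANKS: tuple[str, ...] = RANKS[1:]

#: tokens treated as "no annotation" (compared case-insensitively)
UNANNOTATED_TOKENS = frozenset({"", "unidentified", "unclassified", "na", "n/a", "none"})

#: species epithets that mark an undetermined species, e.g. "Candida sp."
_SP_EPITHETS = frozenset({"sp", "sp.", "spp", "spp."})

#: id prefix marking newly generated barcodes (vs. repository accessions)
NEW_ID_PREFIX = "WI"


def normalize_taxon(value: str | None, rank: str) -> str:
    """Return the cleaned taxon name, or '' when the value means unannotated."""
    if value is None:
        return ""
    name = str(value).strip()
    if name.lower() in UNANNOTATED_TOKENS:
        return ""
    if rank == "species":
        parts = name.split()
        if parts and parts[-1].lower() in _SP_EPITHETS:
            return ""
    return name


@dataclass(frozen=True)
class BarcodeRecord:
    """One barcode sequence.

    The marker label (ITS, ITS1, ITS2, LSU, other) is carried for reporting
    only; it never changes how a sequence is aligned or scored.
    """

    id: str
    seq: str
    marker: str = "other"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("BarcodeRecord id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")


@dataclass(frozen=True)
class RankPartition:
    """Grouping of sequence ids by taxon name at one rank.

    ``groups`` maps taxon name -> set of ids; ``covered`` is the union of the
    groups, i.e. the ids annotated at this rank.  Ids unannotated at the rank
    are simply absent.
    """

    rank: str
    groups: Mapping[str, frozenset[str]]
    covered: frozenset[str]

    def n_groups(self) -> int:
        return len(self.groups)

    def labels(self) -> dict[str, str]:
        """id -> taxon name, for covered ids."""
        out: dict[str, str] = {}
        for name, ids in self.groups.items():
            for i in ids:
                out[i] = name
        return out


@dataclass
class TaxonomyTable:
    """Per-id taxonomy at the seven ranks, plus strain/type/new flags.

    ``rows`` maps id -> {rank: name, 'strain': str, 'is_type': bool | None,
    'is_new': bool | None}.  Empty names mean unannotated.
    """

    rows: dict[str, dict] = field(default_factory=dict)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.rows

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def name_at(self, seq_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        row = self.rows[seq_id]
        if rank == "strain":
            return row.get("strain", "")
        return row.get(rank, "")

    def add_row(self, seq_id: str, *, strain: str = "", is_type: bool | None = None,
                is_new: bool | None = None, **names: str) -> None:
        if seq_id in self.rows:
            raise ValueError(f"duplicate id {seq_id!r} in taxonomy table")
        row = {rank: normalize_taxon(names.get(rank, ""), rank) for rank in NAMED_RANKS}
        row["strain"] = strain
        row["is_type"] = is_type
        row["is_new"] = is_new if is_new is not None else seq_id.startswith(NEW_ID_PREFIX)
        self.rows[seq_id] = row

    def subset(self, ids: Iterable[str]) -> "TaxonomyTable":
        sub = TaxonomyTable()
        for i in ids:
            sub.rows[i] = dict(self.rows[i])
        return sub

    def ancestors_of(self, taxon: str, rank: str) -> list[tuple[str, str]]:
        """Ancestor chain [(higher_rank, name), ...] of a taxon, low to high.

        The chain is read off the first row carrying ``taxon`` at ``rank``;
        empty ancestor names are skipped.
        """
        if rank not in NAMED_RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        start = NAMED_RANKS.index(rank)
        for row in self.rows.values():
            if row.get(rank, "") == taxon:
                chain = []
                for higher in NAMED_RANKS[start + 1:]:
                    name = row.get(higher, "")
                    if name:
                        chain.append((higher, name))
                return chain
        raise KeyError(f"taxon {taxon!r} not found at rank {rank!r}")

    def rank_of(self, taxon: str) -> str | None:
        """Lowest named rank at which ``taxon`` occurs, or None."""
        for rank in NAMED_RANKS:
            for row in self.rows.values():
                if row.get(rank, "") == taxon:
                    return rank
        return None


def read_sequences(path: str | Path, marker: str = "other") -> list[BarcodeRecord]:
    """Read a FASTA file into BarcodeRecords.

    The record id is the first whitespace-delimited header token; residues
    are uppercased.  Duplicate ids and empty files raise ValueError.
    """
    records: list[BarcodeRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate sequence id {entry.id!r} in {path}")
        seen.add(entry.id)
        records.append(BarcodeRecord(entry.id, str(entry.seq).upper(), marker))
    if not records:
        raise ValueError(f"no FASTA entries found in {path}")
    return records


def write_sequences(records: Iterable[BarcodeRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapped at 80 columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 80):
                fh.write(rec.seq[i:i + 80] + "\n")


_ID_ALIASES = ("id", "#id", "sequence id", "sequenceid", "seqid", "seq id", "accession")
_TYPE_TRUE = frozenset({"yes", "y", "true", "1", "type"})
_TYPE_FALSE = frozenset({"no", "n", "false", "0", ""})


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_taxonomy(path: str | Path, column_map: Mapping[str, str] | None = None) -> TaxonomyTable:
    """Read a delimited taxonomy table (tab, comma or semicolon separated).

    The header must contain an id column (``id`` or a common alias, or the
    name supplied via ``column_map={'id': ...}``).  Rank columns are matched
    case-insensitively; missing ones are treated as unannotated.  ``type`` is
    parsed as a yes/no flag; ``new`` overrides the id-prefix convention for
    newly generated barcodes.
    """
    text = Path(path).read_text(encoding="utf-8-sig")
    if not text.strip():
        raise ValueError(f"taxonomy table {path} is empty")
    delim = _sniff_delimiter(text.splitlines()[0])
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    if reader.fieldnames is None:
        raise ValueError(f"taxonomy table {path} has no header")

    lower = {name.lower().strip(): name for name in reader.fieldnames}
    column_map = {k.lower(): v for k, v in (column_map or {}).items()}

    def col_for(key: str, aliases: Sequence[str]) -> str | None:
        if key in column_map:
            return column_map[key]
        for alias in aliases:
            if alias in lower:
                return lower[alias]
        return None

    id_col = col_for("id", _ID_ALIASES)
    if id_col is None:
        raise ValueError(f"taxonomy table {path} lacks an id column")
    rank_cols = {rank: col_for(rank, (rank,)) for rank in NAMED_RANKS}
    strain_col = col_for("strain", ("strain", "strain no", "strain number"))
    type_col = col_for("type", ("type", "is_type", "ex-type", "extype"))
    new_col = col_for("new", ("new", "is_new"))

    table = TaxonomyTable()
    for row in reader:
        seq_id = (row.get(id_col) or "").strip()
        if not seq_id:
            continue
        if seq_id in table:
            raise ValueError(f"duplicate id {seq_id!r} in taxonomy table {path}")
        names = {
            rank: row.get(col, "") if col else ""
            for rank, col in rank_cols.items()
        }
        is_type: bool | None = None
        if type_col is not None:
            raw = (row.get(type_col) or "").strip().lower()
            is_type = True if raw in _TYPE_TRUE else (False if raw in _TYPE_FALSE else None)
        is_new: bool | None = None
        if new_col is not None:
            raw = (row.get(new_col) or "").strip().lower()
            if raw:
                is_new = raw in _TYPE_TRUE
        table.add_row(
            seq_id,
            strain=(row.get(strain_col) or "").strip() if strain_col else "",
            is_type=is_type,
            is_new=is_new,
            **names,
        )
    if len(table) == 0:
        raise ValueError(f"taxonomy table {path} has no rows")
    return table


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    """Write a TaxonomyTable as a tab-separated file (round-trips exactly)."""
    cols = ["id", *NAMED_RANKS, "strain", "type", "new"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(cols)
        for seq_id, row in tax.rows.items():
            writer.writerow([
                seq_id,
                *[row.get(rank, "") for rank in NAMED_RANKS],
                row.get("strain", ""),
                {True: "yes", False: "no", None: ""}[row.get("is_type")],
                {True: "yes", False: "no", None: ""}[row.get("is_new")],
            ])


def partition_at_rank(tax: TaxonomyTable, ids: Iterable[str], rank: str) -> RankPartition:
    """Group ``ids`` by their taxon name at ``rank``.

    Ids unannotated at the rank are excluded from both the groups and the
    covered set.  At strain rank every annotated id is its own group unless
    strains share a name.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    ids = set(ids)
    unknown = ids - set(tax.rows)
    if unknown:
        raise KeyError(f"ids not in taxonomy table: {sorted(unknown)[:5]}")
    groups: dict[str, set[str]] = {}
    for seq_id in ids:
        name = tax.name_at(seq_id, rank)
        if not name:
            continue
        groups.setdefault(name, set()).add(seq_id)
    frozen = {name: frozenset(members) for name, members in groups.items()}
    covered = frozenset().union(*frozen.values()) if frozen else frozenset()
    return RankPartition(rank=rank, groups=frozen, covered=covered)
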