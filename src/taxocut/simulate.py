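"""Synthetic barcode datasets with known taxonomic structure.

The generator emulates the statistical shape of a curated barcode
collection: a seven-rank hierarchical taxonomy with skewed group sizes (a
few dominant genera), sequence divergence that grows with rank height
(near-identity within species, progressively lower identity between
genera, families, orders), optional planted indistinguishable species
complexes (identical barcodes across species), a configurable fraction of
records missing their family annotation, and error-bearing query reads
drawn from a species abundance design.  Every stage is reproducible from a
single master seed.

Evolution is deliberately simple: per rank split a fixed expected fraction
of sites is substituted (transition:transversion 2:1) with a small share of
single-base indels; the analyses downstream depend only on the identity
levels this produces, not on a realistic substitution process.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .similarity import SimilarityMatrix
from .taxonomy import BarcodeRecord, RankPartition, TaxonomyTable

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: default expected substitution fraction introduced at each rank split,
#: increasing with rank height so similarity decreases up the hierarchy
DEFAULT_LADDER: dict[str, float] = {
    "species": 0.005, "genus": 0.05, "family": 0.12, "order": 0.18, "class": 0.25,
}

_LENGTH_RANGES = {"long": (450, 800), "short": (150, 300)}

CountLike = int | tuple[int, int]


@dataclass(frozen=True)
class SimulationSpec:
    """Shape and divergence parameters of one synthetic dataset.

    Count fields accept a fixed int or a (low, high) range; ranges are
    sampled with a power-law skew (exponent ``skew``) so most groups are
    small and a few large, creating the taxonomic imbalance real barcode
    collections show.  ``marker`` selects the length regime: "long"
    (ITS/LSU-like, 450-800 nt) or "short" (ITS1/ITS2-like, 150-300 nt).
    """

    n_phyla: CountLike = 2
    classes_per_phylum: CountLike = 2
    orders_per_class: CountLike = 2
    families_per_order: CountLike = 2
    genera_per_family: CountLike = 3
    species_per_genus: CountLike = (1, 12)
    strains_per_species: CountLike = (1, 6)
    skew: float = 1.5
    marker: str = "long"
    length_range: tuple[int, int] | None = None
    ladder: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_LADDER))
    intra_strain_noise: float = 0.002
    indel_fraction: float = 0.1
    planted_complexes: int = 0
    unannotated_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        order = ["species", "genus", "family", "order", "class"]
        values = [self.ladder[r] for r in order]
        if any(b <= a for a, b in zip(values, values[1:])):
            raise ValueError(
                f"divergence ladder must strictly increase with rank height: {self.ladder}")
        for name in ("intra_strain_noise", "indel_fraction", "unannotated_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.marker not in _LENGTH_RANGES and self.length_range is None:
            raise ValueError("marker must be 'long' or 'short', or give length_range")

    @property
    def lengths(self) -> tuple[int, int]:
        return self.length_range or _LENGTH_RANGES[self.marker]


@dataclass
class GroundTruth:
    """Everything the generator knows that downstream stages must recover."""

    taxonomy: TaxonomyTable
    complexes: list[frozenset[str]]        # planted species complexes
    ladder: Mapping[str, float]
    query_origin: dict[str, tuple[str, str]] = field(default_factory=dict)


def _sample_count(rng: np.random.Generator, value: CountLike, skew: float) -> int:
    if isinstance(value, int):
        return value
    low, high = value
    sizes = np.arange(low, high + 1)
    weights = (sizes - low + 1.0) ** (-skew) if skew > 0 else np.ones_like(sizes, float)
    weights /= weights.sum()
    return int(rng.choice(sizes, p=weights))


def _substitute(rng: np.random.Generator, bases: list[str], pos: int) -> None:
    current = bases[pos]
    if current not in _TRANSITION:
        bases[pos] = str(rng.choice(_BASES))
        return
    transition = _TRANSITION[current]
    transversions = [b for b in "ACGT" if b != current and b != transition]
    choices = [transition, *transversions]
    bases[pos] = str(rng.choice(choices, p=[0.5, 0.25, 0.25]))


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            indel_fraction: float, at_least_one: bool) -> str:
    """Copy ``seq`` with ~rate*len edits; a fraction are single-base indels.

    Rank splits use at_least_one=True with a deterministic edit count, so
    every split introduces divergence and planted identity gaps are real;
    strain-level noise draws a binomial count and may be zero.
    """
    n = len(seq)
    if at_least_one:
        n_edits = max(1, int(round(rate * n))) if rate > 0 else 0
    else:
        n_edits = int(rng.binomial(n, rate)) if rate > 0 else 0
    if n_edits == 0:
        return seq
    n_indels = int(round(n_edits * indel_fraction))
    n_subs = n_edits - n_indels
    bases = list(seq)
    if n_subs > 0:
        for pos in rng.choice(n, size=min(n_subs, n), replace=False):
            _substitute(rng, bases, int(pos))
    for _ in range(n_indels):
        pos = int(rng.integers(0, len(bases)))
        if rng.random() < 0.5 and len(bases) > 1:
            del bases[pos]
        else:
            bases.insert(pos, str(rng.choice(_BASES)))
    return "".join(bases)


def simulate_dataset(spec: SimulationSpec) -> tuple[list[BarcodeRecord],
                                                    TaxonomyTable, GroundTruth]:
    """Generate barcodes, their taxonomy, and the ground truth.

    One random ancestral sequence per phylum; recursive descent introduces
    the ladder's divergence at each split; strains add intra-strain noise.
    Planted complexes copy one species' sequences verbatim onto a sister
    species; ``unannotated_fraction`` of the rows get their family blanked.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    marker = "ITS" if spec.marker == "long" else "ITS2"
    low, high = spec.lengths

    tax = TaxonomyTable()
    records: list[BarcodeRecord] = []
    species_members: dict[str, list[int]] = {}   # species -> record indices
    species_genus: dict[str, str] = {}
    counters = {r: 0 for r in ("phylum", "class", "order", "family",
                               "genus", "species", "seq")}

    def fresh(rank: str, prefix: str) -> str:
        counters[rank] += 1
        return f"{prefix}{counters[rank]:03d}"

    for _ in range(_sample_count(rng, spec.n_phyla, spec.skew)):
        phylum = fresh("phylum", "Phy")
        length = int(rng.integers(low, high + 1))
        root = "".join(rng.choice(_BASES, size=length))
        for _ in range(_sample_count(rng, spec.classes_per_phylum, spec.skew)):
            cls = fresh("class", "Cla")
            cls_seq = _mutate(rng, root, spec.ladder["class"],
                              spec.indel_fraction, True)
            for _ in range(_sample_count(rng, spec.orders_per_class, spec.skew)):
                order = fresh("order", "Ord")
                ord_seq = _mutate(rng, cls_seq, spec.ladder["order"],
                                  spec.indel_fraction, True)
                for _ in range(_sample_count(rng, spec.families_per_order, spec.skew)):
                    family = fresh("family", "Fam")
                    fam_seq = _mutate(rng, ord_seq, spec.ladder["family"],
                                      spec.indel_fraction, True)
                    for _ in range(_sample_count(rng, spec.genera_per_family, spec.skew)):
                        genus = fresh("genus", "Gen")
                        gen_seq = _mutate(rng, fam_seq, spec.ladder["genus"],
                                          spec.indel_fraction, True)
                        n_species = _sample_count(rng, spec.species_per_genus, spec.skew)
                        for _ in range(n_species):
                            species = f"{genus} sp{counters['species']:04d}"
                            counters["species"] += 1
                            sp_seq = _mutate(rng, gen_seq, spec.ladder["species"],
                                             spec.indel_fraction, True)
                            species_members[species] = []
                            species_genus[species] = genus
                            n_strains = _sample_count(rng, spec.strains_per_species,
                                                      spec.skew)
                            for _ in range(n_strains):
                                counters["seq"] += 1
                                seq_id = f"WI{counters['seq']:05d}"
                                strain_seq = _mutate(
                                    rng, sp_seq, spec.intra_strain_noise,
                                    spec.indel_fraction, False)
                                species_members[species].append(len(records))
                                records.append(BarcodeRecord(seq_id, strain_seq, marker))
                                tax.add_row(seq_id, strain=f"ST-{counters['seq']}",
                                            species=species, genus=genus,
                                            family=family, order=order,
                                            **{"class": cls}, phylum=phylum)

    complexes = _plant_complexes(rng, spec, records, species_members, species_genus)

    if spec.unannotated_fraction > 0:
        n_blank = int(round(spec.unannotated_fraction * len(records)))
        for idx in rng.choice(len(records), size=n_blank, replace=False):
            tax.rows[records[int(idx)].id]["family"] = ""

    truth = GroundTruth(taxonomy=tax, complexes=complexes,
                        ladder=dict(spec.ladder))
    return records, tax, truth


def _plant_complexes(rng: np.random.Generator, spec: SimulationSpec,
                     records: list[BarcodeRecord],
                     species_members: dict[str, list[int]],
                     species_genus: dict[str, str]) -> list[frozenset[str]]:
    """Make ``planted_complexes`` pairs of same-genus species identical."""
    if spec.planted_complexes == 0:
        return []
    by_genus: dict[str, list[str]] = {}
    for species, genus in species_genus.items():
        by_genus.setdefault(genus, []).append(species)
    candidates = [sorted(group) for genus, group in sorted(by_genus.items())
                  if len(group) >= 2]
    if len(candidates) < spec.planted_complexes:
        raise ValueError(
            f"cannot plant {spec.planted_complexes} complexes: only "
            f"{len(candidates)} genera have >= 2 species")
    rng.shuffle(candidates)
    complexes: list[frozenset[str]] = []
    for group in candidates[:spec.planted_complexes]:
        donor, acceptor = group[0], group[1]
        donor_idx = species_members[donor]
        for j, rec_idx in enumerate(species_members[acceptor]):
            source = records[donor_idx[j % len(donor_idx)]]
            old = records[rec_idx]
            records[rec_idx] = BarcodeRecord(old.id, source.seq, old.marker)
        complexes.append(frozenset({donor, acceptor}))
    return complexes


def simulate_queries(records: Sequence[BarcodeRecord], tax: TaxonomyTable,
                     abundance: Mapping[str, int], error_rate: float,
                     length: int | tuple[int, int], seed: int = 0,
                     ) -> tuple[list[BarcodeRecord], dict[str, tuple[str, str]]]:
    """Draw error-bearing query reads from a species abundance design.

    Each query is a contiguous subsequence of a randomly chosen strain of
    its species, with substitutions at ``error_rate`` per base.  Requested
    lengths longer than the source are clamped with a warning.  Returns the
    queries and an origin map query id -> (species, source record id).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    by_species: dict[str, list[BarcodeRecord]] = {}
    for rec in records:
        name = tax.name_at(rec.id, "species")
        if name:
            by_species.setdefault(name, []).append(rec)
    queries: list[BarcodeRecord] = []
    origin: dict[str, tuple[str, str]] = {}
    counter = 0
    for species in sorted(abundance):
        count = abundance[species]
        if count == 0:
            continue
        if species not in by_species:
            raise KeyError(f"species {species!r} has no records in the dataset")
        for _ in range(count):
            source = by_species[species][int(rng.integers(0, len(by_species[species])))]
            want = (int(length) if isinstance(length, int)
                    else int(rng.integers(length[0], length[1] + 1)))
            if want > len(source.seq):
                warnings.warn(
                    f"requested query length {want} exceeds source "
                    f"{source.id} ({len(source.seq)} nt); clamping", stacklevel=2)
                want = len(source.seq)
            start = int(rng.integers(0, len(source.seq) - want + 1))
            fragment = source.seq[start:start + want]
            n_err = int(rng.binomial(want, error_rate)) if error_rate > 0 else 0
            if n_err:
                bases = list(fragment)
                for pos in rng.choice(want, size=n_err, replace=False):
                    _substitute(rng, bases, int(pos))
                fragment = "".join(bases)
            counter += 1
            qid = f"Q{counter:05d}"
            queries.append(BarcodeRecord(qid, fragment, source.marker))
            origin[qid] = (species, source.id)
    return queries, origin


def realized_bounds(mat: SimilarityMatrix,
                    truth: RankPartition) -> tuple[float, float]:
    """(max between-group, min within-group) similarity at one rank.

    Measured on the matrix actually used downstream.  Pairs absent from the
    sparse matrix are valued at the floor, so a returned floor value means
    "at or below the floor", not an exact score.
    """
    labels = truth.labels()
    max_between = mat.floor
    for a, b, score in mat.edges(within=set(truth.covered)):
        if labels[a] != labels[b] and score > max_between:
            max_between = score
    min_within = 1.0
    for members in truth.groups.values():
        ordered = sorted(members)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1:]:
                value = mat.get(a, b, default=mat.floor)
                if value < min_within:
                    min_within = value
    return max_between, min_within
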