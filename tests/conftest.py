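from __future__ import annotations

import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

from taxocut import (AlignmentParams, SimilarityMatrix, SimulationSpec,
                     TaxonomyTable, build_matrix, simulate_dataset)

#: fixture family for identity-gap recovery: divergence spacing far exceeds
#: the strain noise (60x), so the within/between identity gap is well posed
#: even on short sequences where single-edit fluctuations are ~0.6% identity
GAP_LADDER = {"species": 0.03, "genus": 0.07, "family": 0.13,
              "order": 0.19, "class": 0.26}


def gap_spec(seed: int, **overrides) -> SimulationSpec:
    kwargs = dict(
        marker="short", length_range=(150, 220), seed=seed,
        intra_strain_noise=0.0005, ladder=dict(GAP_LADDER),
        n_phyla=1, classes_per_phylum=2, orders_per_class=2,
        families_per_order=2, genera_per_family=2,
        species_per_genus=(2, 8), strains_per_species=(2, 5),
    )
    kwargs.update(overrides)
    return SimulationSpec(**kwargs)


SHORT_PARAMS = AlignmentParams(m=50)


@pytest.fixture(scope="session")
def gap_dataset():
    """One gap-family dataset with its similarity matrix (shared, ~150 seqs)."""
    records, tax, truth = simulate_dataset(gap_spec(seed=11))
    matrix = build_matrix(records, SHORT_PARAMS)
    return records, tax, truth, matrix


@pytest.fixture(scope="session")
def complex_dataset():
    """Gap-family dataset with two planted indistinguishable complexes."""
    records, tax, truth = simulate_dataset(gap_spec(seed=23, planted_complexes=2))
    matrix = build_matrix(records, SHORT_PARAMS)
    return records, tax, truth, matrix


def toy_matrix(scores: dict[tuple[str, str], float], ids=None,
               m: int = 50, floor: float = 0.5) -> SimilarityMatrix:
    """Hand-built similarity matrix for targeted clustering tests."""
    seen: list[str] = []
    for a, b in scores:
        for i in (a, b):
            if i not in seen:
                seen.append(i)
    mat = SimilarityMatrix(ids=list(ids) if ids else seen, m=m, floor=floor)
    for (a, b), score in scores.items():
        mat.set(a, b, score)
    return mat


def toy_taxonomy(species_of: dict[str, str], **ranks_of) -> TaxonomyTable:
    """Taxonomy table from id -> species (and optional id -> name per rank)."""
    tax = TaxonomyTable()
    for seq_id, species in species_of.items():
        names = {rank: mapping.get(seq_id, "")
                 for rank, mapping in ranks_of.items()}
        tax.add_row(seq_id, species=species, **names)
    return tax
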