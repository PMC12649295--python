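from __future__ import annotations

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from taxocut import (AlignmentParams, BarcodeRecord, SimilarityMatrix,
                     adjust_score, build_matrix, import_pairwise,
                     pair_similarity)

from helpers import gotoh_local

P400 = AlignmentParams(m=400)
P50 = AlignmentParams(m=50)


def random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def mutate(rng: random.Random, seq: str, n_subs: int, n_indels: int = 0) -> str:
    bases = list(seq)
    for pos in rng.sample(range(len(bases)), n_subs):
        bases[pos] = rng.choice([b for b in "ACGT" if b != bases[pos]])
    for _ in range(n_indels):
        pos = rng.randrange(len(bases))
        if rng.random() < 0.5:
            del bases[pos]
        else:
            bases.insert(pos, rng.choice("ACGT"))
    return "".join(bases)


class TestAdjustScore:
    @pytest.mark.parametrize("s,l,m,expected", [
        (0.98, 450, 400, 0.98),          # l >= m leaves s unchanged
        (0.98, 300, 400, 0.735),         # s * l / m
        (1.0, 0, 50, 0.0),               # no alignment
        (0.985, 300, 400, 0.73875),
    ])
    def test_examples(self, s, l, m, expected):
        assert adjust_score(s, l, AlignmentParams(m=m)) == pytest.approx(expected)

    def test_accepts_bare_minimum_length(self):
        assert adjust_score(0.5, 25, 50) == pytest.approx(0.25)

    @given(st.floats(0, 1), st.integers(0, 1000), st.integers(1, 500))
    def test_formula_exactness(self, s, l, m):
        value = adjust_score(s, l, m)
        if l == 0:
            assert value == 0.0
        elif l >= m:
            assert value == min(1.0, s)
        else:
            assert value == min(1.0, s * l / m)

    @given(st.floats(0, 1), st.integers(0, 600), st.integers(0, 600),
           st.integers(1, 500))
    def test_monotone_in_length(self, s, l1, l2, m):
        lo, hi = sorted((l1, l2))
        assert adjust_score(s, lo, m) <= adjust_score(s, hi, m)


class TestPairSimilarity:
    def test_identical_sequences_score_one(self):
        rng = random.Random(0)
        seq = random_seq(rng, 500)
        pair = pair_similarity(BarcodeRecord("a", seq), BarcodeRecord("b", seq), P400)
        assert pair.s == 1.0
        assert pair.l == 500
        assert pair.score == 1.0

    def test_five_substitutions_match_dp_oracle(self):
        rng = random.Random(42)
        seq = random_seq(rng, 500)
        other = mutate(rng, seq, n_subs=5)
        pair = pair_similarity(BarcodeRecord("a", seq), BarcodeRecord("b", other), P400)
        score, identities, columns = gotoh_local(seq, other)
        assert pair.l == columns
        assert pair.s == pytest.approx(identities / columns)
        assert pair.s == pytest.approx(0.99)
        assert pair.score == pytest.approx(pair.s)

    def test_unrelated_sequences_score_below_070(self):
        rng = random.Random(7)
        a = BarcodeRecord("a", random_seq(rng, 500))
        b = BarcodeRecord("b", random_seq(rng, 500))
        assert pair_similarity(a, b, P400).score < 0.7

    def test_symmetry(self):
        rng = random.Random(3)
        a = BarcodeRecord("a", random_seq(rng, 300))
        b = BarcodeRecord("b", mutate(rng, a.seq, 10, 2))
        assert pair_similarity(a, b, P400) == pair_similarity(b, a, P400)

    def test_short_alignment_is_downweighted(self):
        # 100 identical bases but m=400: score = 1.0 * 100/400
        seq = "ACGT" * 25
        pair = pair_similarity(BarcodeRecord("a", seq), BarcodeRecord("b", seq), P400)
        assert pair.s == 1.0
        assert pair.score == pytest.approx(100 / 400)

    def test_score_never_exceeds_identity(self):
        rng = random.Random(9)
        for _ in range(20):
            a = BarcodeRecord("a", random_seq(rng, rng.randrange(60, 300)))
            b = BarcodeRecord("b", random_seq(rng, rng.randrange(60, 300)))
            pair = pair_similarity(a, b, P50)
            assert 0.0 <= pair.score <= pair.s <= 1.0


def test_aligner_agrees_with_dp_oracle_on_seeded_pairs():
    """Optimal local alignment score matches an independent Gotoh DP on 100
    seeded pairs; identity and length are re-counted from the alignment's
    own columns.  Substitution-only pairs also match the oracle traceback."""
    from taxocut.similarity import _aligner

    rng = random.Random(2024)
    aligner = _aligner(P50)
    for case in range(100):
        length = rng.randrange(40, 120)
        a = random_seq(rng, length)
        if case % 3 == 0:
            b = random_seq(rng, rng.randrange(40, 120))
        elif case % 3 == 1:
            b = mutate(rng, a, n_subs=rng.randrange(0, length // 8))
        else:
            b = mutate(rng, a, n_subs=rng.randrange(0, length // 10),
                       n_indels=rng.randrange(0, 4))
        oracle_score, oracle_ident, oracle_cols = gotoh_local(a, b)
        # same canonical operand order as pair_similarity
        first, second = (a, b) if (a, "a") <= (b, "b") else (b, a)
        alignments = aligner.align(first, second)
        if oracle_score == 0:
            assert len(alignments) == 0 or alignments[0].score <= 0
            continue
        best = alignments[0]
        assert best.score == pytest.approx(oracle_score)
        # re-count identity/columns directly from the alignment text
        top, bottom = str(best[0]), str(best[1])
        identities = sum(x == y and x in "ACGT" for x, y in zip(top, bottom))
        pair = pair_similarity(BarcodeRecord("a", a), BarcodeRecord("b", b), P50)
        assert pair.l == len(top)
        assert pair.s == pytest.approx(identities / len(top))
        if case % 3 == 1:  # substitution-only: traceback is unambiguous
            assert (pair.l, pair.s) == (oracle_cols,
                                        pytest.approx(oracle_ident / oracle_cols))


class TestBuildMatrix:
    def test_three_identical_sequences(self):
        seq = "ACGT" * 30
        records = [BarcodeRecord(i, seq) for i in "abc"]
        mat = build_matrix(records, P50)
        assert len(mat.entries) == 3
        assert all(v == 1.0 for v in mat.entries.values())

    def test_floor_drops_unrelated_pair(self):
        rng = random.Random(5)
        records = [BarcodeRecord("a", random_seq(rng, 200)),
                   BarcodeRecord("b", random_seq(rng, 200))]
        mat = build_matrix(records, AlignmentParams(m=50, floor=0.7))
        direct = pair_similarity(records[0], records[1], P50)
        assert direct.score < 0.7
        assert len(mat.entries) == 0

    def test_all_pairs_evaluated(self):
        rng = random.Random(6)
        base = random_seq(rng, 150)
        records = [BarcodeRecord(f"r{i}", mutate(rng, base, 1)) for i in range(10)]
        mat = build_matrix(records, P50)
        assert len(mat.entries) == 45  # C(10,2), all related so none dropped

    def test_duplicate_ids_rejected(self):
        records = [BarcodeRecord("a", "ACGT" * 20), BarcodeRecord("a", "ACGT" * 20)]
        with pytest.raises(ValueError, match="duplicate"):
            build_matrix(records, P50)

    def test_permutation_changes_only_id_order(self):
        rng = random.Random(8)
        base = random_seq(rng, 150)
        records = [BarcodeRecord(f"r{i}", mutate(rng, base, i)) for i in range(5)]
        forward = build_matrix(records, P50)
        backward = build_matrix(records[::-1], P50)
        assert forward.entries == backward.entries
        assert backward.ids == forward.ids[::-1]


class TestImportPairwise:
    ROW = "{q}\t{s}\t{ident}\t{length}\t1\t0\t1\t300\t1\t300\t1e-50\t{bit}\n"

    def test_length_adjustment_applied(self, tmp_path):
        path = tmp_path / "hits.tab"
        path.write_text(self.ROW.format(q="a", s="b", ident=98.5, length=300, bit=500))
        mat = import_pairwise(path, AlignmentParams(m=400))
        assert mat.get("a", "b") == pytest.approx(0.73875)

    def test_directions_symmetrised_by_max(self, tmp_path):
        path = tmp_path / "hits.tab"
        path.write_text(
            self.ROW.format(q="a", s="b", ident=98.0, length=400, bit=500)
            + self.ROW.format(q="b", s="a", ident=97.0, length=400, bit=480))
        mat = import_pairwise(path, AlignmentParams(m=400))
        assert mat.get("a", "b") == pytest.approx(0.98)

    def test_best_bit_score_row_wins(self, tmp_path):
        path = tmp_path / "hits.tab"
        path.write_text(
            self.ROW.format(q="a", s="b", ident=90.0, length=400, bit=500)
            + self.ROW.format(q="a", s="b", ident=99.0, length=400, bit=300))
        mat = import_pairwise(path, AlignmentParams(m=400))
        assert mat.get("a", "b") == pytest.approx(0.90)

    def test_self_pairs_dropped(self, tmp_path):
        path = tmp_path / "hits.tab"
        path.write_text(self.ROW.format(q="a", s="a", ident=100.0, length=400, bit=700))
        mat = import_pairwise(path, AlignmentParams(m=400))
        assert mat.entries == {}

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "hits.tab"
        path.write_text("a\tb\tnot-a-number\n")
        with pytest.raises(ValueError, match=":1:"):
            import_pairwise(path, P400)


def test_matrix_tsv_round_trip(tmp_path):
    mat = SimilarityMatrix(ids=["a", "b", "c"], m=50, floor=0.6)
    mat.set("a", "b", 0.987654)
    mat.set("b", "c", 0.75)
    path = tmp_path / "m.tsv"
    mat.to_tsv(path)
    back = SimilarityMatrix.from_tsv(path)
    assert back.m == 50 and back.floor == 0.6
    assert back.get("a", "b") == pytest.approx(0.987654, abs=1e-6)
    assert back.get("c", "b") == pytest.approx(0.75)
    assert back.get("a", "a") == 1.0


def test_import_agrees_with_blastn(tmp_path):
    """Importing real blastn tabular output reproduces our own aligner's
    identity within rounding for near-identical sequences."""
    import shutil
    import subprocess

    if shutil.which("blastn") is None or shutil.which("makeblastdb") is None:
        pytest.skip("BLAST+ not on PATH")
    rng = random.Random(77)
    ref = random_seq(rng, 500)
    query = mutate(rng, ref, n_subs=10)
    (tmp_path / "ref.fa").write_text(f">r1\n{ref}\n")
    (tmp_path / "q.fa").write_text(f">q1\n{query}\n")
    subprocess.run(["makeblastdb", "-in", "ref.fa", "-dbtype", "nucl"],
                   cwd=tmp_path, check=True, capture_output=True)
    subprocess.run(["blastn", "-query", "q.fa", "-db", "ref.fa",
                    "-outfmt", "6", "-out", "hits.tab"],
                   cwd=tmp_path, check=True, capture_output=True)
    mat = import_pairwise(tmp_path / "hits.tab", P400)
    ours = pair_similarity(BarcodeRecord("q1", query), BarcodeRecord("r1", ref), P400)
    assert mat.get("q1", "r1") == pytest.approx(ours.score, abs=0.02)
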