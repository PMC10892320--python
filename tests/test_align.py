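"""Pairwise identity, identity matrices, MSA ingestion and masking."""

import math

import numpy as np
import pytest

from gamoscan.align import (
    AlignParams,
    MaskPolicy,
    MultipleAlignment,
    PairwiseAlignment,
    align_pair,
    build_identity_matrix,
    column_entropy,
    identity_table_text,
    ingest_msa,
    mask_columns,
    percent_identity,
)
from gamoscan.codec import SequenceRecord

from tests.conftest import make_msa, random_protein


def prot(id_, seq):
    return SequenceRecord(id=id_, residues=seq, alphabet="protein")


class TestAlignPair:
    def test_identical_no_gaps(self):
        a = prot("a", "ACDEFGHIKLMNPQRSTVWY")
        aln = align_pair(a, prot("b", a.residues))
        assert "-" not in aln.aligned_a + aln.aligned_b
        assert percent_identity(aln) == 100.0

    def test_single_residue_gap(self):
        aln = align_pair(prot("a", "ACDE"), prot("b", "ACE"))
        assert aln.aligned_a == "ACDE"
        assert aln.aligned_b.count("-") == 1

    def test_optimality_beats_hand_alignments(self):
        # NW score must be >= any hand-constructed alignment under same params
        params = AlignParams()
        a, b = "MKWVTFISLL", "MKWTFISL"
        best = align_pair(prot("a", a), prot("b", b), params)
        matrix = params.aligner().substitution_matrix
        for handb in ("MKW--TFISL", "MKWTFISL--", "--MKWTFISL"):
            score = 0.0
            in_gap = False
            for x, y in zip(a, handb):
                if y == "-":
                    score += -params.gap_extend if in_gap else -params.gap_open
                    in_gap = True
                else:
                    score += matrix[x, y]
                    in_gap = False
            assert best.score >= score

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            align_pair(prot("a", "ACDE"), prot("b", "A"[:0]))


class TestPercentIdentity:
    def test_hand_count(self):
        aln = PairwiseAlignment("a", "b", "ACDEFG", "ACDEFA", score=0)
        assert percent_identity(aln) == pytest.approx(83.3333, abs=1e-3)

    def test_row_swap_invariance(self, rng):
        a = prot("a", random_protein(rng, 80))
        b = prot("b", random_protein(rng, 70))
        aln = align_pair(a, b)
        flipped = PairwiseAlignment("b", "a", aln.aligned_b, aln.aligned_a, aln.score)
        for mode in ("aligned_columns", "shorter_seq"):
            assert percent_identity(aln, mode) == percent_identity(flipped, mode)

    def test_modes_agree_without_gaps(self):
        aln = PairwiseAlignment("a", "b", "ACDEFG", "ACDEFA", score=0)
        assert percent_identity(aln, "aligned_columns") == percent_identity(
            aln, "shorter_seq"
        )

    def test_zero_denominator_raises(self):
        aln = PairwiseAlignment("a", "b", "A-", "-C", score=0)
        with pytest.raises(ValueError):
            percent_identity(aln)


class TestIdentityMatrix:
    def test_identical_records_all_100(self):
        recs = [prot(f"s{i}", "MKWVTFISLLKK") for i in range(3)]
        m = build_identity_matrix(recs)
        assert np.allclose(m.values, 100.0)

    def test_symmetry_and_diagonal(self, rng):
        recs = [prot(f"s{i}", random_protein(rng, 60)) for i in range(4)]
        m = build_identity_matrix(recs)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 100.0)

    def test_matches_per_pair_oracle(self, rng):
        recs = [prot(f"s{i}", random_protein(rng, 50)) for i in range(3)]
        m = build_identity_matrix(recs)
        for i in range(3):
            for j in range(i + 1, 3):
                want = percent_identity(align_pair(recs[i], recs[j]))
                assert m.values[i, j] == pytest.approx(want)

    def test_duplicate_ids_raise(self):
        with pytest.raises(ValueError):
            build_identity_matrix([prot("a", "MK"), prot("a", "MK")])

    def test_table_flags_threshold(self):
        recs = [prot("a", "MKWVTFISLL"), prot("b", "MKWVTFISLA")]
        m = build_identity_matrix(recs)
        text = identity_table_text(m, recs, flag_threshold=87.0)
        assert "90.0*" in text
        text95 = identity_table_text(m, recs, flag_threshold=95.0)
        assert "90.0*" not in text95 and "90.0" in text95


class TestIngestMsa:
    def test_fasta_and_clustal_equivalence(self, tmp_path, rng):
        rows = {f"s{i}": random_protein(rng, 40) for i in range(4)}
        fasta = tmp_path / "a.fasta"
        fasta.write_text("".join(f">{k}\n{v}\n" for k, v in rows.items()))
        from Bio import AlignIO

        aln = AlignIO.read(str(fasta), "fasta")
        clustal = tmp_path / "a.aln"
        AlignIO.write(aln, str(clustal), "clustal")

        m1 = ingest_msa(fasta, "aligned-fasta")
        m2 = ingest_msa(clustal, "clustal")
        assert m1.ncols == m2.ncols == 40
        assert [(r.id, r.residues) for r in m1.records] == [
            (r.id, r.residues) for r in m2.records
        ]

    def test_ragged_rows_raise(self, tmp_path):
        bad = tmp_path / "bad.fasta"
        bad.write_text(">a\nMKWV\n>b\nMKW\n")
        with pytest.raises(ValueError):
            ingest_msa(bad, "aligned-fasta")

    def test_degapping_recovers_input(self, tmp_path):
        f = tmp_path / "g.fasta"
        f.write_text(">a\nMK-WV\n>b\nMKAWV\n")
        msa = ingest_msa(f, "aligned-fasta")
        assert msa.row("a").ungapped == "MKWV"


class TestMaskColumns:
    def test_conserved_gapfree_keeps_all(self):
        msa = make_msa({"a": "MKWV", "b": "MKWV", "c": "MKWV"})
        for thr in (0.1, 0.5, 2.0):
            mask = mask_columns(msa, MaskPolicy(entropy_threshold=thr))
            assert mask.n_kept == 4

    def test_gap_column_dropped(self):
        msa = make_msa({"a": "MKWV", "b": "MK-V"})
        mask = mask_columns(msa, MaskPolicy(drop_any_gap=True, entropy_threshold=99))
        assert list(mask.keep) == [True, True, False, True]
        assert (2, "gap") in mask.rule_log

    def test_entropy_rule_with_flanks(self):
        # 10 columns; column 4 has 4 distinct residues -> entropy ln(4)
        rows = {
            "a": "MMMMAMMMMM",
            "b": "MMMMCMMMMM",
            "c": "MMMMDMMMMM",
            "d": "MMMMEMMMMM",
        }
        msa = make_msa(rows)
        assert column_entropy(msa.column(4)) == pytest.approx(math.log(4))
        mask = mask_columns(
            msa, MaskPolicy(drop_any_gap=False, entropy_threshold=1.2, flank_extension=1)
        )
        assert mask.n_kept == 7
        assert list(np.where(~mask.keep)[0]) == [3, 4, 5]
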