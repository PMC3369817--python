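"""Tests of the local-alignment scorer and the similarity table."""

import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st

from panclog.model import Gene
from panclog.scoring import (
    AlignmentParams,
    SimilarityTable,
    load_external_scores,
    local_align_bitscore,
    make_scorer,
    score_all_pairs,
)

PARAMS = AlignmentParams()
_B62 = substitution_matrices.load("BLOSUM62")


def sw_affine_oracle(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Textbook Smith-Waterman with affine gaps (Gotoh three-matrix DP).

    A gap of length k costs gap_open + k * gap_extend.  Independent of the
    production scorer's implementation.
    """

    def sub(x, y):
        if x == "X" or y == "X":
            return 0.0
        return _B62[x, y]

    n, m = len(a), len(b)
    neg = -math.inf
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b
    Iy = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(
                M[i - 1][j] - gap_open - gap_extend, Ix[i - 1][j] - gap_extend
            )
            Iy[i][j] = max(
                M[i][j - 1] - gap_open - gap_extend, Iy[i][j - 1] - gap_extend
            )
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = max(0.0, diag + sub(a[i - 1], b[j - 1]))
            best = max(best, M[i][j], Ix[i][j], Iy[i][j])
    return best


protein = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=40)


class TestLocalAlign:
    def test_matches_independent_dp_oracle_on_textbook_pair(self):
        raw = sw_affine_oracle("HEAGAWGHEE", "PAWHEAE")
        expected_bits = PARAMS.raw_to_bits(raw)
        assert local_align_bitscore("HEAGAWGHEE", "PAWHEAE") == pytest.approx(
            expected_bits, abs=1e-9
        )

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(protein, protein)
    def test_matches_oracle_on_random_pairs(self, a, b):
        assert local_align_bitscore(a, b) == pytest.approx(
            PARAMS.raw_to_bits(sw_affine_oracle(a, b)), abs=1e-9
        )

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(protein, protein)
    def test_symmetry(self, a, b):
        assert local_align_bitscore(a, b) == local_align_bitscore(b, a)

    def test_self_score_positive_and_swap_invariant(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))
        assert local_align_bitscore(seq, seq) > 0
        other = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))
        assert local_align_bitscore(seq, other) == local_align_bitscore(other, seq)

    def test_no_positive_match_scores_raw_zero(self):
        # G vs W scores -2 under BLOSUM62, so the local optimum is empty
        raw = sw_affine_oracle("GGGG", "WWWW")
        assert raw == 0.0
        assert local_align_bitscore("GGGG", "WWWW") == PARAMS.raw_to_bits(0.0)
        assert local_align_bitscore("GGGG", "WWWW") < 50.0

    def test_unknown_residue_scores_zero_everywhere(self):
        assert local_align_bitscore("XXXX", "ACDE") == PARAMS.raw_to_bits(0.0)

    @pytest.mark.parametrize("bad", ["", "ACDU", "AC1D", "acde"])
    def test_invalid_sequences_rejected(self, bad):
        with pytest.raises(ValueError):
            local_align_bitscore(bad, "ACDE")


def _toy_proteomes():
    rng = np.random.default_rng(42)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    mk = lambda n: "".join(rng.choice(aa, size=n))
    return {
        "A": [Gene(f"a{i}", "A", mk(120)) for i in range(4)],
        "B": [Gene(f"b{i}", "B", mk(120)) for i in range(4)],
        "C": [Gene(f"c{i}", "C", mk(120)) for i in range(2)],
    }


class TestScoreAllPairs:
    def test_two_identical_singleton_strains(self):
        g = "MKT" * 40
        proteomes = {"A": [Gene("a1", "A", g)], "B": [Gene("b1", "B", g)]}
        table = score_all_pairs(proteomes)
        assert len(table) == 2
        assert table.score("a1", "b1") == table.score("b1", "a1") > 50

    def test_zero_scorer_yields_empty_table(self):
        table = score_all_pairs(_toy_proteomes(), scorer=lambda a, b: 0.0)
        assert len(table) == 0

    def test_matches_exhaustive_double_loop_oracle(self):
        proteomes = _toy_proteomes()
        scorer = make_scorer()
        table = score_all_pairs(proteomes, min_bits=10.0)
        genes = [g for gs in proteomes.values() for g in gs]
        expected = {}
        for ga in genes:
            for gb in genes:
                if ga.id == gb.id:
                    continue
                bits = scorer(ga.protein, gb.protein)
                if bits >= 10.0:
                    expected[(ga.id, gb.id)] = bits
        assert table.entries == expected

    def test_duplicate_gene_ids_rejected(self):
        proteomes = {
            "A": [Gene("g1", "A", "ACDEFGHIKL" * 10)],
            "B": [Gene("g1", "B", "ACDEFGHIKL" * 10)],
        }
        with pytest.raises(ValueError, match="g1"):
            score_all_pairs(proteomes)

    def test_single_strain_rejected(self):
        with pytest.raises(ValueError):
            score_all_pairs({"A": [Gene("a", "A", "ACDE" * 30)]})

    def test_floor_invariant_and_best_query(self):
        table = score_all_pairs(_toy_proteomes(), min_bits=10.0)
        assert all(v >= 10.0 for v in table.entries.values())
        # best-against is the max over stored directed entries
        for (a, b), s in table.entries.items():
            assert table.best_against(a, table.strain_of(b)) >= s
        with pytest.raises(KeyError):
            SimilarityTable({}, {"g": "A", "h": "B"}).best_against("g", "B")


class TestExternalScores:
    STRAINS = {"A": [Gene("g1", "A", "ACDE" * 30)], "B": [Gene("g2", "B", "ACDE" * 30)]}

    def test_single_row(self, tmp_path):
        p = tmp_path / "scores.tsv"
        p.write_text("g1\tg2\t60.0\n")
        table = load_external_scores(str(p), self.STRAINS)
        assert table.entries == {("g1", "g2"): 60.0}

    def test_row_below_floor_dropped(self, tmp_path):
        p = tmp_path / "scores.tsv"
        p.write_text("g1\tg2\t49.9\n")
        assert len(load_external_scores(str(p), self.STRAINS)) == 0

    def test_duplicate_rows_keep_maximum(self, tmp_path):
        p = tmp_path / "scores.tsv"
        p.write_text("g1\tg2\t55\ng1\tg2\t80\ng1\tg2\t60\n")
        table = load_external_scores(str(p), self.STRAINS)
        assert table.score("g1", "g2") == 80.0

    def test_blast_12_column_dialect(self, tmp_path):
        p = tmp_path / "scores.tsv"
        row = "g1\tg2\t95.0\t100\t5\t0\t1\t100\t1\t100\t1e-50\t183.2\n"
        p.write_text(row)
        table = load_external_scores(str(p), self.STRAINS)
        assert table.score("g1", "g2") == 183.2

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "scores.tsv"
        p.write_text("g1\tg2\t60\ng1\tg2\n")
        with pytest.raises(ValueError, match=":2"):
            load_external_scores(str(p), self.STRAINS)

    def test_unknown_gene_id_reported(self, tmp_path):
        p = tmp_path / "scores.tsv"
        p.write_text("g1\tnope\t60\n")
        with pytest.raises(ValueError, match="nope"):
            load_external_scores(str(p), self.STRAINS)
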