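"""Multiple alignment, clustering, trimming and profile construction."""

import numpy as np
import pytest

from promispred.alphabet import (
    AA_ORDER,
    BACKGROUND,
    BLOSUM62,
    BLOSUM62_CONDITIONAL,
)
from promispred.io import ProteinRecord
from promispred.search import (
    Alignment,
    align_sequences,
    build_profile,
    cluster_representatives,
    pairwise_identity,
    trim_alignment,
)


def rec(gid, seq):
    return ProteinRecord(gid, "eco", seq)


# ---------------------------------------------------------------------------
# independent oracle: affine-gap global alignment score by plain DP
# ---------------------------------------------------------------------------

def nw_affine_score(a, b, open_=11.0, ext=1.0):
    idx = {c: i for i, c in enumerate(AA_ORDER)}
    NEG = -1e18
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -open_ - (i - 1) * ext
    for j in range(1, m + 1):
        Y[0, j] = -open_ - (j - 1) * ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[idx[a[i - 1]], idx[b[j - 1]]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - open_, X[i - 1, j] - ext)
            Y[i, j] = max(M[i, j - 1] - open_, Y[i, j - 1] - ext)
    return max(M[n, m], X[n, m], Y[n, m])


def alignment_score(row_a, row_b, open_=11.0, ext=1.0):
    """Score of one already-aligned pair under the same scheme."""
    idx = {c: i for i, c in enumerate(AA_ORDER)}
    score = 0.0
    gap_a = gap_b = False
    for x, y in zip(row_a, row_b):
        if x == "-" and y == "-":
            continue
        if x == "-":
            score -= ext if gap_a else open_
            gap_a, gap_b = True, False
        elif y == "-":
            score -= ext if gap_b else open_
            gap_b, gap_a = True, False
        else:
            score += BLOSUM62[idx[x], idx[y]]
            gap_a = gap_b = False
    return score


class TestAlignSequences:
    def test_single_sequence_is_itself_ungapped(self):
        aln = align_sequences([rec("g1", "MKTAY")])
        assert aln.rows == [("g1", "MKTAY")]

    def test_identical_sequences_align_gap_free(self):
        aln = align_sequences([rec("g1", "MKTAYI"), rec("g2", "MKTAYI")])
        assert aln.length == 6
        assert all("-" not in s for _, s in aln.rows)

    def test_single_deletion_matches_needleman_wunsch_oracle(self):
        a, b = "ACDEF", "ACEF"
        aln = align_sequences([rec("g1", a), rec("g2", b)])
        assert aln.length == 5
        assert aln.rows[1][1].count("-") == 1
        # the realized pairwise score must equal the DP optimum
        assert alignment_score(aln.rows[0][1], aln.rows[1][1]) == pytest.approx(
            nw_affine_score(a, b)
        )

    def test_ungapping_any_row_reproduces_its_sequence(self):
        seqs = {"g1": "MKTAYIAKQRQISFVK", "g2": "MKTAYIAQRQISFVK",
                "g3": "KTAYIAKQRQISF", "g4": "MKTAYWAKQRQWSFVK"}
        aln = align_sequences([rec(g, s) for g, s in seqs.items()])
        for g, row in aln.rows:
            assert row.replace("-", "") == seqs[g]

    def test_rows_must_have_equal_length(self):
        with pytest.raises(ValueError):
            Alignment(rows=[("a", "MK-"), ("b", "MK")])


class TestClusterRepresentatives:
    def test_identical_rows_collapse_to_one(self):
        aln = Alignment(rows=[("a", "MKTAY"), ("b", "MKTAY")])
        out = cluster_representatives(aln, 0.90)
        assert len(out.rows) == 1

    def test_mutually_distant_rows_all_retained(self):
        aln = Alignment(rows=[("a", "MKTAY"), ("b", "QWERT"), ("c", "LIVGH")])
        out = cluster_representatives(aln, 0.90)
        assert out.rows == aln.rows

    def test_near_identical_pair_plus_outlier_gives_two_reps(self):
        # brute-force identities: a-b = 19/20, both far from c
        sa = "MKTAYIAKQRQISFVKSHFS"
        sb = sa[:10] + "W" + sa[11:]
        sc = "GGGGGGGGGGGGGGGGGGGG"
        aln = Alignment(rows=[("a", sa), ("b", sb), ("c", sc)])
        assert pairwise_identity(sa, sb) == pytest.approx(0.95)
        out = cluster_representatives(aln, 0.90)
        assert len(out.rows) == 2
        assert {g for g, _ in out.rows} >= {"c"}

    def test_removed_rows_are_within_threshold_of_a_representative(self):
        rows = [("a", "MKTAYIAKQR"), ("b", "MKTAYIAKQR"),
                ("c", "MKTAYIAKQW"), ("d", "QQQQQQQQQQ")]
        aln = Alignment(rows=rows)
        out = cluster_representatives(aln, 0.85)
        kept = {g: s for g, s in out.rows}
        for g, s in rows:
            if g not in kept:
                assert any(
                    pairwise_identity(s, ks) >= 0.85 for ks in kept.values()
                )

    def test_idempotent_at_same_threshold(self):
        aln = Alignment(rows=[("a", "MKTAY"), ("b", "MKTAY"), ("c", "QWERT")])
        once = cluster_representatives(aln, 0.90)
        twice = cluster_representatives(once, 0.90)
        assert once.rows == twice.rows

    def test_keep_list_forces_retention(self):
        aln = Alignment(rows=[("a", "MKTAY"), ("b", "MKTAY")])
        out = cluster_representatives(aln, 0.90, keep=("b",))
        assert out.rows == [("b", "MKTAY")]


class TestTrimAlignment:
    def test_fully_occupied_alignment_unchanged(self):
        aln = Alignment(rows=[("a", "MKTAY"), ("b", "MQTAY")])
        assert trim_alignment(aln, 0.5).rows == aln.rows

    def test_single_row_overhang_removed_at_half_occupancy(self):
        rows = [("a", "KRMKTAY"), ("b", "--MKTAY"),
                ("c", "--MKTAY"), ("d", "--MKTAY")]
        out = trim_alignment(Alignment(rows=rows), 0.5)
        assert out.rows[0][1] == "MKTAY"

    def test_occupancy_pattern_keeps_interval_between_first_and_last(self):
        # column occupancies 0.2 / 0.6 / 0.9 / 0.6 / 0.1 over 10 rows
        occ = [2, 6, 9, 6, 1]
        rows = []
        for r in range(10):
            rows.append(
                (f"g{r}", "".join("A" if r < o else "-" for o in occ))
            )
        out = trim_alignment(Alignment(rows=rows), 0.5)
        assert out.length == 3  # columns [1, 4)
        assert out.rows[0][1] == "".join(
            "A" if 0 < o else "-" for o in occ[1:4]
        )

    def test_all_columns_below_occupancy_is_empty_profile_error(self):
        rows = [("a", "MK---"), ("b", "---AY"), ("c", "-----"),
                ("d", "-----"), ("e", "-----")]
        with pytest.raises(ValueError, match="empty profile"):
            trim_alignment(Alignment(rows=rows), 0.5)

    def test_trimmed_rows_are_substrings_of_originals(self):
        rows = [("a", "KRMKTAYWW"), ("b", "--MKTAY--"),
                ("c", "--MKTAY--"), ("d", "--MKTAY--")]
        out = trim_alignment(Alignment(rows=rows), 0.5)
        originals = dict(rows)
        for g, s in out.rows:
            assert s.replace("-", "") in originals[g].replace("-", "")


class TestBuildProfile:
    def test_single_sequence_top_residue_per_column_is_that_sequence(self):
        seq = "MKTAYIAKQR"
        prof = build_profile(align_sequences([rec("g", seq)]))
        top = "".join(AA_ORDER[i] for i in prof.scores[:, :20].argmax(axis=1))
        assert top == seq

    def test_unanimous_column_scores_its_residue_strictly_highest(self):
        aln = Alignment(rows=[("a", "A"), ("b", "A"), ("c", "A")])
        prof = build_profile(aln)
        col = prof.scores[0, :20]
        assert np.all(col[0] > np.delete(col, 0))

    def test_mixed_column_matches_documented_formula(self):
        # column {A:3, S:1}, pseudocount weight 1: hand-computed log-odds
        aln = Alignment(rows=[("a", "A"), ("b", "A"), ("c", "A"), ("d", "S")])
        prof = build_profile(aln, pseudocount=1.0)
        f = np.zeros(20)
        f[AA_ORDER.index("A")] = 0.75
        f[AA_ORDER.index("S")] = 0.25
        prior = f @ BLOSUM62_CONDITIONAL
        expected = np.log2(((4 - 1) * f + 1.0 * prior) / (4 - 1 + 1.0) / BACKGROUND)
        np.testing.assert_allclose(prof.scores[0, :20], expected, atol=1e-12)

    def test_profile_is_deterministic(self):
        aln = align_sequences([rec("a", "MKTAYIAK"), rec("b", "MKTAYWAK")])
        p1, p2 = build_profile(aln), build_profile(aln)
        np.testing.assert_array_equal(p1.scores, p2.scores)
        np.testing.assert_array_equal(p1.consensus, p2.consensus)
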