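"""Profile search, hit filtering and the iterative recruitment loop."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promispred import fixtures as fx
from promispred.io import ProteinRecord, ProteomeSet
from promispred.search import (
    DEFAULT_ROUNDS,
    FilterCriteria,
    RoundConfig,
    SearchHit,
    align_sequences,
    build_profile,
    cluster_representatives,
    filter_hits,
    iterate_search,
    search_profile,
    trim_alignment,
)


def rec(gid, seq, org="eco"):
    return ProteinRecord(gid, org, seq)


def proteome(*records):
    return ProteomeSet(records={r.gene_id: r for r in records})


def hit(identity=0.5, positives=0.6, coverage=0.9, uncovered=10):
    return SearchHit(
        subject_gene_id="s",
        aligned_interval_query=(0, 1),
        aligned_interval_subject=(0, 1),
        identity=identity,
        positives=positives,
        query_coverage=coverage,
        uncovered_query=uncovered,
        raw_score=50.0,
    )


SEQ = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQ"


class TestSearchProfile:
    def test_self_recovery_is_perfect(self):
        root = rec("root", SEQ)
        prof = build_profile(align_sequences([root]))
        hits = search_profile(prof, proteome(root))
        assert len(hits) == 1
        h = hits[0]
        assert h.identity == 1.0 and h.positives == 1.0
        assert h.query_coverage == 1.0 and h.uncovered_query == 0

    def test_all_negative_scores_give_no_hit(self):
        # W-vs-P scores -4 under BLOSUM62: nothing positive to extend
        prof = build_profile(align_sequences([rec("root", "W" * 30)]))
        hits = search_profile(prof, proteome(rec("sub", "P" * 30)))
        assert hits == []

    def test_empty_database_gives_empty_list(self):
        prof = build_profile(align_sequences([rec("root", SEQ)]))
        assert search_profile(prof, proteome()) == []

    def test_planted_homolog_identity_near_ground_truth(self):
        mutant = fx.mutate_sequence(SEQ * 3, 0.40, seed=7)
        root = rec("root", SEQ * 3)
        prof = build_profile(align_sequences([root]))
        hits = search_profile(prof, proteome(rec("hom", mutant)))
        assert len(hits) == 1
        assert hits[0].identity == pytest.approx(0.40, abs=0.08)


class TestFilterHits:
    def test_identity_just_below_threshold_rejected(self):
        h = hit(identity=0.14, positives=0.50, coverage=0.90, uncovered=10)
        assert filter_hits([h], FilterCriteria()) == []

    def test_all_boundaries_inclusive(self):
        h = hit(identity=0.15, positives=0.30, coverage=0.60, uncovered=100)
        assert filter_hits([h], FilterCriteria()) == [h]

    def test_perfect_self_hit_always_accepted(self):
        h = hit(identity=1.0, positives=1.0, coverage=1.0, uncovered=0)
        for crit in [r.criteria for r in DEFAULT_ROUNDS]:
            assert filter_hits([h], crit) == [h]

    @settings(deadline=None, max_examples=50)
    @given(
        hits=st.lists(
            st.builds(
                hit,
                identity=st.floats(0, 1),
                positives=st.floats(0, 1),
                coverage=st.floats(0, 1),
                uncovered=st.integers(0, 300),
            ),
            max_size=20,
        ),
        loose=st.tuples(
            st.integers(0, 200), st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)
        ),
        tighten=st.tuples(
            st.integers(0, 50), st.floats(0, 0.3), st.floats(0, 0.3), st.floats(0, 0.3)
        ),
    )
    def test_relaxing_criteria_is_monotone(self, hits, loose, tighten):
        """A stricter filter never keeps a hit the looser filter drops."""
        unc, cov, ident, pos = loose
        loose_c = FilterCriteria(unc, cov, ident, pos)
        strict_c = FilterCriteria(
            max(0, unc - tighten[0]),
            min(1.0, cov + tighten[1]),
            min(1.0, ident + tighten[2]),
            min(1.0, pos + tighten[3]),
        )
        assert set(map(id, filter_hits(hits, strict_c))) <= set(
            map(id, filter_hits(hits, loose_c))
        )


class TestIterateSearch:
    def test_database_with_only_root_gives_singleton_tree(self):
        root = rec("root", SEQ)
        tree = iterate_search(root, proteome(root))
        assert tree.member_gene_ids == {"root"}
        assert tree.hits["root"].identity == 1.0

    def test_one_round_equals_stage_composition(self):
        root = rec("root", SEQ * 3)
        hom = rec("hom", fx.mutate_sequence(SEQ * 3, 0.5, seed=3), "shi")
        db = proteome(root, hom)
        rounds = [DEFAULT_ROUNDS[0]]
        tree = iterate_search(root, db, rounds=rounds)

        aln = trim_alignment(
            cluster_representatives(
                align_sequences([root]), rounds[0].cluster_identity,
                keep=("root",),
            ),
            rounds[0].trim_occupancy,
        )
        manual = filter_hits(
            search_profile(build_profile(aln), db), rounds[0].criteria
        )
        assert tree.member_gene_ids == {"root"} | {
            h.subject_gene_id for h in manual
        }

    def test_non_monotone_round_criteria_rejected(self):
        rounds = [
            RoundConfig(FilterCriteria(min_identity=0.15)),
            RoundConfig(FilterCriteria(min_identity=0.30)),
        ]
        with pytest.raises(ValueError, match="monotonic"):
            iterate_search(rec("root", SEQ), proteome(rec("root", SEQ)), rounds)

    def test_deterministic_tree_for_fixed_inputs(self):
        spec = fx.stepping_stone_spec(0)
        prot = fx.generate_proteome(spec)
        root = prot.proteome.records["eco_g01"]
        t1 = iterate_search(root, prot.proteome)
        t2 = iterate_search(root, prot.proteome)
        assert t1.member_gene_ids == t2.member_gene_ids
        assert t1.hits == t2.hits

    def test_stepping_stone_needs_multiple_rounds(self):
        """The ~25%-identity homolog B is reachable only through A."""
        spec = fx.stepping_stone_spec(0)
        prot = fx.generate_proteome(spec)
        root = prot.proteome.records["eco_g01"]
        one_round = iterate_search(
            root, prot.proteome, rounds=[DEFAULT_ROUNDS[0]]
        )
        full = iterate_search(root, prot.proteome)
        assert "orgB_g01" in one_round.member_gene_ids  # A at ~0.5 identity
        assert "orgC_g01" not in one_round.member_gene_ids
        assert "orgC_g01" in full.member_gene_ids

    def test_topology_sidecar_contains_all_members(self):
        spec = fx.stepping_stone_spec(0)
        prot = fx.generate_proteome(spec)
        root = prot.proteome.records["eco_g01"]
        tree = iterate_search(root, prot.proteome, with_topology=True)
        for member in tree.member_gene_ids:
            assert member in tree.newick
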