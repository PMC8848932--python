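from __future__ import annotations

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirtail.isomir import (
    IsomiRCall,
    ReferenceIndex,
    build_cube,
    classify_category,
    classify_tail,
    resolve_multimap,
)
from mirtail.reference import HairpinRecord

from _oracle import OracleArm, oracle_category, oracle_classify


class TestClassifyTail:
    @pytest.mark.parametrize(
        "tail, expected",
        [
            ("", "none"),
            ("U", "U"), ("T", "U"), ("UU", "UU"), ("A", "A"), ("AA", "AA"),
            ("AU", "AU"), ("UA", "UA"), ("G", "G"), ("C", "C"),
            ("UUUU", "polyU"), ("AAA", "polyA"),
            ("AAU", "other"), ("GG", "other"), ("GGG", "other"), ("CGC", "other"),
        ],
    )
    def test_typology(self, tail, expected):
        assert classify_tail(tail) == expected

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            classify_tail("AXU")

    @given(st.text(alphabet="ACGU", min_size=0, max_size=6))
    def test_u_t_alphabet_equivalence_and_homopolymer_rule(self, tail):
        tt = classify_tail(tail)
        assert tt == classify_tail(tail.replace("U", "T"))
        if len(tail) >= 3 and set(tail) == {"A"}:
            assert tt == "polyA"
        if len(set(tail)) > 1 and tail not in ("AU", "UA"):
            assert tt == "other"


class TestClassifyCategory:
    @pytest.mark.parametrize(
        "offset5, templated3, tail, mm, expected",
        [
            (0, 0, "", 0, "exact"),
            (0, 1, "", 0, "lv3pE"),
            (0, -2, "", 0, "lv3pT"),
            (-1, 0, "", 0, "lv5pE"),
            (1, 0, "", 0, "lv5pT"),
            (1, -2, "", 0, "mv"),
            (0, 0, "UU", 0, "nta"),
            (1, 2, "U", 0, "nta"),  # tail presence dominates
            (0, 0, "", 1, "snp_flagged"),
            (0, 1, "", 1, "lv3pE"),  # mismatch recorded but coords decide
        ],
    )
    def test_mapping(self, offset5, templated3, tail, mm, expected):
        assert classify_category(offset5, templated3, tail, mm) == expected


def _index(record, **kwargs):
    return ReferenceIndex([record], **kwargs)


def _arm_read(record, arm, offset5=0, templated3=0, tail=""):
    ctx = record.sequence + record.flank3p
    lo, hi = record.arm_interval(arm)
    return ctx[lo + offset5: hi + templated3] + tail


class TestGreedyDecomposition:
    def test_canonical_read_is_exact(self, toy_hairpin):
        idx = _index(toy_hairpin)
        (call,) = idx.classify(_arm_read(toy_hairpin, "5p"))
        assert (call.category, call.offset5, call.templated3, call.tail) == ("exact", 0, 0, "")

    def test_tail_mismatching_template_is_nta(self, toy_hairpin):
        idx = _index(toy_hairpin)
        # next template base after the 5p arm is C; a U tail cannot extend it
        (call,) = idx.classify(_arm_read(toy_hairpin, "5p", tail="T"))
        assert (call.category, call.tail, call.tail_type) == ("nta", "U", "U")

    def test_template_mimicking_tail_absorbed_as_templated(self, toy_hairpin):
        # append the actual next template base: greedy calls it lv3pE, not nta
        ctx = toy_hairpin.sequence
        hi = toy_hairpin.mature5p[1]
        (call,) = _index(toy_hairpin).classify(_arm_read(toy_hairpin, "5p") + ctx[hi])
        assert (call.category, call.templated3, call.tail) == ("lv3pE", 1, "")

    def test_greedy_prefers_maximal_templated_split(self, toy_hairpin):
        # read = mature + next-template-base + that base again: the greedy
        # split is (+1, one-base tail), never (0, two-base tail)
        ctx = toy_hairpin.sequence
        hi = toy_hairpin.mature5p[1]
        nxt = ctx[hi]
        read = _arm_read(toy_hairpin, "5p") + nxt + nxt
        assert nxt != ctx[hi + 1]  # holds for this fixture
        (call,) = _index(toy_hairpin).classify(read)
        assert (call.templated3, call.tail) == (1, nxt.replace("T", "U"))

    def test_extension_beyond_hairpin_uses_flank_then_tail(self, toy_hairpin):
        idx = _index(toy_hairpin)
        read = _arm_read(toy_hairpin, "3p", templated3=4)  # 2 nt into the flank
        (call,) = idx.classify(read)
        assert (call.category, call.templated3) == ("lv3pE", 4)

    def test_without_flank_extension_is_nontemplated(self, toy_hairpin):
        bare = HairpinRecord(toy_hairpin.id, toy_hairpin.sequence,
                             toy_hairpin.mature5p, toy_hairpin.mature3p)
        read = _arm_read(toy_hairpin, "3p", templated3=4)
        (call,) = ReferenceIndex([bare]).classify(read)
        # the 2 bases past the hairpin end are nontemplated without a flank
        assert call.category == "nta" and call.templated3 == 2 and len(call.tail) == 2

    def test_trim_plus_tail_keeps_tail(self, toy_hairpin):
        # trimmed base is G; a planted A tail mismatches it and must survive
        read = _arm_read(toy_hairpin, "5p", templated3=-1, tail="A")
        (call,) = _index(toy_hairpin).classify(read)
        assert (call.category, call.templated3, call.tail) == ("nta", -1, "A")

    def test_internal_mismatch_flagged_not_decomposed(self, toy_hairpin):
        read = list(_arm_read(toy_hairpin, "5p"))
        read[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[10]]
        (call,) = _index(toy_hairpin).classify("".join(read))
        assert (call.category, call.internal_mismatches) == ("snp_flagged", 1)
        assert (call.offset5, call.templated3, call.tail) == (0, 0, "")

    def test_three_mismatches_unassigned(self, toy_hairpin):
        read = list(_arm_read(toy_hairpin, "5p"))
        for pos in (5, 10, 15):
            read[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[pos]]
        (call,) = _index(toy_hairpin).classify("".join(read))
        assert call.category == "unassigned"

    def test_five_prime_offsets_recovered(self, toy_hairpin):
        idx = _index(toy_hairpin)
        for off, cat in ((-2, "lv5pE"), (-1, "lv5pE"), (1, "lv5pT"), (2, "lv5pT")):
            (call,) = idx.classify(_arm_read(toy_hairpin, "5p", offset5=off))
            assert (call.offset5, call.category) == (off, cat)


class TestMultimap:
    def _twin_records(self, toy_hairpin):
        twin = HairpinRecord("toy-mir-b", toy_hairpin.sequence, toy_hairpin.mature5p,
                             toy_hairpin.mature3p, flank3p=toy_hairpin.flank3p)
        return [toy_hairpin, twin]

    def test_family_paralogues_split_weight(self, toy_hairpin):
        idx = ReferenceIndex(self._twin_records(toy_hairpin))
        calls = idx.classify(_arm_read(toy_hairpin, "5p"))
        assert len(calls) == 2
        assert all(c.weight == pytest.approx(0.5) for c in calls)
        assert sum(c.weight for c in calls) == pytest.approx(1.0)

    def test_unique_mode_picks_lexicographic_smallest(self, toy_hairpin):
        idx = ReferenceIndex(self._twin_records(toy_hairpin), multimap_mode="unique")
        (call,) = idx.classify(_arm_read(toy_hairpin, "5p"))
        assert call.mirna_id == "toy-mir"  # < "toy-mir-b"
        assert call.weight == 1.0

    def test_mismatch_free_candidate_wins(self):
        calls = [
            IsomiRCall("mirB", "5p", 0, 0, "", 1, "snp_flagged", "none"),
            IsomiRCall("mirA", "5p", 0, 0, "", 0, "exact", "none"),
        ]
        best = resolve_multimap(calls)
        assert len(best) == 1 and best[0].mirna_id == "mirA" and best[0].weight == 1.0


class TestOracleAgreement:
    def test_enumerated_reads_match_brute_force(self, toy_hairpin):
        """Spot check of the exhaustive agreement (full sweep lives in the
        acceptance suite): offsets x trims x one-base tails."""
        idx = _index(toy_hairpin)
        arms = [OracleArm(toy_hairpin.id, a, toy_hairpin.sequence + toy_hairpin.flank3p,
                          *toy_hairpin.arm_interval(a)) for a in ("5p", "3p")]
        for arm, off, t3, tail in itertools.product(
                ("5p", "3p"), (-2, 0, 2), (-1, 0, 1), ("", "T", "A", "GC")):
            read = _arm_read(toy_hairpin, arm, off, t3, tail)
            calls = idx.classify(read)
            expected = oracle_classify(read, arms)
            if not expected:
                assert calls[0].category == "unassigned"
                continue
            assert len(calls) == len(expected)
            for got, want in zip(calls, expected):
                assert (got.mirna_id, got.arm, got.offset5, got.templated3, got.tail) == (
                    want["mirna_id"], want["arm"], want["offset5"], want["templated3"], want["tail"])
                assert got.category == oracle_category(
                    want["offset5"], want["templated3"], want["tail"], want["mm"])


class TestBuildCube:
    def test_weighted_counts_sum_to_reads(self, toy_hairpin):
        idx = _index(toy_hairpin)
        counts = {"s1": {_arm_read(toy_hairpin, "5p"): 7, _arm_read(toy_hairpin, "3p", tail="T"): 3}}
        cube = build_cube(counts, idx)
        assert cube["count"].sum() == pytest.approx(10.0)
        u = cube[(cube["tail_type"] == "U")]["count"].sum()
        assert u == pytest.approx(3.0)
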