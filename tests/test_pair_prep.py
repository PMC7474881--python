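import pytest
from hypothesis import given
from hypothesis import strategies as st

from ovbin.errors import ContractError
from ovbin.pair_prep import (
    MergeParams,
    force_merge,
    merge_pair,
    pair_up,
    prepare_binning_input,
    restore_original,
    revcomp,
)
from ovbin.sequence_io import Read

dna = st.text(alphabet="ACGTN", min_size=0, max_size=80)


@given(dna)
def test_revcomp_is_an_involution(seq):
    assert revcomp(revcomp(seq)) == seq


def test_revcomp_complement_table():
    assert revcomp("ACGTN") == "NACGT"
    assert revcomp("N") == "N"


class TestMergePair:
    def test_exact_four_base_overlap(self):
        r1 = Read("p/1", "AAAACCCC")
        r2 = Read("p/2", revcomp("CCCCGGGG"))
        merged = merge_pair(r1, r2, MergeParams(min_overlap=4))
        assert merged is not None and not merged.forced
        assert merged.sequence == "AAAACCCCGGGG"
        assert merged.source_ids == ("p/1", "p/2")

    def test_no_shared_overlap_returns_none(self):
        r1 = Read("p/1", "AAAAAAAA")
        r2 = Read("p/2", "AAAAAAAA")  # revcomp is TTTTTTTT: no common region
        assert merge_pair(r1, r2, MergeParams(min_overlap=4)) is None

    def test_full_containment_yields_r1(self):
        r1 = Read("p/1", "ACGGTTCA")
        r2 = Read("p/2", revcomp("ACGGTTCA"))
        merged = merge_pair(r1, r2, MergeParams(min_overlap=4))
        assert merged.sequence == r1.sequence

    def test_longest_overlap_wins(self):
        # both a 4- and an 8-base overlap exist; the longest must be chosen
        r1 = Read("p/1", "GGGGACGTACGT")
        r2 = Read("p/2", revcomp("ACGTACGTTTTT"))
        merged = merge_pair(r1, r2, MergeParams(min_overlap=4))
        assert merged.sequence == "GGGGACGTACGTTTTT"

    def test_mismatch_resolved_toward_higher_quality(self):
        r1 = Read("p/1", "AAAACCCC", [40] * 4 + [10] * 4)
        rc = "CCGCGGGG"  # one mismatch (G at overlap position 2)
        r2 = Read("p/2", revcomp(rc), [40] * 8)
        merged = merge_pair(r1, r2, MergeParams(min_overlap=4, max_mismatch_rate=0.3))
        assert merged.sequence == "AAAACCGCGGGG"  # r2 wins: higher quality
        assert merged.qualities[4:8] == [40, 40, 40, 40]

    def test_zero_length_read_is_contract_error(self):
        with pytest.raises(ContractError):
            merge_pair(Read("a", ""), Read("b", "ACGT"), MergeParams())


class TestForceMerge:
    def test_worked_example(self):
        r1 = Read("p/1", "ATCGT")
        r2 = Read("p/2", revcomp("TTATC"))
        merged = force_merge(r1, r2)
        assert merged.sequence == "ATCGTNNNTTATC"
        assert merged.forced
        assert merged.sequence.count("N") == 3
        # spacer sits exactly at the junction
        assert merged.sequence[len(r1) : len(r1) + 3] == "NNN"

    @given(st.text(alphabet="ACGT", min_size=1, max_size=40),
           st.text(alphabet="ACGT", min_size=1, max_size=40))
    def test_length_is_sum_plus_three(self, s1, s2):
        merged = force_merge(Read("a", s1), Read("b", s2))
        assert len(merged.sequence) == len(s1) + len(s2) + 3

    def test_minimal_mates(self):
        merged = force_merge(Read("a", "A"), Read("b", "A"))
        assert merged.sequence == "ANNNT"


class TestPrepareBinningInput:
    def test_empty_inputs_give_empty_outputs(self):
        merged, prov = prepare_binning_input([], [], MergeParams())
        assert merged == [] and prov == {}

    def test_overlapping_pairs_plus_single(self):
        p1 = (Read("a/1", "AAAACCCC"), Read("a/2", revcomp("CCCCGGGG")))
        p2 = (Read("b/1", "TTTTGGGG"), Read("b/2", revcomp("GGGGAAAA")))
        single = Read("s", "ACGTACGT")
        merged, prov = prepare_binning_input([p1, p2], [single], MergeParams(min_overlap=4))
        assert len(merged) == 3
        assert not any(m.forced for m in merged)
        assert set(prov) == {m.merged_id for m in merged}
        # oracle: the pair merges agree with merge_pair directly
        assert merged[0].sequence == merge_pair(*p1, MergeParams(min_overlap=4)).sequence

    def test_non_overlapping_pair_is_forced(self):
        pair = (Read("a/1", "AAAAAAAA"), Read("a/2", "AAAAAAAA"))
        merged, _ = prepare_binning_input([pair], [], MergeParams(min_overlap=4))
        assert len(merged) == 1 and merged[0].forced

    def test_conservation_count(self):
        pairs = [
            (Read(f"p{i}/1", "ACGTACGTAA"), Read(f"p{i}/2", "ACGTACGTAA"))
            for i in range(3)
        ]
        singles = [Read(f"s{i}", "ACGTACGT") for i in range(2)]
        merged, prov = prepare_binning_input(pairs, singles, MergeParams())
        assert len(merged) == len(pairs) + len(singles)
        all_sources = set()
        for sources in prov.values():
            all_sources.update(sources)
        assert all_sources == {r.read_id for pair in pairs for r in pair} | {
            s.read_id for s in singles
        }

    def test_inconsistent_mate_links_rejected(self):
        r1 = Read("a/1", "ACGT", mate_of="zzz")
        r2 = Read("a/2", "ACGT", mate_of="a/1")
        with pytest.raises(ContractError):
            prepare_binning_input([(r1, r2)], [], MergeParams())


class TestPairUp:
    def test_explicit_links_and_suffix_convention(self):
        reads = [
            Read("x", "ACGT", mate_of="y"),
            Read("y", "ACGT", mate_of="x"),
            Read("s/1", "ACGT"),
            Read("s/2", "ACGT"),
            Read("lonely", "ACGT"),
        ]
        pairs, singles = pair_up(reads)
        assert [(a.read_id, b.read_id) for a, b in pairs] == [("x", "y"), ("s/1", "s/2")]
        assert [r.read_id for r in singles] == ["lonely"]

    def test_dangling_explicit_link_names_read(self):
        with pytest.raises(ContractError, match="gone"):
            pair_up([Read("a", "ACGT", mate_of="gone")])

    def test_missing_inferred_mate_stays_single(self):
        pairs, singles = pair_up([Read("a/1", "ACGT")])
        assert pairs == [] and [r.read_id for r in singles] == ["a/1"]


class TestRestoreOriginal:
    def test_empty(self):
        assert restore_original([], {}) == []

    def test_forced_pair_restores_both_mates(self):
        prov = {"a/1+a/2": ("a/1", "a/2")}
        assert restore_original(["a/1+a/2"], prov) == ["a/1", "a/2"]

    def test_union_without_duplicates(self):
        prov = {
            "m1": ("r1", "r2"),
            "m2": ("r2", "r3"),
            "m3": ("r4", "r5"),
        }
        assert restore_original(["m1", "m2", "m3"], prov) == ["r1", "r2", "r3", "r4", "r5"]

    def test_unknown_merged_id_rejected(self):
        with pytest.raises(ContractError, match="mystery"):
            restore_original(["mystery"], {})
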