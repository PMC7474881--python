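import pytest
from hypothesis import given
from hypothesis import strategies as st

from ovbin.errors import ConfigurationError, ContractError, ParseError
from ovbin.sequence_io import (
    Read,
    TrimParams,
    read_sequences,
    trim_reads,
    write_sequences,
)

dna = st.text(alphabet="ACGTN", min_size=1, max_size=60)


def reads_strategy(with_quals: bool):
    def build(seqs):
        out = []
        for i, seq in enumerate(seqs):
            quals = [(i + j) % 42 for j in range(len(seq))] if with_quals else None
            out.append(Read(f"read_{i:03d}", seq, quals))
        return out

    return st.lists(dna, min_size=0, max_size=8).map(build)


class TestParsing:
    def test_empty_fastq_gives_empty_collection(self, tmp_path):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        assert read_sequences(path, "fastq") == []

    def test_fastq_qualities_decode_phred33(self, tmp_path):
        path = tmp_path / "two.fastq"
        path.write_text("@r1\nAC\n+\nII\n@r2\nGT\n+\nII\n")
        reads = read_sequences(path, "fastq")
        assert [r.read_id for r in reads] == ["r1", "r2"]
        # 'I' is ASCII 73 -> phred 40
        assert reads[0].qualities == [40, 40]
        assert reads[1].qualities == [40, 40]

    def test_fasta_record_has_no_qualities(self, tmp_path):
        path = tmp_path / "one.fasta"
        path.write_text(">r1\nACGT\n")
        (read,) = read_sequences(path, "fasta")
        assert read.sequence == "ACGT" and read.qualities is None

    def test_wrapped_fasta_accepted(self, tmp_path):
        path = tmp_path / "wrap.fasta"
        path.write_text(">r1\nACGT\nACGT\n")
        (read,) = read_sequences(path, "fasta")
        assert read.sequence == "ACGTACGT"

    def test_malformed_fastq_names_record_index(self, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r1\nACGT\n+\nII\n")  # 4 bases, 2 quality chars
        with pytest.raises(ParseError, match="index 0"):
            read_sequences(path, "fastq")

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">r1\nAC\n>r1\nGT\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_sequences(path, "fasta")

    @pytest.mark.parametrize("fmt", ["sff", "bam", ""])
    def test_unknown_format_rejected(self, tmp_path, fmt):
        path = tmp_path / "x"
        path.write_text("")
        with pytest.raises(ConfigurationError):
            read_sequences(path, fmt)

    def test_lowercase_normalized_and_bad_chars_rejected(self):
        assert Read("r", "acgtn").sequence == "ACGTN"
        with pytest.raises(ParseError):
            Read("r", "ACGU")


class TestWriting:
    def test_empty_collection_writes_empty_file(self, tmp_path):
        path = tmp_path / "out.fasta"
        assert write_sequences([], path, "fasta") == 0
        assert path.read_text() == ""

    def test_fasta_emits_two_lines_per_record(self, tmp_path):
        reads = [Read(f"r{i}", "ACGT" * 20) for i in range(3)]
        path = tmp_path / "out.fasta"
        assert write_sequences(reads, path, "fasta") == 3
        assert len(path.read_text().splitlines()) == 6

    def test_fastq_requires_qualities(self, tmp_path):
        with pytest.raises(ContractError):
            write_sequences([Read("r", "ACGT")], tmp_path / "x.fastq", "fastq")

    @given(reads=reads_strategy(with_quals=True))
    def test_fastq_round_trip_identity(self, tmp_path_factory, reads):
        path = tmp_path_factory.mktemp("rt") / "rt.fastq"
        write_sequences(reads, path, "fastq")
        back = read_sequences(path, "fastq")
        assert [(r.read_id, r.sequence, r.qualities) for r in back] == [
            (r.read_id, r.sequence, r.qualities) for r in reads
        ]

    @given(reads=reads_strategy(with_quals=False))
    def test_fasta_round_trip_identity(self, tmp_path_factory, reads):
        path = tmp_path_factory.mktemp("rt") / "rt.fasta"
        write_sequences(reads, path, "fasta")
        back = read_sequences(path, "fasta")
        assert [(r.read_id, r.sequence) for r in back] == [
            (r.read_id, r.sequence) for r in reads
        ]


class TestTrimming:
    def test_high_quality_read_unchanged(self):
        read = Read("r", "A" * 100, [35] * 100)
        kept, stats = trim_reads([read], TrimParams(30, 60))
        assert kept == [read] and stats == (0, 0)

    def test_length_59_dropped_at_floor_60(self):
        read = Read("r", "A" * 59, [35] * 59)
        kept, stats = trim_reads([read], TrimParams(30, 60))
        assert kept == [] and stats.dropped == 1

    def test_end_runs_removed_interior_untouched(self):
        read = Read("r", "ACGTAC", [10, 10, 35, 35, 35, 10])
        kept, stats = trim_reads([read], TrimParams(30, 1))
        assert kept[0].sequence == "GTA"
        assert kept[0].qualities == [35, 35, 35]
        assert stats.trimmed_bases == 3

    def test_interior_low_quality_base_survives(self):
        read = Read("r", "ACGTA", [35, 35, 5, 35, 35])
        kept, _ = trim_reads([read], TrimParams(30, 1))
        assert kept[0].sequence == "ACGTA"

    def test_fasta_reads_only_length_filtered(self):
        reads = [Read("a", "A" * 70), Read("b", "A" * 10)]
        kept, stats = trim_reads(reads, TrimParams(30, 60))
        assert [r.read_id for r in kept] == ["a"] and stats.trimmed_bases == 0

    @given(
        st.lists(
            st.lists(st.integers(min_value=0, max_value=41), min_size=1, max_size=80),
            min_size=0,
            max_size=6,
        )
    )
    def test_idempotent_and_invariants(self, qual_lists):
        params = TrimParams(30, 5)
        reads = [
            Read(f"r{i}", "A" * len(quals), quals) for i, quals in enumerate(qual_lists)
        ]
        kept, stats = trim_reads(reads, params)
        assert stats.dropped + len(kept) == len(reads)
        for r in kept:
            assert len(r) >= params.min_length
            assert r.qualities[0] >= params.min_quality
            assert r.qualities[-1] >= params.min_quality
        again, stats2 = trim_reads(kept, params)
        assert again == kept and stats2 == (0, 0)
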