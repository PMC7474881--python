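"""FASTA/FASTQ input and output plus quality trimming and length filtering.

Reads are lightweight records over the alphabet {A, C, G, T, N}; FASTQ
qualities follow the phred+33 convention.  The trimming stage removes the
maximal run of low-quality bases from each end of a read and drops reads
that end up shorter than a length floor — the quality-control front end of
the binning workflow (default thresholds Q30 / 60 bp).  End trimming is
deliberately simple (strict prefix/suffix scan, no sliding window) so that
it is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from Bio import SeqIO

from .errors import ConfigurationError, ContractError, ParseError

_ALPHABET = frozenset("ACGTN")

#: file formats accepted by :func:`read_sequences` / :func:`write_sequences`
FORMATS = ("fasta", "fastq")


@dataclass
class Read:
    """One sequencing read.

    Parameters
    ----------
    read_id
        Identifier, unique within a dataset.
    sequence
        Bases over {A, C, G, T, N}; normalized to upper case.
    qualities
        Optional phred scores (one per base, >= 0).
    mate_of
        ``read_id`` of the paired mate, when the read is one half of a pair.
    origin
        Optional provenance tag (the source genome label for simulated reads).
    """

    read_id: str
    sequence: str
    qualities: list[int] | None = None
    mate_of: str | None = None
    origin: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ParseError(
                f"read {self.read_id!r}: invalid characters {sorted(bad)} "
                "(allowed: A, C, G, T, N)"
            )
        if self.qualities is not None:
            if len(self.qualities) != len(self.sequence):
                raise ParseError(
                    f"read {self.read_id!r}: {len(self.qualities)} quality values "
                    f"for {len(self.sequence)} bases"
                )
            if any(q < 0 for q in self.qualities):
                raise ParseError(f"read {self.read_id!r}: negative phred score")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TrimParams:
    """Quality/length thresholds for :func:`trim_reads`.

    ``min_quality`` is the phred score below which end bases are trimmed;
    ``min_length`` is the shortest read kept after trimming.
    """

    min_quality: int = 30
    min_length: int = 60

    def __post_init__(self) -> None:
        if self.min_quality < 0:
            raise ConfigurationError("min_quality must be >= 0")
        if self.min_length < 1:
            raise ConfigurationError("min_length must be >= 1")


class TrimStats(NamedTuple):
    trimmed_bases: int
    dropped: int


def record_id(rec) -> str:
    """Identifier of a :class:`Read` or a merged read, duck-typed."""
    rid = getattr(rec, "merged_id", None)
    if rid is not None:
        return rid
    return rec.read_id


def _check_format(fmt: str) -> None:
    if fmt == "sff":
        raise ConfigurationError(
            "SFF input is not supported; convert to FASTA or FASTQ first"
        )
    if fmt not in FORMATS:
        raise ConfigurationError(
            f"unknown sequence format {fmt!r}; expected one of {FORMATS}"
        )


def read_sequences(path: str | Path, format: str) -> list[Read]:
    """Parse *path* as FASTA or FASTQ into a list of :class:`Read`.

    FASTQ qualities are decoded with the phred+33 convention; FASTA records
    get ``qualities=None``.  Record order is preserved.  Malformed records
    raise :class:`ParseError` naming the failing record index; duplicate ids
    are rejected.
    """
    _check_format(format)
    path = Path(path)
    reads: list[Read] = []
    seen: set[str] = set()
    with open(path) as handle:
        records = SeqIO.parse(handle, format)
        index = 0
        while True:
            try:
                rec = next(records)
            except StopIteration:
                break
            except ValueError as exc:
                raise ParseError(
                    f"{path}: malformed {format} record at index {index}: {exc}"
                ) from exc
            quals = rec.letter_annotations.get("phred_quality")
            read = Read(rec.id, str(rec.seq), list(quals) if quals is not None else None)
            if read.read_id in seen:
                raise ParseError(f"{path}: duplicate read id {read.read_id!r}")
            seen.add(read.read_id)
            reads.append(read)
            index += 1
    return reads


def write_sequences(reads: Iterable, path: str | Path, format: str) -> int:
    """Write reads to *path*; returns the record count.

    FASTA records are emitted as two lines each (header, sequence); FASTQ as
    four lines with phred+33 qualities.  Accepts anything with ``sequence``
    and an id (plain or merged reads).  Requesting FASTQ for a read without
    qualities is a contract violation.
    """
    _check_format(format)
    count = 0
    with open(path, "w") as out:
        for rec in reads:
            rid = record_id(rec)
            seq = rec.sequence
            if format == "fasta":
                out.write(f">{rid}\n{seq}\n")
            else:
                quals = getattr(rec, "qualities", None)
                if quals is None:
                    raise ContractError(
                        f"read {rid!r} has no qualities; cannot write FASTQ"
                    )
                qline = "".join(chr(q + 33) for q in quals)
                out.write(f"@{rid}\n{seq}\n+\n{qline}\n")
            count += 1
    return count


def _trim_one(read: Read, min_quality: int) -> Read | None:
    """Strip the maximal low-quality prefix and suffix; None when empty."""
    quals = read.qualities
    assert quals is not None
    start = 0
    end = len(quals)
    while start < end and quals[start] < min_quality:
        start += 1
    while end > start and quals[end - 1] < min_quality:
        end -= 1
    if start == 0 and end == len(quals):
        return read
    if start >= end:
        return None
    return Read(
        read.read_id,
        read.sequence[start:end],
        quals[start:end],
        mate_of=read.mate_of,
        origin=read.origin,
    )


def trim_reads(
    reads: Sequence[Read], params: TrimParams = TrimParams()
) -> tuple[list[Read], TrimStats]:
    """End-trim low-quality bases and drop short reads.

    For each read with qualities, the maximal run of bases with quality
    strictly below ``params.min_quality`` is removed from each end (interior
    bases are untouched).  Reads without qualities (FASTA input) skip
    trimming and only pass through the length filter.  Reads shorter than
    ``params.min_length`` after trimming are dropped.  Input order is
    preserved; the operation is idempotent.
    """
    kept: list[Read] = []
    trimmed_bases = 0
    dropped = 0
    for read in reads:
        if read.qualities is None:
            out: Read | None = read
        else:
            out = _trim_one(read, params.min_quality)
            trimmed_bases += len(read) - (len(out) if out is not None else 0)
        if out is None or len(out) < params.min_length:
            dropped += 1
            continue
        kept.append(out)
    return kept, TrimStats(trimmed_bases=trimmed_bases, dropped=dropped)
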