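"""Screening of ribosomal (16S-like) reads before binning.

Conserved genes such as 16S rRNA are nearly identical across species, so
reads carrying them connect reads from different organisms in the overlap
graph and fuse bins.  This module partitions reads into *ribosomal* and
*passthrough* fractions by mapping them against a user-supplied reference
FASTA (any 16S collection works) with a built-in seed-and-extend ungapped
mapper: a read is ribosomal when a shared seed k-mer lies on a diagonal
containing a window of ``min_aligned`` bases at identity >= ``min_identity``.
Only separation is performed — taxonomic classification of the ribosomal
fraction is left to external tools, and users of a full read mapper can
inject an externally produced id list instead.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError
from .overlap_index import encode, _N_CODE
from .pair_prep import revcomp
from .sequence_io import Read, read_sequences, record_id, write_sequences


@dataclass(frozen=True)
class ScreenParams:
    """Seed length, identity and aligned-length thresholds for screening."""

    seed_k: int = 21
    min_identity: float = 0.9
    min_aligned: int = 50

    def __post_init__(self) -> None:
        if not 1 <= self.seed_k <= self.min_aligned:
            raise ConfigurationError("require 1 <= seed_k <= min_aligned")
        if not 0.0 < self.min_identity <= 1.0:
            raise ConfigurationError("min_identity must be in (0, 1]")


@dataclass
class RrnaPartition:
    """Disjoint split of the input ids; their union is the input set."""

    ribosomal_ids: tuple[str, ...]
    passthrough_ids: tuple[str, ...]


@dataclass
class ReferenceIndex:
    """K-mer index over both strands of a reference sequence set."""

    seed_k: int
    kmers: dict[str, list[tuple[str, str, int]]]  # kmer -> [(ref_id, strand, pos)]
    strands: dict[tuple[str, str], str]  # (ref_id, strand) -> sequence


def build_reference_index(
    ref: str | Path | Sequence, seed_k: int = 21
) -> ReferenceIndex:
    """Index every N-free k-mer of every reference sequence, both strands.

    ``ref`` is a FASTA path or a sequence of read-like records.  An empty
    reference is a configuration error; references shorter than ``seed_k``
    contribute nothing (a warning is emitted if *no* sequence is indexable).
    """
    if isinstance(ref, (str, Path)):
        records = read_sequences(ref, "fasta")
    else:
        records = list(ref)
    if not records:
        raise ConfigurationError("reference FASTA contains no sequences")
    kmers: dict[str, list[tuple[str, str, int]]] = {}
    strands: dict[tuple[str, str], str] = {}
    indexed_any = False
    for rec in records:
        rid = record_id(rec)
        for strand, seq in (("+", rec.sequence), ("-", revcomp(rec.sequence))):
            strands[(rid, strand)] = seq
            if len(seq) < seed_k:
                continue
            has_n = "N" in seq
            for i in range(len(seq) - seed_k + 1):
                kmer = seq[i : i + seed_k]
                if has_n and "N" in kmer:
                    continue
                kmers.setdefault(kmer, []).append((rid, strand, i))
                indexed_any = True
    if not indexed_any:
        warnings.warn(
            f"no reference sequence reaches seed_k={seed_k}; index is empty",
            stacklevel=2,
        )
    return ReferenceIndex(seed_k=seed_k, kmers=kmers, strands=strands)


def _is_ribosomal(seq: str, index: ReferenceIndex, params: ScreenParams) -> bool:
    k = index.seed_k
    if len(seq) < k:
        return False
    diagonals: set[tuple[str, str, int]] = set()
    has_n = "N" in seq
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if has_n and "N" in kmer:
            continue
        for rid, strand, pos in index.kmers.get(kmer, ()):
            diagonals.add((rid, strand, pos - i))
    if not diagonals:
        return False
    w = params.min_aligned
    need = params.min_identity * w - 1e-9
    enc_read = encode(seq)
    kernel = np.ones(w, dtype=np.int64)
    for rid, strand, diag in sorted(diagonals):
        ref_seq = index.strands[(rid, strand)]
        lo = max(0, -diag)
        hi = min(len(seq), len(ref_seq) - diag)
        if hi - lo < w:
            continue
        a = enc_read[lo:hi]
        t = encode(ref_seq[lo + diag : hi + diag])
        ok = ((a == t) & (a != _N_CODE)).astype(np.int64)
        if np.convolve(ok, kernel, mode="valid").max() >= need:
            return True
    return False


def partition_rrna(
    reads: Sequence, index: ReferenceIndex, params: ScreenParams = ScreenParams()
) -> RrnaPartition:
    """Split reads into ribosomal vs passthrough fractions.

    Deterministic; input order is preserved within each fraction.  The
    classification is strand-symmetric because the index covers both
    reference strands.
    """
    ribo: list[str] = []
    passthrough: list[str] = []
    for rec in reads:
        rid = record_id(rec)
        if _is_ribosomal(rec.sequence, index, params):
            ribo.append(rid)
        else:
            passthrough.append(rid)
    return RrnaPartition(ribosomal_ids=tuple(ribo), passthrough_ids=tuple(passthrough))


def partition_from_id_list(
    reads: Sequence, ribosomal_ids: Iterable[str]
) -> RrnaPartition:
    """Adapter: accept an externally produced ribosomal id list (e.g. from a
    full read mapper) in place of the built-in mapper."""
    flagged = set(ribosomal_ids)
    ribo = tuple(record_id(r) for r in reads if record_id(r) in flagged)
    rest = tuple(record_id(r) for r in reads if record_id(r) not in flagged)
    return RrnaPartition(ribosomal_ids=ribo, passthrough_ids=rest)


def write_partition(
    reads: Sequence,
    partition: RrnaPartition,
    ribosomal_fasta: str | Path,
    passthrough_fasta: str | Path,
    classes_tsv: str | Path,
) -> None:
    """Write the two read fractions as FASTA plus a read_id -> class TSV."""
    by_id = {record_id(r): r for r in reads}
    write_sequences([by_id[r] for r in partition.ribosomal_ids], ribosomal_fasta, "fasta")
    write_sequences(
        [by_id[r] for r in partition.passthrough_ids], passthrough_fasta, "fasta"
    )
    with open(classes_tsv, "w", newline="") as out:
        writer = csv.writer(out, delimiter="\t", lineterminator="\n")
        writer.writerow(["read_id", "class"])
        for rid in partition.ribosomal_ids:
            writer.writerow([rid, "ribosomal"])
        for rid in partition.passthrough_ids:
            writer.writerow([rid, "passthrough"])
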