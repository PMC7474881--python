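"""Synthetic metagenome communities with ground truth.

Generates mixed-species read sets at desk scale: random genomes with
controlled relative abundances, an optional conserved segment copied into
every genome (emulating a ribosomal gene shared across species), and
error-bearing single or paired-end reads.  Every read is labeled with its
source genome in a :class:`TruthTable`, so binning runs can be scored
exactly at the read level.

The error model is substitution-only: the default overlap detector is
exact-match, and indels would conflate the error model with the aligner.
Genomes are linear and single-copy; reads sample both strands with
probability 1/2.  ``coverage`` is the mean per-genome fold coverage, so
the per-genome read count is ``n_genomes * abundance * genome_length *
coverage / read_length`` (half that many pairs in paired mode, keeping the
sequenced base count fixed).  Everything is deterministic given the seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .pair_prep import revcomp
from .sequence_io import Read

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class CommunitySpec:
    """Composition of a synthetic community.

    ``abundances`` are relative weights (normalized to sum 1; equal when
    omitted); ``conserved_segment_length`` > 0 plants one shared segment at
    a random position in every genome.
    """

    n_genomes: int
    genome_length: int
    abundances: tuple[float, ...] | None = None
    conserved_segment_length: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1 or self.genome_length < 1:
            raise ConfigurationError("n_genomes and genome_length must be >= 1")
        if self.abundances is not None:
            object.__setattr__(self, "abundances", tuple(self.abundances))
            if len(self.abundances) != self.n_genomes:
                raise ConfigurationError("need one abundance per genome")
            if any(a <= 0 for a in self.abundances):
                raise ConfigurationError("abundances must be > 0")
        if not 0 <= self.conserved_segment_length < self.genome_length:
            raise ConfigurationError(
                "conserved_segment_length must be < genome_length"
            )

    def normalized_abundances(self) -> tuple[float, ...]:
        if self.abundances is None:
            return tuple([1.0 / self.n_genomes] * self.n_genomes)
        total = sum(self.abundances)
        return tuple(a / total for a in self.abundances)


@dataclass(frozen=True)
class ReadSimSpec:
    """Read sampling parameters: coverage, geometry and error rate."""

    coverage: float = 20.0
    read_length: int = 150
    error_rate: float = 0.0
    paired: bool = False
    insert_mean: float = 350.0
    insert_sd: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 1.0:
            raise ConfigurationError("error_rate must be in [0, 1)")
        if self.coverage < 0:
            raise ConfigurationError("coverage must be >= 0")
        if self.read_length < 1:
            raise ConfigurationError("read_length must be >= 1")


@dataclass
class TruthTable:
    """read_id -> source genome label, plus the genome sequences.

    ``positions`` additionally records each read's source span as
    ``(start, end, strand)`` in genome coordinates ('-' meaning the read is
    the reverse complement of the slice); it is kept in memory only and not
    serialized by :meth:`save`.
    """

    read_to_genome: dict[str, str]
    genomes: dict[str, str]
    positions: dict[str, tuple[int, int, str]] = field(default_factory=dict)

    def source_slice(self, read_id: str) -> str:
        """The error-free sequence the read was sampled from, oriented as
        the read."""
        start, end, strand = self.positions[read_id]
        slice_ = self.genomes[self.read_to_genome[read_id]][start:end]
        return slice_ if strand == "+" else revcomp(slice_)

    def label(self, read_id: str) -> str:
        return self.read_to_genome[read_id]

    def save(self, path: str | Path) -> None:
        with open(path, "w", newline="") as out:
            writer = csv.writer(out, delimiter="\t", lineterminator="\n")
            writer.writerow(["read_id", "genome"])
            for rid in sorted(self.read_to_genome):
                writer.writerow([rid, self.read_to_genome[rid]])

    @classmethod
    def load(cls, path: str | Path) -> "TruthTable":
        mapping: dict[str, str] = {}
        with open(path, newline="") as handle:
            rows = csv.reader(handle, delimiter="\t")
            next(rows, None)
            for row in rows:
                if row:
                    mapping[row[0]] = row[1]
        return cls(read_to_genome=mapping, genomes={})


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode("ascii")


def simulate_community(
    spec: CommunitySpec,
) -> tuple[dict[str, str], str | None]:
    """Draw the community's genomes (and the shared segment, if any).

    Genomes are i.i.d. uniform over {A, C, G, T}; the conserved segment is
    one shared sequence written over a random window of each genome, keeping
    genome lengths exact.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    segment: str | None = None
    if spec.conserved_segment_length > 0:
        segment = _random_sequence(rng, spec.conserved_segment_length)
    genomes: dict[str, str] = {}
    for i in range(spec.n_genomes):
        label = f"genome_{i + 1:02d}"
        seq = _random_sequence(rng, spec.genome_length)
        if segment is not None:
            pos = int(rng.integers(0, spec.genome_length - len(segment) + 1))
            seq = seq[:pos] + segment + seq[pos + len(segment) :]
        genomes[label] = seq
    return genomes, segment


def _apply_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate == 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < error_rate)
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return bytes(arr).decode("ascii")


def simulate_reads(
    genomes: Mapping[str, str],
    abundances: Sequence[float],
    sim: ReadSimSpec,
) -> tuple[list[Read], TruthTable]:
    """Sample labeled reads from the community.

    Per-genome counts follow ``n_genomes * abundance * genome_length *
    coverage / read_length`` (pairs count as two reads of fixed total
    yield).  Start positions are uniform; paired mode draws the fragment
    length from a normal distribution clipped to [read_length,
    genome_length] and emits mates from opposite fragment ends.
    """
    labels = list(genomes)
    if len(abundances) != len(labels):
        raise ConfigurationError("need one abundance per genome")
    total = float(sum(abundances))
    weights = [a / total for a in abundances]
    rng = np.random.default_rng(sim.seed)
    k = len(labels)
    reads: list[Read] = []
    truth: dict[str, str] = {}
    positions: dict[str, tuple[int, int, str]] = {}

    for label, weight in zip(labels, weights):
        genome = genomes[label]
        g_len = len(genome)
        rl = sim.read_length
        if rl > g_len:
            raise ConfigurationError(
                f"read_length {rl} exceeds genome length of {label}"
            )
        yield_per_unit = 2 * rl if sim.paired else rl
        n_units = int(round(k * weight * g_len * sim.coverage / yield_per_unit))
        for j in range(n_units):
            if sim.paired:
                frag = int(
                    np.clip(round(rng.normal(sim.insert_mean, sim.insert_sd)), rl, g_len)
                )
                start = int(rng.integers(0, g_len - frag + 1))
                fragment = genome[start : start + frag]
                flipped = rng.random() < 0.5
                if flipped:
                    fragment = revcomp(fragment)
                r1_seq = _apply_errors(fragment[:rl], rng, sim.error_rate)
                r2_seq = _apply_errors(revcomp(fragment[-rl:]), rng, sim.error_rate)
                id1 = f"{label}_p{j:06d}/1"
                id2 = f"{label}_p{j:06d}/2"
                if flipped:
                    positions[id1] = (start + frag - rl, start + frag, "-")
                    positions[id2] = (start, start + rl, "+")
                else:
                    positions[id1] = (start, start + rl, "+")
                    positions[id2] = (start + frag - rl, start + frag, "-")
                reads.append(
                    Read(id1, r1_seq, [40] * rl, mate_of=id2, origin=label)
                )
                reads.append(
                    Read(id2, r2_seq, [40] * rl, mate_of=id1, origin=label)
                )
                truth[id1] = label
                truth[id2] = label
            else:
                start = int(rng.integers(0, g_len - rl + 1))
                seq = genome[start : start + rl]
                flipped = rng.random() < 0.5
                if flipped:
                    seq = revcomp(seq)
                seq = _apply_errors(seq, rng, sim.error_rate)
                rid = f"{label}_r{j:06d}"
                reads.append(Read(rid, seq, [40] * rl, origin=label))
                truth[rid] = label
                positions[rid] = (start, start + rl, "-" if flipped else "+")
    return reads, TruthTable(
        read_to_genome=truth, genomes=dict(genomes), positions=positions
    )


def shared_kmer_exists(seq_a: str, seq_b: str, k: int) -> bool:
    """True when the two sequences share a k-mer on either strand —
    equivalently, when their longest common substring is >= k.  Used to
    verify the no-shared-sequence premise of purity checks cheaply."""
    kmers_a = {seq_a[i : i + k] for i in range(len(seq_a) - k + 1)}
    rc_b = revcomp(seq_b)
    for s in (seq_b, rc_b):
        for i in range(len(s) - k + 1):
            if s[i : i + k] in kmers_a:
                return True
    return False
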