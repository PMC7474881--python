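"""All-vs-all read overlap detection and the read-overlap graph.

Two reads are connected when they share an alignment of at least ``b``
bases on either strand.  With ``max_mismatches = 0`` (the default) an
alignment is a maximal exact common substring, which admits a complete
accelerated algorithm: a shared substring of length >= b implies a shared
b-mer, so candidate pairs are drawn from a canonical b-mer index and every
candidate is verified with an exact longest-common-substring computation.
``find_overlaps_bruteforce`` performs the same verification on *all* pairs
and serves as the independent oracle in the test suite.

A mismatch-tolerant mode is provided (seeds of length ceil(b/(m+1)),
pigeonhole-complete, plus an ungapped scan) but is not the default.
``N`` bases never match anything.

Edges are undirected, one per read pair, carrying the maximal shared
length and the strand ("same"/"opposite") that achieved it.  Iteration
orders are fixed by lexicographic read id, so output is deterministic.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .errors import ContractError
from .pair_prep import revcomp
from .sequence_io import record_id

#: alias: the overlap graph is an undirected networkx graph whose nodes are
#: read ids and whose edges carry ``length`` and ``strand`` attributes.
OverlapGraph = nx.Graph

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGTN"):
    _CODE[ord(_c)] = _i
_N_CODE = 4


@dataclass(frozen=True, order=True)
class Overlap:
    """An undirected alignment relation between two reads.

    ``id_a < id_b`` lexicographically; ``length`` is the maximal shared
    alignment length; ``strand`` is "same" or "opposite".
    """

    id_a: str
    id_b: str
    length: int
    strand: str


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def lcs_length(a: np.ndarray, b: np.ndarray) -> int:
    """Length of the longest exact common substring of two encoded sequences.

    N (code 4) matches nothing.  Implemented by shearing the match matrix so
    diagonals become columns, then taking the longest vertical run — a fully
    vectorized equivalent of the classic dynamic programme.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return 0
    match = (a[:, None] == b[None, :]) & (a[:, None] != _N_CODE)
    sheared = np.zeros((n, n + m - 1), dtype=bool)
    rows = np.arange(n)[:, None]
    cols = np.arange(m)[None, :] + (n - 1 - np.arange(n))[:, None]
    sheared[rows, cols] = match
    csum = sheared.cumsum(axis=0)
    reset = np.where(~sheared, csum, 0)
    floor = np.maximum.accumulate(reset, axis=0)
    runs = np.where(sheared, csum - floor, 0)
    return int(runs.max())


def _best_window(a: np.ndarray, b: np.ndarray, max_mismatches: int) -> int:
    """Longest ungapped alignment with <= max_mismatches mismatching columns.

    Considers every offset of *a* against *b*; a window must start and end on
    a match.  N columns count as mismatches.
    """
    n, m = len(a), len(b)
    best = 0
    for diag in range(-(m - 1), n):
        lo_a = max(0, diag)
        lo_b = lo_a - diag
        span = min(n - lo_a, m - lo_b)
        if span <= best:
            continue
        va = a[lo_a : lo_a + span]
        vb = b[lo_b : lo_b + span]
        ok = (va == vb) & (va != _N_CODE)
        # two-pointer over the match vector, windows anchored on matches
        left = 0
        mism = 0
        first_match = -1
        match_pos = np.flatnonzero(ok)
        if match_pos.size == 0:
            continue
        next_match = np.full(span + 1, span, dtype=np.int64)
        next_match[match_pos] = match_pos
        for i in range(span - 1, -1, -1):
            if next_match[i] == span:
                next_match[i] = next_match[i + 1]
        for right in range(span):
            if not ok[right]:
                mism += 1
                while mism > max_mismatches:
                    if not ok[left]:
                        mism -= 1
                    left += 1
                continue
            start = next_match[left]
            best = max(best, right - start + 1)
    return best


def pair_overlap(
    seq_a: str, seq_b: str, b: int, max_mismatches: int = 0
) -> tuple[int, str] | None:
    """Maximal alignment length and strand for one read pair, or None.

    Symmetric in its arguments.  Strand ties resolve to "same".
    """
    ea = encode(seq_a)
    eb = encode(seq_b)
    er = encode(revcomp(seq_b))
    if max_mismatches == 0:
        l_same = lcs_length(ea, eb)
        l_opp = lcs_length(ea, er)
    else:
        l_same = _best_window(ea, eb, max_mismatches)
        l_opp = _best_window(ea, er, max_mismatches)
    length = max(l_same, l_opp)
    if length < b:
        return None
    return length, ("same" if l_same >= l_opp else "opposite")


def _read_seqs(reads: Sequence) -> tuple[list[str], list[str]]:
    ids = [record_id(r) for r in reads]
    if len(set(ids)) != len(ids):
        raise ContractError("read ids are not unique")
    return ids, [r.sequence for r in reads]


def _make_overlap(id_x: str, id_y: str, length: int, strand: str) -> Overlap:
    if id_x < id_y:
        return Overlap(id_x, id_y, length, strand)
    return Overlap(id_y, id_x, length, strand)


def find_overlaps_bruteforce(
    reads: Sequence, b: int, max_mismatches: int = 0
) -> set[Overlap]:
    """All-pairs overlap detection: the reference oracle.

    Examines every unordered read pair on both strands; quadratic in the
    number of reads and intended for small instances and verification.
    """
    ids, seqs = _read_seqs(reads)
    out: set[Overlap] = set()
    for i, j in itertools.combinations(range(len(reads)), 2):
        hit = pair_overlap(seqs[i], seqs[j], b, max_mismatches)
        if hit is not None:
            out.add(_make_overlap(ids[i], ids[j], hit[0], hit[1]))
    return out


def _kmer_candidates(seqs: Sequence[str], k: int) -> set[tuple[int, int]]:
    """Unordered index pairs of reads sharing at least one canonical k-mer."""
    buckets: dict[str, list[int]] = {}
    for idx, seq in enumerate(seqs):
        if len(seq) < k:
            continue
        has_n = "N" in seq
        seen: set[str] = set()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if has_n and "N" in kmer:
                continue
            rc = revcomp(kmer)
            canonical = kmer if kmer <= rc else rc
            if canonical in seen:
                continue
            seen.add(canonical)
            buckets.setdefault(canonical, []).append(idx)
    pairs: set[tuple[int, int]] = set()
    for members in buckets.values():
        if len(members) < 2:
            continue
        for x, y in itertools.combinations(members, 2):
            pairs.add((x, y) if x < y else (y, x))
    return pairs


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    """N-free k-mer -> start positions for one sequence."""
    out: dict[str, list[int]] = {}
    if len(seq) < k:
        return out
    has_n = "N" in seq
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if has_n and "N" in kmer:
            continue
        out.setdefault(kmer, []).append(i)
    return out


def _max_shared(da: dict[str, list[int]], db: dict[str, list[int]], k: int) -> int:
    """Maximal shared-substring length between two sequences given their
    k-mer position maps; exact for all lengths >= k (0 when none).

    A shared substring of length L >= k contributes exactly L - k + 1
    consecutive k-mer hits on one diagonal, so the answer is the longest
    such run plus k - 1.
    """
    if len(da) > len(db):
        da, db = db, da
    diagonals: dict[int, list[int]] = {}
    for kmer, pa in da.items():
        pb = db.get(kmer)
        if not pb:
            continue
        for x in pa:
            for y in pb:
                diagonals.setdefault(y - x, []).append(x)
    best = 0
    for xs in diagonals.values():
        xs.sort()
        run = 1
        for prev, cur in zip(xs, xs[1:]):
            if cur == prev + 1:
                run += 1
            else:
                best = max(best, run)
                run = 1
        best = max(best, run)
    return best + k - 1 if best else 0


def _candidates_from_kmer_maps(
    maps: Sequence[dict[str, list[int]]]
) -> set[tuple[int, int]]:
    buckets: dict[str, list[int]] = {}
    for idx, kmap in enumerate(maps):
        seen: set[str] = set()
        for kmer in kmap:
            rc = revcomp(kmer)
            canonical = kmer if kmer <= rc else rc
            if canonical in seen:
                continue
            seen.add(canonical)
            buckets.setdefault(canonical, []).append(idx)
    pairs: set[tuple[int, int]] = set()
    for members in buckets.values():
        if len(members) < 2:
            continue
        for x, y in itertools.combinations(members, 2):
            pairs.add((x, y))
    return pairs


def find_overlaps_indexed(
    reads: Sequence, b: int, max_mismatches: int = 0
) -> set[Overlap]:
    """Index-accelerated overlap detection; identical output to the oracle.

    Exact mode: any shared substring of length >= b contains a shared b-mer,
    so a canonical b-mer index enumerates a complete candidate set, and the
    maximal shared length of each candidate pair is recovered from the
    longest run of consecutive shared b-mers on a diagonal.  Mismatch mode:
    an alignment of length >= b with <= m mismatches contains an exact seed
    of length ceil(b/(m+1)) by pigeonhole; candidates are verified with the
    same per-pair scan the brute force uses.
    """
    ids, seqs = _read_seqs(reads)
    out: set[Overlap] = set()
    if max_mismatches == 0:
        fwd = [_kmer_positions(s, b) for s in seqs]
        rev = [_kmer_positions(revcomp(s), b) for s in seqs]
        for i, j in _candidates_from_kmer_maps(fwd):
            l_same = _max_shared(fwd[i], fwd[j], b)
            l_opp = _max_shared(fwd[i], rev[j], b)
            length = max(l_same, l_opp)
            if length >= b:
                strand = "same" if l_same >= l_opp else "opposite"
                out.add(_make_overlap(ids[i], ids[j], length, strand))
        return out
    seed = -(-b // (max_mismatches + 1))
    for i, j in _kmer_candidates(seqs, seed):
        hit = pair_overlap(seqs[i], seqs[j], b, max_mismatches)
        if hit is not None:
            out.add(_make_overlap(ids[i], ids[j], hit[0], hit[1]))
    return out


def build_graph(overlaps: Iterable[Overlap], node_ids: Iterable[str]) -> OverlapGraph:
    """Assemble the undirected overlap graph; isolated reads keep degree 0."""
    graph = nx.Graph()
    graph.add_nodes_from(node_ids)
    for ov in overlaps:
        if ov.id_a not in graph or ov.id_b not in graph:
            missing = ov.id_a if ov.id_a not in graph else ov.id_b
            raise ContractError(f"overlap endpoint {missing!r} is not a known read")
        if ov.id_a == ov.id_b:
            raise ContractError(f"self-overlap on {ov.id_a!r}")
        graph.add_edge(ov.id_a, ov.id_b, length=ov.length, strand=ov.strand)
    return graph


def write_overlaps(overlaps: Iterable[Overlap], path: str | Path) -> None:
    """TSV serialization: id_a, id_b, length, strand (sorted rows)."""
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, delimiter="\t", lineterminator="\n")
        writer.writerow(["id_a", "id_b", "length", "strand"])
        for ov in sorted(overlaps):
            writer.writerow([ov.id_a, ov.id_b, ov.length, ov.strand])


def read_overlaps(path: str | Path) -> set[Overlap]:
    out: set[Overlap] = set()
    with open(path, newline="") as handle:
        rows = csv.reader(handle, delimiter="\t")
        next(rows, None)
        for row in rows:
            if not row:
                continue
            out.add(Overlap(row[0], row[1], int(row[2]), row[3]))
    return out
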