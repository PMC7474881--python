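"""Paired-read preparation for binning.

Mates are collapsed to single fragments before overlap detection: an
overlap merge joins the 3' end of the forward read to the reverse
complement of its mate when they share a sufficiently long, sufficiently
clean overlap; pairs that cannot be merged are *force-merged* by
concatenating the forward read, a three-base ``NNN`` spacer, and the
reverse complement of the mate.  Because ``N`` never matches anything in
the overlap detector, the spacer keeps the two mates in one graph node
without inventing sequence.  The merged set is used only for binning;
``restore_original`` maps bin members back to the original read ids.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, ContractError
from .sequence_io import Read

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over {A, C, G, T, N}; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MergeParams:
    """Overlap-merge thresholds: minimum overlap length and the tolerated
    per-overlap mismatch fraction."""

    min_overlap: int = 10
    max_mismatch_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ConfigurationError("min_overlap must be >= 1")
        if not 0.0 <= self.max_mismatch_rate <= 1.0:
            raise ConfigurationError("max_mismatch_rate must be in [0, 1]")


@dataclass
class MergedRead:
    """A binning fragment representing one read pair or one single read."""

    merged_id: str
    sequence: str
    source_ids: tuple[str, ...]
    forced: bool = False
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.source_ids) <= 2:
            raise ContractError("source_ids must have 1 or 2 entries")

    def __len__(self) -> int:
        return len(self.sequence)


def merge_pair(r1: Read, r2: Read, params: MergeParams = MergeParams()) -> MergedRead | None:
    """Overlap-merge a mate pair; ``None`` signals that no merge was found.

    ``r2`` is given in sequencing orientation, so the merge considers its
    reverse complement.  The longest suffix of ``r1`` matching a prefix of
    ``revcomp(r2)`` with a mismatch fraction <= ``max_mismatch_rate`` and
    length >= ``min_overlap`` wins.  In the overlap, disagreeing positions
    take the base with the higher quality (ties go to ``r1``); merged
    qualities take the per-position maximum.
    """
    if len(r1) == 0 or len(r2) == 0:
        raise ContractError("cannot merge zero-length reads")
    rc = revcomp(r2.sequence)
    rcq = list(reversed(r2.qualities)) if r2.qualities is not None else None
    n1, n2 = len(r1), len(rc)
    for olap in range(min(n1, n2), params.min_overlap - 1, -1):
        tail = r1.sequence[n1 - olap :]
        head = rc[:olap]
        mismatches = sum(
            1 for x, y in zip(tail, head) if x != y or x == "N" or y == "N"
        )
        if mismatches <= params.max_mismatch_rate * olap:
            break
    else:
        return None

    q1 = r1.qualities
    consensus = []
    cons_quals: list[int] | None = [] if (q1 is not None and rcq is not None) else None
    for k in range(olap):
        i1 = n1 - olap + k
        b1, b2 = r1.sequence[i1], rc[k]
        qa = q1[i1] if q1 is not None else 0
        qb = rcq[k] if rcq is not None else 0
        consensus.append(b1 if (b1 == b2 or qa >= qb) else b2)
        if cons_quals is not None:
            cons_quals.append(max(qa, qb))
    seq = r1.sequence[: n1 - olap] + "".join(consensus) + rc[olap:]
    quals: list[int] | None = None
    if cons_quals is not None:
        quals = list(q1[: n1 - olap]) + cons_quals + list(rcq[olap:])
    return MergedRead(
        merged_id=f"{r1.read_id}+{r2.read_id}",
        sequence=seq,
        source_ids=(r1.read_id, r2.read_id),
        forced=False,
        qualities=quals,
    )


def force_merge(r1: Read, r2: Read) -> MergedRead:
    """Concatenate ``r1 + NNN + revcomp(r2)`` when no true overlap exists.

    The spacer bases get quality 0 when both mates carry qualities.
    """
    if len(r1) == 0 or len(r2) == 0:
        raise ContractError("cannot merge zero-length reads")
    rc = revcomp(r2.sequence)
    quals: list[int] | None = None
    if r1.qualities is not None and r2.qualities is not None:
        quals = list(r1.qualities) + [0, 0, 0] + list(reversed(r2.qualities))
    return MergedRead(
        merged_id=f"{r1.read_id}+{r2.read_id}",
        sequence=r1.sequence + "NNN" + rc,
        source_ids=(r1.read_id, r2.read_id),
        forced=True,
        qualities=quals,
    )


def _inferred_mate_id(read_id: str) -> str | None:
    if read_id.endswith("/1"):
        return read_id[:-2] + "/2"
    if read_id.endswith("/2"):
        return read_id[:-2] + "/1"
    return None


def pair_up(reads: Sequence[Read]) -> tuple[list[tuple[Read, Read]], list[Read]]:
    """Split a flat read collection into mate pairs and singles.

    Pairing uses explicit ``mate_of`` links first and falls back to the
    ``/1``–``/2`` id convention.  An explicit link to a missing read is a
    contract violation; an *inferred* mate that is absent simply leaves the
    read single.  Within a pair the read occurring first in the input is
    treated as the forward read.
    """
    by_id = {r.read_id: r for r in reads}
    pairs: list[tuple[Read, Read]] = []
    singles: list[Read] = []
    used: set[str] = set()
    for read in reads:
        if read.read_id in used:
            continue
        used.add(read.read_id)
        mate_id = read.mate_of
        inferred = mate_id is None
        if inferred:
            mate_id = _inferred_mate_id(read.read_id)
        if mate_id is None:
            singles.append(read)
            continue
        mate = by_id.get(mate_id)
        if mate is None:
            if inferred:
                singles.append(read)
                continue
            raise ContractError(
                f"read {read.read_id!r} names missing mate {mate_id!r}"
            )
        if mate.mate_of is not None and mate.mate_of != read.read_id:
            raise ContractError(
                f"asymmetric mate link between {read.read_id!r} and {mate.read_id!r}"
            )
        used.add(mate.read_id)
        pairs.append((read, mate))
    return pairs, singles


def prepare_binning_input(
    pairs: Sequence[tuple[Read, Read]],
    singles: Sequence[Read],
    params: MergeParams = MergeParams(),
) -> tuple[list[MergedRead], dict[str, tuple[str, ...]]]:
    """Build the merged fragment set for binning, plus its provenance map.

    Every pair yields exactly one :class:`MergedRead` (overlap merge when
    possible, forced merge otherwise); every single read passes through as a
    one-source fragment.  The provenance map is total over merged ids.
    """
    merged: list[MergedRead] = []
    provenance: dict[str, tuple[str, ...]] = {}
    for r1, r2 in pairs:
        if r1.mate_of is not None and r1.mate_of != r2.read_id:
            raise ContractError(
                f"read {r1.read_id!r} is not the mate of {r2.read_id!r}"
            )
        if r2.mate_of is not None and r2.mate_of != r1.read_id:
            raise ContractError(
                f"read {r2.read_id!r} is not the mate of {r1.read_id!r}"
            )
        frag = merge_pair(r1, r2, params)
        if frag is None:
            frag = force_merge(r1, r2)
        merged.append(frag)
        provenance[frag.merged_id] = frag.source_ids
    for read in singles:
        frag = MergedRead(
            merged_id=read.read_id,
            sequence=read.sequence,
            source_ids=(read.read_id,),
            forced=False,
            qualities=list(read.qualities) if read.qualities is not None else None,
        )
        merged.append(frag)
        provenance[frag.merged_id] = frag.source_ids
    return merged, provenance


def restore_original(
    bin_read_ids: Iterable[str], provenance: Mapping[str, tuple[str, ...]]
) -> list[str]:
    """Map merged ids back to the sorted, de-duplicated original read ids."""
    out: set[str] = set()
    for mid in bin_read_ids:
        if mid not in provenance:
            raise ContractError(f"merged id {mid!r} not present in provenance")
        out.update(provenance[mid])
    return sorted(out)


def write_provenance(provenance: Mapping[str, tuple[str, ...]], path: str | Path) -> None:
    """Serialize provenance as a two-column TSV (merged_id, comma-joined sources)."""
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, delimiter="\t", lineterminator="\n")
        for mid in sorted(provenance):
            writer.writerow([mid, ",".join(provenance[mid])])


def read_provenance(path: str | Path) -> dict[str, tuple[str, ...]]:
    provenance: dict[str, tuple[str, ...]] = {}
    with open(path, newline="") as handle:
        for row in csv.reader(handle, delimiter="\t"):
            if not row:
                continue
            provenance[row[0]] = tuple(row[1].split(","))
    return provenance
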