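"""Ground-truth scoring of bin sets on synthetic communities.

With a complete read-level truth table, bin quality can be measured
exactly: a bin's *purity* is the fraction of its reads coming from its
dominant (plurality) source genome, *contamination* its complement, and a
genome's *completeness* is the fraction of its reads captured by the
single bin that holds most of them.  This read-level scoring replaces
marker-gene estimators, which are database-bound and approximate, and is
only possible because the community generator provides exact labels.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .binning import Bin, BinSet, RobustSpread
from .errors import ContractError
from .pair_prep import restore_original
from .synthetic_community import TruthTable


@dataclass(frozen=True)
class BinScore:
    """Purity/contamination of one bin; dominant ties break to the
    lexicographically smallest genome label."""

    bin_id: int
    dominant_genome: str
    purity: float
    contamination: float
    n_reads: int


@dataclass(frozen=True)
class GenomeScore:
    """Fraction of a genome's truth reads captured by its best bin."""

    genome: str
    completeness: float
    best_bin_id: int | None


def evaluate_bins(
    binset: BinSet,
    truth: TruthTable,
    provenance: Mapping[str, tuple[str, ...]] | None = None,
) -> tuple[list[BinScore], list[GenomeScore]]:
    """Score every bin and every genome against the truth table.

    When ``provenance`` is given, bin members (merged ids) are first mapped
    back to original read ids.  A binned read absent from the truth table is
    a contract violation naming the read.
    """
    bin_members: dict[int, list[str]] = {}
    for bn in binset.bins:
        ids = (
            restore_original(bn.read_ids, provenance)
            if provenance is not None
            else list(bn.read_ids)
        )
        for rid in ids:
            if rid not in truth.read_to_genome:
                raise ContractError(f"binned read {rid!r} missing from truth table")
        bin_members[bn.bin_id] = ids

    bin_scores: list[BinScore] = []
    captured: dict[str, dict[int, int]] = {}
    for bn in binset.bins:
        ids = bin_members[bn.bin_id]
        counts = Counter(truth.read_to_genome[r] for r in ids)
        for genome, c in counts.items():
            captured.setdefault(genome, {})[bn.bin_id] = c
        top = max(counts.values())
        dominant = min(g for g, c in counts.items() if c == top)
        purity = top / len(ids)
        bin_scores.append(
            BinScore(
                bin_id=bn.bin_id,
                dominant_genome=dominant,
                purity=purity,
                contamination=1.0 - purity,
                n_reads=len(ids),
            )
        )

    totals = Counter(truth.read_to_genome.values())
    genome_scores: list[GenomeScore] = []
    for genome in sorted(totals):
        per_bin = captured.get(genome, {})
        if per_bin:
            best_count = max(per_bin.values())
            best_bin = min(b for b, c in per_bin.items() if c == best_count)
            completeness = best_count / totals[genome]
        else:
            best_bin = None
            completeness = 0.0
        genome_scores.append(
            GenomeScore(genome=genome, completeness=completeness, best_bin_id=best_bin)
        )
    return bin_scores, genome_scores


def degree_histogram_report(
    bn: Bin,
) -> tuple[list[tuple[int, int]], RobustSpread]:
    """Sorted (degree, count) rows plus the bin's robust spread summary.

    Counts sum to the bin size plus its removed outliers (the histogram is
    taken before filtering).
    """
    rows = sorted(bn.degree_histogram.items())
    return rows, bn.spread


def write_bin_scores(scores: Sequence[BinScore], path: str | Path) -> None:
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, delimiter="\t", lineterminator="\n")
        writer.writerow(["bin_id", "dominant_genome", "purity", "contamination", "n_reads"])
        for s in scores:
            writer.writerow(
                [s.bin_id, s.dominant_genome, f"{s.purity:.6g}", f"{s.contamination:.6g}", s.n_reads]
            )


def write_genome_scores(scores: Sequence[GenomeScore], path: str | Path) -> None:
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, delimiter="\t", lineterminator="\n")
        writer.writerow(["genome", "completeness", "best_bin_id"])
        for s in scores:
            writer.writerow(
                [s.genome, f"{s.completeness:.6g}", "" if s.best_bin_id is None else s.best_bin_id]
            )
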