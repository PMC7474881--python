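"""Bin extraction with automatic MAD-based degree filtering.

Candidate bins are the connected components of the read-overlap graph.
Within a component, a read's degree (number of distinct overlap partners)
tracks the local abundance of the molecule it came from; in a clean
single-molecule bin the degree histogram is roughly normal.  Reads whose
degree sits far in the tail — typically reads touching conserved or
repetitive sequence shared with other molecules — are removed with a
robust outlier rule: the median absolute deviation (MAD) scaled by 1.4826
consistently estimates a normal sigma, and reads farther than
``cutoff * 1.4826 * MAD`` (default cutoff 3) from the median degree are
excluded.  This automates the edge-degree ("e-parameter") threshold a user
would otherwise pick by inspecting each histogram.

After outlier removal, connectivity is recomputed; each remaining
sub-component with at least ``min_bin_size`` reads is reported as a bin.
``iterative_binning`` repeats the whole procedure over a descending
schedule of minimum alignment lengths (default 70, 50, 30 bp), withdrawing
binned reads between passes so later, looser passes only explore what is
left.  ``block_binning`` processes very large read sets in consecutive
blocks and merges bins across blocks.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import ConfigurationError, ContractError
from .overlap_index import OverlapGraph, build_graph, find_overlaps_indexed
from .sequence_io import record_id

#: scale factor turning a MAD into a consistent estimator of a normal
#: standard deviation: 1 / Phi^-1(3/4), printed to four decimals.
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class RobustSpread:
    """Median / MAD summary of a degree sample; ``sigma_hat = 1.4826 * mad``."""

    median: float
    mad: float
    sigma_hat: float


@dataclass(frozen=True)
class BinningParams:
    """Parameters of the binning stage.

    ``b`` is the minimum alignment length of the current pass;
    ``b_schedule`` the descending list of passes (default [70, 50, 30]);
    ``min_bin_size`` the smallest reported bin; ``mad_cutoff`` the outlier
    multiplier; ``block_size`` the number of reads per processing block.
    """

    b: int = 70
    b_schedule: tuple[int, ...] = (70, 50, 30)
    max_mismatches: int = 0
    min_bin_size: int = 2000
    mad_cutoff: float = 3.0
    block_size: int = 20_000_000
    scale_to_sigma: bool = True

    def __post_init__(self) -> None:
        sched = tuple(self.b_schedule)
        object.__setattr__(self, "b_schedule", sched)
        if any(v < 1 for v in sched) or any(
            later >= earlier for later, earlier in zip(sched[1:], sched)
        ):
            raise ConfigurationError("b_schedule must be strictly descending, all >= 1")
        if self.min_bin_size < 1:
            raise ConfigurationError("min_bin_size must be >= 1")
        if self.mad_cutoff <= 0:
            raise ConfigurationError("mad_cutoff must be > 0")
        if self.block_size < 1:
            raise ConfigurationError("block_size must be >= 1")


@dataclass
class Bin:
    """One reported bin with its MAD-filter diagnostics.

    ``degree_histogram`` is computed before filtering, so its counts sum to
    ``len(read_ids) + len(removed_outliers)``.  ``mad_degenerate`` is raised
    when the component's MAD was zero (uniform degrees), in which case the
    filter removed nothing.
    """

    bin_id: int
    read_ids: tuple[str, ...]
    b_used: int
    degree_histogram: dict[int, int]
    spread: RobustSpread
    removed_outliers: tuple[str, ...] = ()
    mad_degenerate: bool = False

    @property
    def size(self) -> int:
        return len(self.read_ids)


@dataclass
class BinSet:
    """Reported bins plus the reads left in no reported bin."""

    bins: list[Bin]
    leftover_ids: tuple[str, ...]

    def all_binned_ids(self) -> set[str]:
        out: set[str] = set()
        for b in self.bins:
            out.update(b.read_ids)
        return out


def mad(values: Sequence[float]) -> RobustSpread:
    """Median, median absolute deviation, and the scaled sigma estimate.

    Medians use the midpoint convention for even sample sizes.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ContractError("mad() requires a nonempty sample")
    med = float(np.median(arr))
    m = float(np.median(np.abs(arr - med)))
    return RobustSpread(median=med, mad=m, sigma_hat=MAD_SCALE * m)


def mad_outlier_filter(
    degrees: Mapping[str, float],
    cutoff: float = 3.0,
    scale_to_sigma: bool = True,
) -> tuple[list[str], list[str], RobustSpread]:
    """Partition ids into kept and removed by the robust degree rule.

    Removes ids whose degree differs from the median by more than
    ``cutoff * sigma_hat`` (or ``cutoff * mad`` raw when ``scale_to_sigma``
    is off).  A zero MAD (uniform degrees) disables removal entirely: a flat
    histogram is the signature of a clean bin and any rule at MAD = 0 would
    delete arbitrary reads.
    """
    if not degrees:
        raise ContractError("mad_outlier_filter() requires a nonempty sample")
    spread = mad(list(degrees.values()))
    scale = spread.sigma_hat if scale_to_sigma else spread.mad
    kept: list[str] = []
    removed: list[str] = []
    if spread.mad == 0:
        kept = sorted(degrees)
        return kept, removed, spread
    threshold = cutoff * scale
    for rid in sorted(degrees):
        if abs(degrees[rid] - spread.median) > threshold:
            removed.append(rid)
        else:
            kept.append(rid)
    return kept, removed, spread


def extract_bins(graph: OverlapGraph, params: BinningParams) -> BinSet:
    """Connected components -> MAD filter -> reported bins.

    For every component, degrees are taken within the component (which, for
    a maximal component, equals the whole-graph degree); the filter runs on
    that sample; connectivity is recomputed on the survivors; and every
    resulting sub-component of at least ``min_bin_size`` reads becomes a
    bin.  Outliers, sub-threshold fragments and isolated reads all fall into
    ``leftover_ids``.  When a component splits, its outliers are attributed
    to the largest resulting bin (tie: smallest min read id) so that each
    bin's histogram invariant holds.  Bin ids follow the order of smallest
    member read id.
    """
    pending: list[tuple[tuple[str, ...], dict]] = []
    leftover: set[str] = set()
    components = sorted(nx.connected_components(graph), key=min)
    for comp in components:
        members = sorted(comp)
        degrees = {rid: graph.degree(rid) for rid in members}
        kept, removed, spread = mad_outlier_filter(
            degrees, params.mad_cutoff, params.scale_to_sigma
        )
        degenerate = spread.mad == 0
        sub = graph.subgraph(kept)
        reported = [
            sorted(sc)
            for sc in nx.connected_components(sub)
            if len(sc) >= params.min_bin_size
        ]
        reported.sort(key=lambda sc: sc[0])
        in_reported: set[str] = set()
        for sc in reported:
            in_reported.update(sc)
        leftover.update(set(members) - in_reported)
        if not reported:
            continue
        # largest bin holds the component's outliers; ties go to smallest min id
        holder = sorted(
            range(len(reported)), key=lambda i: (-len(reported[i]), reported[i][0])
        )[0]
        for i, sc in enumerate(reported):
            outliers = tuple(removed) if i == holder else ()
            hist_sample = list(sc) + list(outliers)
            histogram = dict(sorted(Counter(degrees[r] for r in hist_sample).items()))
            pending.append(
                (
                    tuple(sc),
                    dict(
                        degree_histogram=histogram,
                        spread=spread,
                        removed_outliers=outliers,
                        mad_degenerate=degenerate,
                    ),
                )
            )
    pending.sort(key=lambda item: item[0][0])
    bins = [
        Bin(bin_id=i, read_ids=ids, b_used=params.b, **extra)
        for i, (ids, extra) in enumerate(pending)
    ]
    return BinSet(bins=bins, leftover_ids=tuple(sorted(leftover)))


def iterative_binning(reads: Sequence, params: BinningParams) -> BinSet:
    """Run binning over the descending b-schedule.

    Each pass detects overlaps over the current leftover pool only, extracts
    bins, and withdraws their reads from the pool; reads removed as outliers
    re-enter the pool for later, smaller-b passes.  Bins record the b of the
    pass that produced them.  An empty schedule yields no bins.
    """
    pool = list(reads)
    bins: list[Bin] = []
    for b in params.b_schedule:
        if not pool:
            continue
        ids = [record_id(r) for r in pool]
        overlaps = find_overlaps_indexed(pool, b, params.max_mismatches)
        graph = build_graph(overlaps, ids)
        pass_result = extract_bins(graph, replace(params, b=b))
        taken = pass_result.all_binned_ids()
        for bn in pass_result.bins:
            bins.append(replace(bn, bin_id=len(bins)))
        pool = [r for r in pool if record_id(r) not in taken]
    return BinSet(bins=bins, leftover_ids=tuple(sorted(record_id(r) for r in pool)))


def _merge_bin_group(group: list[Bin]) -> dict:
    read_ids = tuple(sorted(set().union(*(b.read_ids for b in group))))
    removed = tuple(sorted(set().union(*(set(b.removed_outliers) for b in group))))
    histogram: Counter = Counter()
    for b in group:
        histogram.update(b.degree_histogram)
    sample = [d for d, c in histogram.items() for _ in range(c)]
    spread = mad(sample)
    return dict(
        read_ids=read_ids,
        b_used=min(b.b_used for b in group),
        degree_histogram=dict(sorted(histogram.items())),
        spread=spread,
        removed_outliers=removed,
        mad_degenerate=spread.mad == 0,
    )


def block_binning(
    reads: Sequence, params: BinningParams, merge_blocks: bool = True
) -> BinSet:
    """Bin consecutive blocks of reads independently, then merge across blocks.

    Reads are split, in input order, into blocks of at most ``block_size``;
    each block runs :func:`iterative_binning` on its own.  A merge pass then
    connects bins from *different* blocks whenever some cross-bin read pair
    overlaps by at least the smaller of the two bins' b values, and unions
    connected bins.  With a single block the result is bit-identical to the
    non-blocked path (no merge pass runs).
    """
    blocks = [
        list(reads[i : i + params.block_size])
        for i in range(0, len(reads), params.block_size)
    ]
    if len(blocks) <= 1:
        return iterative_binning(reads, params)

    all_bins: list[tuple[int, Bin]] = []
    leftover: set[str] = set()
    for block_idx, block in enumerate(blocks):
        result = iterative_binning(block, params)
        leftover.update(result.leftover_ids)
        for bn in result.bins:
            all_bins.append((block_idx, bn))

    if merge_blocks and len(all_bins) > 1:
        read_to_bin = {
            rid: i for i, (_, bn) in enumerate(all_bins) for rid in bn.read_ids
        }
        binned_reads = [r for r in reads if record_id(r) in read_to_bin]
        b_min = min(bn.b_used for _, bn in all_bins)
        merge_graph = nx.Graph()
        merge_graph.add_nodes_from(range(len(all_bins)))
        for ov in find_overlaps_indexed(binned_reads, b_min, params.max_mismatches):
            i, j = read_to_bin[ov.id_a], read_to_bin[ov.id_b]
            if i == j or all_bins[i][0] == all_bins[j][0]:
                continue
            if ov.length >= min(all_bins[i][1].b_used, all_bins[j][1].b_used):
                merge_graph.add_edge(i, j)
        merged: list[dict] = []
        for group_idx in nx.connected_components(merge_graph):
            group = [all_bins[i][1] for i in sorted(group_idx)]
            if len(group) == 1:
                bn = group[0]
                merged.append(
                    dict(
                        read_ids=bn.read_ids,
                        b_used=bn.b_used,
                        degree_histogram=bn.degree_histogram,
                        spread=bn.spread,
                        removed_outliers=bn.removed_outliers,
                        mad_degenerate=bn.mad_degenerate,
                    )
                )
            else:
                merged.append(_merge_bin_group(group))
        merged.sort(key=lambda d: d["read_ids"][0])
        bins = [Bin(bin_id=i, **d) for i, d in enumerate(merged)]
    else:
        ordered = sorted((bn for _, bn in all_bins), key=lambda b: b.read_ids[0])
        bins = [replace(bn, bin_id=i) for i, bn in enumerate(ordered)]
    return BinSet(bins=bins, leftover_ids=tuple(sorted(leftover)))


def write_bin_table(binset: BinSet, path: str | Path) -> None:
    """Per-bin summary TSV: id, b, size, outliers, median/MAD diagnostics."""
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "bin_id",
                "b_used",
                "n_reads",
                "n_outliers",
                "median_degree",
                "mad",
                "sigma_hat",
                "mad_degenerate",
            ]
        )
        for bn in binset.bins:
            writer.writerow(
                [
                    bn.bin_id,
                    bn.b_used,
                    bn.size,
                    len(bn.removed_outliers),
                    f"{bn.spread.median:.6g}",
                    f"{bn.spread.mad:.6g}",
                    f"{bn.spread.sigma_hat:.6g}",
                    int(bn.mad_degenerate),
                ]
            )


def write_bin_members(binset: BinSet, path: str | Path) -> None:
    """Two-column TSV (bin_id, read_id), plus leftovers under bin_id = -1."""
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, delimiter="\t", lineterminator="\n")
        writer.writerow(["bin_id", "read_id"])
        for bn in binset.bins:
            for rid in bn.read_ids:
                writer.writerow([bn.bin_id, rid])
        for rid in binset.leftover_ids:
            writer.writerow([-1, rid])


def write_degree_histogram(bn: Bin, path: str | Path) -> None:
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, delimiter="\t", lineterminator="\n")
        writer.writerow(["degree", "count"])
        for degree in sorted(bn.degree_histogram):
            writer.writerow([degree, bn.degree_histogram[degree]])
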