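import numpy as np
import pytest

from ovbin.binning import (
    MAD_SCALE,
    BinningParams,
    block_binning,
    extract_bins,
    iterative_binning,
    mad,
    mad_outlier_filter,
)
from ovbin.errors import ConfigurationError, ContractError
from ovbin.overlap_index import (
    Overlap,
    build_graph,
    find_overlaps_bruteforce,
    find_overlaps_indexed,
)
from ovbin.sequence_io import Read
from ovbin.synthetic_community import (
    CommunitySpec,
    ReadSimSpec,
    simulate_community,
    simulate_reads,
)


class TestMad:
    def test_constant_vector(self):
        s = mad([7, 7, 7, 7])
        assert (s.median, s.mad, s.sigma_hat) == (7.0, 0.0, 0.0)

    def test_hand_enumerable(self):
        s = mad([1, 2, 3, 4, 5])
        assert s.median == 3.0 and s.mad == 1.0

    def test_sigma_scale(self):
        assert mad([1, 2, 3, 4, 5]).sigma_hat == MAD_SCALE
        assert mad([0, 2]).sigma_hat == MAD_SCALE  # mad = 1 for {0, 2}

    def test_even_n_midpoint_median(self):
        assert mad([1, 2, 3, 10]).median == 2.5

    def test_empty_rejected(self):
        with pytest.raises(ContractError):
            mad([])


class TestMadOutlierFilter:
    def test_uniform_degrees_degenerate_removes_nothing(self):
        degrees = {f"r{i}": 4 for i in range(10)}
        kept, removed, spread = mad_outlier_filter(degrees)
        assert removed == [] and len(kept) == 10 and spread.mad == 0.0

    def test_hand_computed_vector(self):
        values = [5, 5, 6, 6, 7, 7, 8, 100]
        degrees = {f"r{i}": v for i, v in enumerate(values)}
        kept, removed, spread = mad_outlier_filter(degrees, cutoff=3)
        assert spread.median == 6.5 and spread.mad == 1.0
        assert spread.sigma_hat == pytest.approx(1.4826)
        assert removed == ["r7"]  # only the degree-100 read
        assert len(kept) == 7

    def test_raw_mad_switch_tightens_threshold(self):
        # median 5, MAD 1: |9 - 5| = 4 exceeds 3*MAD raw but not 3*1.4826*MAD
        values = {"a": 3, "b": 4, "c": 5, "d": 5, "e": 5, "f": 6, "g": 7, "h": 9}
        _, removed_scaled, s = mad_outlier_filter(values, cutoff=3, scale_to_sigma=True)
        _, removed_raw, _ = mad_outlier_filter(values, cutoff=3, scale_to_sigma=False)
        assert s.mad == 1.0
        assert removed_scaled == [] and removed_raw == ["h"]

    def test_normal_tail_mass(self):
        rng = np.random.default_rng(42)
        degrees = {f"r{i}": d for i, d in enumerate(rng.normal(50, 5, size=10_000))}
        kept, removed, _ = mad_outlier_filter(degrees, cutoff=3)
        fraction = len(removed) / 10_000
        assert 0 < fraction <= 0.01  # 3-sigma two-sided mass is ~0.27%
        assert len(kept) + len(removed) == 10_000


def _near_clique_edges(ids, n_matching_drops):
    """A clique minus a partial matching, so member degrees take two values
    and the component's MAD is positive."""
    dropped = {
        frozenset((ids[2 * i], ids[2 * i + 1])) for i in range(n_matching_drops)
    }
    edges = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if frozenset((a, b)) in dropped:
                continue
            edges.append(Overlap(*sorted((a, b)), 70, "same"))
    return edges


def _bridge_graph():
    """Two 30-read near-cliques joined by one bridge adjacent to everything.

    Half of all clique members have degree 29, half 30 (median 30, MAD 1);
    the bridge's degree 61 is far outside 3 * 1.4826 * MAD.
    """
    left = [f"l{i:02d}" for i in range(30)]
    right = [f"r{i:02d}" for i in range(30)]
    edges = _near_clique_edges(left, 8) + _near_clique_edges(right, 7)
    edges += [Overlap(*sorted(("bridge", n)), 70, "same") for n in left + right]
    return left, right, build_graph(edges, left + right + ["bridge"])


class TestExtractBins:
    def test_empty_graph_all_leftover(self):
        g = build_graph([], [f"n{i}" for i in range(5)])
        result = extract_bins(g, BinningParams(min_bin_size=2))
        assert result.bins == []
        assert set(result.leftover_ids) == {f"n{i}" for i in range(5)}

    def test_components_become_bins(self):
        edges = [
            Overlap("a1", "a2", 70, "same"),
            Overlap("a2", "a3", 70, "same"),
            Overlap("b1", "b2", 70, "same"),
        ]
        g = build_graph(edges, ["a1", "a2", "a3", "b1", "b2"])
        result = extract_bins(g, BinningParams(min_bin_size=2))
        assert [set(b.read_ids) for b in result.bins] == [
            {"a1", "a2", "a3"},
            {"b1", "b2"},
        ]
        assert result.leftover_ids == ()

    def test_bridge_read_removed_and_component_splits(self):
        left, right, g = _bridge_graph()
        result = extract_bins(g, BinningParams(min_bin_size=5))
        assert len(result.bins) == 2
        assert {frozenset(b.read_ids) for b in result.bins} == {
            frozenset(left),
            frozenset(right),
        }
        all_outliers = {r for b in result.bins for r in b.removed_outliers}
        assert all_outliers == {"bridge"}

    def test_histogram_counts_include_outliers(self):
        _, _, g = _bridge_graph()
        result = extract_bins(g, BinningParams(min_bin_size=5))
        for b in result.bins:
            assert sum(b.degree_histogram.values()) == len(b.read_ids) + len(
                b.removed_outliers
            )

    def test_partition_conservation(self):
        rng = np.random.default_rng(1)
        nodes = [f"n{i:02d}" for i in range(40)]
        edges = set()
        for _ in range(60):
            i, j = rng.choice(40, size=2, replace=False)
            edges.add(Overlap(*sorted((nodes[i], nodes[j])), 70, "same"))
        g = build_graph(edges, nodes)
        result = extract_bins(g, BinningParams(min_bin_size=4))
        binned = result.all_binned_ids()
        assert binned.isdisjoint(result.leftover_ids)
        assert binned | set(result.leftover_ids) == set(nodes)


def _tiled_reads(genome, prefix, read_len, step):
    return [
        Read(f"{prefix}{i:03d}", genome[s : s + read_len])
        for i, s in enumerate(range(0, len(genome) - read_len + 1, step))
    ]


class TestIterativeBinning:
    def test_empty_schedule_no_bins(self):
        reads = [Read("a", "ACGT" * 30), Read("b", "ACGT" * 30)]
        result = iterative_binning(reads, BinningParams(b_schedule=(), min_bin_size=1))
        assert result.bins == []
        assert set(result.leftover_ids) == {"a", "b"}

    def test_two_genomes_captured_at_different_b(self):
        rng = np.random.default_rng(23)
        genome_a = "".join(rng.choice(list("ACGT"), size=600))
        genome_b = "".join(rng.choice(list("ACGT"), size=600))
        # A reads overlap by 80 >= 70; B reads overlap by 55 (in [50, 69])
        reads_a = _tiled_reads(genome_a, "a", 100, 20)
        reads_b = _tiled_reads(genome_b, "b", 100, 45)
        reads = reads_a + reads_b
        # premise: no cross-genome alignment >= 50 (brute-force verified)
        cross = {
            frozenset((o.id_a[0], o.id_b[0]))
            for o in find_overlaps_bruteforce(reads, 50)
        }
        assert frozenset(("a", "b")) not in cross
        result = iterative_binning(
            reads, BinningParams(b_schedule=(70, 50), min_bin_size=3)
        )
        by_b = {b.b_used: set(b.read_ids) for b in result.bins}
        assert by_b[70] == {r.read_id for r in reads_a}
        assert by_b[50] == {r.read_id for r in reads_b}

    def test_exhausted_pool_adds_nothing(self):
        rng = np.random.default_rng(29)
        genome = "".join(rng.choice(list("ACGT"), size=500))
        reads = _tiled_reads(genome, "g", 100, 20)
        result = iterative_binning(
            reads, BinningParams(b_schedule=(70, 50, 30), min_bin_size=3)
        )
        assert len(result.bins) == 1 and result.bins[0].b_used == 70
        assert result.leftover_ids == ()

    def test_schedule_must_descend(self):
        with pytest.raises(ConfigurationError):
            BinningParams(b_schedule=(50, 70))


class TestBlockBinning:
    @staticmethod
    def _community(seed, n_genomes=2, genome_length=4000, coverage=15):
        spec = CommunitySpec(n_genomes=n_genomes, genome_length=genome_length, seed=seed)
        genomes, _ = simulate_community(spec)
        return simulate_reads(
            genomes,
            spec.normalized_abundances(),
            ReadSimSpec(coverage=coverage, read_length=120, seed=seed + 1),
        )

    def test_single_block_identical_to_plain_binning(self):
        reads, _ = self._community(seed=31)
        params = BinningParams(min_bin_size=20, block_size=10**6)
        assert block_binning(reads, params) == iterative_binning(reads, params)

    def test_cross_block_bins_merge_into_one(self):
        reads, truth = self._community(seed=37, n_genomes=1, coverage=25)
        params = BinningParams(b_schedule=(30,), min_bin_size=20,
                               block_size=len(reads) // 2 + 1)
        result = block_binning(reads, params)
        assert len(result.bins) == 1
        assert len(result.bins[0].read_ids) >= 0.9 * len(reads)

    def test_two_genomes_three_blocks_stay_pure(self):
        reads, truth = self._community(seed=41, n_genomes=2)
        params = BinningParams(b_schedule=(30,), min_bin_size=20,
                               block_size=len(reads) // 3 + 1)
        result = block_binning(reads, params)
        assert result.bins
        for b in result.bins:
            labels = {truth.read_to_genome[r] for r in b.read_ids}
            assert len(labels) == 1

    def test_determinism(self):
        reads, _ = self._community(seed=43)
        params = BinningParams(min_bin_size=20, block_size=400)
        assert block_binning(reads, params) == block_binning(reads, params)
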