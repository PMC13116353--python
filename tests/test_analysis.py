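"""Perturbation, clustering, annotation, canyon and long-range analyses."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from nanoloop.analysis import (
    CanyonSet,
    annotate_loop_types,
    call_canyons,
    canyon_overlap_classes,
    cluster_anchors,
    cluster_loops,
    distance_histogram,
    genome_bin_enrichment,
    methylation_swap,
    pattern_combinations,
    recall_at_thresholds,
    signal_enrichment,
    sse_elbow,
)
from nanoloop.core_io import (
    GenomicInterval,
    MethylationIndex,
    MethylationRecord,
    SignalTrack,
    make_loop,
)
from nanoloop.model import METH_BLOCK
from nanoloop.synthetic import make_cluster_blobs


class TestMethylationSwap:
    def test_identity_swap_preserves_probability(self, tiny_world, tiny_bundle):
        _, data, meth, manifest = tiny_world
        loops, _ = manifest.subset("test")
        frame = tiny_bundle.assemble(loops, data.genome, meth)
        probs = tiny_bundle.score_matrix(frame)
        clone = frame.copy()
        clone.loc[:, frame.columns[METH_BLOCK]] = frame.iloc[:][
            frame.columns[METH_BLOCK]
        ].to_numpy()
        np.testing.assert_array_equal(tiny_bundle.score_matrix(clone), probs)

    def test_swap_raises_low_group_probability(self, tiny_world, tiny_bundle):
        _, data, meth, manifest = tiny_world
        loops, _ = manifest.subset("test")
        frame = tiny_bundle.assemble(loops, data.genome, meth)
        probs = tiny_bundle.score_matrix(frame)
        exp = methylation_swap(tiny_bundle, frame, probs, seed=0)
        assert len(exp.low_indices) == len(exp.high_indices)
        assert exp.after.mean() > exp.before.mean()

    def test_empty_group_rejected(self, tiny_world, tiny_bundle):
        _, data, meth, manifest = tiny_world
        loops = manifest.positives[:3]
        frame = tiny_bundle.assemble(loops, data.genome, meth)
        with pytest.raises(ValueError):
            methylation_swap(tiny_bundle, frame, np.array([0.9, 0.9, 0.8]))


class TestClustering:
    def test_blob_recovery_is_exact(self):
        counts, labels = make_cluster_blobs(seed=0)
        model = cluster_anchors(counts, k=4, seed=0)
        assert model.k == 4
        assert adjusted_rand_score(labels, model.labels) == 1.0

    def test_labels_canonicalized_by_mean_methylation(self):
        counts, _ = make_cluster_blobs(seed=1)
        model = cluster_anchors(counts, k=4, seed=0)
        cluster_means = [counts[model.labels == c].mean() for c in range(4)]
        assert cluster_means == sorted(cluster_means)

    def test_standardized_space_zero_mean_unit_variance(self):
        rng = np.random.default_rng(0)
        x = rng.random((200, 20)) * 10
        model = cluster_loops(x, seed=0)
        z = (x - model.mean) / model.std
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-9)

    def test_seeded_determinism(self):
        counts, _ = make_cluster_blobs(seed=2)
        a = cluster_anchors(counts, seed=3)
        b = cluster_anchors(counts, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            cluster_anchors(np.zeros((3, 10)), k=4)

    def test_wrong_width_rejected(self):
        with pytest.raises(ValueError):
            cluster_loops(np.zeros((10, 10)))
        with pytest.raises(ValueError):
            cluster_anchors(np.zeros((10, 20)))


class TestSseElbow:
    def test_monotone_non_increasing(self):
        counts, _ = make_cluster_blobs(n_per_cluster=30, seed=0)
        curve = sse_elbow(counts, range(1, 7), seed=0)
        inertias = [v for _, v in curve]
        assert all(a >= b - 1e-9 for a, b in zip(inertias, inertias[1:]))

    def test_k_equals_n_gives_zero(self):
        x = np.arange(8, dtype=float).reshape(4, 2)
        curve = dict(sse_elbow(x, range(1, 5), seed=0))
        assert curve[4] == pytest.approx(0.0, abs=1e-12)

    def test_repeated_point_zero_inertia(self):
        x = np.ones((6, 3))
        curve = dict(sse_elbow(x, range(1, 3), seed=0))
        assert curve[1] == pytest.approx(0.0)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            sse_elbow(np.ones((3, 2)), range(1, 10))


class TestPatternCombinations:
    def test_all_same_pair_in_one_cell(self):
        mat = pattern_combinations(np.ones(7, int), np.ones(7, int))
        assert mat[1, 1] == 7 and mat.sum() == 7

    def test_unordered_and_conserved(self):
        left = np.array([0, 3, 2])
        right = np.array([3, 0, 1])
        mat = pattern_combinations(left, right)
        assert mat[0, 3] == 2 and mat[1, 2] == 1
        assert np.tril(mat, -1).sum() == 0
        assert mat.sum() == 3

    def test_uniform_labels_give_uniform_unordered_pairs(self):
        rng = np.random.default_rng(0)
        n = 10_000
        left = rng.integers(0, 4, n)
        right = rng.integers(0, 4, n)
        mat = pattern_combinations(left, right)
        # expected unordered-pair probabilities: 1/16 diagonal, 2/16 off
        expected = np.zeros((4, 4))
        for i in range(4):
            for j in range(i, 4):
                expected[i, j] = n / 16 * (1 if i == j else 2)
        observed = mat[np.triu_indices(4)]
        chi2 = ((observed - expected[np.triu_indices(4)]) ** 2
                / expected[np.triu_indices(4)]).sum()
        assert stats.chi2.sf(chi2, df=9) > 0.01


class TestLoopTypes:
    LOOPS = [
        make_loop(GenomicInterval("chr1", 0, 5000), GenomicInterval("chr1", 20000, 25000))
    ]

    def test_classes(self):
        e = [GenomicInterval("chr1", 1000, 1500), GenomicInterval("chr1", 21000, 21500)]
        p = [GenomicInterval("chr1", 21000, 21500)]
        assert annotate_loop_types(self.LOOPS, e, []) == ["E-E"]
        assert annotate_loop_types(self.LOOPS, e[:1], p) == ["E-P"]
        assert annotate_loop_types(self.LOOPS, [], p) == ["other"]
        assert annotate_loop_types(self.LOOPS, [], []) == ["other"]

    def test_promoter_precedence(self):
        both = [GenomicInterval("chr1", 1000, 1500)]
        promoters = both + [GenomicInterval("chr1", 21000, 21500)]
        assert annotate_loop_types(self.LOOPS, both, promoters) == ["P-P"]


class TestSignalEnrichment:
    def test_constant_track(self):
        track = SignalTrack(
            intervals={"chr1": np.array([[0, 10000]])},
            values={"chr1": np.array([3.5])},
        )
        region = [GenomicInterval("chr1", 2000, 4000)]
        assert signal_enrichment(region, track)[0] == pytest.approx(3.5)

    def test_half_covered_length_weighting(self):
        track = SignalTrack(
            intervals={"chr1": np.array([[0, 1000]])},
            values={"chr1": np.array([2.0])},
        )
        region = [GenomicInterval("chr1", 0, 2000)]
        assert signal_enrichment(region, track)[0] == pytest.approx(1.0)

    def test_loop_is_mean_of_anchors(self):
        track = SignalTrack(
            intervals={"chr1": np.array([[0, 5000]])},
            values={"chr1": np.array([4.0])},
        )
        loop = make_loop(
            GenomicInterval("chr1", 0, 5000), GenomicInterval("chr1", 20000, 25000)
        )
        # left anchor fully covered (4.0), right uncovered (0.0)
        assert signal_enrichment([loop], track)[0] == pytest.approx(2.0)

    def test_uncovered_chrom_contributes_zero(self):
        assert signal_enrichment(
            [GenomicInterval("chrX", 0, 100)], SignalTrack()
        )[0] == 0.0


class TestGenomeBins:
    def test_midpoint_bin_and_conservation(self):
        sizes = {"chr1": 100_000}
        intervals = [
            GenomicInterval("chr1", 49_000, 51_000),  # midpoint 50_000 -> bin 50
            GenomicInterval("chr1", 0, 2),
        ]
        counts = genome_bin_enrichment(intervals, sizes)
        assert counts["chr1"][50] == 1 and counts["chr1"][0] == 1
        assert counts["chr1"].sum() == 2

    def test_empty_set_gives_zero_vectors(self):
        counts = genome_bin_enrichment([], {"chr1": 1000})
        assert counts["chr1"].shape == (100,) and not counts["chr1"].any()

    def test_midpoint_beyond_chrom_rejected(self):
        with pytest.raises(ValueError):
            genome_bin_enrichment(
                [GenomicInterval("chr1", 900, 1200)], {"chr1": 1000}
            )


def methylome(segments):
    """Build an index from (start, end, step, prob) segments on chr1."""
    records = []
    for start, end, step, prob in segments:
        for pos in range(start, end, step):
            records.append(MethylationRecord("chr1", pos, prob))
    return MethylationIndex(records)


class TestCanyons:
    SIZES = {"chr1": 60_000}

    def test_fully_methylated_genome_empty(self):
        meth = methylome([(0, 60_000, 100, 1.0)])
        assert call_canyons(meth, self.SIZES).intervals == []

    def test_planted_canyon_recovered(self):
        meth = methylome(
            [(0, 20_000, 100, 0.9), (20_000, 30_000, 100, 0.0), (30_000, 60_000, 100, 0.9)]
        )
        canyons = call_canyons(meth, self.SIZES)
        assert len(canyons.intervals) == 1
        canyon = canyons.intervals[0]
        assert len(canyon) > 7300
        assert canyon.start <= 20_000 and canyon.end >= 30_000

    def test_short_low_region_rejected(self):
        meth = methylome(
            [(0, 20_000, 100, 0.9), (20_000, 25_000, 100, 0.0), (25_000, 60_000, 100, 0.9)]
        )
        assert call_canyons(meth, self.SIZES).intervals == []

    def test_synthetic_planted_canyons_found(self, tiny_world):
        config, data, meth, _ = tiny_world
        called = call_canyons(meth, config.chrom_sizes)
        for planted in data.truth.canyons:
            assert any(planted.overlaps(c) for c in called.intervals)


class TestCanyonOverlap:
    LOOP = make_loop(
        GenomicInterval("chr1", 0, 5000), GenomicInterval("chr1", 20000, 25000)
    )

    def test_no_canyons_all_neither(self):
        out = canyon_overlap_classes([self.LOOP], CanyonSet([]))
        assert out == {"both": 0.0, "one": 0.0, "neither": 1.0}

    def test_both_anchors_inside_one_canyon(self):
        canyons = CanyonSet([GenomicInterval("chr1", 0, 30000)])
        out = canyon_overlap_classes([self.LOOP], canyons)
        assert out["both"] == 1.0

    def test_proportions_sum_to_one(self):
        canyons = CanyonSet([GenomicInterval("chr1", 1000, 2000)])
        out = canyon_overlap_classes([self.LOOP] * 3, canyons)
        assert sum(out.values()) == pytest.approx(1.0)


class TestLongRangeEvaluation:
    def test_recall_direct_count(self):
        recall = recall_at_thresholds(
            np.array([0.9, 0.6, 0.4]), np.ones(3, int), [0.5]
        )
        assert recall[0] == pytest.approx(2 / 3)

    def test_recall_boundaries_and_monotonicity(self):
        probs = np.array([0.95, 0.7, 0.5, 0.2])
        labels = np.ones(4, int)
        grid = np.linspace(0, 1, 21)
        recall = recall_at_thresholds(probs, labels, grid)
        assert recall[0] == 1.0
        assert np.all(np.diff(recall) <= 0)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            recall_at_thresholds(np.array([0.5]), np.zeros(1, int), [0.5])

    def test_distance_histogram_edges_and_conservation(self):
        loops = [
            make_loop(
                GenomicInterval("chr1", 0, 5000),
                GenomicInterval("chr1", d, d + 5000),
            )
            for d in (500_000, 2_000_000, 3_000_000)
        ]
        counts = distance_histogram(loops, [0, 2, 4])
        # 2 Mb sits exactly on an edge: right-open rule puts it in the upper bin
        assert counts.tolist() == [1, 2]
        assert counts.sum() == len(loops)

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ValueError):
            distance_histogram([], [2, 1])
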