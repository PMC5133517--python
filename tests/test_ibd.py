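import numpy as np
import pytest

from ibdqt import (
    GeneticMap,
    IbdSegment,
    build_matrix,
    interpolate_cM,
    merge_runs,
    parse_ibd,
    read_matrix,
    sharing_rate,
    write_ibd,
    write_matrix,
)
from ibdqt.errors import GeneticMapError, IbdParseError, IbdqtError

from oracles import interval_union, membership_matrix, piecewise_linear


def seg(id1, id2, start, end, chrom="3", hap1=1, hap2=1, lod=5.0):
    return IbdSegment(id1, hap1, id2, hap2, chrom, start, end, lod)


class TestParseIbd:
    def test_single_line(self, tmp_path):
        path = tmp_path / "x.ibd"
        path.write_text("A\t1\tB\t2\t3\t101901465\t102620049\t5.1\n")
        (s,) = parse_ibd(path)
        assert s == IbdSegment("A", 1, "B", 2, "3", 101901465, 102620049, 5.1)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "x.ibd"
        path.write_text("")
        assert parse_ibd(path) == []

    def test_wrong_column_count_reports_line(self, tmp_path):
        path = tmp_path / "x.ibd"
        path.write_text("A\t1\tB\t2\t3\t100\t200\t5.0\nA\t1\tB\t2\t3\t100\t200\n")
        with pytest.raises(IbdParseError, match="line 2"):
            parse_ibd(path)

    def test_non_numeric_coordinate_reports_line(self, tmp_path):
        path = tmp_path / "x.ibd"
        path.write_text("A\t1\tB\t2\t3\toops\t200\t5.0\n")
        with pytest.raises(IbdParseError, match="line 1"):
            parse_ibd(path)

    def test_round_trip(self, tmp_path, small_truth):
        path = tmp_path / "rt.ibd"
        write_ibd(small_truth.planted_segments, path)
        assert parse_ibd(path) == small_truth.planted_segments


class TestMergeRuns:
    def test_overlapping_intervals_coalesce(self):
        runs = [[seg("A", "B", 1_000_000, 2_000_000)], [seg("A", "B", 1_500_000, 3_000_000)]]
        (m,) = merge_runs(runs)
        assert (m.start_bp, m.end_bp) == (1_000_000, 3_000_000)

    def test_book_ended_intervals_coalesce(self):
        runs = [[seg("A", "B", 100, 200), seg("A", "B", 201, 300)]]
        (m,) = merge_runs(runs)
        assert (m.start_bp, m.end_bp) == (100, 300)

    def test_disjoint_intervals_kept_separate(self):
        runs = [[seg("A", "B", 100, 200), seg("A", "B", 250, 300)]]
        merged = merge_runs(runs)
        assert [(m.start_bp, m.end_bp) for m in merged] == [(100, 200), (250, 300)]

    def test_haplotypes_ignored_and_pair_order_normalised(self):
        runs = [[seg("B", "A", 100, 200, hap1=2, hap2=1)], [seg("A", "B", 150, 260, hap1=1, hap2=2)]]
        (m,) = merge_runs(runs)
        assert (m.id1, m.id2, m.start_bp, m.end_bp) == ("A", "B", 100, 260)

    def test_mixed_chromosomes_rejected(self):
        runs = [[seg("A", "B", 100, 200, chrom="3")], [seg("A", "B", 100, 200, chrom="4")]]
        with pytest.raises(IbdqtError, match="chromosome"):
            merge_runs(runs)

    def test_against_interval_union_oracle(self, rng):
        """Idempotence and run-order independence on 120 random segment sets."""
        ids = ["A", "B", "C", "D"]
        for _ in range(120):
            n_runs = rng.integers(1, 4)
            runs = []
            for _ in range(n_runs):
                run = []
                for _ in range(rng.integers(0, 6)):
                    i, j = rng.choice(4, 2, replace=False)
                    a = int(rng.integers(1, 150))
                    b = a + int(rng.integers(1, 60))
                    run.append(seg(ids[i], ids[j], a, b))
                runs.append(run)
            merged = merge_runs(runs)
            # oracle: integer-membership union per pair
            by_pair = {}
            for run in runs:
                for s in run:
                    by_pair.setdefault(s.pair(), []).append((s.start_bp, s.end_bp))
            expected = {p: interval_union(iv) for p, iv in by_pair.items()}
            got = {}
            for m in merged:
                got.setdefault(m.pair(), []).append((m.start_bp, m.end_bp))
            assert got == expected
            # idempotence and order independence
            assert merge_runs([merged]) == merged
            assert merge_runs(list(reversed(runs))) == merged


class TestGeneticMap:
    def test_anchor_positions_exact(self):
        gmap = GeneticMap("3", [10, 20, 40], [0.0, 1.0, 1.5])
        assert interpolate_cM(gmap, 20) == 1.0

    def test_midpoint(self):
        gmap = GeneticMap("3", [10, 20], [0.0, 1.0])
        assert interpolate_cM(gmap, 15) == pytest.approx(0.5)

    def test_terminal_rate_extrapolation(self):
        gmap = GeneticMap("3", [10, 20, 30], [0.0, 1.0, 3.0])
        assert interpolate_cM(gmap, 5) == pytest.approx(-0.5)
        assert interpolate_cM(gmap, 35) == pytest.approx(4.0)

    def test_against_piecewise_oracle(self, rng):
        for _ in range(120):
            n = int(rng.integers(2, 8))
            pos = np.sort(rng.choice(10_000, n, replace=False)).astype(float)
            cm = np.cumsum(rng.uniform(0, 2, n))
            gmap = GeneticMap("3", pos, cm)
            anchors = list(zip(pos, cm))
            for q in rng.uniform(-1000, 11_000, 10):
                assert interpolate_cM(gmap, q) == pytest.approx(
                    piecewise_linear(anchors, q), abs=1e-9
                )

    def test_single_anchor_rejected_for_interpolation(self):
        gmap = GeneticMap("3", [10], [1.0])
        with pytest.raises(GeneticMapError):
            interpolate_cM(gmap, 20)

    def test_unsorted_anchors_rejected(self):
        with pytest.raises(GeneticMapError):
            GeneticMap("3", [20, 10], [0.0, 1.0])

    def test_file_round_trip(self, tmp_path, small_truth):
        gmap = small_truth.genetic_map()
        path = tmp_path / "map.txt"
        gmap.write(path)
        back = GeneticMap.read(path, chrom="3")
        assert np.allclose(back.positions_bp, gmap.positions_bp)
        assert np.allclose(back.cm, gmap.cm, atol=1e-6)


class TestBuildMatrix:
    samples = ["A", "B", "C"]

    def test_closed_interval_boundaries(self):
        segments = [seg("A", "B", 100, 200)]
        markers = [99, 100, 150, 200, 201]
        m = build_matrix(segments, markers, self.samples)
        row = m.indicator[[m.pair_index[("A", "B")]], :].toarray().ravel()
        assert row.tolist() == [0, 1, 1, 1, 0]

    def test_never_sharing_pairs_have_all_zero_rows(self):
        m = build_matrix([seg("A", "B", 100, 200)], [150], self.samples)
        assert m.n_pairs == 3
        assert m.indicator[m.pair_index[("A", "C")], 0] == 0
        assert m.indicator[m.pair_index[("B", "C")], 0] == 0

    def test_against_double_loop_oracle(self, rng):
        ids = ["A", "B", "C", "D", "E"]
        from itertools import combinations
        pairs = list(combinations(ids, 2))
        for _ in range(120):
            segments = []
            for _ in range(rng.integers(0, 8)):
                i, j = rng.choice(5, 2, replace=False)
                a = int(rng.integers(1, 180))
                segments.append(seg(ids[i], ids[j], a, a + int(rng.integers(1, 50))))
            markers = np.sort(rng.choice(250, rng.integers(1, 12), replace=False))
            m = build_matrix(segments, markers, ids)
            assert np.array_equal(m.indicator.toarray(), membership_matrix(segments, markers, pairs))

    def test_merge_then_build_equals_elementwise_or(self, rng):
        ids = ["A", "B", "C"]
        markers = np.arange(0, 200, 7)
        for _ in range(40):
            runs = []
            for _ in range(3):
                run = []
                for _ in range(rng.integers(0, 5)):
                    i, j = rng.choice(3, 2, replace=False)
                    a = int(rng.integers(1, 150))
                    run.append(seg(ids[i], ids[j], a, a + int(rng.integers(1, 60))))
                runs.append(run)
            merged_mat = build_matrix(merge_runs(runs), markers, ids).indicator.toarray()
            union = np.zeros_like(merged_mat)
            for run in runs:
                union |= build_matrix(run, markers, ids).indicator.toarray().astype(union.dtype)
            assert np.array_equal(merged_mat, union)

    def test_chromosome_mismatch_rejected(self):
        with pytest.raises(IbdqtError, match="chromosome"):
            build_matrix([seg("A", "B", 100, 200, chrom="4")], [150], self.samples, chrom="3")


class TestSharingRate:
    def test_all_zero_matrix(self):
        m = build_matrix([], [100, 200], ["A", "B", "C"])
        assert sharing_rate(m, 0) == 0.0

    def test_fraction_at_single_marker(self):
        ids = [f"s{k}" for k in range(5)]  # 10 pairs
        segments = [seg("s0", "s1", 100, 200), seg("s0", "s2", 100, 200), seg("s3", "s4", 100, 200)]
        m = build_matrix(segments, [150], ids)
        assert sharing_rate(m, 0) == pytest.approx(0.3)

    def test_range_counts_pairs_sharing_anywhere(self):
        ids = ["A", "B", "C"]
        segments = [seg("A", "B", 100, 110), seg("A", "C", 190, 210)]
        m = build_matrix(segments, [105, 200], ids)
        assert sharing_rate(m, (0, 1)) == pytest.approx(2 / 3)

    def test_empty_range_rejected(self):
        m = build_matrix([seg("A", "B", 100, 200)], [150], ["A", "B"])
        with pytest.raises(IbdqtError, match="range"):
            sharing_rate(m, (1, 0))

    def test_mean_rate_identity(self, small_truth):
        m = small_truth.ibd_matrix()
        per_marker = [sharing_rate(m, j) for j in range(m.n_markers)]
        assert np.mean(per_marker) == pytest.approx(m.mean_sharing_rate(), abs=1e-12)


def test_matrix_disk_round_trip(tmp_path, small_truth):
    m = small_truth.ibd_matrix()
    write_matrix(m, tmp_path)
    back = read_matrix(tmp_path)
    assert back.pairs == m.pairs
    assert np.array_equal(back.marker_positions_bp, m.marker_positions_bp)
    assert (back.indicator != m.indicator).nnz == 0
    assert back.chrom == m.chrom
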