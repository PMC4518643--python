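import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quatfold.contact_data import (
    BlockPartition,
    ContactMatrix,
    MatrixFormatError,
    PartitionError,
    bin_matrix,
    extract_blocks,
    read_contact_matrix,
    read_partition,
    select_fit_set,
    write_contact_matrix,
    write_partition,
)


def _random_symmetric(n, rng, density=1.0):
    m = rng.integers(0, 20, size=(n, n)).astype(float)
    m = np.triu(m)
    if density < 1.0:
        m[rng.random(m.shape) > density] = 0.0
    return m + np.triu(m, 1).T


class TestReadWrite:
    def test_dense_parse(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("# comment\n0 5\n5 0\n")
        m = read_contact_matrix(p, 100_000, format="dense")
        assert np.array_equal(m.counts, [[0, 5], [5, 0]])
        assert m.resolution_bp == 100_000

    def test_sparse_equals_dense(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("0\t1\t5\n1\t1\t0\n")
        m = read_contact_matrix(p, 100_000, format="sparse")
        assert np.array_equal(m.counts, [[0, 5], [5, 0]])

    @pytest.mark.parametrize("fmt", ["dense", "sparse"])
    def test_round_trip(self, tmp_path, rng, fmt):
        m = ContactMatrix(_random_symmetric(10, rng), 50_000)
        p = tmp_path / "m.txt"
        write_contact_matrix(m, p, format=fmt)
        back = read_contact_matrix(p, 50_000, format=fmt)
        assert np.array_equal(back.counts, m.counts)

    def test_non_square_dense_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("1 2 3\n4 5 6\n")
        with pytest.raises(MatrixFormatError):
            read_contact_matrix(p, 100_000, format="dense")

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContactMatrix(np.array([[0.0, -1.0], [-1.0, 0.0]]), 100_000)

    def test_asymmetric_warns_and_symmetrizes(self):
        m = np.array([[0.0, 4.0], [6.0, 0.0]])
        with pytest.warns(UserWarning, match="asymmetric"):
            cm = ContactMatrix(m, 100_000)
        assert np.array_equal(cm.counts, [[0, 5], [5, 0]])


class TestPartition:
    def test_bins_file(self, tmp_path, rng):
        m = ContactMatrix(_random_symmetric(4, rng), 100_000)
        p = tmp_path / "t.bins"
        p.write_text("0 2\n2 4\n")
        part = read_partition(p, m, format="bins")
        assert part.blocks == ((0, 2), (2, 4))

    def test_bed_file_bp_to_bins(self, tmp_path, rng):
        m = ContactMatrix(_random_symmetric(4, rng), 100_000)
        p = tmp_path / "t.bed"
        p.write_text("chr1\t0\t200000\nchr1\t200000\t400000\n")
        part = read_partition(p, m, format="bed")
        assert part.blocks == ((0, 2), (2, 4))

    def test_bed_snapping_warns(self, tmp_path, rng):
        m = ContactMatrix(_random_symmetric(4, rng), 100_000)
        p = tmp_path / "t.bed"
        p.write_text("chr1\t0\t150000\nchr1\t150000\t400000\n")
        with pytest.warns(UserWarning, match="snapping"), pytest.raises(PartitionError):
            # snapped outward the two intervals overlap -> validation error
            read_partition(p, m, format="bed")

    def test_gap_rejected(self, tmp_path, rng):
        m = ContactMatrix(_random_symmetric(6, rng), 100_000)
        p = tmp_path / "t.bins"
        p.write_text("0 2\n3 6\n")
        with pytest.raises(PartitionError):
            read_partition(p, m, format="bins")

    def test_round_trip_random_tiling(self, tmp_path, rng):
        sizes = [7, 9, 5, 11, 6, 8, 4]  # 50 bins in 7 blocks
        part = BlockPartition.from_sizes(sizes)
        p = tmp_path / "t.bins"
        write_partition(part, p)
        m = ContactMatrix(_random_symmetric(50, rng), 100_000)
        assert read_partition(p, m, format="bins") == part

    def test_empty_block_rejected(self):
        with pytest.raises(PartitionError):
            BlockPartition(((0, 2), (2, 2), (2, 4)))


class TestExtractAndBin:
    def test_identity_partition_extracts_diagonal(self, rng):
        m = ContactMatrix(_random_symmetric(5, rng), 100_000)
        blocks = extract_blocks(m, BlockPartition.from_sizes([1] * 5))
        assert [b.counts.item() for b in blocks] == list(np.diag(m.counts))

    def test_single_block_is_identity(self, rng):
        m = ContactMatrix(_random_symmetric(6, rng), 100_000)
        (b,) = extract_blocks(m, BlockPartition(((0, 6),)))
        assert np.array_equal(b.counts, m.counts)

    def test_extract_matches_slicing(self, rng):
        m = ContactMatrix(_random_symmetric(12, rng), 100_000)
        part = BlockPartition(((0, 5), (5, 12)))
        blocks = extract_blocks(m, part)
        for (a, b), blk in zip(part.blocks, blocks):
            assert np.array_equal(blk.counts, m.counts[a:b, a:b])

    def test_bin_identity_partition(self, rng):
        m = ContactMatrix(_random_symmetric(6, rng), 100_000)
        out = bin_matrix(m, BlockPartition.from_sizes([1] * 6))
        assert np.array_equal(out.counts, m.counts)

    def test_bin_all_ones(self):
        m = ContactMatrix(np.ones((4, 4)), 100_000)
        out = bin_matrix(m, BlockPartition.from_sizes([2, 2]))
        assert np.array_equal(out.counts, [[4, 4], [4, 4]])
        assert list(out.bins["end_bp"]) == [200_000, 400_000]

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000), st.integers(2, 20), st.integers(1, 6))
    def test_bin_conserves_total(self, seed, n, k):
        rng = np.random.default_rng(seed)
        m = ContactMatrix(_random_symmetric(n, rng), 100_000)
        cuts = np.sort(rng.choice(np.arange(1, n), size=min(k, n - 1), replace=False))
        edges = np.concatenate([[0], cuts, [n]])
        part = BlockPartition(tuple(zip(edges[:-1], edges[1:])))
        out = bin_matrix(m, part)
        assert out.counts.sum() == m.counts.sum()  # exact, integer-valued
        # diagonal of the binned matrix equals the extracted block sums
        for kk, blk in enumerate(extract_blocks(m, part)):
            assert out.counts[kk, kk] == blk.counts.sum()


class TestSelectFitSet:
    def test_k_exceeding_candidates_returns_all(self, rng):
        m = ContactMatrix(_random_symmetric(5, rng), 100_000)
        fs = select_fit_set(m, 1000, exclude_adjacent=False)
        expected = sum(
            1 for i in range(5) for j in range(i + 1, 5) if m.counts[i, j] > 0
        )
        assert len(fs) == expected

    def test_unique_maximum_found(self):
        m = np.zeros((6, 6))
        m[2, 5] = m[5, 2] = 9.0
        m[0, 3] = m[3, 0] = 4.0
        cm = ContactMatrix(m, 100_000)
        assert select_fit_set(cm, 1).pairs == ((2, 5, 9.0),)

    def test_matches_exhaustive_sort(self, rng):
        m = ContactMatrix(_random_symmetric(10, rng, density=0.7), 100_000)
        fs = select_fit_set(m, 5, exclude_adjacent=False)
        # oracle: full enumeration of all 45 pairs
        pairs = [
            (i, j, m.counts[i, j])
            for i in range(10)
            for j in range(i + 1, 10)
            if m.counts[i, j] > 0
        ]
        pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
        assert list(fs.pairs) == pairs[:5]

    def test_exclude_adjacent(self, rng):
        m = ContactMatrix(_random_symmetric(10, rng), 100_000)
        fs = select_fit_set(m, 45, exclude_adjacent=True)
        assert all(j - i >= 2 for i, j, _ in fs)

    def test_deterministic_tie_break(self):
        m = np.zeros((4, 4))
        for i, j in ((0, 2), (0, 3), (1, 3)):
            m[i, j] = m[j, i] = 7.0
        cm = ContactMatrix(m, 100_000)
        assert select_fit_set(cm, 2).pairs == ((0, 2, 7.0), (0, 3, 7.0))

    def test_no_positive_pairs_warns_empty(self):
        cm = ContactMatrix(np.diag([3.0, 4.0]), 100_000)
        with pytest.warns(UserWarning, match="empty"):
            fs = select_fit_set(cm, 3)
        assert len(fs) == 0


class TestSuggestPartition:
    """The naive diagonal-block heuristic (a convenience, not a TAD caller)."""

    def test_recovers_ideal_block_matrix(self):
        m = np.zeros((12, 12))
        for a, b in ((0, 4), (4, 9), (9, 12)):
            m[a:b, a:b] = 50.0
        from quatfold.contact_data import suggest_partition

        part = suggest_partition(ContactMatrix(m, 100_000))
        assert part.blocks == ((0, 4), (4, 9), (9, 12))

    def test_output_is_a_valid_cover(self, rng):
        from quatfold.contact_data import suggest_partition

        m = ContactMatrix(_random_symmetric(15, rng), 100_000)
        part = suggest_partition(m)
        assert part.covers(m)
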