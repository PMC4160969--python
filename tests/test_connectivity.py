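"""Unit tests for sparse connectivity, delays, and Matrix Market I/O."""

import numpy as np
import pytest

from stdpsim.connectivity import (
    DelayBuffer,
    MatrixFormatError,
    SparseWeightMatrix,
    propagate,
    random_sparse_connect,
    read_matrix,
    write_matrix,
)


class TestConstruction:
    def test_p_zero_gives_no_synapses(self):
        m = random_sparse_connect(50, 50, 0.0, 1.0, seed=1)
        assert m.nnz == 0

    def test_p_one_disjoint_complete_bipartite(self):
        m = random_sparse_connect(3, 4, 1.0, 0.5, seed=1, same_population=False)
        assert m.nnz == 12
        assert np.all(m.weights == 0.5)

    def test_p_one_same_population_excludes_autapses(self):
        m = random_sparse_connect(5, 5, 1.0, 1.0, seed=1)
        assert m.nnz == 20
        for i, j, _w in m.iter_forward():
            assert i != j

    def test_va_scale_synapse_count(self):
        # 4000*4000 grid at p=0.02 -> ~3.2e5 synapses within 4 binomial SD
        m = random_sparse_connect(4000, 4000, 0.02, 1.0, seed=2)
        expected = 0.02 * 4000 * 3999
        sd = np.sqrt(4000 * 3999 * 0.02 * 0.98)
        assert abs(m.nnz - expected) < 4 * sd

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SparseWeightMatrix.from_coo(2, 2, [0, 0], [1, 1], [1.0, 2.0])

    def test_connection_probability_unbiased(self):
        # empirical per-pair probability consistent with p
        m = random_sparse_connect(200, 300, 0.05, 1.0, seed=3, same_population=False)
        n_pairs = 200 * 300
        sd = np.sqrt(n_pairs * 0.05 * 0.95)
        assert abs(m.nnz - 0.05 * n_pairs) < 4 * sd


class TestViews:
    def test_backward_enumerates_same_synapses(self, rng):
        m = random_sparse_connect(40, 30, 0.2, 0.0, seed=4, same_population=False)
        m.weights[:] = rng.normal(size=m.nnz)
        fwd = sorted(m.iter_forward())
        bwd = sorted(m.iter_backward())
        assert fwd == bwd

    def test_views_share_weight_store(self):
        m = random_sparse_connect(10, 10, 0.5, 1.0, seed=5)
        sources, syn = m.col(3)
        if syn.size:
            m.weights[syn[0]] = 42.0
            # forward view sees the same value
            assert 42.0 in np.concatenate([m.row(int(s))[1] for s in sources])


class TestPropagate:
    def test_empty_spike_list_no_change(self):
        m = random_sparse_connect(10, 10, 0.5, 1.0, seed=6)
        field = np.zeros(10)
        propagate(np.empty(0, dtype=np.int64), m, field)
        assert np.all(field == 0)

    def test_single_spike_exact_increments(self):
        m = SparseWeightMatrix.from_coo(3, 5, [1, 1], [2, 4], [0.1, 0.2])
        field = np.zeros(5)
        propagate(np.array([1]), m, field)
        expected = np.zeros(5)
        expected[2], expected[4] = 0.1, 0.2
        assert np.allclose(field, expected, atol=1e-7)

    def test_batch_matches_dense_oracle(self, rng):
        m = random_sparse_connect(500, 400, 0.1, 0.0, seed=7, same_population=False)
        m.weights[:] = rng.normal(size=m.nnz).astype(np.float32)
        spikes = rng.choice(500, 200, replace=False)
        field = np.zeros(400, dtype=np.float64)
        propagate(spikes, m, field)
        dense = m.to_dense().astype(np.float64)
        indicator = np.zeros(500)
        indicator[spikes] = 1.0
        assert np.allclose(field, dense.T @ indicator, atol=1e-6)

    def test_out_of_range_index_is_hard_error(self):
        m = random_sparse_connect(10, 10, 0.5, 1.0, seed=8)
        with pytest.raises(IndexError):
            propagate(np.array([10]), m, np.zeros(10))


class TestDelayBuffer:
    def test_delivery_exactly_delay_steps_later(self):
        buf = DelayBuffer(8)
        buf.enqueue(3, np.array([5, 7]))
        for step in range(3, 11):
            assert buf.deliver(step).size == 0
        assert np.array_equal(buf.deliver(11), np.array([5, 7]))

    def test_spike_conservation(self, rng):
        buf = DelayBuffer(5)
        total = 0
        for step in range(100):
            spikes = rng.integers(0, 50, size=rng.integers(0, 6))
            buf.enqueue(step, spikes)
            total += spikes.size
            buf.deliver(step)
        for step in range(100, 106):  # drain
            buf.deliver(step)
        assert buf.enqueued == total
        assert buf.delivered == total
        assert buf.pending == 0


class TestMatrixIO:
    def test_empty_matrix_round_trip(self, tmp_path):
        m = random_sparse_connect(4, 6, 0.0, 1.0, seed=9, same_population=False)
        path = tmp_path / "empty.wmat"
        write_matrix(m, path)
        m2 = read_matrix(path)
        assert (m2.n_pre, m2.n_post, m2.nnz) == (4, 6, 0)

    def test_toy_matrix_bit_exact_float64(self, tmp_path):
        m = SparseWeightMatrix.from_coo(
            3, 3, [0, 1, 2], [1, 2, 0], [0.125, -2.5, 7.0], dtype=np.float64
        )
        path = tmp_path / "toy.wmat"
        write_matrix(m, path)
        m2 = read_matrix(path, dtype=np.float64)
        assert sorted(m.iter_forward()) == sorted(m2.iter_forward())

    def test_scaled_instance_round_trip(self, tmp_path, rng):
        # scaled stand-in for the 25k-network matrix: sparse I/O never
        # materializes a dense array (dense would be 4e4 x 4e4 here)
        m = random_sparse_connect(2000, 2000, 0.02, 0.0, seed=10)
        m.weights[:] = rng.random(m.nnz).astype(np.float32)
        path = tmp_path / "big.wmat"
        write_matrix(m, path)
        m2 = read_matrix(path)
        assert m2.nnz == m.nnz
        assert np.allclose(
            np.sort(m2.weights), np.sort(m.weights), atol=1e-6
        )

    def test_one_based_indices_on_disk(self, tmp_path):
        m = SparseWeightMatrix.from_coo(2, 2, [0], [1], [3.0])
        path = tmp_path / "m.wmat"
        write_matrix(m, path)
        body = [
            line
            for line in path.read_text().splitlines()
            if line and not line.startswith("%")
        ]
        # dims line then the single entry with 1-based indices
        assert body[0].split() == ["2", "2", "1"]
        assert body[1].split()[:2] == ["1", "2"]

    def test_malformed_entry_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.wmat"
        path.write_text(
            "%%MatrixMarket matrix coordinate real general\n"
            "2 2 2\n"
            "1 1 0.5\n"
            "1 banana 0.5\n"
        )
        with pytest.raises(MatrixFormatError, match="line 4"):
            read_matrix(path)

    def test_missing_header_reports_line(self, tmp_path):
        path = tmp_path / "nohdr.wmat"
        path.write_text("2 2 1\n1 1 0.5\n")
        with pytest.raises(MatrixFormatError, match="line 1"):
            read_matrix(path)
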