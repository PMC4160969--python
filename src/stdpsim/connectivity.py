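"""Sparse delayed synaptic connectivity.

The weight store is a single flat array indexed by synapse id (the
position of the synapse in forward, row-major order).  The forward view
(per presynaptic index) and the backward view (per postsynaptic index)
both hold synapse ids into that store, so they expose identical weight
values by construction.  The backward view is required for plasticity
rules that update weights on postsynaptic spikes.

Delays are uniform per connection object and implemented as a ring buffer
of per-step spike lists: a spike enqueued at step t is delivered exactly
at step t + delay_steps.

Weight matrices round-trip through Matrix Market coordinate format
(real, general, 1-based indices); internal indices are 0-based.
"""

from __future__ import annotations

import numpy as np
import scipy.io
import scipy.sparse

__all__ = [
    "SparseWeightMatrix",
    "DelayBuffer",
    "MatrixFormatError",
    "random_sparse_connect",
    "propagate",
    "read_matrix",
    "write_matrix",
]


class MatrixFormatError(ValueError):
    """Malformed Matrix Market input."""


class SparseWeightMatrix:
    """Forward + backward views over one shared flat weight store.

    Attributes
    ----------
    fwd_ptr : (n_pre+1,) int64
        CSR-style row pointer; synapses of presynaptic neuron i are the
        ids ``fwd_ptr[i]:fwd_ptr[i+1]``.
    targets : (nnz,) int32
        Postsynaptic index per synapse id.
    weights : (nnz,) float
        The single weight store, indexed by synapse id.
    """

    def __init__(
        self,
        n_pre: int,
        n_post: int,
        fwd_ptr: np.ndarray,
        targets: np.ndarray,
        weights: np.ndarray,
    ) -> None:
        self.n_pre = int(n_pre)
        self.n_post = int(n_post)
        self.fwd_ptr = np.asarray(fwd_ptr, dtype=np.int64)
        self.targets = np.asarray(targets, dtype=np.int32)
        self.weights = np.asarray(weights)
        if self.fwd_ptr.size != self.n_pre + 1:
            raise ValueError("fwd_ptr must have length n_pre+1")
        if self.targets.size != self.weights.size:
            raise ValueError("targets and weights must have equal length")
        if self.targets.size and (
            self.targets.min() < 0 or self.targets.max() >= self.n_post
        ):
            raise ValueError("target index out of range")
        self._bwd_ptr: np.ndarray | None = None
        self._bwd_sources: np.ndarray | None = None
        self._bwd_syn: np.ndarray | None = None

    # -- construction -------------------------------------------------
    @classmethod
    def from_coo(
        cls,
        n_pre: int,
        n_post: int,
        pre: np.ndarray,
        post: np.ndarray,
        w: np.ndarray,
        dtype=np.float32,
    ) -> "SparseWeightMatrix":
        pre = np.asarray(pre, dtype=np.int64)
        post = np.asarray(post, dtype=np.int64)
        w = np.asarray(w)
        order = np.lexsort((post, pre))
        pre, post, w = pre[order], post[order], w[order]
        if pre.size:
            dup = (np.diff(pre) == 0) & (np.diff(post) == 0)
            if np.any(dup):
                raise ValueError("duplicate (pre, post) pairs are not allowed")
        ptr = np.zeros(n_pre + 1, dtype=np.int64)
        np.cumsum(np.bincount(pre, minlength=n_pre), out=ptr[1:])
        return cls(n_pre, n_post, ptr, post, w.astype(dtype))

    @property
    def nnz(self) -> int:
        return int(self.targets.size)

    def row(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(targets, weights) of presynaptic neuron i (weights is a view)."""
        sl = slice(self.fwd_ptr[i], self.fwd_ptr[i + 1])
        return self.targets[sl], self.weights[sl]

    def row_syn_ids(self, i: int) -> np.ndarray:
        return np.arange(self.fwd_ptr[i], self.fwd_ptr[i + 1])

    # -- backward view -------------------------------------------------
    def _build_backward(self) -> None:
        order = np.argsort(self.targets, kind="stable")
        self._bwd_syn = order.astype(np.int64)
        counts = np.bincount(self.targets, minlength=self.n_post)
        self._bwd_ptr = np.zeros(self.n_post + 1, dtype=np.int64)
        np.cumsum(counts, out=self._bwd_ptr[1:])
        sources = np.repeat(
            np.arange(self.n_pre, dtype=np.int32),
            np.diff(self.fwd_ptr).astype(np.int64),
        )
        self._bwd_sources = sources[order]

    @property
    def bwd_ptr(self) -> np.ndarray:
        if self._bwd_ptr is None:
            self._build_backward()
        return self._bwd_ptr

    def col(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        """(sources, synapse ids) of postsynaptic neuron j."""
        ptr = self.bwd_ptr
        sl = slice(ptr[j], ptr[j + 1])
        return self._bwd_sources[sl], self._bwd_syn[sl]

    def iter_forward(self):
        """Yield (pre, post, weight) in forward order."""
        for i in range(self.n_pre):
            t, w = self.row(i)
            for j, wij in zip(t, w):
                yield i, int(j), float(wij)

    def iter_backward(self):
        """Yield (pre, post, weight) via the backward view."""
        ptr = self.bwd_ptr
        for j in range(self.n_post):
            src, syn = self.col(j)
            for i, s in zip(src, syn):
                yield int(i), j, float(self.weights[s])

    # -- conversion ----------------------------------------------------
    def to_coo(self) -> scipy.sparse.coo_matrix:
        pre = np.repeat(
            np.arange(self.n_pre, dtype=np.int64), np.diff(self.fwd_ptr)
        )
        return scipy.sparse.coo_matrix(
            (self.weights, (pre, self.targets.astype(np.int64))),
            shape=(self.n_pre, self.n_post),
        )

    def to_dense(self) -> np.ndarray:
        return self.to_coo().toarray()


def random_sparse_connect(
    n_pre: int,
    n_post: int,
    p: float,
    w_init: float,
    seed: int | tuple | np.random.Generator = 1,
    same_population: bool | None = None,
    dtype=np.float32,
) -> SparseWeightMatrix:
    """Erdos-Renyi connectivity: each ordered pair independently with prob p.

    ``same_population=True`` (default when n_pre == n_post) excludes
    autapses (i == j).  Sampling is done with a vectorized geometric-gap
    scan over the flattened cell grid, so no dense matrix is materialized.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if same_population is None:
        same_population = n_pre == n_post
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = n_pre * n_post
    if p == 0.0 or total == 0:
        return SparseWeightMatrix(
            n_pre,
            n_post,
            np.zeros(n_pre + 1, dtype=np.int64),
            np.empty(0, dtype=np.int32),
            np.empty(0, dtype=dtype),
        )
    # geometric gaps between hit cells; expected hits = p * total
    cells_chunks = []
    pos = -1
    while True:
        size = max(64, int((total - pos) * p * 1.05) + 32)
        gaps = rng.geometric(p, size=size)
        hits = pos + np.cumsum(gaps)
        idx = int(np.searchsorted(hits, total))
        if idx < size:
            cells_chunks.append(hits[:idx])
            break
        cells_chunks.append(hits)
        pos = int(hits[-1])
    cells = np.concatenate(cells_chunks)
    pre = cells // n_post
    post = cells % n_post
    if same_population:
        keep = pre != post
        pre, post = pre[keep], post[keep]
    ptr = np.zeros(n_pre + 1, dtype=np.int64)
    np.cumsum(np.bincount(pre, minlength=n_pre), out=ptr[1:])
    weights = np.full(pre.size, w_init, dtype=dtype)
    return SparseWeightMatrix(n_pre, n_post, ptr, post.astype(np.int32), weights)


def multi_row_indices(ptr: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Concatenated ``arange(ptr[r], ptr[r+1])`` for all rows, vectorized."""
    rows = np.asarray(rows, dtype=np.int64)
    starts = ptr[rows]
    lens = ptr[rows + 1] - starts
    nonempty = lens > 0  # empty rows would corrupt the cumsum jump trick
    starts, lens = starts[nonempty], lens[nonempty]
    total = int(lens.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    out = np.ones(total, dtype=np.int64)
    boundaries = np.cumsum(lens)[:-1]
    out[0] = starts[0]
    if boundaries.size:
        out[boundaries] = starts[1:] - (starts[:-1] + lens[:-1] - 1)
    return np.cumsum(out)


def propagate(
    spiking_pre: np.ndarray, m: SparseWeightMatrix, target_field: np.ndarray
) -> np.ndarray:
    """Deliver spikes: target_field[j] += w_ij for every synapse of each
    spiking presynaptic neuron.  Returns the updated target field."""
    spiking_pre = np.asarray(spiking_pre, dtype=np.int64)
    if spiking_pre.size == 0:
        return target_field
    if spiking_pre.min() < 0 or spiking_pre.max() >= m.n_pre:
        raise IndexError("presynaptic index out of range")
    syn = multi_row_indices(m.fwd_ptr, spiking_pre)
    if syn.size == 0:
        return target_field
    inc = np.bincount(
        m.targets[syn], weights=m.weights[syn].astype(np.float64), minlength=m.n_post
    )
    target_field += inc.astype(target_field.dtype)
    return target_field


class DelayBuffer:
    """Ring buffer of per-step spike index arrays.

    A spike enqueued at step t is delivered exactly at step t +
    delay_steps.  ``enqueued``/``delivered`` counters support the spike
    conservation invariant.
    """

    def __init__(self, delay_steps: int) -> None:
        if delay_steps < 1:
            raise ValueError("delay_steps must be >= 1")
        self.delay_steps = int(delay_steps)
        self._ring: list[np.ndarray] = [
            np.empty(0, dtype=np.int64) for _ in range(self.delay_steps + 1)
        ]
        self.enqueued = 0
        self.delivered = 0

    def enqueue(self, step: int, spikes: np.ndarray) -> None:
        spikes = np.asarray(spikes, dtype=np.int64)
        slot = (step + self.delay_steps) % (self.delay_steps + 1)
        if self._ring[slot].size:
            self._ring[slot] = np.concatenate([self._ring[slot], spikes])
        else:
            self._ring[slot] = spikes
        self.enqueued += spikes.size

    def deliver(self, step: int) -> np.ndarray:
        slot = step % (self.delay_steps + 1)
        out = self._ring[slot]
        self._ring[slot] = np.empty(0, dtype=np.int64)
        self.delivered += out.size
        return out

    @property
    def pending(self) -> int:
        return self.enqueued - self.delivered


# ---------------------------------------------------------------------------
# Matrix Market I/O
# ---------------------------------------------------------------------------


def write_matrix(m: SparseWeightMatrix, path) -> None:
    """Write to Matrix Market coordinate real general (1-based indices)."""
    # pass a file object so scipy does not append its own .mtx extension;
    # write values as float64 (scipy's fast_matrix_market backend in this
    # environment crashes on float32 payloads)
    with open(path, "wb") as fh:
        scipy.io.mmwrite(
            fh,
            m.to_coo().astype(np.float64),
            comment="stdpsim sparse weight matrix",
            precision=17,
        )


def _diagnose_mm_error(path, exc: Exception) -> MatrixFormatError:
    """Locate the first malformed line for a readable parse error."""
    try:
        with open(path) as fh:
            lineno = 0
            header_seen = False
            dims_seen = False
            for lineno, line in enumerate(fh, start=1):
                s = line.strip()
                if lineno == 1:
                    if not s.startswith("%%MatrixMarket"):
                        return MatrixFormatError(
                            f"{path}: line {lineno}: missing MatrixMarket header"
                        )
                    header_seen = True
                    continue
                if not s or s.startswith("%"):
                    continue
                parts = s.split()
                if not dims_seen:
                    if len(parts) != 3 or not all(p.isdigit() for p in parts):
                        return MatrixFormatError(
                            f"{path}: line {lineno}: malformed dimensions line {s!r}"
                        )
                    dims_seen = True
                    continue
                if len(parts) != 3:
                    return MatrixFormatError(
                        f"{path}: line {lineno}: expected 'row col value', got {s!r}"
                    )
                try:
                    r, c = int(parts[0]), int(parts[1])
                    float(parts[2])
                    if r < 1 or c < 1:
                        raise ValueError
                except ValueError:
                    return MatrixFormatError(
                        f"{path}: line {lineno}: malformed entry {s!r}"
                    )
            if not header_seen:
                return MatrixFormatError(f"{path}: empty file")
    except OSError as oserr:
        return MatrixFormatError(str(oserr))
    return MatrixFormatError(f"{path}: {exc}")


def read_matrix(path, dtype=np.float32) -> SparseWeightMatrix:
    """Read a Matrix Market coordinate file into a SparseWeightMatrix."""
    # validate the banner ourselves: scipy's reader aborts the process on
    # files without a MatrixMarket header
    with open(path, "rb") as fh:
        first = fh.readline()
    if not first.startswith(b"%%MatrixMarket"):
        raise MatrixFormatError(f"{path}: line 1: missing MatrixMarket header")
    try:
        with open(path, "rb") as fh:
            mat = scipy.io.mmread(fh)
    except OSError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with line diagnostics
        raise _diagnose_mm_error(path, exc) from exc
    coo = scipy.sparse.coo_matrix(mat)
    return SparseWeightMatrix.from_coo(
        coo.shape[0], coo.shape[1], coo.row, coo.col, coo.data, dtype=dtype
    )
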