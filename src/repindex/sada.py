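"""Constant-time document counting from suffix-tree redundancy counts.

For every internal node ``v`` of the binarized suffix tree with children
``u`` and ``w``, the redundancy ``h(v) = |D_u cap D_w|`` satisfies
``count(v) = count(u) + count(w) - h(v)``.  Listing the ``h`` values in
inorder gives an array ``H[1..n-1]`` over which the document frequency of
any suffix-tree node with leaf interval ``[l..r]`` is the closed form

    count(l, r) = (r + 1 - l) - sum(H[l..r-1]).

``H`` is stored unarily as a bitvector ``H'`` (a 1-bit then ``H[i]`` 0-bits
per cell), so the sum becomes a difference of two selects.  Because only
sums over original (non-binarized) node intervals are ever queried, all the
``h`` mass of a node's binarization chain is reassigned to a single inorder
position, which makes ``H'`` far more compressible; optional filters store
only the informative cells:

* ``fs`` (sparse filter): keep cells with ``H[i] > 0``;
* ``f1`` (1-filter): cells with ``H[i] = 1`` are marked in a bitvector and
  contribute no 0s to ``H'``;
* ``fs+f1``: the sparse filter then keeps cells with ``H[i] > 1``;
* ``f`` (count filter): subtrees whose node sees a single distinct document
  are pruned to leaves; remaining binarized nodes are marked in ``F`` and
  ``H'`` is built for the pruned tree.  A locus falling inside a pruned
  subtree has ``count = 1`` by construction and never consults ``H'``.

Queries are defined at pattern loci (suffix-tree node intervals, or single
positions); behaviour on other intervals is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SuffixArrayIndex, distinct_counts
from .succinct import Bitvector
from .suffixtree import LEAF, NODE, SuffixTree, build_suffix_tree

__all__ = ["HArray", "build_h", "encode_h", "CountingStructure", "h_prime_one_runs"]


@dataclass
class HArray:
    """Reassigned redundancy counts plus the data for the count filter.

    ``H[i]`` (1-based cell ``i`` stored at ``H[i-1]``) carries the total
    chain redundancy of the original node whose binarization top has inorder
    rank ``i``; other cells are 0.  ``F_bits[i-1]`` marks binarized nodes
    that see more than one distinct document, and ``H_pruned`` carries the
    chain mass restricted to the unpruned part of each chain.
    """

    n: int
    H: np.ndarray
    F_bits: np.ndarray
    H_pruned: np.ndarray

    def total(self) -> int:
        return int(self.H.sum())


def build_h(index: SuffixArrayIndex, tree: SuffixTree | None = None) -> HArray:
    """Compute the reassigned ``H`` array (and filter data) for an index.

    Works from per-interval distinct-document counts instead of materialized
    document sets: for an original node ``v`` with children ``c_1..c_k`` the
    chain redundancy is ``sum_j count(c_j) - count(v)``, independent of the
    binarization order, and the right-to-left chain node ``b_j`` covering
    ``[start_j..hi]`` has ``h(b_j) = count(c_j) + count(b_{j+1}) - count(b_j)``.
    The mass of a chain is placed at the inorder rank of its top node, the
    end position of the first child's interval.
    """
    n = index.n
    if tree is None:
        tree = build_suffix_tree(index)
    da = index.document_array().array
    H = np.zeros(max(n - 1, 0), dtype=np.int64)
    F_bits = np.zeros(max(n - 1, 0), dtype=np.uint8)
    H_pruned = np.zeros(max(n - 1, 0), dtype=np.int64)
    if n <= 1:
        return HArray(n, H, F_bits, H_pruned)

    queries: list[tuple[int, int]] = []
    node_q: dict[int, int] = {}
    for v in range(len(tree)):
        node_q[v] = len(queries)
        queries.append(tree.interval(v))
    suffix_slices: list[tuple[int, int]] = []
    for v in range(len(tree)):
        childs = tree.children[v]
        hi = int(tree.hi[v])
        begin = len(queries)
        for kind, x in childs[1:]:
            start = x if kind == LEAF else int(tree.lo[x])
            queries.append((start, hi))
        suffix_slices.append((begin, len(queries)))
    counts = distinct_counts(da, queries)

    for v in range(len(tree)):
        childs = tree.children[v]
        k = len(childs)
        count_v = int(counts[node_q[v]])
        child_counts = [
            1 if kind == LEAF else int(counts[node_q[x]]) for kind, x in childs
        ]
        begin, end = suffix_slices[v]
        # count_suffix[j] = distinct docs in [start_j..hi], j = 1..k (1-based)
        count_suffix = [count_v] + [int(counts[t]) for t in range(begin, end)]
        ends = [
            (x if kind == LEAF else int(tree.hi[x])) for kind, x in childs[:-1]
        ]
        e1 = ends[0]
        H[e1 - 1] += sum(child_counts) - count_v

        h_chain = [
            child_counts[j] + (count_suffix[j + 1] if j + 1 < k else child_counts[k - 1])
            - count_suffix[j]
            for j in range(k - 1)
        ]
        mass_pruned = 0
        for j in range(k - 1):
            if count_suffix[j] > 1:
                F_bits[ends[j] - 1] = 1
                mass_pruned += h_chain[j]
        H_pruned[e1 - 1] += mass_pruned
    return HArray(n, H, F_bits, H_pruned)


def _unary_bitvector(cells: np.ndarray, encoding: str) -> Bitvector:
    """Unary encoding: per cell a 1-bit followed by ``cells[i]`` 0-bits."""
    n_cells = cells.size
    length = int(n_cells + cells.sum())
    ones = np.r_[0, np.cumsum(cells[:-1] + 1)] + 1 if n_cells else np.zeros(0, int)
    return Bitvector.from_ones(ones, max(length, 0), encoding=encoding)


class CountingStructure:
    """Encoded ``H'`` with optional filters, answering ``count(l, r)``."""

    def __init__(self, h: HArray, encoding: str = "plain",
                 filters: frozenset[str] = frozenset()):
        filters = frozenset(filters)
        if encoding not in ("plain", "sparse"):
            raise ValueError(f"unknown encoding {encoding!r}")
        unknown = filters - {"f", "fs", "f1"}
        if unknown:
            raise ValueError(f"unknown filters {sorted(unknown)}")
        if "f" in filters and len(filters) > 1:
            raise ValueError(
                "the count filter 'f' changes the tree shape and cannot be "
                "combined with the cell filters 'fs'/'f1'"
            )
        self.encoding = encoding
        self.filters = filters
        self.n = h.n
        H = h.H
        self._F = self._FS = self._F1 = None

        if "f" in filters:
            self._F = Bitvector(h.F_bits)
            cells = h.H_pruned[h.F_bits.astype(bool)]
            self._cells_total = cells.size
            self._hprime = _unary_bitvector(cells, encoding)
            self._total_zeros = int(cells.sum())
            return

        zero_counts = H.copy()
        if "f1" in filters:
            self._F1 = Bitvector((H == 1).astype(np.uint8))
            zero_counts = np.where(H == 1, 0, H)
        if "fs" in filters:
            threshold = 1 if "f1" in filters else 0
            keep = H > threshold
            self._FS = Bitvector(keep.astype(np.uint8))
            zero_counts = zero_counts[keep]
        self._cells_total = zero_counts.size
        self._hprime = _unary_bitvector(zero_counts, encoding)
        self._total_zeros = int(zero_counts.sum())

    # -- internals ----------------------------------------------------------

    def _zeros_through(self, t: int) -> int:
        """Zeros among the first ``t`` cells of ``H'``."""
        if t <= 0:
            return 0
        if t >= self._cells_total:
            return self._total_zeros
        return self._hprime.select(1, t + 1) - (t + 1)

    # -- queries -------------------------------------------------------------

    def count(self, l: int, r: int) -> int:
        """Distinct documents in ``DA[l..r]`` for a suffix-tree node interval."""
        if not (1 <= l <= r <= self.n):
            raise IndexError(f"invalid interval [{l}..{r}] over [1..{self.n}]")
        if l == r:
            return 1
        if self._F is not None:
            a = self._F.rank(1, l - 1)
            b = self._F.rank(1, r - 1)
            if a == b:
                return 1  # locus inside a pruned one-document subtree
            s = self._zeros_through(b) - self._zeros_through(a)
            return (b - a + 1) - s
        if self._FS is not None:
            a = self._FS.rank(1, l - 1)
            b = self._FS.rank(1, r - 1)
            s = self._zeros_through(b) - self._zeros_through(a)
        else:
            s = self._zeros_through(r - 1) - self._zeros_through(l - 1)
        if self._F1 is not None:
            s += self._F1.rank(1, r - 1) - self._F1.rank(1, l - 1)
        return (r + 1 - l) - s


def encode_h(h: HArray, encoding: str = "plain",
             filters=frozenset()) -> CountingStructure:
    """Encode an ``HArray`` with the chosen bitvector encoding and filters."""
    return CountingStructure(h, encoding=encoding, filters=frozenset(filters))


def h_prime_one_runs(h: HArray) -> int:
    """Number of maximal runs of 1-bits in the unfiltered ``H'``.

    A new run starts at cell 1 and at every cell preceded by a non-zero
    cell; repetitive (and even unrelated random) collections keep this
    sublinear in the collection size.
    """
    if h.n <= 1:
        return 0
    H = h.H
    return 1 + int(np.count_nonzero(H[:-1]))
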