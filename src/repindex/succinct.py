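"""Rank/select bitvectors, wavelet trees and range-minimum structures.

These are the building blocks shared by every index in the package.  The
contract is behavioural (rank/select semantics, leftmost-minimum RMQ, the
skewed wavelet-tree depth law), not a particular bit layout: the plain
bitvector keeps a cumulative-count array, the sparse one keeps the sorted
positions of its 1s.

All positions are 1-based; ``rank(c, i)`` counts symbol ``c`` in the prefix
of length ``i`` (``i = 0`` gives 0) and ``select(c, j)`` returns the
position of the ``j``-th occurrence of ``c``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Bitvector", "RMQ", "WaveletTree"]


class Bitvector:
    """A 0/1 sequence with rank and select, in plain or sparse encoding."""

    def __init__(self, bits: Iterable[int], encoding: str = "plain"):
        bits = np.asarray(list(bits) if not isinstance(bits, np.ndarray) else bits,
                          dtype=np.uint8)
        if bits.size and bits.max(initial=0) > 1:
            raise ValueError("bitvector entries must be 0 or 1")
        if encoding not in ("plain", "sparse"):
            raise ValueError(f"unknown bitvector encoding {encoding!r}")
        self.encoding = encoding
        self.length = int(bits.size)
        # ones[j-1] is the 1-based position of the j-th 1-bit.
        self._ones = np.flatnonzero(bits).astype(np.int64) + 1
        if encoding == "plain":
            self._bits = bits
        else:
            self._bits = None

    @classmethod
    def from_ones(cls, positions: Sequence[int], length: int,
                  encoding: str = "sparse") -> "Bitvector":
        bv = cls.__new__(cls)
        bv.encoding = encoding
        bv.length = int(length)
        bv._ones = np.asarray(sorted(positions), dtype=np.int64)
        if bv._ones.size and (bv._ones[0] < 1 or bv._ones[-1] > length):
            raise ValueError("1-positions out of range")
        if encoding == "plain":
            bits = np.zeros(length, dtype=np.uint8)
            bits[bv._ones - 1] = 1
            bv._bits = bits
        else:
            bv._bits = None
        return bv

    def __len__(self) -> int:
        return self.length

    def __getitem__(self, p: int) -> int:
        """Bit at 1-based position ``p``."""
        if not 1 <= p <= self.length:
            raise IndexError(f"position {p} out of range [1..{self.length}]")
        if self._bits is not None:
            return int(self._bits[p - 1])
        i = np.searchsorted(self._ones, p)
        return int(i < self._ones.size and self._ones[i] == p)

    def count(self, c: int = 1) -> int:
        ones = self._ones.size
        return ones if c == 1 else self.length - ones

    def rank(self, c: int, i: int) -> int:
        """Occurrences of bit ``c`` in the prefix of length ``i``."""
        if not 0 <= i <= self.length:
            raise IndexError(f"rank position {i} out of range [0..{self.length}]")
        r1 = int(np.searchsorted(self._ones, i, side="right"))
        return r1 if c == 1 else i - r1

    def select(self, c: int, j: int) -> int:
        """Position of the ``j``-th occurrence of bit ``c`` (1-based)."""
        total = self.count(c)
        if not 1 <= j <= total:
            raise IndexError(f"select index {j} out of range [1..{total}]")
        if c == 1:
            return int(self._ones[j - 1])
        # j-th zero: binary search on p - rank1(p), which is nondecreasing.
        lo, hi = 1, self.length
        while lo < hi:
            mid = (lo + hi) // 2
            if mid - self.rank(1, mid) >= j:
                hi = mid
            else:
                lo = mid + 1
        return lo

    def to_array(self) -> np.ndarray:
        bits = np.zeros(self.length, dtype=np.uint8)
        bits[self._ones - 1] = 1
        return bits


class RMQ:
    """Range-minimum queries returning the *leftmost* minimum position.

    Sparse-table implementation; ``query(i, j)`` over 1-based closed ranges.
    The leftmost tie-break is load-bearing for the document-listing
    recursions built on top of it.
    """

    def __init__(self, array: Sequence[int]):
        a = np.asarray(array, dtype=np.int64)
        if a.size == 0:
            raise ValueError("cannot build RMQ over an empty array")
        self.array = a
        n = a.size
        levels = max(1, int(np.floor(np.log2(n))) + 1)
        idx = np.arange(n, dtype=np.int64)
        self._table = [idx]
        for k in range(1, levels):
            half = 1 << (k - 1)
            prev = self._table[-1]
            if n - (1 << k) + 1 <= 0:
                break
            left = prev[: n - (1 << k) + 1]
            right = prev[half: half + n - (1 << k) + 1]
            # strict < keeps the leftmost minimum on ties
            take_right = a[right] < a[left]
            self._table.append(np.where(take_right, right, left))

    def query(self, i: int, j: int) -> int:
        """Leftmost position of the minimum of ``array[i..j]`` (1-based)."""
        n = self.array.size
        if not (1 <= i <= j <= n):
            raise IndexError(f"invalid RMQ range [{i}..{j}] over length {n}")
        i0, j0 = i - 1, j - 1
        k = (j0 - i0 + 1).bit_length() - 1
        left = int(self._table[k][i0])
        right = int(self._table[k][j0 - (1 << k) + 1])
        if self.array[right] < self.array[left]:
            return right + 1
        return left + 1


class _WTNode:
    __slots__ = ("lo", "hi", "bits", "left", "right")

    def __init__(self, lo: int, hi: int):
        self.lo = lo          # value range [lo..hi] handled by this node
        self.hi = hi
        self.bits: Bitvector | None = None
        self.left: "_WTNode | None" = None
        self.right: "_WTNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.lo == self.hi


class WaveletTree:
    """Wavelet tree over values ``0..sigma-1``, balanced or skewed shape.

    The skewed shape places the ``i``-th leftmost leaf at depth
    ``1 + 2*floor(lg i)``: leaf 1 hangs directly off the root, leaves 2-3
    live in a balanced subtree two levels down, leaves 4-7 two further
    levels down, and so on.  Descending only into subtrees that intersect
    ``[0..m-1]`` then touches O(m) nodes, which is what makes document
    counting over the run heads linear in the pattern length.
    """

    def __init__(self, seq: Sequence[int], sigma: int | None = None,
                 shape: str = "balanced"):
        seq = np.asarray(seq, dtype=np.int64)
        if seq.size == 0:
            raise ValueError("cannot build a wavelet tree over an empty sequence")
        if seq.min() < 0:
            raise ValueError("wavelet tree values must be non-negative")
        if sigma is None:
            sigma = int(seq.max()) + 1
        if seq.max() >= sigma:
            raise ValueError("sequence value outside [0..sigma-1]")
        if shape not in ("balanced", "skewed"):
            raise ValueError(f"unknown wavelet tree shape {shape!r}")
        self.sigma = int(sigma)
        self.shape = shape
        self.n = int(seq.size)
        self.root = self._build_shape(0, self.sigma - 1, spine=(shape == "skewed"))
        self._fill(self.root, seq)

    # -- shape ------------------------------------------------------------

    def _build_shape(self, lo: int, hi: int, spine: bool) -> _WTNode:
        node = _WTNode(lo, hi)
        if lo == hi:
            return node
        if not spine:
            mid = (lo + hi) // 2
            node.left = self._build_shape(lo, mid, spine=False)
            node.right = self._build_shape(mid + 1, hi, spine=False)
            return node
        # Skewed: peel off the current leaf group on the left, keep the
        # spine on the right.  Group g holds 2^(g-1) values; the root's
        # group is the single value `lo`.  Every group subtree hangs one
        # level below its spine node so complete groups land exactly at the
        # depth law; a truncated trailing group sits at most that deep.
        group = self._group_size(lo)
        mid = min(lo + group - 1, hi)
        node.left = self._build_shape(lo, mid, spine=False)
        node.right = self._build_shape(mid + 1, hi, spine=True) if mid < hi else None
        return node

    @staticmethod
    def _group_size(lo: int) -> int:
        # leftmost leaf indices 1,2,4,8,... start groups of sizes 1,2,4,8,...
        leaf_index = lo + 1
        g = leaf_index.bit_length()
        return 1 << (g - 1)

    # -- contents ---------------------------------------------------------

    def _fill(self, node: _WTNode, seq: np.ndarray) -> None:
        if node.is_leaf or seq.size == 0:
            if not node.is_leaf and node.left is not None:
                # empty subsequences still need bitvectors for rank bookkeeping
                node.bits = Bitvector(np.zeros(0, dtype=np.uint8))
                self._fill(node.left, seq)
                if node.right is not None:
                    self._fill(node.right, seq)
            return
        go_right = seq > node.left.hi
        node.bits = Bitvector(go_right.astype(np.uint8))
        self._fill(node.left, seq[~go_right])
        if node.right is not None:
            self._fill(node.right, seq[go_right])

    def access(self, i: int) -> int:
        """Value at 1-based position ``i``."""
        if not 1 <= i <= self.n:
            raise IndexError(f"position {i} out of range [1..{self.n}]")
        node = self.root
        while not node.is_leaf:
            if node.bits[i]:
                i = node.bits.rank(1, i)
                node = node.right
            else:
                i = node.bits.rank(0, i)
                node = node.left
        return node.lo

    def rank(self, value: int, i: int) -> int:
        """Occurrences of ``value`` in the prefix of length ``i``."""
        if not 0 <= i <= self.n:
            raise IndexError(f"rank position {i} out of range")
        node = self.root
        while not node.is_leaf and i > 0:
            if value > node.left.hi:
                i = node.bits.rank(1, i)
                node = node.right
            else:
                i = node.bits.rank(0, i)
                node = node.left
        if node.lo != value:
            return 0
        return i

    def count_below(self, l: int, r: int, m: int):
        """Occurrence intervals of each value ``< m`` inside positions [l..r].

        Returns ``(results, visited)`` where ``results`` is a list of
        ``(value, (a, b))`` with ``[a..b]`` the 1-based interval of absolute
        occurrence ranks of ``value`` covered by [l..r] (i.e. the a-th to
        b-th occurrences of ``value`` in the whole sequence), and
        ``visited`` is the number of wavelet-tree nodes touched.  Subtrees
        whose value range is disjoint from ``[0..m-1]`` are never entered.
        """
        if not (1 <= l <= r <= self.n):
            raise IndexError(f"invalid range [{l}..{r}] over length {self.n}")
        if m < 1:
            raise ValueError("m must be >= 1")
        results: list[tuple[int, tuple[int, int]]] = []
        visited = 0

        def rec(node: _WTNode, lo_i: int, hi_i: int) -> None:
            # lo_i = mapped l-1, hi_i = mapped r within this node
            nonlocal visited
            if node.lo >= m:
                return
            visited += 1
            if node.is_leaf:
                if hi_i > lo_i:
                    results.append((node.lo, (lo_i + 1, hi_i)))
                return
            rec(node.left, node.bits.rank(0, lo_i), node.bits.rank(0, hi_i))
            if node.right is not None:
                rec(node.right, node.bits.rank(1, lo_i), node.bits.rank(1, hi_i))

        visited += 1  # root
        node = self.root
        if node.is_leaf:
            if node.lo < m and r >= l:
                results.append((node.lo, (l, r)))
            return results, visited
        visited -= 1
        rec(node, l - 1, r)
        return results, visited

    def reconstruct(self) -> np.ndarray:
        return np.array([self.access(i) for i in range(1, self.n + 1)],
                        dtype=np.int64)

    def leaf_depths(self) -> dict[int, int]:
        """Depth of each value's leaf (root = depth 0)."""
        depths: dict[int, int] = {}

        def walk(node: _WTNode, depth: int) -> None:
            if node.is_leaf:
                depths[node.lo] = depth
                return
            walk(node.left, depth + 1)
            if node.right is not None:
                walk(node.right, depth + 1)

        walk(self.root, 0)
        return depths
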