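"""Suffix-array backend: construction, pattern search, document array, oracles.

This module plays the role of the compressed suffix array in the design:
``search(P)`` resolves a pattern to its lexicographic interval ``SA[l..r]``
and ``lookup(i)`` returns ``SA[i]``.  On top of it sit the document-array
view and the brute-force / classical document-listing oracles every other
engine is verified against.

The suffix array is built with prefix doubling (numpy ``lexsort`` rounds),
which is comfortably fast at the collection sizes this package targets;
correctness is defined solely by the sorted-suffix invariant.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .collection import Collection
from .succinct import RMQ

__all__ = [
    "build_suffix_array",
    "kasai_lcp",
    "SuffixArrayIndex",
    "build_index",
    "distinct_counts",
]


def build_suffix_array(T: bytes) -> np.ndarray:
    """Suffix array of ``T`` as 0-based start positions (prefix doubling)."""
    n = len(T)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    rank = np.frombuffer(T, dtype=np.uint8).astype(np.int64)
    sa = np.argsort(rank, kind="stable")
    # stable argsort of single symbols; refine ranks, then double
    tmp = np.empty(n, dtype=np.int64)
    tmp[sa] = np.cumsum(np.r_[0, np.diff(rank[sa]) != 0])
    rank = tmp
    k = 1
    while k < n and rank[sa[-1]] < n - 1:
        second = np.full(n, -1, dtype=np.int64)
        second[: n - k] = rank[k:]
        order = np.lexsort((second, rank))
        sa = order
        new_rank = np.empty(n, dtype=np.int64)
        prev = np.zeros(n - 1, dtype=bool)
        prev |= rank[sa[1:]] != rank[sa[:-1]]
        prev |= second[sa[1:]] != second[sa[:-1]]
        new_rank[sa] = np.cumsum(np.r_[0, prev])
        rank = new_rank
        k *= 2
    return sa.astype(np.int64)


def kasai_lcp(T: bytes, sa: np.ndarray) -> np.ndarray:
    """LCP array (0-based): ``lcp[i] = lcp(T[sa[i-1]..], T[sa[i]..])``, lcp[0]=0."""
    n = len(T)
    lcp = np.zeros(n, dtype=np.int64)
    if n == 0:
        return lcp
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    h = 0
    for i in range(n):
        r = rank[i]
        if r == 0:
            h = 0
            continue
        j = int(sa[r - 1])
        while i + h < n and j + h < n and T[i + h] == T[j + h]:
            h += 1
        lcp[r] = h
        if h > 0:
            h -= 1
    return lcp


class DocArrayView:
    """Access to ``DA[i] = rank_1(B, SA[i])``, materialized and on the fly."""

    def __init__(self, index: "SuffixArrayIndex"):
        self._index = index
        starts = np.array(
            [index.collection.doc_start(j) for j in range(1, index.collection.d + 1)],
            dtype=np.int64,
        )
        # materialized: document of each SA entry
        self.array = np.searchsorted(starts, index.sa_positions, side="right").astype(
            np.int64
        )

    def __getitem__(self, i: int) -> int:
        """Document id at SA position ``i`` (1-based)."""
        n = self._index.n
        if not 1 <= i <= n:
            raise IndexError(f"position {i} out of range [1..{n}]")
        return int(self.array[i - 1])

    def on_the_fly(self, i: int) -> int:
        return self._index.collection.doc_of_position(self._index.lookup(i))

    def __len__(self) -> int:
        return self._index.n


class SuffixArrayIndex:
    """Suffix array over the collection concatenation with search/lookup."""

    def __init__(self, collection: Collection):
        self.collection = collection
        self.T = collection.T
        self.n = collection.n
        self._sa0 = build_suffix_array(self.T)      # 0-based
        self.sa_positions = self._sa0 + 1            # 1-based SA values
        self._da: DocArrayView | None = None
        self._lcp: np.ndarray | None = None
        self._muthu_c: np.ndarray | None = None
        self._muthu_rmq: RMQ | None = None

    # -- basic access -------------------------------------------------------

    def lookup(self, i: int) -> int:
        """``SA[i]`` as a 1-based text position."""
        if not 1 <= i <= self.n:
            raise IndexError(f"SA index {i} out of range [1..{self.n}]")
        return int(self.sa_positions[i - 1])

    @property
    def sa(self) -> np.ndarray:
        """The full suffix array as 1-based positions."""
        return self.sa_positions

    def document_array(self) -> DocArrayView:
        if self._da is None:
            self._da = DocArrayView(self)
        return self._da

    def lcp(self) -> np.ndarray:
        """Global LCP array (0-based numpy, semantic positions 1..n)."""
        if self._lcp is None:
            self._lcp = kasai_lcp(self.T, self._sa0)
        return self._lcp

    # -- pattern search -----------------------------------------------------

    def search(self, P: bytes | str) -> tuple[int, int] | None:
        """Interval ``[l..r]`` of suffixes prefixed by ``P``, or None."""
        if isinstance(P, str):
            P = P.encode("utf-8")
        if len(P) == 0:
            raise ValueError("pattern must be non-empty")
        if 0 in P:
            raise ValueError("pattern must not contain the sentinel byte")
        T, sa, m = self.T, self._sa0, len(P)

        # leftmost suffix >= P
        lo, hi = 0, self.n
        while lo < hi:
            mid = (lo + hi) // 2
            if T[sa[mid]: sa[mid] + m] < P:
                lo = mid + 1
            else:
                hi = mid
        left = lo
        # leftmost suffix with prefix > P
        lo, hi = left, self.n
        while lo < hi:
            mid = (lo + hi) // 2
            if T[sa[mid]: sa[mid] + m] <= P:
                lo = mid + 1
            else:
                hi = mid
        right = lo
        if left >= right:
            return None
        return (left + 1, right)

    # -- oracles --------------------------------------------------------------

    def brute_list(self, l: int, r: int) -> list[int]:
        """Sorted distinct document ids in ``DA[l..r]`` (empty if l > r)."""
        if l > r:
            return []
        self._check_interval(l, r)
        da = self.document_array().array
        return sorted(set(int(x) for x in da[l - 1: r]))

    def brute_topk(self, l: int, r: int, k: int) -> list[tuple[int, int]]:
        """Top ``k`` (doc, tf) pairs over ``DA[l..r]``; ties by increasing doc id."""
        if k < 1:
            raise ValueError("k must be >= 1")
        if l > r:
            return []
        self._check_interval(l, r)
        da = self.document_array().array
        counts = Counter(int(x) for x in da[l - 1: r])
        ranked = sorted(counts.items(), key=lambda item: (-item[1], item[0]))
        return ranked[:k]

    def muthu_c(self) -> np.ndarray:
        """Classical C array: C[i] = largest h < i with DA[h] = DA[i], else 0."""
        if self._muthu_c is None:
            da = self.document_array().array
            last = np.zeros(self.collection.d + 1, dtype=np.int64)
            C = np.zeros(self.n, dtype=np.int64)
            for i in range(self.n):
                doc = da[i]
                C[i] = last[doc]
                last[doc] = i + 1
            self._muthu_c = C
        return self._muthu_c

    def muthu_list(self, l: int, r: int) -> list[int]:
        """Classical RMQ-over-C document listing (oracle for the engines).

        Recurses on the leftmost minimum of ``C[l..r]``, left before right,
        reporting ``DA[k]`` while ``C[k] < l`` (the original ``l``).
        """
        if l > r:
            return []
        self._check_interval(l, r)
        C = self.muthu_c()
        if self._muthu_rmq is None:
            self._muthu_rmq = RMQ(C)
        da = self.document_array().array
        out: list[int] = []

        def rec(a: int, b: int) -> None:  # left range explored first
            if a > b:
                return
            kpos = self._muthu_rmq.query(a, b)
            if C[kpos - 1] >= l:
                return
            out.append(int(da[kpos - 1]))
            rec(a, kpos - 1)
            rec(kpos + 1, b)

        rec(l, r)
        return out

    def _check_interval(self, l: int, r: int) -> None:
        if not (1 <= l <= r <= self.n):
            raise IndexError(f"invalid interval [{l}..{r}] over [1..{self.n}]")


def build_index(collection: Collection) -> SuffixArrayIndex:
    """Build the suffix-array index for a collection."""
    return SuffixArrayIndex(collection)


def distinct_counts(da: np.ndarray, queries: list[tuple[int, int]]) -> np.ndarray:
    """Number of distinct values in ``da[l..r]`` for many 1-based queries.

    Offline sweep with a Fenwick tree over last occurrences: O((n+q) log n).
    Used to compute per-node document counts without materializing sets.
    """
    n = da.size
    q = len(queries)
    out = np.zeros(q, dtype=np.int64)
    if q == 0:
        return out
    order = sorted(range(q), key=lambda t: queries[t][1])
    fen = np.zeros(n + 1, dtype=np.int64)

    def fen_add(pos: int, delta: int) -> None:
        while pos <= n:
            fen[pos] += delta
            pos += pos & (-pos)

    def fen_sum(pos: int) -> int:
        s = 0
        while pos > 0:
            s += fen[pos]
            pos -= pos & (-pos)
        return int(s)

    last: dict[int, int] = {}
    r_done = 0
    for t in order:
        l, r = queries[t]
        while r_done < r:
            r_done += 1
            doc = int(da[r_done - 1])
            prev = last.get(doc)
            if prev is not None:
                fen_add(prev, -1)
            fen_add(r_done, 1)
            last[doc] = r_done
        out[t] = fen_sum(r) - fen_sum(l - 1)
    return out
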