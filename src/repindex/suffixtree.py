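"""LCP-interval tree: the explicit suffix-tree topology over the suffix array.

Both the sampled-document-list index and the counting structure need the
internal nodes of the suffix tree of ``T``.  The tree is recovered from the
global LCP array: an internal node is an interval ``SA[lo..hi]`` whose inner
boundaries all have LCP at least the node's string depth, with equality at
the child splits.  Leaves are individual suffixes (all suffixes of ``T`` are
distinct because every document ends with the sentinel).

Construction is an iterative divide-and-conquer on boundary minima; memory
is O(n) words, which is the intended operating point of this package
(indexes are built in RAM at desk scale).
"""

from __future__ import annotations

import numpy as np

from .core import SuffixArrayIndex

__all__ = ["SuffixTree", "build_suffix_tree"]

LEAF = 0
NODE = 1


class SuffixTree:
    """Internal nodes of the suffix tree as SA intervals.

    ``children[v]`` lists ``(kind, x)`` pairs in left-to-right order where
    ``kind`` is ``LEAF`` (x = SA position) or ``NODE`` (x = node id).
    Node 0 is the root and covers ``[1..n]``.
    """

    def __init__(self, lo: list[int], hi: list[int],
                 children: list[list[tuple[int, int]]], depth: list[int], n: int):
        self.lo = np.asarray(lo, dtype=np.int64)
        self.hi = np.asarray(hi, dtype=np.int64)
        self.children = children
        self.depth = np.asarray(depth, dtype=np.int64)
        self.n = n
        self.parent = np.full(len(lo), -1, dtype=np.int64)
        for v, childs in enumerate(children):
            for kind, x in childs:
                if kind == NODE:
                    self.parent[x] = v

    def __len__(self) -> int:
        return len(self.lo)

    def interval(self, v: int) -> tuple[int, int]:
        return int(self.lo[v]), int(self.hi[v])

    def size(self, v: int) -> int:
        return int(self.hi[v] - self.lo[v] + 1)

    def node_intervals(self) -> list[tuple[int, int]]:
        """All internal-node intervals (the loci with more than one suffix)."""
        return [(int(a), int(b)) for a, b in zip(self.lo, self.hi)]

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack: list[tuple[int, bool]] = [(0, False)]
        while stack:
            v, expanded = stack.pop()
            if expanded:
                order.append(v)
                continue
            stack.append((v, True))
            for kind, x in self.children[v]:
                if kind == NODE:
                    stack.append((x, False))
        return order


def build_suffix_tree(index: SuffixArrayIndex) -> SuffixTree:
    """Build the LCP-interval tree of the index's suffix array."""
    n = index.n
    if n == 1:
        return SuffixTree([1], [1], [[(LEAF, 1)]], [0], 1)
    lcp = index.lcp()
    lo_arr: list[int] = []
    hi_arr: list[int] = []
    depth_arr: list[int] = []
    children_arr: list[list[tuple[int, int]]] = []

    def new_node(lo: int, hi: int, depth: int) -> int:
        lo_arr.append(lo)
        hi_arr.append(hi)
        depth_arr.append(depth)
        children_arr.append([])
        return len(lo_arr) - 1

    root = new_node(1, n, 0)
    stack = [root]
    while stack:
        v = stack.pop()
        lo, hi = lo_arr[v], hi_arr[v]
        # inner boundaries lo+1..hi live at lcp indices lo..hi-1 (0-based)
        seg = lcp[lo: hi]
        m = int(seg.min())
        depth_arr[v] = m
        splits = (lo + 1 + np.flatnonzero(seg == m)).tolist()
        children = children_arr[v]
        prev = lo
        for s in splits + [hi + 1]:
            a, b = prev, s - 1
            if a == b:
                children.append((LEAF, a))
            else:
                cid = new_node(a, b, 0)
                children.append((NODE, cid))
                stack.append(cid)
            prev = s
    return SuffixTree(lo_arr, hi_arr, children_arr, depth_arr, n)
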