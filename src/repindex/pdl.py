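"""Precomputed document lists over a sampled suffix tree (PDL).

The suffix tree is sampled with a block size ``b`` and a storing factor
``beta``: nodes whose suffix-array interval fits in a block of ``b`` cells
become the leaves of the sampled tree (their intervals partition
``[1..n]``), and an internal node is kept only if the stored lists of its
sampled children total more than ``beta`` times its own list (otherwise
reconstructing the node by a union is cheap enough and the node is pruned).
With ``beta`` unset, every suffix-tree node above the leaf blocks keeps its
list, which is the configuration used for incremental top-k extraction.

Stored lists are grammar-compressed with a Re-Pair style compressor whose
rules are flattened to terminal-only right-hand sides of length at least
two, so a set decompresses in time linear in its size.  In listing mode the
sets are canonically sorted before compression to expose shared subsets; in
top-k mode the order (decreasing term frequency, ties by increasing document
id) is preserved and the frequencies are kept run-length encoded with
differential run heads.

Queries not aligned to block boundaries fall back to scanning the short
partial blocks through the suffix array, exactly like the brute-force
baseline.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .core import SuffixArrayIndex
from .succinct import Bitvector
from .suffixtree import LEAF, NODE, SuffixTree, build_suffix_tree

__all__ = ["PDLIndex", "build_pdl", "CompressedSets", "compress_sets",
           "decompress_set", "RLEFrequencies"]


# ---------------------------------------------------------------------------
# grammar compression of the stored sets
# ---------------------------------------------------------------------------

@dataclass
class CompressedSets:
    """Reduced sets and flattened grammar rules.

    ``A`` concatenates the reduced set encodings (document ids ``1..d`` and
    rule ids ``d+1..d+n_rules``); ``B_A`` marks the first cell of each set.
    ``G`` concatenates the terminal-only right-hand sides; ``B_G`` marks the
    first cell of each rule.
    """

    d: int
    A: np.ndarray
    B_A: Bitvector
    G: np.ndarray
    B_G: Bitvector
    n_sets: int
    n_rules: int

    def rule_expansion(self, rule_id: int) -> np.ndarray:
        i = rule_id - self.d
        start = self.B_G.select(1, i)
        end = self.B_G.select(1, i + 1) - 1 if i < self.n_rules else len(self.G)
        return self.G[start - 1: end]

    def decompress(self, i: int) -> list[int]:
        """Expand set ``i`` (1-based), preserving the stored order."""
        if not 1 <= i <= self.n_sets:
            raise IndexError(f"set index {i} out of range [1..{self.n_sets}]")
        start = self.B_A.select(1, i)
        end = self.B_A.select(1, i + 1) - 1 if i < self.n_sets else len(self.A)
        out: list[int] = []
        for sym in self.A[start - 1: end]:
            sym = int(sym)
            if sym <= self.d:
                out.append(sym)
            else:
                out.extend(int(x) for x in self.rule_expansion(sym))
        return out


def compress_sets(sets: list[list[int]], d: int) -> CompressedSets:
    """Re-Pair style compression of the concatenated set encodings.

    Repeatedly replaces the most frequent adjacent symbol pair (ties broken
    by the lexicographically smallest pair, for deterministic builds) with a
    fresh nonterminal, never pairing across set boundaries, until no pair
    repeats.  Nonterminals are then flattened so every stored rule expands
    to at least two terminals.
    """
    seqs = [list(s) for s in sets]
    pair_rhs: dict[int, tuple[int, int]] = {}
    next_id = d + 1
    while True:
        counts: Counter[tuple[int, int]] = Counter()
        for seq in seqs:
            for i in range(len(seq) - 1):
                counts[(seq[i], seq[i + 1])] += 1
        if not counts:
            break
        best_count = max(counts.values())
        if best_count < 2:
            break
        best = min(p for p, c in counts.items() if c == best_count)
        rule = next_id
        next_id += 1
        pair_rhs[rule] = best
        for si, seq in enumerate(seqs):
            out: list[int] = []
            i = 0
            while i < len(seq):
                if i + 1 < len(seq) and (seq[i], seq[i + 1]) == best:
                    out.append(rule)
                    i += 2
                else:
                    out.append(seq[i])
                    i += 1
            seqs[si] = out

    def expand(sym: int, memo: dict[int, list[int]]) -> list[int]:
        if sym <= d:
            return [sym]
        if sym not in memo:
            a, b = pair_rhs[sym]
            memo[sym] = expand(a, memo) + expand(b, memo)
        return memo[sym]

    memo: dict[int, list[int]] = {}
    used = sorted({sym for seq in seqs for sym in seq if sym > d})
    remap = {old: d + 1 + i for i, old in enumerate(used)}
    G: list[int] = []
    B_G_ones: list[int] = []
    for old in used:
        B_G_ones.append(len(G) + 1)
        G.extend(expand(old, memo))
    A: list[int] = []
    B_A_ones: list[int] = []
    for seq in seqs:
        B_A_ones.append(len(A) + 1)
        A.extend(remap.get(sym, sym) for sym in seq)
    return CompressedSets(
        d=d,
        A=np.asarray(A, dtype=np.int64),
        B_A=Bitvector.from_ones(B_A_ones, max(len(A), 1) if A else 0),
        G=np.asarray(G, dtype=np.int64),
        B_G=Bitvector.from_ones(B_G_ones, len(G)) if G else Bitvector([], "plain"),
        n_sets=len(seqs),
        n_rules=len(used),
    )


def decompress_set(cs: CompressedSets, i: int) -> list[int]:
    return cs.decompress(i)


# ---------------------------------------------------------------------------
# run-length encoded frequencies
# ---------------------------------------------------------------------------

@dataclass
class RLEFrequencies:
    """Non-increasing term frequencies, run-length + differentially encoded."""

    first_head: int
    head_drops: np.ndarray   # head[i] = head[i-1] - drop[i-1]
    run_lengths: np.ndarray

    @classmethod
    def encode(cls, freqs: list[int]) -> "RLEFrequencies":
        if not freqs:
            return cls(0, np.zeros(0, np.int64), np.zeros(0, np.int64))
        arr = np.asarray(freqs, dtype=np.int64)
        if np.any(np.diff(arr) > 0):
            raise ValueError("frequencies must be non-increasing")
        starts = np.r_[0, np.flatnonzero(np.diff(arr)) + 1]
        heads = arr[starts]
        lengths = np.diff(np.r_[starts, arr.size])
        return cls(int(heads[0]), -np.diff(heads), lengths)

    def decode(self) -> np.ndarray:
        if self.run_lengths.size == 0:
            return np.zeros(0, dtype=np.int64)
        heads = self.first_head - np.r_[0, np.cumsum(self.head_drops)]
        return np.repeat(heads, self.run_lengths)


# ---------------------------------------------------------------------------
# the index
# ---------------------------------------------------------------------------

@dataclass
class PDLIndex:
    """Sampled suffix tree with grammar-compressed document lists."""

    mode: str                      # "list" | "topk"
    b: int
    beta: float | None
    n: int
    d: int
    L: int                         # number of sampled leaves
    I: int                         # number of kept internal nodes
    B_L: Bitvector                 # first SA cell of each leaf block
    B_F: Bitvector                 # marks sampled-tree first children
    F: np.ndarray                  # first child -> parent internal rank
    N: np.ndarray                  # internal node -> following leaf index
    first_leaf: np.ndarray         # per node id (1..L+I): leftmost leaf index
    last_leaf: np.ndarray          # per node id: rightmost leaf index
    intervals: np.ndarray          # per node id: (lo, hi) SA interval
    sets: CompressedSets
    freqs: list[RLEFrequencies] | None
    index: SuffixArrayIndex = field(repr=False)

    # -- geometry -----------------------------------------------------------

    def leaf_block(self, leaf: int) -> tuple[int, int]:
        lo = self.B_L.select(1, leaf)
        hi = self.B_L.select(1, leaf + 1) - 1 if leaf < self.L else self.n
        return lo, hi

    def node_interval(self, node_id: int) -> tuple[int, int]:
        lo, hi = self.intervals[node_id - 1]
        return int(lo), int(hi)

    def stored_node_for(self, l: int, r: int) -> int | None:
        """Sampled node id whose interval is exactly [l..r], if any."""
        return self._interval_map.get((l, r))

    def __post_init__(self) -> None:
        self._interval_map = {
            (int(lo), int(hi)): i + 1 for i, (lo, hi) in enumerate(self.intervals)
        }

    # -- the sampled-tree walk (Fig.-style decompress) ------------------------

    def _covering_nodes(self, ln: int, rn: int) -> list[int]:
        """Maximal sampled nodes covering leaves ``ln..rn``, left to right.

        From each current leaf we climb through first-child links while the
        parent's subtree still ends within ``rn`` (it starts at the current
        leaf by the first-child property), emit the highest such node, and
        jump to the leaf following its subtree.
        """
        out: list[int] = []
        i = ln
        while i <= rn:
            cur = i
            while self.B_F[cur] == 1:
                p = self.L + int(self.F[self.B_F.rank(1, cur) - 1])
                if int(self.last_leaf[p - 1]) <= rn:
                    cur = p
                else:
                    break
            out.append(cur)
            i = int(self.last_leaf[cur - 1]) + 1
        return out

    def _decompress_node(self, node_id: int) -> list[int]:
        return self.sets.decompress(node_id)

    def _node_freqs(self, node_id: int) -> np.ndarray:
        assert self.freqs is not None
        return self.freqs[node_id - 1].decode()

    # -- queries --------------------------------------------------------------

    def _block_split(self, l: int, r: int):
        """Split [l..r] into (left edge, full leaf range, right edge)."""
        bl = self.B_L.rank(1, l)
        ln = bl if self.B_L.select(1, bl) == l else bl + 1
        br = self.B_L.rank(1, r)
        br_end = self.B_L.select(1, br + 1) - 1 if br < self.L else self.n
        rn = br if br_end == r else br - 1
        if ln > rn:
            return (l, r), None, None
        left_edge = (l, self.B_L.select(1, ln) - 1) if self.B_L.select(1, ln) > l else None
        rn_end = self.B_L.select(1, rn + 1) - 1 if rn < self.L else self.n
        right_edge = (rn_end + 1, r) if rn_end < r else None
        return left_edge, (ln, rn), right_edge

    def list(self, l: int, r: int) -> list[int]:
        """Sorted distinct documents in ``DA[l..r]``."""
        if l > r:
            return []
        if not (1 <= l <= r <= self.n):
            raise IndexError(f"invalid interval [{l}..{r}]")
        left_edge, leaf_range, right_edge = self._block_split(l, r)
        da = self.index.document_array().array
        res: set[int] = set()
        if leaf_range is None:
            return self.index.brute_list(l, r)
        for node_id in self._covering_nodes(*leaf_range):
            res.update(self._decompress_node(node_id))
        for edge in (left_edge, right_edge):
            if edge is not None:
                res.update(int(x) for x in da[edge[0] - 1: edge[1]])
        return sorted(res)

    def _merged_counts(self, l: int, r: int) -> Counter:
        left_edge, leaf_range, right_edge = self._block_split(l, r)
        da = self.index.document_array().array
        counts: Counter[int] = Counter()
        if leaf_range is None:
            counts.update(int(x) for x in da[l - 1: r])
            return counts
        for node_id in self._covering_nodes(*leaf_range):
            docs = self._decompress_node(node_id)
            tfs = self._node_freqs(node_id)
            for doc, tf in zip(docs, tfs):
                counts[doc] += int(tf)
        for edge in (left_edge, right_edge):
            if edge is not None:
                counts.update(int(x) for x in da[edge[0] - 1: edge[1]])
        return counts

    def ranked_documents(self, l: int, r: int) -> list[tuple[int, int]]:
        """All (doc, tf) pairs in [l..r], by decreasing tf then doc id."""
        if self.mode != "topk":
            raise ValueError("index was built in listing mode; no frequencies stored")
        if l > r:
            return []
        if not (1 <= l <= r <= self.n):
            raise IndexError(f"invalid interval [{l}..{r}]")
        node_id = self.stored_node_for(l, r)
        if node_id is not None:
            docs = self._decompress_node(node_id)
            tfs = self._node_freqs(node_id)
            return [(int(doc), int(tf)) for doc, tf in zip(docs, tfs)]
        counts = self._merged_counts(l, r)
        return sorted(counts.items(), key=lambda item: (-item[1], item[0]))

    def topk(self, l: int, r: int, k: int) -> list[tuple[int, int]]:
        """Top ``k`` (doc, tf) pairs; ties broken by increasing doc id."""
        if k < 1:
            raise ValueError("k must be >= 1")
        return self.ranked_documents(l, r)[:k]

    def topk_iter(self, l: int, r: int):
        """Incremental top-k: yield (doc, tf) in non-increasing tf order."""
        yield from self.ranked_documents(l, r)

    def metadata(self) -> dict:
        return {
            "mode": self.mode, "b": self.b, "beta": self.beta,
            "leaves": self.L, "internal": self.I,
            "set_symbols": int(len(self.sets.A)),
            "grammar_symbols": int(len(self.sets.G)),
            "rules": self.sets.n_rules,
        }


def build_pdl(index: SuffixArrayIndex, b: int = 256,
              beta: float | None = 16, mode: str = "list",
              tree: SuffixTree | None = None) -> PDLIndex:
    """Build a PDL index.

    ``beta=None`` stores the lists of *all* suffix-tree nodes above the leaf
    blocks (the configuration used for incremental top-k); ``beta=inf``
    prunes every internal node.  In ``topk`` mode lists are ordered by
    decreasing term frequency and frequencies are stored.
    """
    if b < 1:
        raise ValueError("block size b must be >= 1")
    if beta is not None and beta < 1:
        raise ValueError("storing factor beta must be >= 1 (or None)")
    if mode not in ("list", "topk"):
        raise ValueError(f"unknown PDL mode {mode!r}")
    if tree is None:
        tree = build_suffix_tree(index)
    da = index.document_array().array
    n = index.n

    # --- sampled leaves: maximal nodes with interval size <= b ---------------
    leaf_intervals: list[tuple[int, int]] = []

    def emit_leaves(v: int) -> None:
        stack = [v]
        while stack:
            u = stack.pop()
            if tree.size(u) <= b:
                leaf_intervals.append(tree.interval(u))
                continue
            for kind, x in reversed(tree.children[u]):
                if kind == LEAF:
                    leaf_intervals.append((x, x))
                else:
                    stack.append(x)

    emit_leaves(0)
    leaf_intervals.sort()
    L = len(leaf_intervals)

    def distinct(lo: int, hi: int) -> np.ndarray:
        return np.unique(da[lo - 1: hi])

    # --- candidate internal nodes (size > b) and bottom-up pruning -----------
    candidates = [v for v in range(len(tree)) if tree.size(v) > b]
    cand_set = set(candidates)
    leaf_by_lo = {lo: i + 1 for i, (lo, hi) in enumerate(leaf_intervals)}

    # representation of a subtree after pruning: list of sampled entries,
    # each ('leaf', leaf_index) or ('cand', tree node id)
    rep: dict[int, list[tuple[str, int]]] = {}
    kept: dict[int, list[tuple[str, int]]] = {}   # kept candidate -> children
    set_size: dict[tuple[str, int], int] = {}

    def child_rep(kind: int, x: int) -> list[tuple[str, int]]:
        if kind == LEAF:
            return [("leaf", leaf_by_lo[x])]
        if x in cand_set:
            return rep[x]
        return [("leaf", leaf_by_lo[int(tree.lo[x])])]

    for v in tree.postorder():
        if v not in cand_set:
            continue
        children: list[tuple[str, int]] = []
        for kind, x in tree.children[v]:
            children.extend(child_rep(kind, x))
        lo, hi = tree.interval(v)
        own_size = int(distinct(lo, hi).size)
        total = sum(
            set_size[c] if c[0] == "cand" else
            int(distinct(*leaf_intervals[c[1] - 1]).size)
            for c in children
        )
        if beta is not None and total <= beta * own_size:
            rep[v] = children              # pruned: splice children upward
        else:
            kept[v] = children
            rep[v] = [("cand", v)]
            set_size[("cand", v)] = own_size

    kept_ids = sorted(kept, key=lambda v: (int(tree.lo[v]), -int(tree.hi[v])))
    internal_rank = {v: i + 1 for i, v in enumerate(kept_ids)}
    I = len(kept_ids)

    def node_number(entry: tuple[str, int]) -> int:
        return entry[1] if entry[0] == "leaf" else L + internal_rank[entry[1]]

    # --- navigation bitvectors -----------------------------------------------
    B_L = Bitvector.from_ones([lo for lo, _ in leaf_intervals], n)
    bf_bits = np.zeros(L + I, dtype=np.uint8)
    first_child_parent: dict[int, int] = {}
    for v, children in kept.items():
        first = node_number(children[0])
        bf_bits[first - 1] = 1
        first_child_parent[first] = internal_rank[v]
    B_F = Bitvector(bf_bits)
    F = np.zeros(int(bf_bits.sum()), dtype=np.int64)
    for first, parent_rank in first_child_parent.items():
        F[B_F.rank(1, first) - 1] = parent_rank

    leaf_los = np.array([lo for lo, _ in leaf_intervals], dtype=np.int64)
    intervals = np.zeros((L + I, 2), dtype=np.int64)
    for i, (lo, hi) in enumerate(leaf_intervals):
        intervals[i] = (lo, hi)
    for v in kept_ids:
        intervals[L + internal_rank[v] - 1] = tree.interval(v)
    first_leaf = np.searchsorted(leaf_los, intervals[:, 0], side="left") + 1
    last_leaf = np.searchsorted(leaf_los, intervals[:, 1], side="right")
    N = last_leaf[L:] + 1

    # --- stored sets ----------------------------------------------------------
    raw_sets: list[list[int]] = []
    freq_lists: list[RLEFrequencies] | None = [] if mode == "topk" else None
    for lo, hi in intervals:
        if mode == "list":
            raw_sets.append([int(x) for x in np.unique(da[lo - 1: hi])])
        else:
            counts = Counter(int(x) for x in da[lo - 1: hi])
            ranked = sorted(counts.items(), key=lambda item: (-item[1], item[0]))
            raw_sets.append([doc for doc, _ in ranked])
            freq_lists.append(RLEFrequencies.encode([tf for _, tf in ranked]))
    cs = compress_sets(raw_sets, index.collection.d)

    return PDLIndex(
        mode=mode, b=b, beta=beta, n=n, d=index.collection.d,
        L=L, I=I, B_L=B_L, B_F=B_F, F=F, N=np.asarray(N, dtype=np.int64),
        first_leaf=first_leaf.astype(np.int64), last_leaf=last_leaf.astype(np.int64),
        intervals=intervals, sets=cs, freqs=freq_lists, index=index,
    )
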