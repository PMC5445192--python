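"""Interleaved LCP array: run-length structure, document listing and counting.

The interleaved LCP array merges the per-document LCP arrays in global
suffix-array order: if ``SA[i]`` belongs to document ``j`` and is the r-th
suffix of that document in ``SA``, then ``ILCP[i]`` is the r-th entry of
document ``j``'s own LCP array.  Inside the interval of a pattern of length
``m``, the entries strictly below ``m`` sit exactly at the leftmost
occurrence of each distinct document, so listing and counting reduce to
finding small values in a range.

On repetitive collections ILCP consists of few runs (rho), so the structure
stores the run heads ``VILCP`` in a skewed wavelet tree, a bitvector ``L``
marking run starts, and a second bitvector ``L'`` holding the run lengths
grouped by value and aligned with the wavelet-tree leaves.
"""

from __future__ import annotations

import numpy as np

from .collection import Collection
from .core import SuffixArrayIndex, build_suffix_array, kasai_lcp
from .succinct import RMQ, Bitvector, WaveletTree

__all__ = ["build_ilcp", "encode_runs", "decode_runs", "ILCPStructure", "document_lcp"]


def document_lcp(text_with_sentinel: bytes) -> np.ndarray:
    """LCP array of a single document (sentinel included, LCP[1] = 0)."""
    sa = build_suffix_array(text_with_sentinel)
    return kasai_lcp(text_with_sentinel, sa)


def build_ilcp(collection: Collection, index: SuffixArrayIndex) -> np.ndarray:
    """Interleaved LCP array of the collection (0-based numpy array).

    Per-document LCP arrays are computed with Kasai's scan and assigned in
    global suffix order: the per-document suffix order inside the global SA
    equals the document's own suffix order because each document ends with
    the smallest symbol.
    """
    da = index.document_array().array  # 0-based array of doc ids
    ilcp = np.zeros(index.n, dtype=np.int64)
    for j in range(1, collection.d + 1):
        lcp_j = document_lcp(collection.document_text(j, with_sentinel=True))
        positions = np.flatnonzero(da == j)
        ilcp[positions] = lcp_j
    return ilcp


def encode_runs(ilcp: np.ndarray) -> "ILCPStructure":
    """Run-length encode an ILCP array into the queryable structure."""
    return ILCPStructure(np.asarray(ilcp, dtype=np.int64))


def decode_runs(structure: "ILCPStructure") -> np.ndarray:
    """Expand (VILCP, L) back to the full ILCP array."""
    return np.repeat(structure.vilcp, structure.run_lengths)


class ILCPStructure:
    """Run-length encoded ILCP with listing and counting support.

    Attributes
    ----------
    L : Bitvector
        Length ``n``; 1 at the first position of each of the ``rho`` runs.
    vilcp : numpy array
        Run-head values, also held in a skewed wavelet tree.
    Lprime : Bitvector
        Length ``n`` with ``rho`` 1s: run lengths written unarily
        (1 followed by length-1 zeros) grouped by value in increasing value
        order, runs of equal value ordered by their start in ILCP, each
        group aligned with its wavelet-tree leaf.
    lam : int
        Maximum ILCP value.
    """

    def __init__(self, ilcp: np.ndarray):
        n = ilcp.size
        if n == 0:
            raise ValueError("empty ILCP array")
        self.n = n
        run_start = np.r_[True, ilcp[1:] != ilcp[:-1]]
        starts = np.flatnonzero(run_start)  # 0-based start of each run
        self.rho = starts.size
        self.vilcp = ilcp[starts]
        self.run_lengths = np.diff(np.r_[starts, n])
        self.lam = int(ilcp.max())
        self.L = Bitvector.from_ones(starts + 1, n, encoding="sparse")
        self.wavelet = WaveletTree(self.vilcp, sigma=self.lam + 1, shape="skewed")
        self._rmq = RMQ(self.vilcp)

        # group runs by value (increasing), within a value by start position;
        # absolute run order already is start-position order.
        order = np.argsort(self.vilcp, kind="stable")
        grouped_lengths = self.run_lengths[order]
        heads = np.r_[0, np.cumsum(grouped_lengths)[:-1]] + 1
        self.Lprime = Bitvector.from_ones(heads, n, encoding="sparse")
        # first grouped-run index (0-based) of each value's group
        counts = np.bincount(self.vilcp, minlength=self.lam + 1)
        self._group_start = np.r_[0, np.cumsum(counts)[:-1]]

    # -- helpers ------------------------------------------------------------

    def run_of(self, i: int) -> int:
        """Run index (1-based) containing ILCP position ``i``."""
        return self.L.rank(1, i)

    def run_span(self, i_run: int) -> tuple[int, int]:
        """Positions [start..end] of run ``i_run`` (1-based)."""
        start = self.L.select(1, i_run)
        end = self.L.select(1, i_run + 1) - 1 if i_run < self.rho else self.n
        return start, end

    def _grouped_prefix_length(self, t: int) -> int:
        """Total length of the first ``t`` runs in grouped (by value) order."""
        if t <= 0:
            return 0
        if t >= self.rho:
            return self.n
        return self.Lprime.select(1, t + 1) - 1

    # -- queries ------------------------------------------------------------

    def list(self, index: SuffixArrayIndex, l: int, r: int,
             m: int | None = None) -> list[int]:
        """Distinct documents in ``DA[l..r]``, for a pattern interval.

        Runs the leftmost-minimum RMQ recursion over the run heads,
        expanding each minimal run clipped to ``[l..r]`` and marking
        reported documents; the recursion of a subrange stops as soon as an
        already-marked document is seen (its whole run has ILCP >= m).  The
        pattern length ``m`` is not consulted: for intervals produced by a
        pattern search the marking rule alone yields exactly the distinct
        documents.  On arbitrary intervals the result is unspecified.
        """
        if l > r:
            return []
        if not (1 <= l <= r <= self.n):
            raise IndexError(f"invalid interval [{l}..{r}]")
        lp, rp = self.run_of(l), self.run_of(r)
        da = index.document_array().array
        seen = np.zeros(index.collection.d + 1, dtype=bool)
        out: list[int] = []

        def rec(a: int, b: int) -> None:
            if a > b:
                return
            i_run = self._rmq.query(a, b)
            start, end = self.run_span(i_run)
            for k in range(max(l, start), min(r, end) + 1):
                doc = int(da[k - 1])
                if seen[doc]:
                    return
                seen[doc] = True
                out.append(doc)
            rec(a, i_run - 1)
            rec(i_run + 1, b)

        rec(lp, rp)
        return out

    def count(self, l: int, r: int, m: int) -> int:
        """Number of distinct documents in ``DA[l..r]`` for a length-``m`` pattern.

        Counts positions of ``ILCP[l..r]`` with value below ``m`` by walking
        the skewed wavelet tree into the leaves for values ``0..m-1`` and
        summing the spanned run lengths through ``L'``; the first and last
        run are corrected for partial overlap with ``[l..r]``.
        """
        if m < 1:
            raise ValueError("pattern length m must be >= 1")
        if l > r:
            return 0
        if not (1 <= l <= r <= self.n):
            raise IndexError(f"invalid interval [{l}..{r}]")
        if l == r:
            return 1   # a single suffix is one document
        lp, rp = self.run_of(l), self.run_of(r)
        leaves, _ = self.wavelet.count_below(lp, rp, m)
        total = 0
        for value, (a, b) in leaves:
            g = int(self._group_start[value])
            total += (self._grouped_prefix_length(g + b)
                      - self._grouped_prefix_length(g + a - 1))
        # boundary corrections: clip the first and last run to [l..r]
        if int(self.vilcp[lp - 1]) < m:
            total -= l - self.run_span(lp)[0]
        if int(self.vilcp[rp - 1]) < m:
            total -= self.run_span(rp)[1] - r
        return int(total)
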