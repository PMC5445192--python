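"""Ranked multi-term queries (tf-idf) over incremental top-k lists.

A query is a bag of patterns scored with

    w(D, Q) = sum_i f(tf(D, q_i)) * g(df(q_i)),   f(tf) = tf,
    g(df) = lg(d / max(df, 1)),

where ``tf`` is the occurrence count of the term in document ``D`` and
``df`` its document frequency, obtained from the counting structure at the
term's locus rather than by decompressing lists.  The per-term lists sorted
by decreasing frequency act as abstract inverted lists: the algorithm
repeatedly extracts k' = 2k, 4k, ... more entries per term, maintains lower
and upper score bounds per document (an unseen term contributes the
frequency of the next unextracted entry to the upper bound), and stops when
the top-k set can no longer change.  Ranked-AND restricts candidates to
documents matching every term; ranked-OR may stop early, in which case the
returned identifier set is exact but reported scores can still be partial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .collection import Collection
from .core import SuffixArrayIndex
from .pdl import PDLIndex
from .sada import CountingStructure

__all__ = ["Query", "ScoredDocument", "tfidf_weight", "ranked_query",
           "exhaustive_ranked"]


def tfidf_weight(tf: int, df: int, d: int) -> float:
    """Standard tf-idf contribution of one term: ``tf * lg(d / max(df, 1))``."""
    if tf < 0 or df < 0 or d < 1:
        raise ValueError("tf and df must be >= 0 and d >= 1")
    return tf * math.log2(d / max(df, 1))


@dataclass(frozen=True)
class Query:
    terms: tuple[str, ...]
    mode: str = "or"          # "and" | "or"
    k: int = 10

    def __post_init__(self) -> None:
        if len(self.terms) < 1:
            raise ValueError("query needs at least one term")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.mode not in ("and", "or"):
            raise ValueError(f"unknown query mode {self.mode!r}")


@dataclass
class ScoredDocument:
    doc: int
    score: float
    tf: dict[str, int] = field(default_factory=dict)
    exact: bool = True        # False if an early stop left the score partial


def ranked_query(index: SuffixArrayIndex, pdl: PDLIndex,
                 counter: CountingStructure, query: Query,
                 early_stop: bool = True) -> list[ScoredDocument]:
    """Answer a ranked-AND / ranked-OR query; see the module docstring.

    With ``early_stop=False`` the per-term lists are always exhausted and
    the reported scores are exact (used to verify the early-stopping path).
    """
    d = index.collection.d
    terms = query.terms
    m = len(terms)

    lists: list[list[tuple[int, int]]] = []
    weights: list[float] = []
    members: list[dict[int, int]] = []     # doc -> tf, the decompressed list
    for q in terms:
        interval = index.search(q)
        if interval is None:
            if query.mode == "and":
                return []
            lists.append([])
            weights.append(0.0)
            members.append({})
            continue
        l, r = interval
        df = counter.count(l, r)
        weights.append(math.log2(d / max(df, 1)))
        ranked = pdl.ranked_documents(l, r)
        lists.append(ranked)
        members.append(dict(ranked))

    pos = [0] * m                          # extracted prefix length per term
    extracted: list[dict[int, int]] = [dict() for _ in range(m)]
    kp = 2 * query.k
    while True:
        for i in range(m):
            take = min(len(lists[i]), pos[i] + kp)
            for doc, tf in lists[i][pos[i]: take]:
                extracted[i][doc] = tf
            pos[i] = take
        next_tf = [lists[i][pos[i]][1] if pos[i] < len(lists[i]) else 0
                   for i in range(m)]
        exhausted = all(pos[i] == len(lists[i]) for i in range(m))

        candidates = set()
        for i in range(m):
            candidates.update(extracted[i])
        if query.mode == "and":
            candidates = {D for D in candidates
                          if all(D in members[i] for i in range(m))}

        lower: dict[int, float] = {}
        upper: dict[int, float] = {}
        for D in candidates:
            lo = hi = 0.0
            for i in range(m):
                if D in extracted[i]:
                    contrib = extracted[i][D] * weights[i]
                    lo += contrib
                    hi += contrib
                else:
                    hi += next_tf[i] * weights[i]
            lower[D] = lo
            upper[D] = hi
        unseen_upper = sum(next_tf[i] * weights[i] for i in range(m))

        order = sorted(candidates, key=lambda D: (-lower[D], D))
        top = order[: query.k]

        if exhausted:
            return [
                ScoredDocument(
                    doc=D, score=lower[D], exact=True,
                    tf={terms[i]: members[i].get(D, 0) for i in range(m)},
                )
                for D in top
            ]
        if early_stop and len(top) == query.k:
            kth = lower[top[-1]]
            rest_upper = max((upper[D] for D in order[query.k:]), default=-math.inf)
            if kth > rest_upper and kth > unseen_upper:
                return [
                    ScoredDocument(
                        doc=D, score=lower[D], exact=False,
                        tf={terms[i]: extracted[i].get(D, 0) for i in range(m)},
                    )
                    for D in top
                ]
        kp *= 2


def term_frequency(text: bytes, pattern: bytes) -> int:
    """Overlapping occurrence count of ``pattern`` in ``text``."""
    count = 0
    start = text.find(pattern)
    while start != -1:
        count += 1
        start = text.find(pattern, start + 1)
    return count


def exhaustive_ranked(collection: Collection, query: Query) -> list[ScoredDocument]:
    """Oracle scorer: scans every document, computes exact tf-idf, ranks.

    Used to verify :func:`ranked_query`; independent of every index
    structure (term frequencies come from direct text scans).
    """
    d = collection.d
    terms = [q.encode("utf-8") if isinstance(q, str) else q for q in query.terms]
    tf = [[term_frequency(collection.document_text(j), t)
           for j in range(1, d + 1)] for t in terms]
    df = [sum(1 for x in row if x > 0) for row in tf]
    results: list[ScoredDocument] = []
    for j in range(1, d + 1):
        per_term = [row[j - 1] for row in tf]
        if query.mode == "and" and not all(x > 0 for x in per_term):
            continue
        if query.mode == "or" and not any(x > 0 for x in per_term):
            continue
        score = sum(tfidf_weight(per_term[i], df[i], d) for i in range(len(terms)))
        results.append(ScoredDocument(
            doc=j, score=score,
            tf={query.terms[i]: per_term[i] for i in range(len(terms))},
        ))
    results.sort(key=lambda s: (-s.score, s.doc))
    return results[: query.k]
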