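# repindex

Document retrieval indexes for **repetitive string collections** — pan-genome
panels, versioned documents, strain databases — where most documents closely
resemble the others and classical retrieval structures waste space on
redundancy.

Given a collection of documents `S_1 .. S_d` concatenated with sentinels into
a text `T[1..n]`, the package answers, for a pattern `P`:

* **document listing** — every distinct document containing `P`, once each;
* **document counting** — `df`, the number of such documents, without
  listing them;
* **top-k retrieval** — the `k` documents with the most occurrences of `P`
  (ties by increasing document id);
* **ranked multi-term queries** — top-k under tf-idf scoring
  `w(D,Q) = Σ_i tf(D,q_i) · lg(d / max(df(q_i),1))`, conjunctive
  (ranked-AND) or disjunctive (ranked-OR).

Three engines exploit repetitiveness:

* **ILCP** — the interleaved LCP array merges the per-document LCP arrays in
  global suffix-array order. Inside a pattern interval `SA[ℓ..r]`, entries
  `< |P|` sit exactly at the leftmost occurrence of each distinct document,
  and on repetitive collections the array consists of few runs (`ρ`). The
  run heads are kept in a skewed wavelet tree; listing is an RMQ recursion
  over the runs, counting walks only the wavelet-tree leaves for values
  `0..|P|-1` (at most `4m−2` nodes for the `m`-th leaf).
* **PDL** — precomputed document lists at a sampled suffix tree (block size
  `b`, storing factor `β`), grammar-compressed with a Re-Pair style
  compressor; top-k lists are stored frequency-sorted, so a top-k query on a
  stored node reads a list prefix, and incremental extraction drives the
  multi-term index.
* **Sada** — Sadakane's counting structure: per-node redundancies `H` encoded
  unarily in a bitvector `H'` so that
  `count(ℓ,r) = (r+1−ℓ) − Σ H[ℓ..r−1]` is two selects; run-length, sparse
  and filter encodings exploit the (provably sublinear) run structure.

Brute-force oracles (`brute_list`, `brute_topk`, the classical RMQ-over-C
listing) and synthetic repetitive-collection generators make every engine
verifiable end to end.

## Worked example

```python
import repindex as ri

col = ri.from_texts(["TATA", "LATA", "AAAA"])
idx = ri.build_index(col)
idx.sa.tolist()
# [15, 10, 5, 14, 9, 4, 13, 12, 11, 7, 2, 6, 8, 3, 1]
idx.document_array().array.tolist()
# [3, 2, 1, 3, 2, 1, 3, 3, 3, 2, 1, 2, 2, 1, 1]

ilcp = ri.build_ilcp(col, idx)
ilcp.tolist()
# [0, 0, 0, 0, 0, 0, 1, 2, 3, 1, 1, 0, 0, 0, 2]
st = ri.encode_runs(ilcp)
st.rho, st.vilcp.tolist()
# (7, [0, 1, 2, 3, 1, 0, 2])

l, r = idx.search("TA")          # (13, 15): suffixes prefixed by "TA"
st.list(idx, l, r, 2)            # [2, 1]  -> documents containing "TA"
st.count(l, r, 2)                # 2       -> df without listing

counting = ri.encode_h(ri.build_h(idx))
counting.count(l, r)             # 2       -> same df in constant time

bundle = ri.build_bundle(col)
q = ri.Query(terms=("TA", "AA"), mode="or", k=3)
[(s.doc, round(s.score, 3)) for s in
 ri.ranked_query(bundle.index, bundle.pdl_topk, bundle.sada, q)]
# [(3, 4.755), (1, 1.17), (2, 0.585)]
```

The interleaved LCP array has `ρ = 7` runs with heads `⟨0,1,2,3,1,0,2⟩`;
pattern `TA` occupies `SA[13..15]`, documents 2 and 1 are reported (their
ILCP entries are below the pattern length), and the tf-idf query ranks
document 3 first because `AA` occurs three times in it and nowhere else
(`3·lg 3 ≈ 4.755`).

The same queries run from the shell:

```
repindex build -i d1.txt -i d2.txt -i d3.txt -o example.idx
repindex query -x example.idx --engine ilcp --mode list --pattern TA
repindex search -x example.idx --mode or -k 3 TA AA
repindex synth --family dna --d-base 2 --variants 8 -p 0.01 -o panel.fasta
```

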