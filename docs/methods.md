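# Methods

## Model and data layout

A collection is an ordered list of `d` non-empty documents over bytes.  Each
document is terminated with a single reserved sentinel byte (0x00), smaller
than every other symbol, and the concatenation `T[1..n]` carries a bitvector
`B` marking document starts, so `rank_1(B, p)` maps text positions to
document ids.  One shared sentinel suffices because suffixes are compared
over the whole concatenation; inputs containing the sentinel byte are
rejected.  All public interfaces are 1-based with closed intervals; numpy
storage is 0-based internally and converted at the boundary.

The suffix-array backend plays the role of a compressed suffix array: it
provides `search(P) -> [l..r]` and `lookup(i) = SA[i]` and nothing else is
assumed about it.  Construction is prefix doubling over numpy `lexsort`
(O(n log² n)); a run-length compressed CSA would change space and lookup
cost, not answers, and is out of scope.  The document array `DA[i] =
rank_1(B, SA[i])` is materialized; per-document and global LCP arrays use
Kasai's linear scan.

## ILCP

`ILCP` interleaves the per-document LCP arrays in global suffix order.  Two
facts drive the engine: (1) within a pattern interval `SA[l..r]` for
`P[1..m]`, entries `< m` are exactly the leftmost occurrences of each
distinct document — per-document suffix order is preserved inside the global
SA because every document ends with the smallest symbol; (2) on repetitive
collections the array has few runs `ρ` (for `d` copies of a length-`r` base
with `s` edits, `ρ ≤ r + O(s·lg(r+s))` almost surely).

The encoding stores run starts in a sparse bitvector `L`, run heads `VILCP`
in a skewed wavelet tree, and run lengths in a second bitvector `L'`,
grouped by head value in increasing value order (runs of equal value in
text order) and aligned with the wavelet-tree leaves.  The inter-group
order is our choice — it makes leaf offset arithmetic a single cumulative
index — the source structure only fixes the per-value grouping.

*Listing* maps `[l..r]` to the run interval and runs the leftmost-minimum
RMQ recursion over run heads, left half before right, expanding each
minimal run clipped to `[l..r]` and marking documents in a seen-array; a
subrange stops as soon as an already-marked document appears (the whole run
is then a non-leftmost repeat).  The marking array is allocated per query
and only touched entries are written, so queries cost O(output) extra work.
The pattern length is accepted but not consulted; on intervals that are not
pattern intervals the result is unspecified (documented contract).

*Counting* descends the skewed wavelet tree only into value ranges
intersecting `[0..m-1]`, sums spanned run lengths via `select` on `L'`, and
corrects the first and last run of the interval for partial overlap: an
interior run contributes its full length, the boundary runs contribute
`min(end, r) − max(start, l) + 1`.  The correction formula is the direct
geometric resolution of the stated need; a single-position interval
short-circuits to 1 (a single suffix is one document) since the value-rule
applies only to genuine pattern intervals.

### Skewed wavelet tree

Leaf `i` (value `i−1`) sits at depth `1 + 2·floor(lg i)`: each spine node
hangs one complete leaf group (sizes 1, 2, 4, ...) one level below itself.
When the alphabet ends mid-group the trailing group is attached at most
that deep, never deeper, which is the direction the `≤ 4m−2`
visited-nodes bound needs; the law is exact whenever groups are complete
(alphabet sizes `2^g − 1`).  Empty subsequences still get (empty)
bitvectors so rank bookkeeping stays uniform.

## PDL

Sampled suffix tree: leaves are the maximal suffix-tree nodes whose SA
interval fits in a block of `b` cells (plus singleton blocks for suffix-tree
leaf children of larger nodes); their intervals partition `[1..n]`.  All
ancestors are candidates; a bottom-up pass removes a node when the stored
lists of its current sampled children total at most `β` times its own
distinct-document list, splicing the children upward.  `β = None` keeps
every candidate (the incremental top-k configuration); `β = inf` prunes all
of them.  Defaults `b = 256`, `β = 16`.

Navigation uses the published component set: `B_L` (block starts), `B_F`
(first children), `F` (first child → parent rank), `N` (leaf following each
internal subtree).  The query walk is an interpretation choice, recorded
here: from each current leaf, climb first-child links while the parent's
subtree still ends inside the queried block range (it starts at the current
leaf by the first-child property), emit the highest such node, and jump to
the leaf after its subtree.  Intervals not aligned to block boundaries are
split into a left partial block, spanned nodes, and a right partial block;
partial blocks are scanned through the suffix array exactly like the
brute-force baseline.

Stored sets are compressed with a Re-Pair style compressor over the
concatenated set encodings: repeatedly replace the most frequent adjacent
pair (ties: lexicographically smallest pair, so builds are deterministic)
with a fresh nonterminal, never across set boundaries, then flatten rules
to terminal-only right-hand sides of length ≥ 2 so any set decompresses in
time linear in its size.  Listing-mode sets are canonically sorted before
compression to expose shared subsets; top-k mode preserves the
frequency-descending order (ties by increasing document id) and stores the
frequencies run-length encoded with differential run heads.  Top-k queries
at a stored node read a list prefix; elsewhere the decompressed lists of
the covering nodes are brute-force merged (their intervals partition the
covered range, so term frequencies add), plus edge scans — heuristic
early-termination merging is deliberately absent.

## Counting structure

For the binarized suffix tree, `h(v) = |D_u ∩ D_w|` satisfies `count(v) =
count(u) + count(w) − h(v)`, giving `count(l, r) = (r+1−l) − Σ H[l..r−1]`
over the inorder-listed `H`.  Children of multi-way nodes are combined
right-to-left into a chain; since only sums over original-node intervals
are queried, the whole chain mass `Σ_j count(c_j) − count(v)` is reassigned
to the inorder rank of the chain top (the end position of the first child's
interval).  This identity lets `H` be computed from distinct-document
counts alone — an offline Fenwick-tree sweep answers all per-node and
per-chain-suffix interval counts in O((n+q) log n) — with no materialized
document sets.

`H` is encoded unarily (`1` then `H[i]` zeros) over a plain or sparse
bitvector, optionally filtered: `fs` keeps cells with `H > 0`; `f1` marks
`H = 1` cells in a separate bitvector and writes no zeros for them (their
count is added back at query time); together, `fs` keeps `H > 1`.  The
count filter `f` prunes binarized subtrees seeing a single distinct
document: chain-node counts come from suffix unions of child intervals,
the remaining chain prefix keeps its mass, and the query maps its range
through `rank` over `F`; a locus that falls entirely inside a pruned
subtree has no marked cells in range and short-circuits to `count = 1`.
`f` changes the tree shape, so combining it with the cell filters is
rejected rather than guessed.  Queries are defined at pattern loci
(suffix-tree node intervals or single positions); arbitrary intervals are
undefined, matching the structure's contract.

One consequence of the shared sentinel is worth recording: even a
collection of pairwise-disjoint documents carries `h`-mass `d` at the root
chain, because all documents meet in the sentinel subtree.  `H'` is
therefore never a single run of 1s for `d > 1`; the minimal form is the
mass confined to one root-chain cell (two runs), and the tests assert that
form.

## Multi-term index

Document frequencies come from the counting structure at each term's locus;
term lists come from the top-k PDL (all nodes above leaf blocks stored).
The loop extracts `k' = 2k, 4k, ...` entries per term, maintains per-document
lower bounds (unseen terms contribute 0) and upper bounds (unseen terms
contribute the frequency of the next unextracted entry; exhausted lists
contribute 0), filters conjunctive candidates with fully decompressed
lists, and stops when the k-th lower bound strictly exceeds every other
candidate's upper bound and the generic unseen-document bound.  Strict
inequality means ties force continued extraction, so the returned
identifier set always equals the exhaustive scorer's (verified by disabling
early stopping); scores reported after an early disjunctive stop may be
partial and are flagged as such.  If no document matches a conjunctive
query the loop runs until all lists are exhausted and returns the empty
set.  Ties across equal scores break by increasing document id everywhere.

## Synthetic collections

The generators reproduce the study conditions: `fig5` (one random DNA base
duplicated `d` times, entropy-preserving point mutations at rate `p` —
replacement drawn from the source's empirical distribution, so it may be a
no-op), `dna` (bases mutated from a common length-1000 prefix at `10p`,
variants at `p`), `version`/`concat` (independent random bases of default
length 10,000 with mutated variants, one document per variant vs. one per
base).  Base sequences are uniform random over the alphabet: the original
experiments seeded generators with natural-text prefixes, which adds
higher-order structure the uniform model lacks; run-count bounds and oracle
equivalences do not depend on that structure, but absolute compressibility
on real corpora will differ.  Pattern extraction samples substrings
uniformly over in-document positions, deduplicates, computes `occ` from the
search interval and `df` from a counting engine, and keeps the best
`occ/df` ratios (ties lexicographic).  All generators draw from
per-document streams spawned from one seed, so outputs are bit-identical
across runs and platforms.

## Problem sizes and defaults

The package is built for in-memory, desk-scale experimentation: indexes are
plain Python/numpy objects, the suffix tree is explicit during
construction (O(n) words), and space is reported rather than optimized.
The test suite verifies oracle equivalence on ~100 seeded collections
(σ ∈ {2, 4, 26}, up to 20 documents of length up to 100, every pattern of
length ≤ 4, the full `b × β` grid), and the stochastic bounds at
`r_doc = 256` with `d` up to 64 (20 seeds per configuration): large enough
for the asymptotic trends (√d growth of counting runs, logarithmic run
growth per edit) to be visible, small enough to run in minutes.  Slack
constants on the asymptotic statements (4 on the `s·lg(r+s)` term, 2 on the
`(σ/2+1)·r·√d` expectation) are empirical choices, fixed before scaling up
and recorded in the tests.

## Known limitations

* No run-length compressed suffix array: `search`/`lookup` are exact but
  not succinct, and the space bounds tied to `|CSA|` are not asserted.
* Serialization is a versioned pickle container; round-trips are
  query-identical but the byte layout is implementation-defined.
* Counting queries outside pattern loci are undefined by contract.
* The Re-Pair compressor recounts pair frequencies per round (quadratic in
  the worst case); fine at the intended scale, not for gigabyte corpora.
* Multi-thread query throughput and real-corpus benchmarks are out of
  scope; `repindex bench` reports informational timings only.
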