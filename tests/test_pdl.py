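import itertools
import math

import numpy as np
import pytest

import repindex as ri
from conftest import all_patterns, random_collection


class TestCompressedSets:
    def test_shared_subset_becomes_rule(self):
        sets = [[1, 2, 3], [1, 2, 3], [1, 2, 3], [1, 2, 3]]
        cs = ri.compress_sets(sets, d=5)
        assert cs.n_rules >= 1
        # each stored encoding collapsed to a single symbol
        for i in range(1, 5):
            assert ri.decompress_set(cs, i) == [1, 2, 3]
        assert all(len(cs.rule_expansion(cs.d + r + 1)) >= 2
                   for r in range(cs.n_rules))

    def test_singleton_sets_get_no_rules(self):
        cs = ri.compress_sets([[1], [2], [1]], d=3)
        assert cs.n_rules == 0
        assert [ri.decompress_set(cs, i) for i in (1, 2, 3)] == [[1], [2], [1]]

    @pytest.mark.parametrize("seed", range(20))
    def test_round_trip_preserves_order(self, seed):
        rng = np.random.default_rng(seed)
        d = int(rng.integers(2, 12))
        sets = []
        for _ in range(int(rng.integers(1, 15))):
            size = int(rng.integers(1, d + 1))
            sets.append(list(rng.permutation(d)[:size] + 1))
        cs = ri.compress_sets(sets, d=d)
        for i, s in enumerate(sets, start=1):
            assert ri.decompress_set(cs, i) == s
        # terminal-only right-hand sides of length >= 2
        for r in range(cs.n_rules):
            exp = cs.rule_expansion(cs.d + r + 1)
            assert len(exp) >= 2
            assert all(1 <= x <= d for x in exp)


class TestBuild:
    def test_parameter_validation(self, example_index):
        with pytest.raises(ValueError):
            ri.build_pdl(example_index, b=0)
        with pytest.raises(ValueError):
            ri.build_pdl(example_index, b=2, beta=0.5)
        with pytest.raises(ValueError):
            ri.build_pdl(example_index, mode="bogus")

    def test_default_parameters_recorded(self, example_index):
        pdl = ri.build_pdl(example_index)
        meta = pdl.metadata()
        assert meta["b"] == 256 and meta["beta"] == 16

    def test_huge_beta_prunes_all_internal_nodes(self, example_index):
        pdl = ri.build_pdl(example_index, b=2, beta=math.inf)
        assert pdl.I == 0
        assert pdl.list(13, 15) == [1, 2]

    def test_leaf_blocks_partition_suffix_array(self):
        for seed in range(6):
            col = random_collection(seed)
            idx = ri.build_index(col)
            for b in (1, 3, 8):
                pdl = ri.build_pdl(idx, b=b, beta=2)
                end = 0
                for leaf in range(1, pdl.L + 1):
                    lo, hi = pdl.leaf_block(leaf)
                    assert lo == end + 1
                    assert hi - lo + 1 <= b
                    end = hi
                assert end == idx.n

    def test_storing_factor_audit(self):
        """Retained internal nodes violate the beta bound, pruned ones obey it.

        Pruning is bottom-up, so for every internal suffix-tree node the
        stored maximal nodes inside its interval are exactly the children it
        was judged by at pruning time.
        """
        from repindex.suffixtree import build_suffix_tree

        def maximal_inside(intervals, lo, hi, skip):
            inside = [iv for iv in intervals
                      if lo <= iv[0] and iv[1] <= hi and iv != skip]
            return [iv for iv in inside
                    if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1]
                               for o in inside)]

        for seed in range(4):
            col = random_collection(seed)
            idx = ri.build_index(col)
            beta = 2
            pdl = ri.build_pdl(idx, b=2, beta=beta)
            tree = build_suffix_tree(idx)
            da = idx.document_array().array
            stored = {pdl.node_interval(i): i
                      for i in range(1, pdl.L + pdl.I + 1)}
            set_size = {iv: len(set(da[iv[0] - 1: iv[1]].tolist()))
                        for iv in stored}
            for v in range(len(tree)):
                lo, hi = tree.interval(v)
                if tree.size(v) <= pdl.b:
                    continue
                children = maximal_inside(list(stored), lo, hi, (lo, hi))
                total = sum(set_size[c] for c in children)
                own = len(set(da[lo - 1: hi].tolist()))
                if (lo, hi) in stored:
                    assert total > beta * own
                else:
                    assert total <= beta * own


class TestListing:
    def test_worked_example(self, example_index):
        pdl = ri.build_pdl(example_index, b=1, beta=1)
        assert pdl.list(13, 15) == [1, 2]

    def test_interval_inside_single_block_uses_fallback(self, example_index):
        pdl = ri.build_pdl(example_index, b=8, beta=1)
        # any sub-block interval must still match brute force
        assert pdl.list(2, 3) == example_index.brute_list(2, 3)
        assert pdl.list(9, 9) == example_index.brute_list(9, 9)

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_brute_across_parameter_grid(self, seed):
        col = random_collection(seed, sigma=[2, 4, 26][seed % 3])
        idx = ri.build_index(col)
        pats = all_patterns(col)
        for b, beta in itertools.product((1, 2, 4, 16), (1, 2, 16, math.inf)):
            pdl = ri.build_pdl(idx, b=b, beta=beta)
            for pat in pats:
                interval = idx.search(pat)
                if interval is None:
                    continue
                assert pdl.list(*interval) == idx.brute_list(*interval), (b, beta, pat)


class TestTopK:
    def test_worked_example(self, example_index):
        pdl = ri.build_pdl(example_index, b=2, beta=None, mode="topk")
        assert pdl.topk(13, 15, 1) == [(1, 2)]
        # k >= d returns everything, tf-sorted with doc-id ties increasing
        assert pdl.topk(13, 15, 5) == [(1, 2), (2, 1)]

    def test_k_validation(self, example_index):
        pdl = ri.build_pdl(example_index, b=2, beta=None, mode="topk")
        with pytest.raises(ValueError):
            pdl.topk(13, 15, 0)

    def test_listing_mode_has_no_frequencies(self, example_index):
        pdl = ri.build_pdl(example_index, b=2, beta=2, mode="list")
        with pytest.raises(ValueError):
            pdl.topk(13, 15, 1)

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("beta", [None, 2])
    def test_equals_brute_topk(self, seed, beta):
        col = random_collection(seed)
        idx = ri.build_index(col)
        pdl = ri.build_pdl(idx, b=2, beta=beta, mode="topk")
        for pat in all_patterns(col):
            interval = idx.search(pat)
            if interval is None:
                continue
            for k in (1, 10):
                assert pdl.topk(*interval, k) == idx.brute_topk(*interval, k)

    def test_stored_frequencies_are_monotone_and_exact(self):
        for seed in range(4):
            col = random_collection(seed)
            idx = ri.build_index(col)
            pdl = ri.build_pdl(idx, b=4, beta=None, mode="topk")
            da = idx.document_array().array
            for node_id in range(1, pdl.L + pdl.I + 1):
                docs = pdl.sets.decompress(node_id)
                tfs = pdl.freqs[node_id - 1].decode().tolist()
                assert all(a >= b for a, b in zip(tfs, tfs[1:]))
                lo, hi = pdl.node_interval(node_id)
                from collections import Counter
                want = Counter(int(x) for x in da[lo - 1: hi])
                assert dict(zip(docs, tfs)) == dict(want)

    def test_incremental_iterator_order(self, example_index):
        pdl = ri.build_pdl(example_index, b=2, beta=None, mode="topk")
        seen = list(pdl.topk_iter(1, 15))
        assert seen == [(1, 5), (2, 5), (3, 5)]
        tfs = [tf for _, tf in seen]
        assert tfs == sorted(tfs, reverse=True)
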