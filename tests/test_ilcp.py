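import math
import random

import numpy as np
import pytest

import repindex as ri
from conftest import all_patterns, random_collection

EXAMPLE_ILCP = [0, 0, 0, 0, 0, 0, 1, 2, 3, 1, 1, 0, 0, 0, 2]


class TestBuildILCP:
    def test_worked_example(self, example_collection, example_index):
        ilcp = ri.build_ilcp(example_collection, example_index)
        assert ilcp.tolist() == EXAMPLE_ILCP

    def test_per_document_lcp_arrays_of_example(self, example_collection):
        from repindex.ilcp import document_lcp
        lcps = [document_lcp(example_collection.document_text(j, with_sentinel=True))
                for j in (1, 2, 3)]
        assert lcps[0].tolist() == [0, 0, 1, 0, 2]
        assert lcps[1].tolist() == [0, 0, 1, 0, 0]
        assert lcps[2].tolist() == [0, 0, 1, 2, 3]

    def test_single_document_equals_own_lcp(self):
        col = ri.from_texts(["BANANA"])
        idx = ri.build_index(col)
        from repindex.ilcp import document_lcp
        own = document_lcp(col.document_text(1, with_sentinel=True))
        assert ri.build_ilcp(col, idx).tolist() == own.tolist()

    @pytest.mark.parametrize("seed", range(10))
    def test_interleaving_definition_holds(self, seed):
        """ILCP[i] equals LCP_{S_j}[rank_j(DA, i)] for j = DA[i]."""
        from repindex.ilcp import document_lcp
        col = random_collection(seed)
        idx = ri.build_index(col)
        ilcp = ri.build_ilcp(col, idx)
        da = idx.document_array().array
        lcps = {j: document_lcp(col.document_text(j, with_sentinel=True))
                for j in range(1, col.d + 1)}
        seen = {j: 0 for j in range(1, col.d + 1)}
        for i in range(col.n):
            j = int(da[i])
            assert ilcp[i] == lcps[j][seen[j]]
            seen[j] += 1


class TestRunEncoding:
    def test_worked_example_runs(self, example_collection, example_index):
        st = ri.encode_runs(ri.build_ilcp(example_collection, example_index))
        assert st.rho == 7
        assert st.vilcp.tolist() == [0, 1, 2, 3, 1, 0, 2]
        assert "".join(map(str, st.L.to_array())) == "100000111101001"
        assert st.lam == 3

    def test_constant_array_single_run(self):
        st = ri.encode_runs(np.full(9, 5))
        assert st.rho == 1
        assert ri.decode_runs(st).tolist() == [5] * 9

    @pytest.mark.parametrize("seed", range(15))
    def test_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.integers(0, 5, size=rng.integers(1, 120))
        st = ri.encode_runs(arr)
        assert ri.decode_runs(st).tolist() == arr.tolist()
        # ILCP[i] = VILCP[rank_1(L, i)]
        for i in range(1, arr.size + 1):
            assert arr[i - 1] == st.vilcp[st.L.rank(1, i) - 1]
        # L' groups account for every position once
        assert int(st.Lprime.count(1)) == st.rho
        assert len(st.Lprime) == arr.size


class TestQueries:
    def test_listing_worked_example(self, example_collection, example_index):
        st = ri.encode_runs(ri.build_ilcp(example_collection, example_index))
        assert st.list(example_index, 13, 15, 2) == [2, 1]
        assert st.list(example_index, 7, 7, 1) == [3]

    def test_counting_worked_example(self, example_collection, example_index):
        st = ri.encode_runs(ri.build_ilcp(example_collection, example_index))
        assert st.count(13, 15, 2) == 2
        assert st.count(7, 7, 1) == 1

    @pytest.mark.parametrize("seed", range(12))
    def test_equal_to_brute_oracle_on_all_short_patterns(self, seed):
        col = random_collection(seed, sigma=[2, 4, 26][seed % 3])
        idx = ri.build_index(col)
        st = ri.encode_runs(ri.build_ilcp(col, idx))
        for pat in all_patterns(col):
            interval = idx.search(pat)
            if interval is None:
                continue
            l, r = interval
            want = idx.brute_list(l, r)
            assert sorted(st.list(idx, l, r, len(pat))) == want
            assert st.count(l, r, len(pat)) == len(want)

    @pytest.mark.parametrize("seed", range(6))
    def test_lemma_values_below_m_are_leftmost_occurrences(self, seed):
        """Positions with ILCP < m are exactly the leftmost per-document hits."""
        col = random_collection(seed)
        idx = ri.build_index(col)
        ilcp = ri.build_ilcp(col, idx)
        da = idx.document_array().array
        for pat in all_patterns(col, max_len=3):
            interval = idx.search(pat)
            if interval is None:
                continue
            l, r = interval
            m = len(pat)
            below = {k for k in range(l, r + 1) if ilcp[k - 1] < m}
            leftmost = set()
            seen = set()
            for k in range(l, r + 1):
                if da[k - 1] not in seen:
                    seen.add(da[k - 1])
                    leftmost.add(k)
            assert below == leftmost


class TestRunGrowth:
    @staticmethod
    def _rho(r_doc: int, d: int, s: int, seed: int) -> int:
        rng = np.random.default_rng(seed)
        base = rng.choice(np.frombuffer(b"ACGT", np.uint8), size=r_doc)
        docs = [base.copy() for _ in range(d)]
        for _ in range(s):
            pos = int(rng.integers(0, r_doc * d))
            j, off = divmod(pos, r_doc)
            docs[j][off] = rng.choice(np.frombuffer(b"ACGT", np.uint8))
        col = ri.from_texts([doc.tobytes() for doc in docs])
        idx = ri.build_index(col)
        return ri.encode_runs(ri.build_ilcp(col, idx)).rho

    def test_zero_edit_run_bound(self):
        """d identical copies of a length-r base give at most r+1 ILCP runs."""
        for seed in range(5):
            assert self._rho(64, 8, 0, seed) <= 65

    def test_substitutions_grow_runs_logarithmically(self):
        # slack constant 4 chosen empirically; the analytic statement is
        # rho <= r + O(s lg(r+s)) almost surely
        r_doc, d = 128, 8
        for s in (8, 32):
            bound = r_doc + 1 + 4 * s * math.log2(r_doc + s)
            for seed in range(5):
                assert self._rho(r_doc, d, s, seed) <= bound
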