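import math

import numpy as np
import pytest

import repindex as ri


class TestMutate:
    def test_zero_rate_is_identity(self):
        S = b"ACGTACGTAA"
        assert ri.mutate(S, ri.MutationModel(p=0.0, seed=1)) == S

    def test_deterministic_under_seed(self):
        S = b"ACGT" * 50
        a = ri.mutate(S, ri.MutationModel(p=0.3, seed=42))
        b = ri.mutate(S, ri.MutationModel(p=0.3, seed=42))
        assert a == b
        assert a != ri.mutate(S, ri.MutationModel(p=0.3, seed=43))

    def test_full_rate_hamming_distance_binomial(self):
        """p=1 on a uniform 4-symbol sequence: E[distance] = |S|(1 - 1/4)."""
        rng = np.random.default_rng(5)
        length = 2000
        S = rng.choice(np.frombuffer(b"ACGT", np.uint8), size=length).tobytes()
        expected = length * 0.75
        sd = math.sqrt(length * 0.75 * 0.25)
        for seed in range(20):
            out = ri.mutate(S, ri.MutationModel(p=1.0, seed=seed))
            dist = sum(a != b for a, b in zip(S, out))
            assert abs(dist - expected) <= 5 * sd

    def test_replacement_preserves_zero_order_composition(self):
        # skewed source distribution must be preserved within 5 sigma
        rng = np.random.default_rng(11)
        probs = np.array([0.7, 0.1, 0.1, 0.1])
        length = 4000
        S = rng.choice(np.frombuffer(b"ACGT", np.uint8), size=length, p=probs).tobytes()
        source_freq = np.array([S.count(c) for c in b"ACGT"]) / length
        out = ri.mutate(S, ri.MutationModel(p=1.0, seed=3))
        for i, c in enumerate(b"ACGT"):
            p = source_freq[i]
            sd = math.sqrt(length * p * (1 - p))
            assert abs(out.count(c) - length * p) <= 5 * sd

    def test_validation(self):
        with pytest.raises(ValueError):
            ri.MutationModel(p=1.5, seed=0)
        with pytest.raises(ValueError):
            ri.mutate(b"", ri.MutationModel(p=0.1, seed=0))


class TestGenerators:
    def test_fig5_zero_rate_gives_identical_copies_and_run_bound(self):
        for seed in range(5):
            col = ri.generate_fig5(128, 8, 0.0, seed)
            texts = {d.text for d in col.documents}
            assert len(texts) == 1 and col.d == 8
            idx = ri.build_index(col)
            st = ri.encode_runs(ri.build_ilcp(col, idx))
            assert st.rho <= 129    # r + 1 runs with zero edits

    def test_version_and_concat_document_counts(self):
        v = ri.generate_version(2, 3, 0.01, seed=7, base_length=50)
        c = ri.generate_concat(2, 3, 0.01, seed=7, base_length=50)
        assert v.d == 6
        assert c.d == 2
        # concat documents hold all variants of one base
        assert sum(len(d.text) for d in c.documents) == \
            sum(len(d.text) for d in v.documents)

    def test_dna_family_pairwise_distances(self):
        """Variants of one base differ by about 2p(1 - 1/sigma) per symbol."""
        p, length = 0.05, 2000
        col = ri.generate_dna(2, 4, p, seed=9, base_length=length)
        assert col.d == 8
        expected = 2 * p * (1 - 1 / 4) * length
        sd = math.sqrt(expected)
        group = [d.text for d in col.documents[:4]]
        dists = [sum(a != b for a, b in zip(x, y))
                 for i, x in enumerate(group) for y in group[i + 1:]]
        assert abs(np.mean(dists) - expected) <= 6 * sd
        # bases come from a common prefix mutated at 10p: documents of
        # different bases are further apart than same-base variants
        other = col.documents[4].text
        cross = np.mean([sum(a != b for a, b in zip(x, other)) for x in group])
        assert cross > np.mean(dists)

    def test_generators_deterministic(self):
        for family in ("fig5", "dna", "version", "concat"):
            spec = ri.SyntheticSpec(family=family, p=0.02, seed=123,
                                    base_length=60, d_base=2, variants=3)
            a = ri.generate(spec)
            b = ri.generate(spec)
            assert [x.text for x in a.documents] == [x.text for x in b.documents]

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ri.SyntheticSpec(family="nope", p=0.1, seed=0)
        with pytest.raises(ValueError):
            ri.SyntheticSpec(family="dna", p=0.1, seed=0, variants=0)


class TestExtractPatterns:
    def test_ratio_ranking_matches_brute_statistics(self):
        col = ri.generate_fig5(40, 6, 0.05, seed=4)
        idx = ri.build_index(col)
        pats = ri.extract_patterns(col, idx, length=4, n_samples=300,
                                   n_keep=10, seed=1)
        assert 0 < len(pats) <= 10
        ratios = []
        for pat in pats:
            l, r = idx.search(pat)
            ratios.append((r - l + 1) / len(idx.brute_list(l, r)))
        assert ratios == sorted(ratios, reverse=True)

    def test_keep_more_than_available_returns_all(self):
        col = ri.from_texts(["AB"])
        idx = ri.build_index(col)
        pats = ri.extract_patterns(col, idx, length=2, n_samples=50,
                                   n_keep=100, seed=0)
        assert pats == [b"AB"]

    def test_deterministic_under_seed(self):
        col = ri.generate_fig5(50, 4, 0.1, seed=2)
        idx = ri.build_index(col)
        a = ri.extract_patterns(col, idx, length=5, n_samples=200, n_keep=20, seed=9)
        b = ri.extract_patterns(col, idx, length=5, n_samples=200, n_keep=20, seed=9)
        assert a == b

    def test_no_valid_substrings_warns(self):
        col = ri.from_texts(["AB"])
        idx = ri.build_index(col)
        with pytest.warns(UserWarning):
            assert ri.extract_patterns(col, idx, length=10, n_samples=10,
                                       n_keep=5, seed=0) == []
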