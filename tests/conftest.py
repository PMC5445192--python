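import random

import pytest

import repindex as ri


@pytest.fixture(scope="session")
def example_collection() -> ri.Collection:
    """The three-document worked example: TATA$, LATA$, AAAA$."""
    return ri.from_texts(["TATA", "LATA", "AAAA"])


@pytest.fixture(scope="session")
def example_index(example_collection) -> ri.SuffixArrayIndex:
    return ri.build_index(example_collection)


ALPHABETS = {2: "AB", 4: "ACGT", 26: "abcdefghijklmnopqrstuvwxyz"}


def random_collection(seed: int, sigma: int = 4, max_docs: int = 10,
                      max_len: int = 30) -> ri.Collection:
    """Small random collection with seeded contents."""
    rng = random.Random(seed)
    alpha = ALPHABETS[sigma]
    d = rng.randint(2, max_docs)
    docs = ["".join(rng.choice(alpha) for _ in range(rng.randint(1, max_len)))
            for _ in range(d)]
    return ri.from_texts(docs)


def all_patterns(collection: ri.Collection, max_len: int = 4) -> list[str]:
    """Every distinct sentinel-free substring of length <= max_len."""
    pats: set[str] = set()
    for j in range(1, collection.d + 1):
        text = collection.document_text(j).decode("latin-1")
        for m in range(1, max_len + 1):
            for off in range(len(text) - m + 1):
                pats.add(text[off: off + m])
    return sorted(pats)
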