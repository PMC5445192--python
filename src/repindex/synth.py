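"""Synthetic repetitive collections and query-pattern extraction.

The generators emulate the collection families used to study repetitive
document retrieval:

* ``fig5``: one random base sequence of length ``m`` duplicated ``d`` times,
  then hit with entropy-preserving point mutations at probability ``p``
  (the replacement symbol is drawn from the empirical distribution of the
  original sequence, and may equal the mutated symbol);
* ``dna``: ``d_base`` base documents derived from a common random DNA prefix
  at mutation rate ``10p``, each spawning ``variants`` variant documents at
  rate ``p`` (unrelated-strain collections);
* ``version``: independent random base texts, each spawning variants at
  rate ``p``, every variant a separate document (versioned collections);
* ``concat``: as ``version`` but all variants of one base are concatenated
  into a single document.

All generators are deterministic under their seed (independent per-document
streams spawned from one seed sequence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .collection import Collection, from_texts
from .core import SuffixArrayIndex

__all__ = ["MutationModel", "mutate", "SyntheticSpec", "generate",
           "generate_fig5", "generate_dna", "generate_version",
           "generate_concat", "extract_patterns"]

DNA = b"ACGT"
TEXT = b"abcdefghijklmnopqrstuvwxyz "


@dataclass(frozen=True)
class MutationModel:
    """Point-mutation model: per-symbol probability ``p``, fixed seed.

    Replacement symbols are drawn from the empirical symbol distribution of
    the sequence being mutated (zero-order entropy preserving), so a
    "mutation" may leave the symbol unchanged.
    """

    p: float
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("mutation probability must be in [0, 1]")


def _mutate_array(arr: np.ndarray, p: float, rng: np.random.Generator,
                  values: np.ndarray, probs: np.ndarray) -> np.ndarray:
    out = arr.copy()
    if p <= 0.0 or arr.size == 0:
        return out
    mask = rng.random(arr.size) < p
    hits = int(mask.sum())
    if hits:
        out[mask] = rng.choice(values, size=hits, p=probs)
    return out


def _empirical(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values, counts = np.unique(arr, return_counts=True)
    return values, counts / counts.sum()


def mutate(S: bytes, model: MutationModel) -> bytes:
    """Apply independent point mutations to every position of ``S``."""
    if len(S) == 0:
        raise ValueError("cannot mutate an empty sequence")
    arr = np.frombuffer(S, dtype=np.uint8)
    values, probs = _empirical(arr)
    rng = np.random.default_rng(model.seed)
    return _mutate_array(arr, model.p, rng, values, probs).tobytes()


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic collection family."""

    family: str                 # fig5 | dna | concat | version
    p: float
    seed: int
    base_length: int = 1000
    d_base: int = 1             # base documents (dna/concat/version)
    variants: int = 10          # copies per base (fig5: total copies)
    alphabet: bytes = DNA

    def __post_init__(self) -> None:
        if self.family not in ("fig5", "dna", "concat", "version"):
            raise ValueError(f"unknown family {self.family!r}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("mutation probability must be in [0, 1]")
        if self.base_length < 1 or self.d_base < 1 or self.variants < 1:
            raise ValueError("base_length, d_base and variants must be >= 1")


def _random_sequence(rng: np.random.Generator, length: int,
                     alphabet: bytes) -> np.ndarray:
    return rng.choice(np.frombuffer(alphabet, dtype=np.uint8), size=length)


def generate(spec: SyntheticSpec) -> Collection:
    if spec.family == "fig5":
        return generate_fig5(spec.base_length, spec.variants, spec.p,
                             spec.seed, spec.alphabet)
    if spec.family == "dna":
        return generate_dna(spec.d_base, spec.variants, spec.p, spec.seed,
                            spec.base_length)
    if spec.family == "version":
        return generate_version(spec.d_base, spec.variants, spec.p, spec.seed,
                                spec.base_length, spec.alphabet)
    return generate_concat(spec.d_base, spec.variants, spec.p, spec.seed,
                           spec.base_length, spec.alphabet)


def _spawn(seed: int, count: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(count)]


def generate_fig5(m: int, d: int, p: float, seed: int,
                  alphabet: bytes = DNA) -> Collection:
    """``d`` mutated copies of one random base sequence of length ``m``."""
    rngs = _spawn(seed, d + 1)
    base = _random_sequence(rngs[0], m, alphabet)
    values, probs = _empirical(base)
    docs = [_mutate_array(base, p, rngs[1 + i], values, probs).tobytes()
            for i in range(d)]
    return from_texts(docs)


def generate_dna(d_base: int, variants: int, p: float, seed: int,
                 base_length: int = 1000) -> Collection:
    """Bases mutated from a common DNA prefix at ``10p``, variants at ``p``."""
    rngs = _spawn(seed, 1 + d_base * (1 + variants))
    prefix = _random_sequence(rngs[0], base_length, DNA)
    values, probs = _empirical(prefix)
    docs: list[bytes] = []
    t = 1
    for _ in range(d_base):
        base = _mutate_array(prefix, min(10 * p, 1.0), rngs[t], values, probs)
        t += 1
        b_values, b_probs = _empirical(base)
        for _ in range(variants):
            docs.append(_mutate_array(base, p, rngs[t], b_values, b_probs).tobytes())
            t += 1
    return from_texts(docs)


def _version_variants(d_base: int, variants: int, p: float, seed: int,
                      base_length: int, alphabet: bytes) -> list[list[bytes]]:
    rngs = _spawn(seed, d_base * (1 + variants))
    groups: list[list[bytes]] = []
    t = 0
    for _ in range(d_base):
        base = _random_sequence(rngs[t], base_length, alphabet)
        t += 1
        values, probs = _empirical(base)
        group = []
        for _ in range(variants):
            group.append(_mutate_array(base, p, rngs[t], values, probs).tobytes())
            t += 1
        groups.append(group)
    return groups


def generate_version(d_base: int, variants: int, p: float, seed: int,
                     base_length: int = 10_000,
                     alphabet: bytes = TEXT) -> Collection:
    """Every variant of every base becomes its own document."""
    groups = _version_variants(d_base, variants, p, seed, base_length, alphabet)
    return from_texts([v for group in groups for v in group])


def generate_concat(d_base: int, variants: int, p: float, seed: int,
                    base_length: int = 10_000,
                    alphabet: bytes = TEXT) -> Collection:
    """All variants of one base are concatenated into a single document."""
    groups = _version_variants(d_base, variants, p, seed, base_length, alphabet)
    return from_texts([b"".join(group) for group in groups])


def extract_patterns(collection: Collection, index: SuffixArrayIndex,
                     length: int, n_samples: int, n_keep: int,
                     ranking: str = "occ_over_df", seed: int = 0,
                     counter=None) -> list[bytes]:
    """Sample random substrings and keep those with the best retrieval ratio.

    ``n_samples`` substrings of the given length are drawn uniformly over
    all valid in-document positions, duplicates are removed, the statistic
    (``occ/df`` or plain occurrence count) is computed exactly from the
    index (``df`` from the counting structure when provided, otherwise from
    the brute listing), and the ``n_keep`` best patterns are returned; ties
    are broken lexicographically for determinism.
    """
    if length < 1:
        raise ValueError("pattern length must be >= 1")
    if ranking not in ("occ_over_df", "term_frequency"):
        raise ValueError(f"unknown ranking {ranking!r}")
    starts: list[tuple[int, int]] = []          # (document, offset)
    for j in range(1, collection.d + 1):
        size = len(collection.document_text(j))
        for off in range(size - length + 1):
            starts.append((j, off))
    if not starts:
        import warnings
        warnings.warn("no substrings of the requested length exist")
        return []
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(starts), size=n_samples)
    patterns = {collection.document_text(j)[off: off + length]
                for j, off in (starts[i] for i in picks)}
    scored: list[tuple[float, bytes]] = []
    for pat in patterns:
        interval = index.search(pat)
        if interval is None:               # cannot happen for sampled substrings
            continue
        l, r = interval
        occ = r - l + 1
        if ranking == "term_frequency":
            stat = float(occ)
        else:
            df = counter.count(l, r) if counter is not None else len(
                index.brute_list(l, r))
            stat = occ / df
        scored.append((stat, pat))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [pat for _, pat in scored[:n_keep]]
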