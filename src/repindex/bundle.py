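"""Index bundles: build, save and load every engine over one collection.

A bundle holds the collection, the suffix-array backend and any subset of
the query engines (ILCP, PDL in listing and/or top-k mode, the counting
structure).  Serialization is a versioned pickle container; loading rebuilds
nothing, so saved and loaded bundles answer queries identically.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

from .collection import Collection
from .core import SuffixArrayIndex, build_index
from .ilcp import ILCPStructure, build_ilcp, encode_runs
from .pdl import PDLIndex, build_pdl
from .sada import CountingStructure, build_h, encode_h
from .suffixtree import build_suffix_tree

__all__ = ["IndexBundle", "build_bundle", "save_bundle", "load_bundle"]

FORMAT_VERSION = 1
ALL_ENGINES = ("ilcp", "pdl", "sada")


@dataclass
class IndexBundle:
    collection: Collection
    index: SuffixArrayIndex
    ilcp: ILCPStructure | None = None
    pdl: PDLIndex | None = None            # listing mode
    pdl_topk: PDLIndex | None = None       # top-k mode (frequencies stored)
    sada: CountingStructure | None = None
    params: dict = field(default_factory=dict)
    format_version: int = FORMAT_VERSION

    def require(self, engine: str):
        value = getattr(self, engine, None)
        if value is None:
            raise ValueError(
                f"engine {engine!r} was not built in this bundle "
                f"(available: {self.available()})"
            )
        return value

    def available(self) -> list[str]:
        return [e for e in ("ilcp", "pdl", "pdl_topk", "sada")
                if getattr(self, e) is not None]


def build_bundle(collection: Collection, engines=ALL_ENGINES,
                 b: int = 256, beta: float | None = 16,
                 topk_beta: float | None = None,
                 encoding: str = "plain", filters=frozenset(),
                 store_freqs: bool = True) -> IndexBundle:
    """Build the requested engines over one shared suffix-array index.

    ``beta`` drives the listing-mode PDL; the top-k PDL defaults to storing
    all nodes above the leaf blocks (``topk_beta=None``), the configuration
    the multi-term index relies on for incremental extraction.
    """
    engines = set(engines)
    unknown = engines - set(ALL_ENGINES)
    if unknown:
        raise ValueError(f"unknown engines {sorted(unknown)}")
    index = build_index(collection)
    bundle = IndexBundle(collection=collection, index=index, params={
        "b": b, "beta": beta, "topk_beta": topk_beta,
        "encoding": encoding, "filters": sorted(filters),
    })
    tree = None
    if "pdl" in engines or "sada" in engines:
        tree = build_suffix_tree(index)
    if "ilcp" in engines:
        bundle.ilcp = encode_runs(build_ilcp(collection, index))
    if "pdl" in engines:
        bundle.pdl = build_pdl(index, b=b, beta=beta, mode="list", tree=tree)
        if store_freqs:
            bundle.pdl_topk = build_pdl(index, b=b, beta=topk_beta,
                                        mode="topk", tree=tree)
    if "sada" in engines:
        bundle.sada = encode_h(build_h(index, tree=tree),
                               encoding=encoding, filters=filters)
    return bundle


def save_bundle(bundle: IndexBundle, path) -> None:
    with open(path, "wb") as fh:
        pickle.dump(bundle, fh, protocol=pickle.HIGHEST_PROTOCOL)


def load_bundle(path) -> IndexBundle:
    with open(path, "rb") as fh:
        bundle = pickle.load(fh)
    if not isinstance(bundle, IndexBundle):
        raise ValueError(f"{path} does not contain an index bundle")
    if bundle.format_version != FORMAT_VERSION:
        raise ValueError(
            f"bundle format version {bundle.format_version} not supported "
            f"(expected {FORMAT_VERSION})"
        )
    return bundle
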