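"""Document collections over a sentinel-terminated concatenation.

A collection holds ``d`` documents ``S_1 .. S_d``.  Each document is
terminated with a sentinel byte that compares smaller than every other
symbol, and the concatenation ``T = S_1 $ S_2 $ ... S_d $`` of length ``n``
is the text all indexes in this package are built over.  A bitvector ``B``
of length ``n`` marks the first symbol of each document, so that
``rank_1(B, p)`` maps any text position to the identifier of the document
containing it.

All public coordinates are 1-based with closed intervals.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .succinct import Bitvector

#: Sentinel byte appended to every document.  It is reserved: input
#: documents must not contain it.  A single shared sentinel suffices because
#: suffixes are compared over the whole concatenation.
SENTINEL = 0


class CollectionError(ValueError):
    """Raised for invalid collection inputs (empty documents, sentinel bytes)."""


@dataclass(frozen=True)
class Document:
    """One document: a 1-based identifier and its text (sentinel excluded)."""

    id: int
    text: bytes
    name: str | None = None

    def __post_init__(self) -> None:
        if len(self.text) == 0:
            raise CollectionError(f"document {self.id} is empty")
        if SENTINEL in self.text:
            raise CollectionError(
                f"document {self.id} contains the reserved sentinel byte "
                f"0x{SENTINEL:02x}"
            )


@dataclass
class Collection:
    """Ordered documents plus their sentinel-terminated concatenation."""

    documents: list[Document]
    T: bytes = field(init=False)
    n: int = field(init=False)
    d: int = field(init=False)
    B: Bitvector = field(init=False)

    def __post_init__(self) -> None:
        if not self.documents:
            raise CollectionError("collection must contain at least one document")
        parts = []
        starts = np.zeros(sum(len(doc.text) + 1 for doc in self.documents), dtype=np.uint8)
        pos = 0
        for j, doc in enumerate(self.documents, start=1):
            if doc.id != j:
                raise CollectionError("documents must be numbered 1..d in order")
            starts[pos] = 1
            pos += len(doc.text) + 1
            parts.append(doc.text)
            parts.append(bytes([SENTINEL]))
        self.T = b"".join(parts)
        self.n = len(self.T)
        self.d = len(self.documents)
        self.B = Bitvector(starts)

    def doc_of_position(self, p: int) -> int:
        """Document id containing text position ``p`` (1-based).

        Equals ``rank_1(B, p)``.
        """
        if not 1 <= p <= self.n:
            raise IndexError(f"position {p} out of range [1..{self.n}]")
        return self.B.rank(1, p)

    def doc_start(self, j: int) -> int:
        """1-based start position of document ``j`` in ``T``."""
        if not 1 <= j <= self.d:
            raise IndexError(f"document {j} out of range [1..{self.d}]")
        return self.B.select(1, j)

    def document_text(self, j: int, with_sentinel: bool = False) -> bytes:
        text = self.documents[j - 1].text
        return text + bytes([SENTINEL]) if with_sentinel else text

    def __len__(self) -> int:
        return self.d


def from_texts(texts: Iterable[bytes | str], names: Sequence[str] | None = None) -> Collection:
    """Build a collection from in-memory document texts, in order."""
    docs = []
    for j, text in enumerate(texts, start=1):
        if isinstance(text, str):
            text = text.encode("utf-8")
        name = names[j - 1] if names is not None else None
        docs.append(Document(id=j, text=bytes(text), name=name))
    return Collection(docs)


def load_collection(
    source,
    format: str = "plain",
    separator: bytes = b"\n",
) -> Collection:
    """Read a document collection.

    Parameters
    ----------
    source
        A path, a list of paths, or an open binary stream.  In ``plain``
        mode, a list of paths yields one document per file while a single
        path/stream is split into records on ``separator``.  In ``fasta``
        mode each record is one document (record order defines ids, headers
        are retained as display names).
    format
        ``"plain"`` or ``"fasta"``.
    """
    if format == "fasta":
        return _load_fasta(source)
    if format != "plain":
        raise CollectionError(f"unknown format {format!r}")
    if isinstance(source, (list, tuple)):
        texts, names = [], []
        for path in source:
            with open(path, "rb") as fh:
                texts.append(fh.read().rstrip(b"\r\n"))
            names.append(os.path.basename(os.fspath(path)))
        return from_texts(texts, names)
    if hasattr(source, "read"):
        data = source.read()
    else:
        with open(source, "rb") as fh:
            data = fh.read()
    if isinstance(data, str):
        data = data.encode("utf-8")
    records = [rec for rec in data.split(separator) if rec]
    if not records:
        raise CollectionError("no documents found in input")
    return from_texts(records)


def _load_fasta(source) -> Collection:
    from Bio import SeqIO

    if hasattr(source, "read"):
        handle = io.TextIOWrapper(source) if isinstance(source.read(0), bytes) else source
        records = list(SeqIO.parse(handle, "fasta"))
    else:
        records = list(SeqIO.parse(os.fspath(source), "fasta"))
    if not records:
        raise CollectionError("no FASTA records found in input")
    texts = [str(rec.seq).encode("ascii") for rec in records]
    names = [rec.description for rec in records]
    return from_texts(texts, names)


def write_fasta(collection: Collection, path) -> None:
    """Write the collection as uncompressed FASTA, one record per document."""
    with open(path, "w") as fh:
        for doc in collection.documents:
            header = doc.name if doc.name else f"doc{doc.id}"
            fh.write(f">{header}\n")
            fh.write(doc.text.decode("latin-1"))
            fh.write("\n")
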