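"""Embedding-based semantic retrieval.

Texts are embedded by any object satisfying :class:`EncoderContract` — a
deterministic ``encode(text) -> vector`` with a fixed output dimension.  The
production setting would plug a sentence-transformer behind this contract;
the test suite and the synthetic benchmark use the deterministic encoders in
:mod:`pubfuse.synthetic`.

Vectors live in a :class:`VectorStore`, optionally at half precision
(16-bit floats, the scalar-quantization analogue); similarity math always
runs at full precision after dequantization.  Retrieval is exact brute-force
cosine similarity with a non-negative cutoff ``t``: only documents with
``cosim >= t`` are retained (excluded, not clamped), then ranked descending.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

from .corpus import Corpus

STORE_VERSION = 1


@runtime_checkable
class EncoderContract(Protocol):
    """Deterministic text encoder with constant output dimension."""

    dim: int
    name: str

    def encode(self, text: str) -> np.ndarray:  # pragma: no cover - protocol
        ...


def cosim(q: np.ndarray, d: np.ndarray) -> float:
    """Cosine similarity q·d / (‖q‖‖d‖), in [-1, 1]; errors on zero vectors."""
    q = np.asarray(q, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    nq = np.linalg.norm(q)
    nd = np.linalg.norm(d)
    if nq == 0.0 or nd == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.dot(q, d) / (nq * nd))


class VectorStore:
    """doc_id -> embedding map with exact cosine search.

    ``precision`` is ``"full"`` (float32) or ``"half"`` (float16); half
    precision stores compressed vectors but all similarity computation
    dequantizes to float64 first.
    """

    def __init__(self, dim: int, precision: str = "full") -> None:
        if precision not in ("full", "half"):
            raise ValueError("precision must be 'full' or 'half'")
        self.dim = dim
        self.precision = precision
        self._dtype = np.float32 if precision == "full" else np.float16
        self._doc_ids: list[str] = []
        self._pos: dict[str, int] = {}
        self._rows: list[np.ndarray] = []
        self._matrix: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self._doc_ids)

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self._pos

    @property
    def doc_ids(self) -> list[str]:
        return list(self._doc_ids)

    def add(self, doc_id: str, vector: np.ndarray) -> None:
        vec = np.asarray(vector, dtype=np.float64)
        if vec.shape != (self.dim,):
            raise ValueError(f"vector for {doc_id!r} has shape {vec.shape}, want ({self.dim},)")
        if not np.all(np.isfinite(vec)):
            raise ValueError(f"vector for {doc_id!r} has non-finite entries")
        if doc_id in self._pos:
            raise ValueError(f"doc_id {doc_id!r} already in store")
        self._pos[doc_id] = len(self._doc_ids)
        self._doc_ids.append(doc_id)
        self._rows.append(vec.astype(self._dtype))
        self._matrix = None

    def get(self, doc_id: str) -> np.ndarray:
        """Dequantized (float64) vector for one document."""
        if doc_id not in self._pos:
            raise KeyError(f"doc_id {doc_id!r} not in vector store")
        return self.matrix[self._pos[doc_id]]

    @property
    def matrix(self) -> np.ndarray:
        """(n, dim) float64 matrix in insertion order (dequantized)."""
        if self._matrix is None:
            if self._rows:
                self._matrix = np.stack(self._rows).astype(np.float64)
            else:
                self._matrix = np.empty((0, self.dim), dtype=np.float64)
        return self._matrix

    def cosims(self, query_vec: np.ndarray) -> np.ndarray:
        """Cosine similarity of the query against every stored vector."""
        q = np.asarray(query_vec, dtype=np.float64)
        nq = np.linalg.norm(q)
        if nq == 0.0:
            raise ValueError("query vector has zero norm")
        mat = self.matrix
        norms = np.linalg.norm(mat, axis=1)
        # indexed texts are guaranteed non-zero-norm at build time
        return (mat @ q) / (norms * nq)

    # -- serialization: header JSON + contiguous vector bytes -----------------

    def save(self, path: str | Path) -> None:
        header = {
            "store_version": STORE_VERSION,
            "dim": self.dim,
            "precision": self.precision,
            "count": len(self),
            "doc_ids": self._doc_ids,
        }
        raw = (
            np.stack(self._rows).astype(self._dtype).tobytes()
            if self._rows
            else b""
        )
        header_bytes = json.dumps(header, ensure_ascii=False).encode("utf-8")
        with open(path, "wb") as fh:
            fh.write(len(header_bytes).to_bytes(8, "little"))
            fh.write(header_bytes)
            fh.write(raw)

    @classmethod
    def load(cls, path: str | Path) -> "VectorStore":
        with open(path, "rb") as fh:
            hlen = int.from_bytes(fh.read(8), "little")
            header = json.loads(fh.read(hlen).decode("utf-8"))
            raw = fh.read()
        if header.get("store_version") != STORE_VERSION:
            raise ValueError(
                f"vector store version {header.get('store_version')!r} "
                f"!= expected {STORE_VERSION}"
            )
        store = cls(dim=header["dim"], precision=header["precision"])
        dtype = store._dtype
        mat = np.frombuffer(raw, dtype=dtype).reshape(header["count"], header["dim"])
        for doc_id, row in zip(header["doc_ids"], mat):
            store.add(doc_id, row.astype(np.float64))
        return store


def build_vector_store(
    corpus: Corpus, encoder: EncoderContract, precision: str = "full"
) -> VectorStore:
    """Encode every record's index text (title + abstract) into a store.

    An encoder failure — including a zero-norm output, which would make
    cosine similarity undefined — raises an error naming the offending
    doc_id.
    """
    store = VectorStore(dim=encoder.dim, precision=precision)
    for rec in corpus:
        try:
            vec = np.asarray(encoder.encode(rec.index_text), dtype=np.float64)
        except Exception as exc:
            raise RuntimeError(f"encoder failed on doc_id {rec.doc_id!r}: {exc}") from exc
        if np.linalg.norm(vec) == 0.0:
            raise RuntimeError(f"encoder produced a zero vector for doc_id {rec.doc_id!r}")
        store.add(rec.doc_id, vec)
    return store


def semantic_search(
    query_vec: np.ndarray,
    store: VectorStore,
    t_cutoff: float = 0.0,
    top_m: int = 1000,
) -> list[tuple[str, float]]:
    """Exact cosine retrieval with cutoff ``t``.

    Documents with ``cosim >= t_cutoff`` are kept (those below are excluded,
    not clamped), sorted descending with lexicographic doc_id tie-break, and
    truncated to ``top_m``.  Filtering happens before truncation.
    """
    if t_cutoff < 0:
        raise ValueError("t_cutoff must be non-negative")
    if top_m < 1:
        raise ValueError("top_m must be >= 1")
    if len(store) == 0:
        return []
    sims = store.cosims(query_vec)
    ids = store.doc_ids
    hits = [(ids[i], float(sims[i])) for i in np.flatnonzero(sims >= t_cutoff)]
    hits.sort(key=lambda h: (-h[1], h[0]))
    return hits[:top_m]


__all__ = [
    "STORE_VERSION",
    "EncoderContract",
    "VectorStore",
    "cosim",
    "build_vector_store",
    "semantic_search",
]
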