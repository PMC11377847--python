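"""Text-to-vector encoding and nearest-neighbour retrieval.

Every harmonization step compares free text against a catalog of labels by
encoding both into vectors and taking cosine similarity.  Production
deployments plug in a trained biomedical sentence encoder through
:func:`register_encoder`; the built-in ``fallback`` encoder is a hashed
character-trigram model that is fully deterministic across platforms, so the
whole pipeline is testable offline with no model weights.

The fallback encoder lowercases and whitespace-normalizes the text, pads it
with a single space on each side, hashes every character trigram (keyed
BLAKE2b, fixed key) into 256 buckets, and L2-normalizes the bucket counts.
Identical strings therefore always map to identical vectors.
"""

from __future__ import annotations

import hashlib
from typing import Iterable, Protocol, runtime_checkable

import numpy as np

__all__ = [
    "EncoderContract",
    "TrigramEncoder",
    "EncoderError",
    "cosine",
    "fallback_encode",
    "top_k_similar",
    "register_encoder",
    "get_encoder",
    "available_encoders",
]


class EncoderError(ValueError):
    """Violation of the encoder contract (e.g. dimension mismatch)."""


@runtime_checkable
class EncoderContract(Protocol):
    """Minimal contract a pluggable encoder must satisfy.

    ``encode`` must be a pure function: the same text always yields the same
    vector, and the dimension is constant per encoder instance.
    """

    dimension: int

    def encode(self, text: str) -> np.ndarray: ...


class TrigramEncoder:
    """Deterministic hashed character-trigram encoder (the ``fallback``)."""

    #: Fixed hashing key; changing it changes every vector, so it is part of
    #: the on-disk compatibility contract.
    HASH_KEY = b"claimtriage-trigram-v1"

    def __init__(self, dimension: int = 256) -> None:
        if dimension < 1:
            raise EncoderError("dimension must be >= 1")
        self.dimension = dimension
        self._cache: dict[str, np.ndarray] = {}

    @staticmethod
    def normalize(text: str) -> str:
        return " ".join(text.lower().split())

    def _bucket(self, gram: str) -> int:
        digest = hashlib.blake2b(
            gram.encode("utf-8"), digest_size=8, key=self.HASH_KEY
        ).digest()
        return int.from_bytes(digest, "big") % self.dimension

    def encode(self, text: str) -> np.ndarray:
        cached = self._cache.get(text)
        if cached is not None:
            return cached
        norm = self.normalize(text)
        vec = np.zeros(self.dimension, dtype=np.float64)
        if norm:
            padded = f" {norm} "
            grams = (
                [padded[i : i + 3] for i in range(len(padded) - 2)]
                if len(padded) >= 3
                else [padded]
            )
            for gram in grams:
                vec[self._bucket(gram)] += 1.0
            n = np.linalg.norm(vec)
            if n > 0:
                vec /= n
        vec.setflags(write=False)
        self._cache[text] = vec
        return vec


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity; 0.0 when either vector has zero norm."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise EncoderError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    # guard against floating-point drift just past +/-1
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


# -- encoder registry ------------------------------------------------------

_ENCODERS: dict = {}


def register_encoder(name: str, factory) -> None:
    """Register an encoder factory under ``name`` for config-file selection."""
    _ENCODERS[name] = factory


def get_encoder(name: str = "fallback") -> EncoderContract:
    try:
        factory = _ENCODERS[name]
    except KeyError:
        raise EncoderError(
            f"unknown encoder {name!r}; registered: {sorted(_ENCODERS)}"
        ) from None
    return factory()


def available_encoders() -> list:
    return sorted(_ENCODERS)


# A single shared fallback instance so the embedding cache persists across
# queries (encode is pure, so sharing is safe).
_FALLBACK = TrigramEncoder()
register_encoder("fallback", lambda: _FALLBACK)


def fallback_encode(text: str) -> np.ndarray:
    """Encode with the built-in trigram fallback encoder."""
    return _FALLBACK.encode(text)


def top_k_similar(
    query_text: str,
    catalog: Iterable,
    k: int,
    min_similarity: float = 0.0,
    encoder: EncoderContract | None = None,
) -> list:
    """Rank catalog items ``(id, label)`` by similarity to ``query_text``.

    Returns at most ``k`` pairs ``(id, similarity)`` with similarity >=
    ``min_similarity``, sorted by similarity descending with ties broken by
    id ascending.
    """
    if k < 1:
        raise EncoderError("k must be >= 1")
    if not (0.0 <= min_similarity <= 1.0):
        raise EncoderError("min_similarity must be in [0, 1]")
    encoder = encoder or get_encoder("fallback")
    q = encoder.encode(query_text)
    scored = []
    for item_id, label in catalog:
        sim = cosine(q, encoder.encode(label))
        if sim >= min_similarity:
            scored.append((item_id, sim))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[:k]
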