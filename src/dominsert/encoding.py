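"""Per-residue sequence encodings.

The classifier head consumes an ``L x D`` matrix of per-residue features.
Three sources are supported behind one provider contract:

* a one-hot baseline over the 20 canonical amino acids (D = 20);
* external protein language-model embeddings (e.g. an ESM-2 3B service with
  D = 2560), plugged in by implementing :class:`EmbeddingProvider`;
* a deterministic *fixture* embedder for tests: it hashes each residue's
  local 5-mer context into a pseudo-random ``D``-vector, so planted
  sequence motifs are learnable without any model download.

Providers must return exactly one row per residue — encoders that emit
begin/end special tokens have to strip them before returning.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

from .corpus import CANONICAL_AA

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}


class EncodingError(ValueError):
    pass


@dataclass(frozen=True)
class EncodedSequence:
    """An ``L x D`` per-residue feature matrix for one sequence."""

    accession: str
    matrix: np.ndarray
    encoder_id: str

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2:
            raise EncodingError("encoding matrix must be 2-D (L x D)")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def dimension(self) -> int:
        return self.matrix.shape[1]


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Contract for per-residue embedding sources.

    Implementations must be deterministic for a fixed sequence and return
    a float matrix with exactly ``len(sequence)`` rows and ``dimension``
    columns.
    """

    encoder_id: str
    dimension: int

    def embed(self, sequence: str) -> np.ndarray: ...


# ---------------------------------------------------------------------------
# One-hot baseline
# ---------------------------------------------------------------------------


def one_hot_encode(
    sequence: str,
    accession: str = "",
    strict: bool = True,
) -> EncodedSequence:
    """One-hot over the canonical amino acids, columns alphabetical (A..Y).

    In strict mode a non-canonical character raises, naming its position;
    otherwise it yields an all-zero row.
    """
    L = len(sequence)
    matrix = np.zeros((L, 20), dtype=np.float32)
    for i, aa in enumerate(sequence):
        col = _AA_INDEX.get(aa)
        if col is None:
            if strict:
                raise EncodingError(
                    f"non-canonical residue {aa!r} at position {i}"
                    + (f" of {accession}" if accession else "")
                )
            continue
        matrix[i, col] = 1.0
    return EncodedSequence(accession, matrix, "onehot")


class OneHotProvider:
    """One-hot encoding exposed through the provider contract."""

    encoder_id = "onehot"
    dimension = 20

    def __init__(self, strict: bool = True):
        self.strict = strict

    def embed(self, sequence: str) -> np.ndarray:
        return one_hot_encode(sequence, strict=self.strict).matrix


# ---------------------------------------------------------------------------
# Deterministic fixture embedder
# ---------------------------------------------------------------------------


class FixtureEmbedder:
    """Seeded k-mer-context embedder for tests and pipeline rehearsal.

    Each position's row is the (scaled) sum of pseudo-random basis vectors
    keyed by ``(residue, offset)`` over a centred window of k residues
    (offsets -(k//2)..k//2); positions hanging over a sequence end
    contribute a per-side boundary symbol instead. Consequences used by the
    tests: identical k-mer contexts give identical rows; rows carry local
    context, so a planted junction motif is linearly separable; and the
    whole map is a pure function of (seed, sequence).
    """

    def __init__(self, dimension: int = 64, seed: int = 0, k: int = 5):
        if dimension < 1:
            raise EncodingError("dimension must be >= 1")
        if k < 1 or k % 2 == 0:
            raise EncodingError("window size k must be a positive odd number")
        self.dimension = dimension
        self.seed = seed
        self.k = k
        self.encoder_id = f"fixture-d{dimension}-k{k}-s{seed}"
        rng = np.random.default_rng(seed)
        # alphabet: 20 canonical residues + left/right boundary symbols
        self._basis = rng.standard_normal((k, 22, dimension)).astype(
            np.float64
        )

    def embed(self, sequence: str) -> np.ndarray:
        L = len(sequence)
        half = self.k // 2
        idx = np.empty(L, dtype=np.intp)
        for i, aa in enumerate(sequence):
            col = _AA_INDEX.get(aa)
            if col is None:
                raise EncodingError(
                    f"non-canonical residue {aa!r} at position {i}"
                )
            idx[i] = col
        rows = np.zeros((L, self.dimension))
        for w, off in enumerate(range(-half, half + 1)):
            pos = np.arange(L) + off
            sym = np.where(
                pos < 0, 20, np.where(pos >= L, 21, idx[np.clip(pos, 0, L - 1)])
            )
            rows += self._basis[w, sym, :]
        return (rows / np.sqrt(self.k)).astype(np.float32)


def fixture_embedder(
    dimension: int = 64, seed: int = 0, k: int = 5
) -> FixtureEmbedder:
    return FixtureEmbedder(dimension=dimension, seed=seed, k=k)


# ---------------------------------------------------------------------------
# Provider plumbing and on-disk cache
# ---------------------------------------------------------------------------


def _sequence_digest(sequence: str) -> str:
    return hashlib.sha256(sequence.encode("ascii")).hexdigest()


def encode_with_provider(
    sequence: str,
    provider: EmbeddingProvider,
    accession: str = "",
    cache_dir: str | Path | None = None,
) -> EncodedSequence:
    """Run a provider, with an optional on-disk cache.

    The cache is keyed by (encoder_id, sequence hash); each entry is a
    ``.npy`` matrix plus a JSON sidecar recording the encoder, dimension
    and hash. Cache hits return bitwise-identical matrices. A provider
    returning the wrong number of rows (the classic special-token bug)
    raises immediately.
    """
    digest = _sequence_digest(sequence)
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        stem = cache_dir / f"{provider.encoder_id}_{digest[:24]}"
        npy, sidecar = stem.with_suffix(".npy"), stem.with_suffix(".json")
        if npy.exists() and sidecar.exists():
            meta = json.loads(sidecar.read_text())
            if (
                meta["encoder_id"] == provider.encoder_id
                and meta["sequence_sha256"] == digest
            ):
                return EncodedSequence(
                    accession, np.load(npy), provider.encoder_id
                )

    try:
        matrix = np.asarray(provider.embed(sequence))
    except Exception as exc:
        raise EncodingError(
            f"provider {provider.encoder_id} failed on "
            f"{accession or 'sequence'}: {exc}"
        ) from exc
    if matrix.shape != (len(sequence), provider.dimension):
        raise EncodingError(
            f"provider {provider.encoder_id} returned shape {matrix.shape} "
            f"for a {len(sequence)}-residue sequence (expected "
            f"({len(sequence)}, {provider.dimension})); special tokens "
            "must be stripped"
        )

    if cache_dir is not None:
        cache_dir.mkdir(parents=True, exist_ok=True)
        np.save(npy, matrix)
        sidecar.write_text(
            json.dumps(
                {
                    "encoder_id": provider.encoder_id,
                    "dimension": provider.dimension,
                    "sequence_sha256": digest,
                    "length": len(sequence),
                },
                indent=1,
            )
        )
    return EncodedSequence(accession, matrix, provider.encoder_id)
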