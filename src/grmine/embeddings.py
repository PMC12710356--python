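"""Frozen protein-embedding backends.

The classifier head never trains its feature extractor: a backend is a
deterministic map from an amino-acid sequence to an L x dim matrix of
per-residue vectors, mirroring a frozen protein language model. The
default desk-scale backend embeds each residue as a seeded random
projection of the one-hot k-mer window centred on it, which gives the
head local compositional and positional signal without any download.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

# 20 amino acids + X (unknown) + sentinel '^' for window padding
_STUB_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX^"
_STUB_INDEX = {ch: i for i, ch in enumerate(_STUB_ALPHABET)}


@dataclass(frozen=True)
class EmbeddingBackend:
    """A frozen residue-embedding function: sequence -> (L, dim) matrix."""

    name: str
    dim: int
    embed_fn: Callable[[str], np.ndarray]

    def embed(self, sequence: str) -> np.ndarray:
        if not sequence:
            raise ValueError("cannot embed an empty sequence")
        matrix = self.embed_fn(sequence)
        if matrix.shape != (len(sequence), self.dim):
            raise AssertionError(
                f"backend {self.name} returned shape {matrix.shape}, "
                f"expected ({len(sequence)}, {self.dim})"
            )
        return matrix


@dataclass(frozen=True)
class ResidueEmbeddings:
    """Per-residue embedding matrix for one sequence."""

    sequence_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[0] < 1:
            raise ValueError("embedding matrix must be (L >= 1, dim)")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(f"{self.sequence_id}: non-finite embedding entries")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


def kmer_stub_backend(k: int = 3, dim: int = 32, seed: int = 0) -> EmbeddingBackend:
    """Deterministic stand-in for a protein-language-model backbone.

    Each residue's vector is a fixed pseudo-random linear projection
    (Gaussian, seeded) of the one-hot encoding of the k-mer window centred
    at that residue; windows at the boundary are padded with a sentinel
    letter. Identical (k, dim, seed) always yields identical embeddings.

    Parameters
    ----------
    k:
        Window size, 1..4. With k=1 pooled embeddings depend only on
        residue composition; k>=2 makes them order-sensitive.
    dim:
        Output embedding dimension (>= 8).
    seed:
        Seed for the projection matrix.
    """
    if not 1 <= k <= 4:
        raise ValueError("k must be in 1..4")
    if dim < 8:
        raise ValueError("dim must be >= 8")
    n_letters = len(_STUB_ALPHABET)
    rng = np.random.default_rng(seed)
    # one projection row per (position in window, letter)
    projection = rng.standard_normal((k * n_letters, dim)) / np.sqrt(k)
    pad = k // 2

    def embed_fn(sequence: str) -> np.ndarray:
        padded = "^" * pad + sequence + "^" * (k - 1 - pad)
        idx = np.array([_STUB_INDEX.get(ch, _STUB_INDEX["X"]) for ch in padded])
        length = len(sequence)
        out = np.zeros((length, dim))
        for offset in range(k):
            rows = idx[offset : offset + length]
            out += projection[offset * n_letters + rows]
        return out

    return EmbeddingBackend(name=f"kmer_stub(k={k},dim={dim},seed={seed})", dim=dim, embed_fn=embed_fn)


def mean_pool(embeddings: ResidueEmbeddings) -> np.ndarray:
    """Arithmetic mean of the per-residue vectors (dim-vector)."""
    return embeddings.matrix.mean(axis=0)
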