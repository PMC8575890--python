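"""Shared low-level helpers: edge vectorization, seeding, z-transform."""

from __future__ import annotations

import numpy as np

__all__ = [
    "triu_index",
    "vectorize_matrix",
    "devectorize",
    "fisher_z",
    "inverse_fisher_z",
    "child_rngs",
    "n_edges",
]


def n_edges(n_parcels: int) -> int:
    """Number of unique off-diagonal edges among ``n_parcels`` regions."""
    return n_parcels * (n_parcels - 1) // 2


def triu_index(n_parcels: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical edge ordering: upper triangle, row-major, 0-based, no diagonal.

    This single ordering is shared by every module that touches edge space
    (feature vectors, component maps, network-cell assignment).
    """
    return np.triu_indices(n_parcels, k=1)


def vectorize_matrix(mat: np.ndarray) -> np.ndarray:
    """Extract the upper-triangle feature vector of a symmetric matrix."""
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {mat.shape}")
    i, j = triu_index(mat.shape[0])
    return mat[i, j].copy()


def devectorize(vec: np.ndarray, n_parcels: int, diag: float = 0.0) -> np.ndarray:
    """Rebuild a symmetric matrix from an edge vector (diagonal set to ``diag``)."""
    vec = np.asarray(vec)
    if vec.shape[-1] != n_edges(n_parcels):
        raise ValueError(
            f"edge vector of length {vec.shape[-1]} does not match "
            f"{n_parcels} parcels ({n_edges(n_parcels)} edges expected)"
        )
    out = np.full((n_parcels, n_parcels), 0.0)
    i, j = triu_index(n_parcels)
    out[i, j] = vec
    out[j, i] = vec
    np.fill_diagonal(out, diag)
    return out


_CLIP = 1.0 - 1e-7


def fisher_z(values: np.ndarray) -> np.ndarray:
    """Fisher variance-stabilizing transform, atanh(r), with |r| clipped at 1-1e-7.

    Accepts either edge vectors or full matrices; for matrices the diagonal is
    left untouched at 0 after transforming off-diagonals.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 2 and arr.shape[0] == arr.shape[1]:
        out = np.arctanh(np.clip(arr, -_CLIP, _CLIP))
        np.fill_diagonal(out, 0.0)
        return out
    return np.arctanh(np.clip(arr, -_CLIP, _CLIP))


def inverse_fisher_z(values: np.ndarray) -> np.ndarray:
    return np.tanh(np.asarray(values, dtype=float))


def child_rngs(seed: int | np.random.Generator, n: int) -> list[np.random.Generator]:
    """Spawn ``n`` independent generators from one root seed."""
    if isinstance(seed, np.random.Generator):
        ss = seed.bit_generator.seed_seq  # type: ignore[attr-defined]
        return [np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(n)]
    ss = np.random.SeedSequence(seed)
    return [np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(n)]
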