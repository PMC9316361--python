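"""Heterogeneous miRNA-disease graph assembly and spectral normalization.

The heterogeneous graph stacks two intra-type similarity networks (miRNA
functional similarity SM, disease semantic similarity SD) with the bipartite
association matrix A into one adjacency over both node types::

    A_H = [[SM, A  ],
           [A^T, SD]]

miRNAs occupy indices ``0..m-1`` and diseases ``m..m+n-1``; this ordering is
fixed across all modules.  The propagation operator fed to the GCN is the
symmetrically normalized adjacency ``D^{-1/2} A_H D^{-1/2}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SimilarityMatrix",
    "AssociationData",
    "HeteroAdjacency",
    "NormalizedAdjacency",
    "LaplacianMatrix",
    "build_hetero_adjacency",
    "symmetric_normalize",
    "normalized_laplacian",
]

_SYM_TOL = 1e-9


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix in [0, 1] with unit diagonal.

    Parameters
    ----------
    values
        ``(k, k)`` array of pairwise similarities.
    names
        Ordered node labels, one per row/column.
    """

    values: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"similarity matrix must be square, got {self.values.shape}")
        k = self.values.shape[0]
        if not self.names:
            self.names = [f"node{i}" for i in range(k)]
        if len(self.names) != k:
            raise ValueError(f"{len(self.names)} names for a {k}x{k} matrix")
        if not np.allclose(self.values, self.values.T, atol=_SYM_TOL, rtol=0.0):
            raise ValueError("similarity matrix is not symmetric within 1e-9")
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise ValueError("similarity values must lie in [0, 1]")
        if not np.allclose(np.diag(self.values), 1.0, atol=_SYM_TOL):
            raise ValueError("similarity diagonal must equal 1")

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass
class AssociationData:
    """Binary miRNA-disease association matrix with name indices.

    ``positives`` holds the verified pairs y = {(i, j): A[i, j] = 1};
    ``unknowns`` the complement y^- (candidate pairs in the ranking
    protocols, negative samples in the loss).
    """

    matrix: np.ndarray
    mirna_names: list[str] = field(default_factory=list)
    disease_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("association matrix must be 2-D")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        self.matrix = self.matrix.astype(np.int8)
        m, n = self.matrix.shape
        if not self.mirna_names:
            self.mirna_names = [f"mirna{i}" for i in range(m)]
        if not self.disease_names:
            self.disease_names = [f"disease{j}" for j in range(n)]
        if len(self.mirna_names) != m:
            raise ValueError(f"{len(self.mirna_names)} miRNA names for {m} rows")
        if len(self.disease_names) != n:
            raise ValueError(f"{len(self.disease_names)} disease names for {n} columns")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    @property
    def positives(self) -> list[tuple[int, int]]:
        return [tuple(p) for p in np.argwhere(self.matrix == 1)]

    @property
    def unknowns(self) -> list[tuple[int, int]]:
        return [tuple(p) for p in np.argwhere(self.matrix == 0)]

    def masked(self, pairs: Sequence[tuple[int, int]]) -> "AssociationData":
        """Return a copy with the given positive pairs set to 0 (held out)."""
        out = self.matrix.copy()
        for i, j in pairs:
            out[i, j] = 0
        return AssociationData(out, list(self.mirna_names), list(self.disease_names))


@dataclass
class HeteroAdjacency:
    """(m+n)x(m+n) block adjacency of the heterogeneous graph."""

    values: np.ndarray
    m: int
    n: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = self.m + self.n
        if self.values.shape != (k, k):
            raise ValueError(
                f"adjacency shape {self.values.shape} inconsistent with m={self.m}, n={self.n}"
            )


@dataclass
class NormalizedAdjacency:
    """Symmetrically normalized adjacency D^{-1/2} A_H D^{-1/2}."""

    values: np.ndarray
    degrees: np.ndarray


@dataclass
class LaplacianMatrix:
    """Symmetric normalized Laplacian: I - D^{-1/2} A D^{-1/2} on the support."""

    values: np.ndarray


def _as_array(adj: HeteroAdjacency | np.ndarray) -> np.ndarray:
    return adj.values if isinstance(adj, HeteroAdjacency) else np.asarray(adj, dtype=float)


def build_hetero_adjacency(
    sm: SimilarityMatrix, sd: SimilarityMatrix, assoc: AssociationData
) -> HeteroAdjacency:
    """Assemble the block matrix ``[[SM, A], [A^T, SD]]``.

    Raises
    ------
    ValueError
        if the similarity sizes do not match the association matrix shape.
    """
    m, n = assoc.shape
    if sm.size != m:
        raise ValueError(f"SM is {sm.size}x{sm.size} but association matrix has {m} miRNA rows")
    if sd.size != n:
        raise ValueError(f"SD is {sd.size}x{sd.size} but association matrix has {n} disease columns")
    a = assoc.matrix.astype(float)
    top = np.hstack([sm.values, a])
    bottom = np.hstack([a.T, sd.values])
    return HeteroAdjacency(np.vstack([top, bottom]), m=m, n=n)


def _degree_invsqrt(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if adj.min() < 0:
        raise ValueError("adjacency must be nonnegative")
    deg = adj.sum(axis=1)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    return deg, inv_sqrt


def symmetric_normalize(adj: HeteroAdjacency | np.ndarray) -> NormalizedAdjacency:
    """Return ``D^{-1/2} A D^{-1/2}`` with D = diag(row sums).

    Zero-degree rows/columns map to zero: an isolated node neither sends nor
    receives propagation mass.
    """
    a = _as_array(adj)
    deg, inv_sqrt = _degree_invsqrt(a)
    return NormalizedAdjacency(values=inv_sqrt[:, None] * a * inv_sqrt[None, :], degrees=deg)


def normalized_laplacian(adj: HeteroAdjacency | np.ndarray) -> LaplacianMatrix:
    """Symmetric normalized Laplacian.

    Diagonal entries are 1 on nodes of nonzero degree and 0 on isolated
    nodes; off-diagonal entries are ``-A[i, j] / sqrt(d_i d_j)``.  All
    eigenvalues lie in [0, 2].
    """
    a = _as_array(adj)
    norm = symmetric_normalize(a)
    off = norm.values.copy()
    np.fill_diagonal(off, 0.0)
    lap = np.diag(np.where(norm.degrees > 0, 1.0, 0.0)) - off
    return LaplacianMatrix(values=lap)
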