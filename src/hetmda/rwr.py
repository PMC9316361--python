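"""Random-walk-with-restart node features.

Raw similarity rows are noisy feature vectors: similarity computation is
itself an estimate.  Propagating each node's indicator vector through the
similarity network with a restart,

    r^{k+1} = c W r^k + (1 - c) e_i,

and taking the stationary distribution as that node's feature vector smooths
the raw similarities with the global network structure.  ``W`` is the
column-stochastic transition matrix obtained from the similarity matrix, and
``c`` is the probability of continuing the walk (so ``1 - c`` is the restart
mass returned to the seed each step).  The fixed point has the closed form
``(1 - c)(I - cW)^{-1} e_i``, which converges since ``c < 1``.

Per-type feature matrices RM (miRNA) and RD (disease) are stacked into the
combined feature matrix ``A_F``, block-diagonal by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import SimilarityMatrix

__all__ = [
    "RestartConfig",
    "TransitionMatrix",
    "FeatureMatrix",
    "CombinedFeatures",
    "make_transition",
    "rwr_solve",
    "rwr_feature_matrix",
    "build_feature_matrix",
]


@dataclass
class RestartConfig:
    """Restart-walk parameters.

    Attributes
    ----------
    c
        Walk-continuation probability in (0, 1); the walker restarts at the
        seed with probability ``1 - c`` each step.
    tol
        L1 convergence tolerance on successive iterates.
    max_iter
        Iteration cap; exceeding it raises ``RuntimeError``.
    """

    c: float = 0.5
    tol: float = 1e-8
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.c < 1.0:
            raise ValueError(f"restart parameter c must be in (0, 1), got {self.c}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class TransitionMatrix:
    """Column-stochastic transition matrix: W[i, j] is the flow j -> i."""

    values: np.ndarray


@dataclass
class FeatureMatrix:
    """Row-normalized stationary RWR scores; row i is the profile seeded at i."""

    values: np.ndarray


@dataclass
class CombinedFeatures:
    """(m+n)x(m+n) combined feature matrix A_F."""

    values: np.ndarray
    m: int
    n: int
    placement: str = "diagonal"


def make_transition(sim: SimilarityMatrix | np.ndarray) -> TransitionMatrix:
    """Column-normalize a similarity matrix into a transition matrix.

    Columns summing to zero (a node nobody is similar to) fall back to the
    uniform distribution so W stays stochastic.
    """
    s = sim.values if isinstance(sim, SimilarityMatrix) else np.asarray(sim, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("similarity must be a square matrix")
    if s.min() < 0:
        raise ValueError("similarity must be nonnegative")
    col_sums = s.sum(axis=0)
    if np.all(col_sums == 0):
        raise ValueError("all-zero similarity matrix has no transition structure")
    k = s.shape[0]
    w = np.empty_like(s)
    nz = col_sums > 0
    w[:, nz] = s[:, nz] / col_sums[nz]
    w[:, ~nz] = 1.0 / k
    return TransitionMatrix(values=w)


def rwr_solve(w: TransitionMatrix | np.ndarray, seed_index: int, cfg: RestartConfig) -> np.ndarray:
    """Iterate the restart walk from one seed until the L1 residual < tol.

    Returns the converged probability vector (sums to 1 within tol).
    """
    wm = w.values if isinstance(w, TransitionMatrix) else np.asarray(w, dtype=float)
    k = wm.shape[0]
    if not 0 <= seed_index < k:
        raise IndexError(f"seed index {seed_index} out of range for {k} nodes")
    e = np.zeros(k)
    e[seed_index] = 1.0
    r = e.copy()
    for _ in range(cfg.max_iter):
        r_next = cfg.c * (wm @ r) + (1.0 - cfg.c) * e
        resid = np.abs(r_next - r).sum()
        r = r_next
        if resid < cfg.tol:
            return r
    raise RuntimeError(
        f"restart walk did not converge in {cfg.max_iter} iterations (residual {resid:.3e})"
    )


def rwr_feature_matrix(
    sim: SimilarityMatrix | np.ndarray, cfg: RestartConfig | None = None
) -> FeatureMatrix:
    """Stationary RWR profile for every seed, one row per node, row-normalized.

    All seeds are iterated simultaneously (the restart vectors form the
    identity), which is equivalent to per-seed ``rwr_solve``.
    """
    cfg = cfg or RestartConfig()
    w = make_transition(sim).values
    k = w.shape[0]
    eye = np.eye(k)
    r = eye.copy()  # column s is the walk seeded at s
    for _ in range(cfg.max_iter):
        r_next = cfg.c * (w @ r) + (1.0 - cfg.c) * eye
        resid = np.abs(r_next - r).sum(axis=0).max()
        r = r_next
        if resid < cfg.tol:
            break
    else:
        raise RuntimeError(
            f"restart walk did not converge in {cfg.max_iter} iterations (residual {resid:.3e})"
        )
    feats = r.T  # row i: profile seeded at i
    row_sums = feats.sum(axis=1, keepdims=True)
    return FeatureMatrix(values=feats / row_sums)


def build_feature_matrix(
    rm: FeatureMatrix | np.ndarray,
    rd: FeatureMatrix | np.ndarray,
    placement: str = "diagonal",
) -> CombinedFeatures:
    """Stack RM and RD into the (m+n)x(m+n) combined feature matrix.

    ``placement="diagonal"`` (default) puts each type's propagation profile
    on its own block: ``[[RM, 0], [0, RD]]``.  ``placement="off_diagonal"``
    zero-pads RM and RD into the cross-type blocks instead (only possible
    representation of the alternative layout; requires padding since the
    blocks are m×n and n×m).
    """
    rm_v = rm.values if isinstance(rm, FeatureMatrix) else np.asarray(rm, dtype=float)
    rd_v = rd.values if isinstance(rd, FeatureMatrix) else np.asarray(rd, dtype=float)
    m, n = rm_v.shape[0], rd_v.shape[0]
    if rm_v.shape != (m, m) or rd_v.shape != (n, n):
        raise ValueError("RM and RD must be square")
    out = np.zeros((m + n, m + n))
    if placement == "diagonal":
        out[:m, :m] = rm_v
        out[m:, m:] = rd_v
    elif placement == "off_diagonal":
        c = min(m, n)  # blocks are m×n / n×m: truncate or zero-pad columns
        out[:m, m : m + c] = rm_v[:, :c]
        out[m:, :c] = rd_v[:, :c]
    else:
        raise ValueError(f"unknown placement {placement!r}")
    return CombinedFeatures(values=out, m=m, n=n, placement=placement)
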