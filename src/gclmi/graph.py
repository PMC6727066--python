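"""Block-matrix assembly and the spectral graph-convolution filter.

The bipartite interaction matrix ``M`` (n_lnc x n_mir) is expanded into a
symmetric block adjacency ``A = [[0, M], [M^T, 0]]`` over the union of both
node sets, and the two feature tables are stacked block-diagonally into
``X``. Features are then smoothed over the one-hop neighbourhood with a
first-order spectral filter ``S``, giving the convolved matrix ``G = S X``.

Two filter dialects are provided:

* ``"renormalized"`` (default) -- ``S = D~^{-1/2} (A + I) D~^{-1/2}`` where
  ``D~`` is the degree matrix of ``A + I`` (the standard renormalization
  trick; eigenvalues of ``S`` lie in [-1, 1]).
* ``"plain"`` -- ``S = I + D^{-1/2} A D^{-1/2}`` with the convention that
  zero-degree nodes contribute ``D_ii^{-1/2} = 0``.

Both coincide with the identity filter on an edgeless graph.
"""

from __future__ import annotations

import numpy as np

DIALECTS = ("renormalized", "plain")


def assemble_feature_block(F_l: np.ndarray, F_m: np.ndarray) -> np.ndarray:
    """Stack lncRNA and miRNA features into one block-diagonal matrix.

    Returns ``X`` of shape (n_lnc + n_mir, d_lnc + d_mir) with ``F_l`` in
    the top-left block, ``F_m`` in the bottom-right block and zeros
    elsewhere; lncRNA rows come first.
    """
    F_l = np.asarray(F_l, dtype=float)
    F_m = np.asarray(F_m, dtype=float)
    if not (np.isfinite(F_l).all() and np.isfinite(F_m).all()):
        raise ValueError("feature matrices must be finite")
    n_l, d_l = F_l.shape
    n_m, d_m = F_m.shape
    X = np.zeros((n_l + n_m, d_l + d_m))
    X[:n_l, :d_l] = F_l
    X[n_l:, d_l:] = F_m
    return X


def assemble_adjacency_block(M: np.ndarray) -> np.ndarray:
    """Expand a bipartite matrix into the symmetric block adjacency.

    ``A = [[0, M], [M^T, 0]]``: lncRNA nodes occupy the first ``n_lnc``
    rows/columns, miRNA nodes the rest. ``A`` is symmetric with zero
    diagonal and zero within-type blocks.
    """
    M = np.asarray(M, dtype=float)
    n_l, n_m = M.shape
    A = np.zeros((n_l + n_m, n_l + n_m))
    A[:n_l, n_l:] = M
    A[n_l:, :n_l] = M.T
    return A


def normalize_adjacency(A: np.ndarray, dialect: str = "renormalized") -> np.ndarray:
    """Build the symmetric convolution filter ``S`` from an adjacency.

    Parameters
    ----------
    A : ndarray
        Symmetric nonnegative adjacency (zero diagonal for bipartite use).
    dialect : {"renormalized", "plain"}
        Filter form; see module docstring.
    """
    A = np.asarray(A, dtype=float)
    if A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if (A < 0).any():
        raise ValueError("adjacency must be nonnegative")
    n = A.shape[0]
    if dialect == "renormalized":
        A_tilde = A + np.eye(n)
        d = A_tilde.sum(axis=1)
        inv_sqrt = 1.0 / np.sqrt(d)  # d >= 1 always thanks to the self-loop
        S = inv_sqrt[:, None] * A_tilde * inv_sqrt[None, :]
    elif dialect == "plain":
        d = A.sum(axis=1)
        inv_sqrt = np.zeros_like(d)
        nz = d > 0
        inv_sqrt[nz] = 1.0 / np.sqrt(d[nz])
        S = np.eye(n) + inv_sqrt[:, None] * A * inv_sqrt[None, :]
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    return S


def graph_convolve(S: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Apply the filter on the node axis: ``G = S @ X``.

    Row ``i`` of ``G`` is the filter-weighted mix of the feature rows of
    node ``i``'s (self-looped) neighbourhood.
    """
    S = np.asarray(S, dtype=float)
    X = np.asarray(X, dtype=float)
    if S.shape[1] != X.shape[0]:
        raise ValueError(
            f"filter columns ({S.shape[1]}) must match feature rows ({X.shape[0]})"
        )
    return S @ X


def row_normalize(X: np.ndarray) -> np.ndarray:
    """Optional L1 row normalization of the feature block (off by default:
    the model is designed to consume raw expression values)."""
    X = np.asarray(X, dtype=float)
    norms = np.abs(X).sum(axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return X / norms


def convolved_features(
    M: np.ndarray,
    F_l: np.ndarray,
    F_m: np.ndarray,
    dialect: str = "renormalized",
    row_normalize_features: bool = False,
) -> np.ndarray:
    """Convenience pipeline: assemble blocks, normalize, convolve.

    Returns ``G`` of shape (n_lnc + n_mir, d_lnc + d_mir).
    """
    X = assemble_feature_block(F_l, F_m)
    if row_normalize_features:
        X = row_normalize(X)
    A = assemble_adjacency_block(M)
    S = normalize_adjacency(A, dialect=dialect)
    return graph_convolve(S, X)
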