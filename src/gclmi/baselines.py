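"""Similarity- and factorization-based comparison predictors.

Five standard link-prediction baselines, all producing an n_lnc x n_mir
score matrix from the training interactions (and, for the neighbour
methods, a Pearson-correlation similarity of expression profiles):

* lncRNA-based and miRNA-based neighbour collaborative filtering,
* truncated-SVD reconstruction,
* the Katz index on the bipartite block graph,
* a basic latent factor model trained with the same masked loss and
  negative sampling as the auto-encoder.

The neighbour CF normalises by the sum of absolute similarities so that
anticorrelated profiles still carry signal (with negative weight) rather
than being discarded.
"""

from __future__ import annotations

import numpy as np

from .model import AdamState, sample_negatives


def pearson_similarity(F: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation matrix of a feature table.

    Rows with zero variance get similarity 0 to every other row and 1 to
    themselves. Requires at least two feature columns.
    """
    F = np.asarray(F, dtype=float)
    if F.shape[1] < 2:
        raise ValueError("Pearson similarity needs >= 2 feature columns")
    sd = F.std(axis=1)
    ok = sd > 0
    S = np.zeros((F.shape[0], F.shape[0]))
    if ok.sum() >= 1:
        C = np.corrcoef(F[ok])
        C = np.atleast_2d(C)
        S[np.ix_(ok, ok)] = C
    np.fill_diagonal(S, 1.0)
    return np.clip(S, -1.0, 1.0)


def neighbor_cf_scores(M: np.ndarray, sim: np.ndarray, axis: str = "lnc") -> np.ndarray:
    """Neighbour collaborative filtering over one node type.

    ``axis="lnc"``: score(i, j) = sum_{i'!=i} sim(i,i') M(i',j) /
    sum_{i'!=i} |sim(i,i')| (0 when the denominator is 0);
    ``axis="mir"`` is the symmetric formula over columns.
    """
    M = np.asarray(M, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if axis not in ("lnc", "mir"):
        raise ValueError("axis must be 'lnc' or 'mir'")
    if axis == "mir":
        return neighbor_cf_scores(M.T, sim, axis="lnc").T
    if sim.shape != (M.shape[0], M.shape[0]):
        raise ValueError("similarity matrix does not match the lncRNA side")
    W = sim.copy()
    np.fill_diagonal(W, 0.0)
    denom = np.abs(W).sum(axis=1, keepdims=True)
    scores = W @ M
    np.divide(scores, denom, out=scores, where=denom > 0)
    scores[np.repeat(denom == 0, M.shape[1], axis=1)] = 0.0
    return scores


def svd_cf_scores(M: np.ndarray, rank: int) -> np.ndarray:
    """Truncated singular-value reconstruction of the interaction matrix."""
    M = np.asarray(M, dtype=float)
    if not (1 <= rank <= min(M.shape)):
        raise ValueError(f"rank must be in [1, {min(M.shape)}], got {rank}")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    return (U[:, :rank] * s[:rank]) @ Vt[:rank]


def katz_scores(
    M: np.ndarray,
    beta: float = 0.01,
    k_max: int | str = "closed_form",
) -> np.ndarray:
    """Katz index on the bipartite block graph, lncRNA x miRNA block.

    Closed form ``(I - beta A)^{-1} - I`` requires ``beta < 1/rho(A)``
    (spectral radius of the block adjacency); the truncated form sums
    ``beta^k A^k`` for k = 1..k_max. ``beta = 0`` gives all-zero scores.
    """
    M = np.asarray(M, dtype=float)
    if beta < 0:
        raise ValueError("beta must be >= 0")
    n_l, n_m = M.shape
    n = n_l + n_m
    A = np.zeros((n, n))
    A[:n_l, n_l:] = M
    A[n_l:, :n_l] = M.T
    if k_max == "closed_form":
        rho = max(abs(np.linalg.eigvalsh(A))) if A.any() else 0.0
        if rho > 0 and beta >= 1.0 / rho:
            raise ValueError(
                f"beta={beta} >= 1/spectral radius ({1.0 / rho:.6g}); "
                "Katz series diverges"
            )
        K = np.linalg.inv(np.eye(n) - beta * A) - np.eye(n)
    else:
        k_max = int(k_max)
        if k_max < 1:
            raise ValueError("k_max must be >= 1")
        K = np.zeros((n, n))
        term = np.eye(n)
        for _ in range(k_max):
            term = beta * (term @ A)
            K += term
    return K[:n_l, n_l:]


def latent_factor_scores(
    M: np.ndarray,
    rank: int = 16,
    lam_reg: float = 0.1,
    p: float = 3.0,
    epochs: int = 1000,
    lr: float = 0.005,
    seed: int = 0,
) -> np.ndarray:
    """Basic latent factor model: ``scores = b_i + c_j + P Q^T``.

    The classic biased matrix factorization: per-row and per-column biases
    (which absorb degree effects) plus rank-``rank`` factors P (n_lnc x
    rank) and Q (n_mir x rank), fitted by Adam on the masked squared loss
    over positives plus negatives resampled each epoch at ratio ``p``,
    with L2 regularization ``lam_reg/2`` on every parameter block.
    Deterministic given ``seed``.
    """
    M = np.asarray(M, dtype=float)
    if rank < 1:
        raise ValueError("rank must be >= 1")
    rng = np.random.default_rng(seed)
    n_l, n_m = M.shape
    scale = np.sqrt(2.0 / (rank + max(n_l, n_m)))
    P = rng.normal(0.0, scale, size=(n_l, rank))
    Q = rng.normal(0.0, scale, size=(n_m, rank))
    b = np.zeros((n_l, 1))
    c = np.zeros((1, n_m))
    omega_p = (M > 0).astype(float)
    opt = AdamState([P, Q, b, c], lr=lr)
    for epoch in range(epochs):
        omega_n = sample_negatives(M, p, rng)
        mask = omega_p + omega_n
        n_masked = mask.sum()
        if n_masked == 0:
            raise ValueError("empty training mask")
        resid = (b + c + P @ Q.T - M) * mask
        loss = (resid ** 2).sum() / n_masked + 0.5 * lam_reg * (
            (P ** 2).sum() + (Q ** 2).sum() + (b ** 2).sum() + (c ** 2).sum()
        )
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        dM = 2.0 * resid / n_masked
        dP = dM @ Q + lam_reg * P
        dQ = dM.T @ P + lam_reg * Q
        db = dM.sum(axis=1, keepdims=True) + lam_reg * b
        dc = dM.sum(axis=0, keepdims=True) + lam_reg * c
        opt.step([P, Q, b, c], [dP, dQ, db, dc])
    return b + c + P @ Q.T
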