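"""Repeated k-fold cross-validation with candidate ranking and ROC/AUC.

Known interactions are partitioned into k folds; each fold in turn is
hidden from the training matrix (features are never touched), the scoring
method is run on the reduced network, and the hidden edges are ranked
among the candidate set — every pair that is not a training positive,
i.e. all unlabeled pairs plus the held-out positives. AUC is the
Mann-Whitney statistic (ties count 1/2): the probability that a held-out
true pair outranks a random unlabeled pair. Each cross-validation is
repeated with fresh random partitions (default 20, matching common
practice for this protocol) and the standard deviation across repeats is
reported alongside the mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .datamodel import AlignedDataset

# A scoring method maps a training dataset (fold edges removed) and a seed
# to a full n_lnc x n_mir score matrix.
ScoringMethod = Callable[[AlignedDataset, int], np.ndarray]


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of each positive edge to one of k folds."""

    k: int
    assignments: np.ndarray
    seed: int

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)


@dataclass
class EvaluationResult:
    """Per-repeat/per-fold AUCs plus a pooled ROC curve.

    ``aucs`` has shape (repeats, k). ``mean_auc`` averages everything;
    ``std_auc`` is the standard deviation of the per-repeat mean AUCs.
    The pooled curve concatenates candidate scores across all folds and
    repeats.
    """

    aucs: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    @property
    def std_auc(self) -> float:
        return float(self.aucs.mean(axis=1).std(ddof=0))


def derive_seed(master: int, *keys: int) -> int:
    """Labelled sub-stream seed: every subsystem (fold split, model init,
    negative sampling, simulation) gets its own reproducible stream."""
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(k) for k in keys))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def kfold_split(n_edges: int, k: int, seed: int) -> FoldPlan:
    """Uniform random partition of edge indices into k folds.

    Fold sizes differ by at most one; reproducible given ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_edges < k:
        raise ValueError(f"cannot split {n_edges} edges into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_edges)
    assignments = np.empty(n_edges, dtype=int)
    assignments[order] = np.arange(n_edges) % k
    return FoldPlan(k=k, assignments=assignments, seed=seed)


def rank_candidates(scores: np.ndarray, train_positive_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rank all non-training pairs by descending score (ties -> average rank).

    Returns ``(flat_candidate_indices, ranks)`` where rank 1 is the best
    score. Candidates are every pair not marked in the training positive
    mask, i.e. unlabeled pairs plus held-out test positives.
    """
    scores = np.asarray(scores, dtype=float)
    train_positive_mask = np.asarray(train_positive_mask)
    if scores.shape != train_positive_mask.shape:
        raise ValueError("scores and mask shapes differ")
    candidates = np.flatnonzero(train_positive_mask == 0)
    if candidates.size == 0:
        raise ValueError("empty candidate set: every pair is a training positive")
    ranks = rankdata(-scores.flat[candidates], method="average")
    return candidates, ranks


def roc_auc(candidate_scores: np.ndarray, test_positive_flags: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC (Mann-Whitney with ties as 1/2) and the ROC curve points.

    Returns ``(auc, fpr, tpr)``; the curve starts at (0, 0) and ends at
    (1, 1), and the AUC equals its trapezoidal integral.
    """
    scores = np.asarray(candidate_scores, dtype=float)
    flags = np.asarray(test_positive_flags).astype(int)
    if scores.shape != flags.shape:
        raise ValueError("scores and flags shapes differ")
    n_pos = int(flags.sum())
    if n_pos == 0 or n_pos == flags.size:
        raise ValueError("need at least one positive and one negative candidate")
    fpr, tpr, _ = roc_curve(flags, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, fpr, tpr


def cross_validate(
    method: ScoringMethod,
    dataset: AlignedDataset,
    k: int = 5,
    repeats: int = 20,
    seed: int = 0,
) -> EvaluationResult:
    """Repeated k-fold CV of a scoring method on an aligned dataset.

    For each repeat and fold: the fold's edges are zeroed in the training
    matrix (features are untouched), the method scores all pairs, and AUC
    is computed over the candidate set with the hidden edges as positives.
    Repeat ``r`` uses fold seed ``derive_seed(seed, 1, r)`` and method seed
    ``derive_seed(seed, 2, r, fold)`` so any single run is independently
    reproducible.
    """
    M = dataset.M
    pos_rows, pos_cols = np.nonzero(M)
    n_edges = pos_rows.size
    aucs = np.zeros((repeats, k))
    all_scores: list[np.ndarray] = []
    all_flags: list[np.ndarray] = []
    for r in range(repeats):
        plan = kfold_split(n_edges, k, derive_seed(seed, 1, r))
        for fold in range(k):
            hidden = plan.fold_indices(fold)
            M_train = M.copy()
            M_train[pos_rows[hidden], pos_cols[hidden]] = 0.0
            train_ds = dataset.with_interactions(M_train)
            scores = method(train_ds, derive_seed(seed, 2, r, fold))
            candidates, _ = rank_candidates(scores, M_train > 0)
            held_out = np.zeros_like(M)
            held_out[pos_rows[hidden], pos_cols[hidden]] = 1.0
            cand_scores = scores.flat[candidates]
            cand_flags = held_out.flat[candidates]
            auc, _, _ = roc_auc(cand_scores, cand_flags)
            aucs[r, fold] = auc
            all_scores.append(cand_scores)
            all_flags.append(cand_flags)
    pooled_scores = np.concatenate(all_scores)
    pooled_flags = np.concatenate(all_flags)
    _, fpr, tpr = roc_auc(pooled_scores, pooled_flags)
    return EvaluationResult(aucs=aucs, fpr=fpr, tpr=tpr)
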