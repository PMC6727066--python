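"""Graph-convolution auto-encoder for bipartite link prediction.

The model encodes convolved node features ``G`` into nonnegative latent
embeddings ``E = ReLU(G W_e + B_e)`` and reconstructs the interaction
matrix bilinearly, ``M' = E_l W_d E_m^T``, where ``E_l`` / ``E_m`` are the
lncRNA / miRNA rows of ``E``. Training minimises a masked squared error
over the known positives plus negatives sampled fresh each epoch from the
unlabeled pairs (ratio ``p`` negatives per positive), with an L2 penalty
``lambda * (1/2 ||W_e||^2 + 1/2 ||W_d||^2 + 1/2 ||B_e||^2)``.

Gradients are derived in closed form (the network is two shallow layers)
and checked against finite differences in the test suite; optimisation
uses Adam on the full graph — the networks are small enough that
minibatching would only add variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datamodel import AlignedDataset
from .graph import convolved_features

logger = logging.getLogger("gclmi")


@dataclass
class ModelParams:
    """Trainable parameters of the auto-encoder.

    ``W_e``: (d_lnc + d_mir) x n_latent encoder weights; ``B_e``: one bias
    row of length n_latent broadcast to every node; ``W_d``: n_latent x
    n_latent bilinear decoder weights.
    """

    W_e: np.ndarray
    B_e: np.ndarray
    W_d: np.ndarray

    @property
    def n_latent(self) -> int:
        return int(self.W_e.shape[1])

    def copy(self) -> "ModelParams":
        return ModelParams(self.W_e.copy(), self.B_e.copy(), self.W_d.copy())


@dataclass
class Embeddings:
    """Nonnegative latent node embeddings, split by node type."""

    E: np.ndarray
    n_lnc: int

    @property
    def E_l(self) -> np.ndarray:
        return self.E[: self.n_lnc]

    @property
    def E_m(self) -> np.ndarray:
        return self.E[self.n_lnc:]


@dataclass
class TrainingMasks:
    """Positive mask (fixed per fold) and sampled negative mask (per epoch).

    Invariant: the masks are disjoint and ``omega_n`` only marks zero
    entries of the training matrix.
    """

    omega_p: np.ndarray
    omega_n: np.ndarray
    p: float

    def __post_init__(self) -> None:
        if (self.omega_p * self.omega_n).any():
            raise ValueError("positive and negative masks must be disjoint")


@dataclass
class TrainedModel:
    """A fitted auto-encoder plus everything needed to reproduce it."""

    params: ModelParams
    embeddings: Embeddings
    loss_history: list[float]
    error_history: list[float]
    config: dict
    seed: int
    M_train: np.ndarray = field(repr=False, default=None)


def glorot_scale(fan_in: int, fan_out: int) -> float:
    return float(np.sqrt(2.0 / (fan_in + fan_out)))


def init_params(d_total: int, n_latent: int, seed: int) -> ModelParams:
    """Variance-scaled zero-mean random init; bias starts at zero."""
    if d_total < 1 or n_latent < 1:
        raise ValueError("dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    W_e = rng.normal(0.0, glorot_scale(d_total, n_latent), size=(d_total, n_latent))
    W_d = rng.normal(0.0, glorot_scale(n_latent, n_latent), size=(n_latent, n_latent))
    B_e = np.zeros(n_latent)
    return ModelParams(W_e=W_e, B_e=B_e, W_d=W_d)


def encode(G: np.ndarray, params: ModelParams, n_lnc: int) -> Embeddings:
    """``E = ReLU(G W_e + B_e)``, split into lncRNA and miRNA rows."""
    G = np.asarray(G, dtype=float)
    if G.shape[1] != params.W_e.shape[0]:
        raise ValueError(
            f"G has {G.shape[1]} columns but W_e expects {params.W_e.shape[0]}"
        )
    Z = G @ params.W_e + params.B_e
    return Embeddings(E=np.maximum(Z, 0.0), n_lnc=n_lnc)


def decode(embeddings: Embeddings, W_d: np.ndarray) -> np.ndarray:
    """Bilinear reconstruction ``M' = E_l W_d E_m^T`` (n_lnc x n_mir)."""
    E_l, E_m = embeddings.E_l, embeddings.E_m
    if E_l.shape[1] != W_d.shape[0] or E_m.shape[1] != W_d.shape[1]:
        raise ValueError("embedding width does not match decoder weights")
    return E_l @ W_d @ E_m.T


def sample_negatives(M_train: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Sample ``round(p * n_positives)`` unlabeled pairs as negatives.

    Uniform without replacement over the zero entries of the training
    matrix; capped (with a log warning) when fewer zeros exist. ``p = 0``
    returns an empty mask, i.e. training on positives only.
    """
    if p < 0:
        raise ValueError("negative sampling ratio p must be >= 0")
    M_train = np.asarray(M_train)
    omega_n = np.zeros_like(M_train, dtype=float)
    n_pos = int(M_train.sum())
    want = int(round(p * n_pos))
    if want == 0:
        return omega_n
    zeros_flat = np.flatnonzero(M_train == 0)
    if want > zeros_flat.size:
        logger.warning(
            "requested %d negatives but only %d unlabeled pairs exist; capping",
            want, zeros_flat.size,
        )
        want = zeros_flat.size
    chosen = rng.choice(zeros_flat, size=want, replace=False)
    omega_n.flat[chosen] = 1.0
    return omega_n


def compute_loss(
    M_pred: np.ndarray,
    M_train: np.ndarray,
    masks: TrainingMasks,
    params: ModelParams,
    lam: float = 0.1,
) -> tuple[float, float]:
    """Masked mean squared error plus L2 penalty.

    Returns ``(loss, error)`` where ``error`` is the mask-averaged squared
    reconstruction error and ``loss = error + lam * (1/2||W_e||^2 +
    1/2||W_d||^2 + 1/2||B_e||^2)``.
    """
    mask = masks.omega_p + masks.omega_n
    n_masked = mask.sum()
    if n_masked == 0:
        raise ValueError("empty training mask: no positives and no negatives")
    resid = (M_pred - M_train) * mask
    error = float((resid ** 2).sum() / n_masked)
    penalty = 0.5 * (
        np.sum(params.W_e ** 2) + np.sum(params.W_d ** 2) + np.sum(params.B_e ** 2)
    )
    return error + lam * float(penalty), error


def loss_gradients(
    G: np.ndarray,
    M_train: np.ndarray,
    masks: TrainingMasks,
    params: ModelParams,
    lam: float = 0.1,
) -> tuple[float, float, ModelParams]:
    """Forward pass plus closed-form gradients of the loss.

    Returns ``(loss, error, grads)`` with ``grads`` stored in a
    :class:`ModelParams` of matching shapes. The ReLU subgradient at 0 is
    taken as 0.
    """
    n_lnc = M_train.shape[0]
    Z = G @ params.W_e + params.B_e
    E = np.maximum(Z, 0.0)
    E_l, E_m = E[:n_lnc], E[n_lnc:]
    M_pred = E_l @ params.W_d @ E_m.T

    mask = masks.omega_p + masks.omega_n
    n_masked = mask.sum()
    if n_masked == 0:
        raise ValueError("empty training mask: no positives and no negatives")
    resid = (M_pred - M_train) * mask
    error = float((resid ** 2).sum() / n_masked)
    loss = error + lam * 0.5 * float(
        np.sum(params.W_e ** 2) + np.sum(params.W_d ** 2) + np.sum(params.B_e ** 2)
    )

    dM = 2.0 * resid / n_masked
    dW_d = E_l.T @ dM @ E_m + lam * params.W_d
    dE = np.vstack([dM @ E_m @ params.W_d.T, dM.T @ E_l @ params.W_d])
    dZ = dE * (Z > 0)
    dW_e = G.T @ dZ + lam * params.W_e
    dB_e = dZ.sum(axis=0) + lam * params.B_e
    return loss, error, ModelParams(W_e=dW_e, B_e=dB_e, W_d=dW_d)


class AdamState:
    """Minimal Adam optimiser over a list of parameter arrays."""

    def __init__(self, arrays: list[np.ndarray], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, arrays: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for a, g, m, v in zip(arrays, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            a -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def train(
    dataset: AlignedDataset,
    n_latent: int = 16,
    lam: float = 0.1,
    p_ratio: float = 3.0,
    epochs: int = 1000,
    lr: float = 0.005,
    seed: int = 0,
    dialect: str = "renormalized",
    row_normalize_features: bool = False,
) -> TrainedModel:
    """Fit the auto-encoder on an aligned dataset.

    The negative mask is redrawn every epoch; the positive mask is the full
    set of training interactions. Deterministic given ``seed``. Raises
    ``FloatingPointError`` if the loss becomes non-finite.
    """
    rng = np.random.default_rng(seed)
    M_train = dataset.M
    n_lnc = M_train.shape[0]
    G = convolved_features(
        M_train, dataset.lnc_features.F, dataset.mir_features.F,
        dialect=dialect, row_normalize_features=row_normalize_features,
    )
    params = init_params(G.shape[1], n_latent, seed)
    omega_p = (M_train > 0).astype(float)
    opt = AdamState([params.W_e, params.B_e, params.W_d], lr=lr)

    loss_history: list[float] = []
    error_history: list[float] = []
    for epoch in range(epochs):
        omega_n = sample_negatives(M_train, p_ratio, rng)
        masks = TrainingMasks(omega_p=omega_p, omega_n=omega_n, p=p_ratio)
        loss, error, grads = loss_gradients(G, M_train, masks, params, lam=lam)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss {loss} at epoch {epoch}; "
                "try a smaller learning rate"
            )
        opt.step(
            [params.W_e, params.B_e, params.W_d],
            [grads.W_e, grads.B_e, grads.W_d],
        )
        loss_history.append(loss)
        error_history.append(error)

    embeddings = encode(G, params, n_lnc)
    config = {
        "n_latent": n_latent, "lambda": lam, "p_ratio": p_ratio,
        "epochs": epochs, "lr": lr, "dialect": dialect,
        "row_normalize_features": row_normalize_features,
    }
    return TrainedModel(
        params=params, embeddings=embeddings,
        loss_history=loss_history, error_history=error_history,
        config=config, seed=seed, M_train=M_train.copy(),
    )


def predict_scores(model: TrainedModel, dataset: AlignedDataset) -> np.ndarray:
    """Score every lncRNA-miRNA pair (n_lnc x n_mir).

    Recomputes the convolution from the training interactions and the
    dataset features, encodes and decodes. Known positives are scored too;
    masking them out is the evaluator's job.
    """
    M_train = model.M_train if model.M_train is not None else dataset.M
    if M_train.shape != dataset.shape:
        raise ValueError("model/dataset shape mismatch")
    G = convolved_features(
        M_train, dataset.lnc_features.F, dataset.mir_features.F,
        dialect=model.config["dialect"],
        row_normalize_features=model.config["row_normalize_features"],
    )
    embeddings = encode(G, model.params, dataset.shape[0])
    return decode(embeddings, model.params.W_d)
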