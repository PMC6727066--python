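"""Registry mapping method names to scoring callables for the evaluator.

Every method shares the same contract: given a training dataset (with the
evaluation fold's edges already removed) and a seed, return a full
n_lnc x n_mir score matrix. Deterministic methods ignore the seed.
"""

from __future__ import annotations

import numpy as np

from . import baselines as bl
from . import model as gm
from .config import RunConfig
from .datamodel import AlignedDataset
from .evaluation import ScoringMethod

METHOD_NAMES = ("gclmi", "lnc_cf", "mir_cf", "svd", "katz", "lfm")


def make_scorer(name: str, config: RunConfig) -> ScoringMethod:
    """Build a scoring method from a resolved configuration."""
    if name == "gclmi":
        def score(ds: AlignedDataset, seed: int) -> np.ndarray:
            trained = gm.train(
                ds,
                n_latent=config.get("model.n_latent"),
                lam=config.get("model.lambda"),
                p_ratio=config.get("train.p_ratio"),
                epochs=config.get("train.epochs"),
                lr=config.get("train.lr"),
                seed=seed,
                dialect=config.get("conv.dialect"),
                row_normalize_features=config.get("conv.row_normalize_features"),
            )
            return gm.predict_scores(trained, ds)
    elif name in ("lnc_cf", "mir_cf"):
        axis = "lnc" if name == "lnc_cf" else "mir"

        def score(ds: AlignedDataset, seed: int) -> np.ndarray:
            feats = ds.lnc_features if axis == "lnc" else ds.mir_features
            sim = bl.pearson_similarity(feats.F)
            return bl.neighbor_cf_scores(ds.M, sim, axis=axis)
    elif name == "svd":
        def score(ds: AlignedDataset, seed: int) -> np.ndarray:
            rank = min(config.get("baseline.rank"), min(ds.shape))
            return bl.svd_cf_scores(ds.M, rank)
    elif name == "katz":
        def score(ds: AlignedDataset, seed: int) -> np.ndarray:
            return bl.katz_scores(
                ds.M,
                beta=config.get("baseline.beta"),
                k_max=config.get("baseline.k_max"),
            )
    elif name == "lfm":
        def score(ds: AlignedDataset, seed: int) -> np.ndarray:
            rank = min(config.get("baseline.rank"), min(ds.shape))
            return bl.latent_factor_scores(
                ds.M,
                rank=rank,
                lam_reg=config.get("baseline.lam_reg"),
                p=config.get("train.p_ratio"),
                epochs=config.get("train.epochs"),
                lr=config.get("train.lr"),
                seed=seed,
            )
    else:
        raise ValueError(f"unknown method {name!r}; expected one of {METHOD_NAMES}")
    return score
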