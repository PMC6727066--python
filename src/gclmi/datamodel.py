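"""Domain types and file I/O for bipartite lncRNA-miRNA interaction data.

The package works on three aligned objects: a binary interaction matrix
``M`` (lncRNAs x miRNAs, 1 = experimentally confirmed pair, 0 = unlabeled),
and two numeric feature tables holding expression profiles for each side.
Interactions are exchanged as 2-column headerless TSV edge lists; features
as TSV with a header whose first column is ``id``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("gclmi")


class ParseError(ValueError):
    """Raised when an input file does not conform to the expected format."""


class AlignmentError(ValueError):
    """Raised when interaction ids and feature ids share no common nodes."""


@dataclass(frozen=True)
class BipartiteInteractionSet:
    """Binary lncRNA-miRNA interaction matrix with node identifier lists.

    Attributes
    ----------
    lnc_ids : list of str
        Row identifiers (lncRNAs), unique, in matrix row order.
    mir_ids : list of str
        Column identifiers (miRNAs), unique, in matrix column order.
    M : ndarray of shape (n_lnc, n_mir)
        Entries are exactly 0.0 or 1.0; 1 marks a confirmed interaction.
    """

    lnc_ids: tuple[str, ...]
    mir_ids: tuple[str, ...]
    M: np.ndarray

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "lnc_ids", tuple(self.lnc_ids))
        object.__setattr__(self, "mir_ids", tuple(self.mir_ids))
        if M.ndim != 2:
            raise ValueError("M must be a 2-D matrix")
        if M.shape != (len(self.lnc_ids), len(self.mir_ids)):
            raise ValueError(
                f"M shape {M.shape} does not match id counts "
                f"({len(self.lnc_ids)}, {len(self.mir_ids)})"
            )
        if len(set(self.lnc_ids)) != len(self.lnc_ids):
            raise ValueError("duplicate lncRNA identifiers")
        if len(set(self.mir_ids)) != len(self.mir_ids):
            raise ValueError("duplicate miRNA identifiers")
        if not np.isin(M, (0.0, 1.0)).all():
            raise ValueError("interaction matrix entries must be 0 or 1")

    @property
    def n_lnc(self) -> int:
        return len(self.lnc_ids)

    @property
    def n_mir(self) -> int:
        return len(self.mir_ids)

    @property
    def n_edges(self) -> int:
        return int(self.M.sum())


@dataclass(frozen=True)
class FeatureTable:
    """Per-node numeric feature rows (e.g. expression across tissues).

    ``F`` has one row per identifier in ``ids``; all values must be finite.
    """

    ids: tuple[str, ...]
    F: np.ndarray

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        if F.ndim != 2:
            raise ValueError("F must be a 2-D matrix")
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "ids", tuple(self.ids))
        if F.shape[0] != len(self.ids):
            raise ValueError("row count does not match number of ids")
        if F.shape[1] < 1:
            raise ValueError("feature table needs at least one column")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate identifiers in feature table")
        if not np.isfinite(F).all():
            raise ValueError("feature values must be finite")

    @property
    def n_features(self) -> int:
        return int(self.F.shape[1])

    def reorder(self, ids: list[str] | tuple[str, ...]) -> "FeatureTable":
        """Return a copy with rows re-ordered to follow ``ids``."""
        index = {v: i for i, v in enumerate(self.ids)}
        rows = [index[i] for i in ids]
        return FeatureTable(ids=tuple(ids), F=self.F[rows])


@dataclass(frozen=True)
class AlignedDataset:
    """Interaction matrix plus feature tables with identical node ordering.

    Invariant: ``lnc_features.ids == interactions.lnc_ids`` and likewise on
    the miRNA side, so matrix row/column i always refers to feature row i.
    """

    interactions: BipartiteInteractionSet
    lnc_features: FeatureTable
    mir_features: FeatureTable

    def __post_init__(self) -> None:
        if self.lnc_features.ids != self.interactions.lnc_ids:
            raise ValueError("lncRNA feature ids do not match interaction ids")
        if self.mir_features.ids != self.interactions.mir_ids:
            raise ValueError("miRNA feature ids do not match interaction ids")

    @property
    def M(self) -> np.ndarray:
        return self.interactions.M

    @property
    def shape(self) -> tuple[int, int]:
        return self.interactions.M.shape

    def with_interactions(self, M: np.ndarray) -> "AlignedDataset":
        """Same nodes and features, different interaction matrix (e.g. a
        training fold with held-out edges zeroed)."""
        inter = replace(self.interactions, M=np.asarray(M, dtype=float))
        return AlignedDataset(inter, self.lnc_features, self.mir_features)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_interactions(path) -> BipartiteInteractionSet:
    """Read a 2-column headerless TSV edge list into an interaction set.

    Node order is first-appearance order; duplicate edges collapse to a
    single 1. Raises :class:`ParseError` (naming the line) on malformed
    lines and on an empty file.
    """
    lnc_ids: list[str] = []
    mir_ids: list[str] = []
    lnc_index: dict[str, int] = {}
    mir_index: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise ParseError(
                    f"{path}: line {lineno}: expected two non-empty "
                    f"tab-separated fields, got {line!r}"
                )
            lnc, mir = parts[0].strip(), parts[1].strip()
            if lnc not in lnc_index:
                lnc_index[lnc] = len(lnc_ids)
                lnc_ids.append(lnc)
            if mir not in mir_index:
                mir_index[mir] = len(mir_ids)
                mir_ids.append(mir)
            edges.add((lnc_index[lnc], mir_index[mir]))
    if not edges:
        raise ParseError(f"{path}: no interaction edges found")
    M = np.zeros((len(lnc_ids), len(mir_ids)))
    rows, cols = zip(*edges)
    M[list(rows), list(cols)] = 1.0
    return BipartiteInteractionSet(tuple(lnc_ids), tuple(mir_ids), M)


def write_interactions(interactions: BipartiteInteractionSet, path) -> None:
    """Write an interaction set as a 2-column headerless TSV edge list."""
    with open(path, "w", encoding="utf-8") as fh:
        rows, cols = np.nonzero(interactions.M)
        for i, j in zip(rows, cols):
            fh.write(f"{interactions.lnc_ids[i]}\t{interactions.mir_ids[j]}\n")


def read_features(path, zscore: bool = False) -> FeatureTable:
    """Read a TSV feature table (header row, first column = id).

    Values are used raw by default; ``zscore=True`` standardises each
    column to zero mean / unit variance (constant columns become zero).
    """
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: could not parse feature table: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need an id column plus >=1 numeric column")
    ids = [str(v).strip() for v in df.iloc[:, 0]]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ParseError(f"{path}: duplicated ids: {dupes[:5]}")
    values = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        row, col = np.argwhere(values.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value at data row {row + 1}, "
            f"column {values.columns[col]!r}"
        )
    F = values.to_numpy(dtype=float)
    if zscore:
        mu = F.mean(axis=0)
        sd = F.std(axis=0)
        sd[sd == 0] = 1.0
        F = (F - mu) / sd
    return FeatureTable(ids=tuple(ids), F=F)


def write_features(features: FeatureTable, path) -> None:
    """Write a feature table as TSV with an ``id`` first column."""
    df = pd.DataFrame(features.F, columns=[f"f{k}" for k in range(features.n_features)])
    df.insert(0, "id", list(features.ids))
    df.to_csv(path, sep="\t", index=False)


def align_dataset(
    interactions: BipartiteInteractionSet,
    lnc_features: FeatureTable,
    mir_features: FeatureTable,
) -> AlignedDataset:
    """Intersect interaction nodes with feature ids and drop the rest.

    Nodes without a feature row (and their edges) are removed; matching is
    exact string match after whitespace trimming. Node order follows the
    interaction set's first-appearance order. Raises
    :class:`AlignmentError` when either side has an empty intersection.
    """
    lnc_keep = [i for i in interactions.lnc_ids if i in set(lnc_features.ids)]
    mir_keep = [i for i in interactions.mir_ids if i in set(mir_features.ids)]
    if not lnc_keep or not mir_keep:
        raise AlignmentError("no common identifiers between interactions and features")
    lnc_rows = [interactions.lnc_ids.index(i) for i in lnc_keep]
    mir_cols = [interactions.mir_ids.index(i) for i in mir_keep]
    M = interactions.M[np.ix_(lnc_rows, mir_cols)]
    kept = BipartiteInteractionSet(tuple(lnc_keep), tuple(mir_keep), M)
    logger.info(
        "alignment kept %d/%d lncRNAs, %d/%d miRNAs, %d/%d edges",
        kept.n_lnc, interactions.n_lnc,
        kept.n_mir, interactions.n_mir,
        kept.n_edges, interactions.n_edges,
    )
    return AlignedDataset(
        interactions=kept,
        lnc_features=lnc_features.reorder(lnc_keep),
        mir_features=mir_features.reorder(mir_keep),
    )


def write_predictions(
    scores: np.ndarray,
    dataset: AlignedDataset,
    path,
    top_k: int,
) -> pd.DataFrame:
    """Write the top-``top_k`` unlabeled pairs ranked by descending score.

    Only pairs with ``M == 0`` are candidates. Ties are broken by
    (lncRNA_id, miRNA_id) lexicographic order so output is reproducible.
    Returns the written frame for convenience.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != dataset.shape:
        raise ValueError(
            f"score shape {scores.shape} does not match dataset {dataset.shape}"
        )
    rows, cols = np.nonzero(dataset.M == 0)
    records = [
        (dataset.interactions.lnc_ids[i], dataset.interactions.mir_ids[j], scores[i, j])
        for i, j in zip(rows, cols)
    ]
    records.sort(key=lambda r: (-r[2], r[0], r[1]))
    records = records[: max(top_k, 0)]
    df = pd.DataFrame(records, columns=["lncRNA_id", "miRNA_id", "score"])
    df["rank"] = np.arange(1, len(df) + 1)
    df.to_csv(path, sep="\t", index=False)
    return df
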