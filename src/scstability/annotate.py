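"""Reference-projection of high-mitochondrial cells onto annotated cell types.

Cells above the mitochondrial QC cut-off are excluded from clustering, but
degradation statistics need them assigned to a type. This module builds
per-type centroid profiles from the low-MT reference cells and assigns each
query cell to its most cosine-similar centroid, abstaining below a
similarity threshold — a single-measure simplification of cluster-level
projection tools such as scmap.

Feature selection follows the dropout-vs-expression idea: genes whose
dropout rate sits furthest above the trend expected from their mean
expression are the most informative; the top ``n_features`` positive
residuals are kept (falling back to top-variance genes when the fit is not
possible).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from .errors import InputError

__all__ = ["CentroidIndex", "build_centroids", "assign_by_similarity", "log_normalize"]

TARGET_SUM = 10_000.0


def log_normalize(x: sparse.spmatrix | np.ndarray, target_sum: float = TARGET_SUM) -> np.ndarray:
    """Counts-per-``target_sum`` per cell, then log1p. Returns dense."""
    x = np.asarray(x.todense() if sparse.issparse(x) else x, dtype=float)
    totals = x.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(x * (target_sum / totals))


def _dropout_informative_features(x_counts: np.ndarray, n_features: int) -> np.ndarray:
    """Indices of genes with the largest positive dropout residuals.

    Fits a line to (log mean expression, dropout rate) over genes expressed
    in at least one cell and with at least one dropout; genes outside that
    range carry no dropout signal and fall back to the variance ranking.
    """
    mean = x_counts.mean(axis=0)
    dropout = (x_counts == 0).mean(axis=0)
    usable = (mean > 0) & (dropout > 0) & (dropout < 1)
    if usable.sum() >= max(10, min(n_features, x_counts.shape[1]) // 2):
        lm = np.log1p(mean[usable])
        coef = np.polyfit(lm, dropout[usable], 1)
        resid = dropout[usable] - np.polyval(coef, lm)
        ranked = np.flatnonzero(usable)[np.argsort(-resid, kind="stable")]
    else:  # fallback: top-variance genes
        ranked = np.argsort(-x_counts.var(axis=0), kind="stable")
    return np.sort(ranked[:n_features])


@dataclass
class CentroidIndex:
    """Per-cell-type reference profiles over a selected feature set."""

    centroids: pd.DataFrame  # cell types x features, log-normalized medians
    features: list[str]
    threshold: float = 0.7
    measure: str = "cosine"

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise InputError("similarity threshold must lie in (0, 1]")
        if self.centroids.shape[1] != len(self.features):
            raise InputError("centroid feature dimension mismatch")


def build_centroids(reference: AnnData, labels, n_features: int = 500) -> CentroidIndex:
    """Build per-type centroids (gene-wise medians of log-normalized counts).

    ``reference`` holds raw counts of the low-MT reference cells; ``labels``
    their cell-type annotation, aligned to ``reference.obs_names``.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != reference.n_obs:
        raise InputError("labels not aligned with reference cells")
    counts = np.asarray(
        reference.X.todense() if sparse.issparse(reference.X) else reference.X, dtype=float
    )
    empty = [str(lb) for lb in pd.unique(labels) if (labels == lb).sum() == 0]
    if empty:
        raise InputError(f"cell types with zero reference cells: {empty}")
    n_features = min(n_features, reference.n_vars)
    feat_idx = _dropout_informative_features(counts, n_features)
    logx = log_normalize(counts)[:, feat_idx]
    types = sorted(pd.unique(labels).tolist())
    cent = np.vstack([np.median(logx[labels == t], axis=0) for t in types])
    features = [reference.var_names[i] for i in feat_idx]
    return CentroidIndex(pd.DataFrame(cent, index=types, columns=features), features)


def assign_by_similarity(query: AnnData, index: CentroidIndex) -> pd.DataFrame:
    """Assign each query cell to its most similar centroid, or "unassigned".

    Cosine similarity on the intersection of the query's features with the
    index features (at least half of the index features must be present).
    Ties go to the lexicographically first label and are flagged.
    """
    shared = [f for f in index.features if f in set(query.var_names)]
    if len(shared) < 0.5 * len(index.features):
        raise InputError(
            f"only {len(shared)}/{len(index.features)} index features present in query (< 50%)"
        )
    qx = log_normalize(query[:, shared].X)
    cx = index.centroids[shared].to_numpy()
    qn = np.linalg.norm(qx, axis=1)
    cn = np.linalg.norm(cx, axis=1)
    denom = np.outer(qn, cn)
    denom[denom == 0] = np.inf  # zero vectors are similar to nothing
    sim = (qx @ cx.T) / denom
    best = np.argmax(sim, axis=1)
    best_sim = sim[np.arange(len(best)), best]
    labels = np.asarray(index.centroids.index)[best].astype(object)
    # detect exact ties with the chosen maximum
    tied = (np.isclose(sim, best_sim[:, None]).sum(axis=1)) > 1
    unassigned = best_sim < index.threshold
    labels[unassigned] = "unassigned"
    return pd.DataFrame(
        {
            "barcode": query.obs_names,
            "label": labels,
            "similarity": best_sim,
            "assigned": ~unassigned,
            "tie": tied,
        }
    ).set_index("barcode", drop=False)
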