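"""Degradation statistics: mitochondrial fold-change tables, cell-type
composition tests, variance partitioning and the cross-organ dendrogram.

The fold-change table follows strict masking semantics: a (tissue, cell
type, time) stratum with fewer than 5 cells on either side of the contrast
is reported as ``too_few_cells`` with no fold change or p-value, and a
(tissue, time) combination with no sample at all is ``missing_sample``.
Significance of the per-stratum contrast is a two-sided rank-based
two-sample test of per-cell mitochondrial percentages against the T0 cells
of the same tissue and cell type, BH-corrected within each tissue.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import InputError
from .stats import bh_adjust, t_test

__all__ = [
    "mito_fold_change",
    "composition_proportions",
    "composition_time_tests",
    "composition_donor_anova",
    "variance_explained",
    "crossorgan_dendrogram",
    "significance_bins",
]

MIN_CELLS_PER_STRATUM = 5

# reporting bins used for fold-change annotation asterisks
SIGNIFICANCE_BINS = ((1e-8, "***"), (1e-5, "**"), (1e-2, "*"))


def significance_bins(p_adj: float) -> str:
    for cut, stars in SIGNIFICANCE_BINS:
        if p_adj < cut:
            return stars
    return ""


def mito_fold_change(
    cells: pd.DataFrame,
    t0_label: float = 0.0,
    expected_times: list[float] | None = None,
) -> pd.DataFrame:
    """Per (tissue, cell type, time) mitochondrial fold change relative to T0.

    ``cells`` must carry tissue, cell_type, time_h and mt_pct per cell — the
    *combined* table including reassigned high-MT cells. FC = mean mt_pct at
    time t over mean mt_pct at T0; p-values from a two-sided Mann-Whitney
    rank test of the per-cell values, BH-corrected across all non-baseline
    strata within a tissue. ``expected_times`` (default: times observed
    anywhere in the table) defines the grid so absent samples can be marked
    ``missing_sample``.
    """
    for col in ("tissue", "cell_type", "time_h", "mt_pct"):
        if col not in cells.columns:
            raise InputError(f"cell table lacks column {col!r}")
    times = sorted(expected_times if expected_times is not None else cells["time_h"].unique())
    if t0_label not in times:
        raise InputError(f"baseline time {t0_label} not in expected times {times}")
    rows = []
    for tissue, tgrp in cells.groupby("tissue", sort=True):
        present_times = set(tgrp["time_h"].unique())
        for ct in sorted(tgrp["cell_type"].unique()):
            base = tgrp.loc[(tgrp["cell_type"] == ct) & (tgrp["time_h"] == t0_label), "mt_pct"]
            for tp in times:
                rec = {"tissue": tissue, "cell_type": ct, "time_h": tp}
                if tp not in present_times:
                    rec.update(fold_change=np.nan, pvalue=np.nan, n_cells=0,
                               n_cells_t0=len(base), status="missing_sample")
                    rows.append(rec)
                    continue
                vals = tgrp.loc[(tgrp["cell_type"] == ct) & (tgrp["time_h"] == tp), "mt_pct"]
                rec.update(n_cells=len(vals), n_cells_t0=len(base))
                if len(vals) < MIN_CELLS_PER_STRATUM or len(base) < MIN_CELLS_PER_STRATUM:
                    rec.update(fold_change=np.nan, pvalue=np.nan, status="too_few_cells")
                elif tp == t0_label:
                    rec.update(fold_change=1.0, pvalue=1.0, status="ok")
                elif base.mean() == 0:
                    rec.update(fold_change=np.nan, pvalue=np.nan, status="undefined_baseline")
                else:
                    stat = sps.mannwhitneyu(vals, base, alternative="two-sided")
                    rec.update(fold_change=float(vals.mean() / base.mean()),
                               pvalue=float(stat.pvalue), status="ok")
                rows.append(rec)
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    for tissue, idx in out.groupby("tissue").groups.items():
        sub = out.loc[idx]
        family = sub.index[(sub["status"] == "ok") & (sub["time_h"] != t0_label)]
        out.loc[family, "p_adj"] = bh_adjust(out.loc[family, "pvalue"])
    out.loc[(out["status"] == "ok") & (out["time_h"] == t0_label), "p_adj"] = 1.0
    out["stars"] = [
        significance_bins(p) if np.isfinite(p) else "" for p in out["p_adj"].fillna(np.nan)
    ]
    return out


def composition_proportions(cells: pd.DataFrame) -> pd.DataFrame:
    """Cell-type proportions per sample; types absent from a sample get 0."""
    for col in ("sample_id", "donor", "tissue", "time_h", "cell_type"):
        if col not in cells.columns:
            raise InputError(f"cell table lacks column {col!r}")
    rows = []
    for tissue, tgrp in cells.groupby("tissue", sort=True):
        types = sorted(tgrp["cell_type"].unique())
        for sid, sgrp in tgrp.groupby("sample_id", sort=True):
            n = len(sgrp)
            counts = sgrp["cell_type"].value_counts()
            for ct in types:
                rows.append(
                    {
                        "tissue": tissue,
                        "sample_id": sid,
                        "donor": sgrp["donor"].iat[0],
                        "time_h": sgrp["time_h"].iat[0],
                        "cell_type": ct,
                        "n_cells": int(counts.get(ct, 0)),
                        "proportion": float(counts.get(ct, 0)) / n,
                    }
                )
    return pd.DataFrame(rows)


def composition_time_tests(
    comp: pd.DataFrame,
    t0_label: float = 0.0,
    late_label: float = 72.0,
) -> pd.DataFrame:
    """Per (tissue, cell type) composition change tests over time.

    Two families of unpaired two-sided t tests on per-sample proportions:
    every pairwise time contrast, and the combined early time points
    ({T0, 12, 24} — i.e. everything except ``late_label``) against the late
    time point. BH correction spans all cell types x contrasts within a
    tissue. Contrasts with fewer than 2 samples per side are skipped.
    """
    rows = []
    for (tissue, ct), grp in comp.groupby(["tissue", "cell_type"], sort=True):
        times = sorted(grp["time_h"].unique())
        contrasts: list[tuple[str, np.ndarray, np.ndarray]] = []
        for i, ta in enumerate(times):
            for tb in times[i + 1 :]:
                contrasts.append(
                    (
                        f"{ta}v{tb}",
                        grp.loc[grp["time_h"] == ta, "proportion"].to_numpy(),
                        grp.loc[grp["time_h"] == tb, "proportion"].to_numpy(),
                    )
                )
        if late_label in times and len(times) > 1:
            contrasts.append(
                (
                    f"combined_v{late_label}",
                    grp.loc[grp["time_h"] != late_label, "proportion"].to_numpy(),
                    grp.loc[grp["time_h"] == late_label, "proportion"].to_numpy(),
                )
            )
        for name, a, b in contrasts:
            rec = {"tissue": tissue, "cell_type": ct, "contrast": name, "n_a": len(a), "n_b": len(b)}
            if len(a) < 2 or len(b) < 2:
                rec.update(statistic=np.nan, pvalue=np.nan, status="skipped")
            else:
                res = t_test(a, b, paired=False)
                rec.update(statistic=res.statistic, pvalue=res.pvalue, status="ok")
            rows.append(rec)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["p_adj"] = np.nan
    for tissue, idx in out.groupby("tissue").groups.items():
        out.loc[idx, "p_adj"] = bh_adjust(out.loc[idx, "pvalue"])
    return out


def composition_donor_anova(comp: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """One-way ANOVA of proportion ~ donor per (tissue, cell type).

    Returns the test table and the number of combinations significant at
    BH-adjusted p < 0.05. Groups where every donor has identical values
    (zero within-donor variance everywhere) are flagged degenerate.
    """
    rows = []
    for (tissue, ct), grp in comp.groupby(["tissue", "cell_type"], sort=True):
        donors = [g["proportion"].to_numpy() for _, g in grp.groupby("donor")]
        rec = {"tissue": tissue, "cell_type": ct, "n_donors": len(donors),
               "n_samples": int(len(grp))}
        if len(donors) < 2:
            raise InputError(f"ANOVA needs >= 2 donors; {tissue}/{ct} has {len(donors)}")
        if len(grp) < 3:
            rec.update(F=np.nan, pvalue=np.nan, status="skipped")
        elif all(np.allclose(d, d[0]) for d in donors if len(d)) and len(
            {round(float(d[0]), 12) for d in donors}
        ) == 1:
            rec.update(F=np.nan, pvalue=np.nan, status="degenerate")
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                res = sps.f_oneway(*donors)
            if not np.isfinite(res.statistic):
                rec.update(F=np.nan, pvalue=np.nan, status="degenerate")
            else:
                rec.update(F=float(res.statistic), pvalue=float(res.pvalue), status="ok")
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    for tissue, idx in out.groupby("tissue").groups.items():
        out.loc[idx, "p_adj"] = bh_adjust(out.loc[idx, "pvalue"])
    n_sig = int((out["p_adj"] < 0.05).sum())
    return out, n_sig


def _residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """OLS residuals of each column of y on the design matrix (with intercept)."""
    X = np.column_stack([np.ones(len(design)), design])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def variance_explained(
    expr: np.ndarray | pd.DataFrame,
    factors: pd.DataFrame,
    categorical: list[str] | None = None,
    residualize_for: list[str] | None = None,
) -> pd.DataFrame:
    """Marginal R² per gene and factor: each factor is fitted alone.

    ``expr`` is cells x genes normalized expression (dense or DataFrame with
    gene columns); ``factors`` one row per cell. Categorical factors use the
    group-mean fit (one-hot regression), continuous factors a univariate
    linear fit; in both cases R² = 1 − RSS/TSS. Genes with zero variance are
    reported NaN. ``residualize_for`` optionally removes the stated
    (categorical or continuous) factors from the expression first — used for
    the per-cell-type time analysis where donor and depth are regressed out.
    """
    genes = list(expr.columns) if isinstance(expr, pd.DataFrame) else None
    y = np.asarray(expr, dtype=float)
    if len(factors) != y.shape[0]:
        raise InputError("factors not aligned with expression rows")
    if categorical is None:
        categorical = [c for c in factors.columns if not pd.api.types.is_numeric_dtype(factors[c])]
    for col in factors.columns:
        if factors[col].nunique() < 2:
            raise InputError(f"factor {col!r} is constant")
    if residualize_for:
        cols = []
        for col in residualize_for:
            if col in categorical:
                cols.append(pd.get_dummies(factors[col], drop_first=True).to_numpy(dtype=float))
            else:
                cols.append(factors[[col]].to_numpy(dtype=float))
        y = _residualize(y, np.column_stack(cols))
    tss = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    zero_var = tss <= 0
    tss_safe = np.where(zero_var, 1.0, tss)
    out = {}
    for col in factors.columns:
        if col in categorical:
            codes, _ = pd.factorize(factors[col])
            rss = np.zeros(y.shape[1])
            for level in np.unique(codes):
                block = y[codes == level]
                rss += ((block - block.mean(axis=0)) ** 2).sum(axis=0)
            r2 = 1.0 - rss / tss_safe
        else:
            x = factors[col].to_numpy(dtype=float)
            xc = x - x.mean()
            denom = (xc**2).sum()
            yc = y - y.mean(axis=0)
            r2 = (xc @ yc) ** 2 / (denom * tss_safe)
        r2 = np.clip(r2, 0.0, 1.0)
        r2[zero_var] = np.nan
        out[col] = r2
    idx = genes if genes is not None else [f"g{i}" for i in range(y.shape[1])]
    return pd.DataFrame(out, index=idx)


def crossorgan_dendrogram(
    expr: np.ndarray | pd.DataFrame,
    labels: pd.DataFrame,
    n_per_stratum: int = 10,
    n_hvg: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Average-linkage clustering of subsampled cells across organs.

    Up to ``n_per_stratum`` cells per (cell type, tissue, time, donor)
    stratum are drawn deterministically from ``seed``; the ``n_hvg`` most
    variable genes (mean-binned normalized dispersion) are selected on the
    subsample; linkage is average on correlation distance. Returns the scipy
    linkage matrix and the leaf metadata table (row order = leaf ids).
    """
    for col in ("cell_type", "tissue", "time_h", "donor"):
        if col not in labels.columns:
            raise InputError(f"labels lack column {col!r}")
    y = np.asarray(expr, dtype=float)
    if len(labels) != y.shape[0]:
        raise InputError("labels not aligned with expression rows")
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for _, grp in labels.groupby(["cell_type", "tissue", "time_h", "donor"], sort=True):
        idx = grp.index.to_numpy()
        if len(idx) > n_per_stratum:
            idx = rng.choice(idx, size=n_per_stratum, replace=False)
        keep.append(np.sort(idx))
    if len(keep) < 2:
        raise InputError("need at least 2 strata for clustering")
    sel = np.concatenate(keep)
    pos = labels.index.get_indexer(sel)
    ys = y[pos]
    hvg = _highly_variable(ys, n_hvg)
    ys = ys[:, hvg]
    dist = pdist(ys, metric="correlation")
    link = hierarchy.linkage(dist, method="average")
    leaf_meta = labels.loc[sel].reset_index(drop=True)
    leaf_meta.insert(0, "leaf", np.arange(len(sel)))
    return link, leaf_meta


def _highly_variable(x: np.ndarray, n_hvg: int, n_bins: int = 20) -> np.ndarray:
    """Top-``n_hvg`` genes by normalized dispersion (z-scored within mean bins)."""
    mean = x.mean(axis=0)
    var = x.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = np.argsort(mean, kind="stable")
    bins = np.array_split(order, n_bins)
    z = np.zeros_like(disp)
    for b in bins:
        if len(b) == 0:
            continue
        mu, sd = disp[b].mean(), disp[b].std()
        z[b] = (disp[b] - mu) / sd if sd > 0 else 0.0
    n_hvg = min(n_hvg, x.shape[1])
    return np.sort(np.argsort(-z, kind="stable")[:n_hvg])


def linkage_to_newick(link: np.ndarray, leaf_names: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(link, leaf_names)
    return str(tree).strip()
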