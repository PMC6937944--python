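"""Cell-level QC: read-category fractions, quartile trends, cell/gene filters,
mitochondrial metrics and per-sample QC summary tables.

The cell filter reproduces a fixed threshold scheme: cells with fewer than
300 or more than 5000 detected genes (8000 in esophagus), more than 20,000
UMIs, or more than 10% mitochondrial reads are removed; boundary values are
kept ("less than" / "more than" are strict). Genes detected in fewer than
three cells of a tissue are dropped. These boundary semantics are asserted
by tests because an off-by-one here changes every downstream cell count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from .errors import InputError
from .stats import bh_adjust, t_test

__all__ = [
    "CellQcThresholds",
    "read_category_fractions",
    "quartile_extremes",
    "cell_metrics",
    "filter_cells",
    "filter_genes",
    "high_mito_rate",
    "sample_metrics",
]

KNOWN_TISSUES = ("lung", "esophagus", "spleen")


@dataclass(frozen=True)
class CellQcThresholds:
    """Cell and gene filter bounds; ``max_genes_esophagus`` replaces
    ``max_genes`` for esophagus samples."""

    min_genes: int = 300
    max_genes: int = 5000
    max_genes_esophagus: int = 8000
    max_umi: int = 20_000
    max_mt_pct: float = 10.0
    min_cells_per_gene: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.min_genes < self.max_genes):
            raise InputError("require 0 < min_genes < max_genes")
        if self.max_umi <= 0 or self.max_mt_pct <= 0 or self.min_cells_per_gene <= 0:
            raise InputError("thresholds must be positive")

    def gene_limit(self, tissue: str) -> int:
        return self.max_genes_esophagus if tissue == "esophagus" else self.max_genes


DEFAULT_CELL_THRESHOLDS = CellQcThresholds()


def read_category_fractions(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-barcode exonic/intronic/intergenic fractions of confident reads.

    ``counts`` must carry integer columns exonic, intronic, intergenic
    (indexed or keyed by barcode). Barcodes with zero confident reads are
    flagged (``flagged=True``) rather than dropped; their fractions are NaN
    and they are excluded from all downstream summaries.
    """
    for col in ("exonic", "intronic", "intergenic"):
        if col not in counts.columns:
            raise InputError(f"read-category table missing column {col!r}")
        if (counts[col] < 0).any():
            raise InputError(f"negative read counts in column {col!r}")
    total = counts[["exonic", "intronic", "intergenic"]].sum(axis=1)
    out = counts.copy()
    out["total_reads"] = total
    with np.errstate(invalid="ignore", divide="ignore"):
        for col in ("exonic", "intronic", "intergenic"):
            out[f"{col}_frac"] = np.where(total > 0, counts[col] / total, np.nan)
    out["flagged"] = total == 0
    return out


def quartile_extremes(
    fractions: pd.DataFrame,
    metric: str,
    sample_col: str = "sample_id",
    barcode_col: str = "barcode",
) -> pd.DataFrame:
    """Mean of the top and bottom quartile of cells per sample, by one metric.

    Cells are ranked by ``<metric>_frac``; the extreme quartiles contain
    ceil(n/4) cells each, with ties broken by barcode order so results are
    deterministic. Samples with fewer than 4 cells are skipped.
    """
    if metric not in ("exonic", "intronic"):
        raise InputError("metric must be 'exonic' or 'intronic'")
    col = f"{metric}_frac"
    rows = []
    usable = fractions[~fractions.get("flagged", False)] if "flagged" in fractions else fractions
    for sid, grp in usable.groupby(sample_col, sort=True):
        n = len(grp)
        if n < 4:
            continue
        k = math.ceil(n / 4)
        ordered = grp.sort_values([col, barcode_col], kind="mergesort")
        rows.append(
            {
                sample_col: sid,
                "metric": metric,
                "n_cells": n,
                "quartile_size": k,
                "bottom_mean": float(ordered[col].head(k).mean()),
                "top_mean": float(ordered[col].tail(k).mean()),
            }
        )
    return pd.DataFrame(rows)


def _to_csr(adata: AnnData) -> sparse.csr_matrix:
    x = adata.X
    return sparse.csr_matrix(x)


def cell_metrics(adata: AnnData, mt_genes: list[str] | None = None) -> pd.DataFrame:
    """Per-cell QC metrics: detected genes, UMI counts, mitochondrial percent.

    ``mt_genes`` defaults to features whose name starts with ``MT-``.
    mt_pct = 100 * (UMIs on the MT gene set) / (total UMIs).
    """
    x = _to_csr(adata)
    if mt_genes is None:
        mt_mask = adata.var_names.str.startswith("MT-")
    else:
        mt_mask = adata.var_names.isin(mt_genes)
    n_counts = np.asarray(x.sum(axis=1)).ravel()
    n_genes = np.asarray((x > 0).sum(axis=1)).ravel()
    mt_counts = np.asarray(x[:, np.asarray(mt_mask)].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mt_pct = np.where(n_counts > 0, 100.0 * mt_counts / n_counts, 0.0)
    return pd.DataFrame(
        {
            "barcode": adata.obs_names,
            "n_genes": n_genes.astype(int),
            "n_counts": n_counts.astype(int),
            "mt_pct": mt_pct,
        }
    ).set_index("barcode", drop=False)


def filter_cells(
    adata: AnnData,
    tissue: str,
    thresholds: CellQcThresholds = DEFAULT_CELL_THRESHOLDS,
    mt_genes: list[str] | None = None,
) -> tuple[AnnData, pd.DataFrame, pd.DataFrame]:
    """Apply the cell-level QC filter for one tissue.

    Returns (filtered AnnData, per-cell metric table of the *kept* cells,
    removal log). The removal log records, per removed cell, the first rule
    that fired, in the fixed order min_genes, max_genes, max_umi, max_mt.
    """
    if tissue not in KNOWN_TISSUES:
        raise InputError(f"unknown tissue label {tissue!r}; expected one of {KNOWN_TISSUES}")
    metrics = cell_metrics(adata, mt_genes)
    limit = thresholds.gene_limit(tissue)
    reasons = np.full(len(metrics), "", dtype=object)
    ng = metrics["n_genes"].to_numpy()
    nc = metrics["n_counts"].to_numpy()
    mt = metrics["mt_pct"].to_numpy()
    # first matching rule wins; boundary values pass every rule
    for name, bad in (
        ("min_genes", ng < thresholds.min_genes),
        ("max_genes", ng > limit),
        ("max_umi", nc > thresholds.max_umi),
        ("max_mt", mt > thresholds.max_mt_pct),
    ):
        reasons[(reasons == "") & bad] = name
    keep = reasons == ""
    removal_log = pd.DataFrame(
        {
            "barcode": metrics["barcode"].to_numpy()[~keep],
            "rule": reasons[~keep],
            "n_genes": ng[~keep],
            "n_counts": nc[~keep],
            "mt_pct": mt[~keep],
        }
    )
    kept = adata[keep].copy()
    return kept, metrics.loc[keep].copy(), removal_log


def filter_genes(adata: AnnData, min_cells: int = 3) -> AnnData:
    """Keep genes detected (count > 0) in at least ``min_cells`` cells.

    The matrix must already pool all cells of one tissue.
    """
    x = _to_csr(adata)
    detected = np.asarray((x > 0).sum(axis=0)).ravel()
    return adata[:, detected >= min_cells].copy()


def high_mito_rate(cells: pd.DataFrame, sample_col: str = "sample_id", cutoff: float = 10.0) -> pd.Series:
    """Per-sample fraction of cells with mt_pct strictly above ``cutoff``.

    Meant to run on the *unfiltered* cell table, before the mitochondrial
    filter removes exactly these cells.
    """
    if "mt_pct" not in cells.columns:
        raise InputError("cell table lacks mt_pct")
    return cells.groupby(sample_col)["mt_pct"].apply(lambda v: float((v > cutoff).mean()))


def sample_metrics(
    cells: pd.DataFrame,
    t0_label=0,
    metric_cols: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample QC metric table plus time-trend t tests.

    ``cells`` needs sample_id, donor, tissue, time_h, n_genes, n_counts and
    (optionally) total_reads / exonic_frac per cell. Metrics per sample:
    n_cells, median genes per cell, total confident reads, mean exonic
    (confidently mapped) fraction. Trend tests contrast the T0 sample group
    against each later time point per tissue with an unpaired two-sided t
    test, BH-corrected within each metric. Contrasts with fewer than two
    samples on a side are skipped and flagged; zero-variance identical
    groups report p = 1.
    """
    agg: dict[str, pd.Series] = {}
    grp = cells.groupby("sample_id")
    agg["n_cells"] = grp.size().astype(float)
    agg["median_genes"] = grp["n_genes"].median()
    if "total_reads" in cells.columns:
        agg["total_reads"] = grp["total_reads"].sum().astype(float)
    if "exonic_frac" in cells.columns:
        agg["mean_exonic_frac"] = grp["exonic_frac"].mean()
    meta = grp[["donor", "tissue", "time_h"]].first()
    metrics = pd.concat([meta, pd.DataFrame(agg)], axis=1).reset_index()
    metric_names = list(metric_cols) if metric_cols else [c for c in agg]

    rows = []
    for metric in metric_names:
        for tissue, tgrp in metrics.groupby("tissue"):
            base = tgrp.loc[tgrp["time_h"] == t0_label, metric].dropna()
            for tp in sorted(t for t in tgrp["time_h"].unique() if t != t0_label):
                other = tgrp.loc[tgrp["time_h"] == tp, metric].dropna()
                row = {"metric": metric, "tissue": tissue, "time_h": tp, "n_t0": len(base), "n_t": len(other)}
                if len(base) < 2 or len(other) < 2:
                    row.update(statistic=np.nan, pvalue=np.nan, status="skipped_single_sample")
                else:
                    res = t_test(base, other, paired=False)
                    row.update(statistic=res.statistic, pvalue=res.pvalue, status="ok")
                rows.append(row)
    tests = pd.DataFrame(rows)
    if not tests.empty:
        tests["p_adj"] = np.nan
        for metric, idx in tests.groupby("metric").groups.items():
            tests.loc[idx, "p_adj"] = bh_adjust(tests.loc[idx, "pvalue"])
    return metrics, tests
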