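"""Pseudo-bulk construction and differential expression.

Bulk and pseudo-bulk libraries are normalized to counts per million (CPM)
per sample before testing; fold changes are median-over-samples
log2((a + 1) / (b + 1)) on the CPM scale. The paired comparison uses the
Wilcoxon signed-rank test across matched samples (exact when sample counts
are small and tie-free), the unpaired variant a Mann-Whitney rank-sum test.
Gene-set overrepresentation uses a one-sided Fisher exact test.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse
from scipy import stats as sps

from .errors import InputError
from .stats import bh_adjust

__all__ = [
    "make_pseudobulk",
    "cpm",
    "wilcoxon_de",
    "storage_signature",
    "signature_overlap_fisher",
]


def make_pseudobulk(adata: AnnData, sample_col: str = "sample_id") -> pd.DataFrame:
    """Sum raw counts per sample: gene x sample matrix with full gene universe."""
    if sample_col not in adata.obs.columns:
        raise InputError(f"obs lacks column {sample_col!r}")
    assign = adata.obs[sample_col]
    unassigned = adata.obs_names[assign.isna() | (assign.astype(str) == "")]
    if len(unassigned):
        raise InputError(f"cells without sample assignment: {list(unassigned[:5])}...")
    x = sparse.csr_matrix(adata.X)
    cols = {}
    for sid, idx in adata.obs.groupby(sample_col, observed=True).groups.items():
        pos = adata.obs_names.get_indexer(idx)
        cols[sid] = np.asarray(x[pos].sum(axis=0)).ravel().astype(np.int64)
    return pd.DataFrame(cols, index=adata.var_names)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per sample (column)."""
    totals = counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        raise InputError("sample with zero total counts")
    return counts * (1e6 / totals)


def wilcoxon_de(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    paired: bool = True,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene differential expression between two gene x sample matrices.

    Matrices are CPM-normalized internally (raw counts in). When paired,
    columns are matched by name and a Wilcoxon signed-rank test is run per
    gene with zero differences dropped; genes with fewer than 2 usable pairs
    (or all-zero in both groups) are reported untested (NaN p). BH
    correction spans the tested genes.
    """
    genes = group_a.index.intersection(group_b.index)
    if len(genes) == 0:
        raise InputError("no shared genes between the two groups")
    a_raw = group_a.loc[genes]
    b_raw = group_b.loc[genes]
    if paired:
        shared = [c for c in a_raw.columns if c in set(b_raw.columns)]
        if len(shared) < 2:
            raise InputError("paired DE needs >= 2 matched samples")
        a_raw, b_raw = a_raw[shared], b_raw[shared]
    a = cpm(a_raw)
    b = cpm(b_raw)
    rows = []
    for g in genes:
        av = a.loc[g].to_numpy(dtype=float)
        bv = b.loc[g].to_numpy(dtype=float)
        if paired:
            lfc = float(np.median(np.log2((av + pseudocount) / (bv + pseudocount))))
            d = av - bv
            usable = d[d != 0]
            if (av == 0).all() and (bv == 0).all():
                p, status = np.nan, "untested_all_zero"
            elif len(usable) == 0:
                # every pair is a zero difference: no evidence of change
                p, status = 1.0, "ok"
            elif len(usable) < 2:
                p, status = np.nan, "untested_too_few_pairs"
            else:
                p = float(sps.wilcoxon(av, bv, zero_method="wilcox", mode="auto").pvalue)
                status = "ok"
            n_used = len(usable)
        else:
            lfc = float(
                np.median(np.log2((av + pseudocount))) - np.median(np.log2(bv + pseudocount))
            )
            if (av == 0).all() and (bv == 0).all():
                p, status = np.nan, "untested_all_zero"
            elif np.allclose(av, av[0]) and np.allclose(bv, bv[0]) and np.isclose(av[0], bv[0]):
                p, status = 1.0, "ok"
            else:
                p = float(sps.mannwhitneyu(av, bv, alternative="two-sided").pvalue)
                status = "ok"
            n_used = len(av) + len(bv)
        rows.append(
            {
                "gene": g,
                "pvalue": p,
                "median_log2_foldchange": lfc,
                "direction": "up" if lfc > 0 else ("down" if lfc < 0 else "flat"),
                "n_pairs": n_used,
                "status": status,
            }
        )
    out = pd.DataFrame(rows).set_index("gene", drop=False)
    if out["pvalue"].isna().all():
        raise InputError("zero genes tested")
    out["p_adj"] = bh_adjust(out["pvalue"])
    return out


def storage_signature(
    adata: AnnData,
    cell_type_col: str = "cell_type",
    time_col: str = "time_h",
    t0_label: float = 0.0,
    late_label: float = 72.0,
    min_cells: int = 20,
    alpha: float = 0.01,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-cell-type cold-storage gene signatures, plus their Jaccard matrix.

    For every cell type with at least ``min_cells`` cells at both time
    points, each gene's log-normalized expression is compared T0 vs late by
    a two-sided rank-sum test; the signature is the genes with BH-adjusted
    p < ``alpha``, ranked by absolute effect (difference of mean
    log-normalized expression, late minus T0).
    """
    from .annotate import log_normalize

    obs = adata.obs
    logx = log_normalize(adata.X)
    signatures: dict[str, pd.DataFrame] = {}
    for ct in sorted(obs[cell_type_col].unique()):
        m0 = (obs[cell_type_col] == ct) & (obs[time_col] == t0_label)
        m1 = (obs[cell_type_col] == ct) & (obs[time_col] == late_label)
        if m0.sum() < min_cells or m1.sum() < min_cells:
            continue
        x0 = logx[np.asarray(m0)]
        x1 = logx[np.asarray(m1)]
        pvals = np.full(adata.n_vars, np.nan)
        for j in range(adata.n_vars):
            if np.allclose(x0[:, j], 0) and np.allclose(x1[:, j], 0):
                continue
            pvals[j] = sps.mannwhitneyu(x1[:, j], x0[:, j], alternative="two-sided").pvalue
        p_adj = bh_adjust(pvals)
        effect = x1.mean(axis=0) - x0.mean(axis=0)
        table = pd.DataFrame(
            {"gene": adata.var_names, "pvalue": pvals, "p_adj": p_adj, "effect": effect}
        )
        sig = table[table["p_adj"] < alpha].copy()
        sig["abs_effect"] = sig["effect"].abs()
        sig = sig.sort_values(["abs_effect", "gene"], ascending=[False, True]).drop(
            columns="abs_effect"
        )
        signatures[ct] = sig.reset_index(drop=True)
    names = sorted(signatures)
    jac = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        sa, sb = set(signatures[a]["gene"]), set(signatures[b]["gene"])
        union = sa | sb
        j = len(sa & sb) / len(union) if union else 0.0
        jac.loc[a, b] = jac.loc[b, a] = j
    return signatures, jac


def signature_overlap_fisher(
    signature: set[str] | list[str],
    reference: set[str] | list[str],
    universe: set[str] | list[str],
) -> tuple[float, float, pd.DataFrame]:
    """One-sided (enrichment) Fisher exact test of signature vs reference genes.

    Returns (odds ratio, p-value, 2x2 table). The odds ratio uses a Haldane
    0.5 correction when any margin cell is zero; the p-value is the exact
    hypergeometric upper tail.
    """
    uni = set(universe)
    if not uni:
        raise InputError("empty gene universe")
    sig = set(signature)
    ref = set(reference)
    if not sig <= uni or not ref <= uni:
        raise InputError("signature and reference must be subsets of the universe")
    a = len(sig & ref)
    b = len(sig - ref)
    c = len(ref - sig)
    d = len(uni - sig - ref)
    table = pd.DataFrame(
        [[a, b], [c, d]],
        index=["in_signature", "out_signature"],
        columns=["in_reference", "out_reference"],
    )
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="greater")
    if min(a, b, c, d) == 0:
        oddsratio = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        oddsratio = (a * d) / (b * c)
    return float(oddsratio), float(p), table
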