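"""Reading and writing the standard on-disk formats.

Count matrices use the 10x filtered-matrix convention: a MatrixMarket
coordinate file (genes x barcodes, 1-based indices) next to barcodes.tsv and
features.tsv. Internally everything is 0-based with barcodes as rows.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from anndata import AnnData
from scipy import io as spio
from scipy import sparse

from .droplets import DropletTable
from .errors import FormatError

__all__ = ["load_count_matrix", "droplet_table_to_anndata", "read_gene_set"]


def load_count_matrix(
    mtx_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
    sample_id: str = "",
) -> DropletTable:
    """Load an MTX triplet into a :class:`DropletTable` (barcodes x genes).

    The MTX file stores genes as rows; header dimensions must match the TSV
    line counts or a :class:`FormatError` naming the offending file is raised.
    """
    mtx_path, barcodes_path, features_path = Path(mtx_path), Path(barcodes_path), Path(features_path)
    for p in (mtx_path, barcodes_path, features_path):
        if not p.exists():
            raise FormatError(f"missing input file: {p}")
    try:
        mat = spio.mmread(str(mtx_path))
    except Exception as exc:  # malformed header/triplets
        raise FormatError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc
    barcodes = [ln.split("\t")[0] for ln in barcodes_path.read_text().splitlines() if ln.strip()]
    features = [ln.split("\t")[0] for ln in features_path.read_text().splitlines() if ln.strip()]
    n_genes, n_barcodes = mat.shape
    if n_barcodes != len(barcodes):
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} barcodes but matrix has {n_barcodes} columns"
        )
    if n_genes != len(features):
        raise FormatError(
            f"{features_path}: {len(features)} features but matrix has {n_genes} rows"
        )
    counts = sparse.csr_matrix(mat.T)
    return DropletTable(sample_id or mtx_path.parent.name, barcodes, features, counts)


def droplet_table_to_anndata(table: DropletTable, obs: pd.DataFrame | None = None) -> AnnData:
    """Wrap a droplet table (or a subset of it) as an AnnData for QC analysis."""
    adata = AnnData(X=table.counts.copy())
    adata.obs_names = pd.Index(table.barcodes)
    adata.var_names = pd.Index(table.features)
    if obs is not None:
        adata.obs = obs.reindex(adata.obs_names)
    return adata


def read_gene_set(path: str | Path) -> list[str]:
    """Read a gene-set file: one symbol per line, '#' comments allowed."""
    out = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if ln and not ln.startswith("#"):
            out.append(ln)
    return out
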