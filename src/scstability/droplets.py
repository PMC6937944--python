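"""Droplet-level QC: depth-normalized UMI statistic and its three-way classification.

A droplet sequencing run captures, besides intact cells, many droplets that
contain only cell-free "ambient" transcripts or fragments of damaged cells
("debris"). The depth-corrected statistic used here is

    normalized UMI = UMI per droplet * 1,000,000 / UMI in all droplets of the run

so that the values of one run sum to one million regardless of sequencing
depth. Droplets are then binned into three intervals of normalized UMI:
ambient RNA (0, 0.25], debris (0.25, 5], and cellular material (5, inf).
Zero-UMI barcodes fall outside the first (open) interval and are reported as
"unclassified".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import InputError
from .stats import TTestResult, t_test

__all__ = [
    "DropletTable",
    "ClassThresholds",
    "DEFAULT_THRESHOLDS",
    "normalize_umi",
    "classify_droplets",
    "class_means",
    "compare_time_points",
    "ambient_profile",
]

MILLION = 1_000_000.0

AMBIENT = "ambient"
DEBRIS = "debris"
CELLULAR = "cellular"
UNCLASSIFIED = "unclassified"


@dataclass
class DropletTable:
    """Per-barcode UMI counts of one sequencing run, before cell calling.

    ``counts`` is a barcodes x genes sparse matrix of raw UMI counts;
    ``umi_total`` is derived from its row sums so the conservation invariant
    (per-droplet gene counts sum to the droplet's UMI total) holds by
    construction.
    """

    sample_id: str
    barcodes: list[str]
    features: list[str]
    counts: sparse.csr_matrix
    umi_total: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.barcodes), len(self.features)):
            raise InputError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.features)} features"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise InputError(f"duplicate barcodes in sample {self.sample_id}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise InputError("negative counts")
        self.umi_total = np.asarray(self.counts.sum(axis=1)).ravel().astype(np.int64)

    @property
    def n_droplets(self) -> int:
        return len(self.barcodes)


@dataclass(frozen=True)
class ClassThresholds:
    """Interval bounds of the three droplet classes, on the normalized-UMI scale.

    The intervals are (lower_ambient, upper_ambient], (upper_ambient,
    upper_debris], (upper_debris, inf); upper bounds inclusive.
    """

    lower_ambient: float = 0.0
    upper_ambient: float = 0.25
    upper_debris: float = 5.0

    def __post_init__(self) -> None:
        if not (self.lower_ambient < self.upper_ambient < self.upper_debris):
            raise InputError("droplet class thresholds must be strictly ordered")


DEFAULT_THRESHOLDS = ClassThresholds()


def normalize_umi(table: DropletTable | np.ndarray) -> np.ndarray:
    """Read-depth-normalized UMI per droplet.

    Accepts a :class:`DropletTable` or a plain vector of per-barcode UMI
    totals. The returned values sum to 1,000,000 over the run.
    """
    totals = table.umi_total if isinstance(table, DropletTable) else np.asarray(table, dtype=float)
    if totals.ndim != 1:
        raise InputError("umi totals must be one-dimensional")
    if (totals < 0).any():
        raise InputError("negative UMI totals")
    grand = totals.sum()
    if grand <= 0:
        raise InputError("empty run: all barcodes have zero UMIs")
    return totals * (MILLION / grand)


def classify_droplets(norm: np.ndarray, thresholds: ClassThresholds = DEFAULT_THRESHOLDS) -> np.ndarray:
    """Assign each droplet to ambient / debris / cellular by its normalized UMI.

    Boundaries are inclusive on the upper end; exactly-zero droplets are
    "unclassified" because the ambient interval is open at 0.
    """
    norm = np.asarray(norm, dtype=float)
    labels = np.full(norm.shape, UNCLASSIFIED, dtype=object)
    labels[(norm > thresholds.lower_ambient) & (norm <= thresholds.upper_ambient)] = AMBIENT
    labels[(norm > thresholds.upper_ambient) & (norm <= thresholds.upper_debris)] = DEBRIS
    labels[norm > thresholds.upper_debris] = CELLULAR
    return labels


def class_means(norm: np.ndarray, labels: np.ndarray, sample_id: str = "") -> pd.DataFrame:
    """Per-class droplet count and mean normalized UMI for one run.

    Classes with no droplets are absent from the table (missing, not zero).
    """
    norm = np.asarray(norm, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if norm.shape != labels.shape:
        raise InputError("labels not aligned with normalized values")
    rows = []
    for cls in (AMBIENT, DEBRIS, CELLULAR):
        mask = labels == cls
        if mask.any():
            rows.append(
                {
                    "sample_id": sample_id,
                    "droplet_class": cls,
                    "n_droplets": int(mask.sum()),
                    "mean_norm_umi": float(norm[mask].mean()),
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "droplet_class", "n_droplets", "mean_norm_umi"])


def compare_time_points(
    per_donor_means: pd.DataFrame,
    t0_label,
    other_label,
    paired: bool,
    value_col: str = "mean_norm_umi",
    group_col: str = "time_h",
    donor_col: str = "donor",
) -> TTestResult:
    """Student t test of per-donor class means between two time points.

    ``paired=True`` matches donors across the two time points (the design
    used for the T0 vs 72 h contrast); unpaired compares the two donor
    groups directly (T0 vs 24 h).
    """
    df = per_donor_means
    a = df[df[group_col] == t0_label]
    b = df[df[group_col] == other_label]
    if a.empty or b.empty:
        raise InputError(f"no observations for group {t0_label if a.empty else other_label}")
    if paired:
        merged = a.merge(b, on=donor_col, suffixes=("_0", "_1"))
        if len(merged) < 2:
            raise InputError("paired comparison needs >= 2 matched donors")
        return t_test(merged[f"{value_col}_0"], merged[f"{value_col}_1"], paired=True)
    return t_test(a[value_col], b[value_col], paired=False)


def ambient_profile(table: DropletTable, labels: np.ndarray) -> pd.DataFrame:
    """Gene-level composition of the ambient RNA pool.

    Sums counts over droplets labelled ambient, divides by the total ambient
    UMIs and returns genes ranked by their soup fraction (descending; the
    fractions sum to 1).
    """
    labels = np.asarray(labels, dtype=object)
    mask = labels == AMBIENT
    if not mask.any():
        raise InputError(f"no ambient droplets in sample {table.sample_id}")
    sums = np.asarray(table.counts[mask].sum(axis=0)).ravel().astype(float)
    total = sums.sum()
    if total <= 0:
        raise InputError("ambient droplets contain no UMIs")
    out = pd.DataFrame({"gene": table.features, "ambient_umis": sums, "fraction": sums / total})
    out = out.sort_values(["fraction", "gene"], ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)
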