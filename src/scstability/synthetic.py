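"""Synthetic droplet-experiment generator with known ground truth.

Emulates the structure of a multi-donor, multi-tissue cold-storage study:
for every (donor, tissue, time point) one sequencing run is generated whose
droplets span three regimes — intact cells, debris (damaged-cell fragments
at reduced depth), and ambient RNA (cell-free transcripts at very low
depth). Degradation effects can be injected per tissue and time point:

* mitochondrial inflation — a fraction of each cell's UMIs is reallocated
  to the mitochondrial gene set (depth is preserved, so MT% and depth stay
  orthogonal);
* intron shift — the per-barcode exonic read fraction is translated down by
  a stated amount, the intronic fraction gaining correspondingly;
* ambient fraction — the share of the run's total UMIs sitting in ambient
  droplets is driven to a stated target;
* storage-signature scaling — a set of genes whose expression is multiplied
  by a per-time-point factor.

Count model: per-droplet UMI totals are log-normal around their class mean
(classes roughly a decade apart in depth), and each droplet's total is
partitioned over genes by a multinomial on its (adjusted) expression
profile. Ambient droplets draw from the UMI-weighted mixture of all cell
type profiles ("soup"). Generation is a pure function of the configuration:
the same config (including seed) reproduces the experiment bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .droplets import DropletTable
from .errors import ConfigurationError, InputError

__all__ = [
    "DegradationParams",
    "SimConfig",
    "SampleMeta",
    "SyntheticSample",
    "SyntheticExperiment",
    "generate_experiment",
    "generate_bulk",
    "write_fixture",
    "load_fixture",
]

# Human mitochondrial protein-coding gene names used for the MT feature block.
MT_GENE_NAMES = [
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
]
# Immediate-early dissociation-stress genes, kept by name in the synthetic
# feature space so overlap tests against the shipped reference list have
# known positives.
STRESS_GENE_NAMES = ["FOS", "FOSB", "JUN", "JUNB"]


@dataclass
class DegradationParams:
    """Injectable degradation effects; all default to the null (no effect).

    Keys are (tissue, cell_type, time_h) for ``mt_fold_change`` and
    (tissue, time_h) for the per-run effects; unlisted keys mean factor 1 /
    shift 0 / default ambient depth.
    """

    mt_fold_change: dict[tuple[str, str, float], float] = field(default_factory=dict)
    intron_shift: dict[tuple[str, float], float] = field(default_factory=dict)
    ambient_umi_fraction: dict[tuple[str, float], float] = field(default_factory=dict)
    storage_signature_genes: list[int] = field(default_factory=list)
    signature_fold_by_time: dict[float, float] = field(default_factory=dict)

    def mt_factor(self, tissue: str, cell_type: str, time_h: float) -> float:
        return self.mt_fold_change.get((tissue, cell_type, time_h), 1.0)

    def intron_shift_at(self, tissue: str, time_h: float) -> float:
        return self.intron_shift.get((tissue, time_h), 0.0)

    def ambient_fraction_at(self, tissue: str, time_h: float) -> float | None:
        return self.ambient_umi_fraction.get((tissue, time_h))

    def signature_factor(self, time_h: float) -> float:
        return self.signature_fold_by_time.get(time_h, 1.0)

    def validate(self) -> None:
        for key, v in self.mt_fold_change.items():
            if v <= 0:
                raise ConfigurationError(f"mt_fold_change{key} must be > 0, got {v}")
            if key[2] == 0 and v != 1.0:
                raise ConfigurationError(f"mt_fold_change{key}: factor at time 0 must be 1")
        for key, v in self.intron_shift.items():
            if not 0 <= v < 1:
                raise ConfigurationError(f"intron_shift{key} must be in [0, 1), got {v}")
            if key[1] == 0 and v != 0.0:
                raise ConfigurationError(f"intron_shift{key}: shift at time 0 must be 0")
        for key, v in self.ambient_umi_fraction.items():
            if not 0 <= v < 1:
                raise ConfigurationError(f"ambient_umi_fraction{key} must be in [0, 1), got {v}")
        for t, v in self.signature_fold_by_time.items():
            if v <= 0:
                raise ConfigurationError(f"signature_fold_by_time[{t}] must be > 0, got {v}")
            if t == 0 and v != 1.0:
                raise ConfigurationError("signature_fold_by_time at time 0 must be 1")

    def to_jsonable(self) -> dict:
        return {
            "mt_fold_change": [
                {"tissue": k[0], "cell_type": k[1], "time_h": k[2], "value": v}
                for k, v in self.mt_fold_change.items()
            ],
            "intron_shift": [
                {"tissue": k[0], "time_h": k[1], "value": v} for k, v in self.intron_shift.items()
            ],
            "ambient_umi_fraction": [
                {"tissue": k[0], "time_h": k[1], "value": v}
                for k, v in self.ambient_umi_fraction.items()
            ],
            "storage_signature_genes": list(self.storage_signature_genes),
            "signature_fold_by_time": {str(k): v for k, v in self.signature_fold_by_time.items()},
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "DegradationParams":
        return cls(
            mt_fold_change={
                (r["tissue"], r["cell_type"], r["time_h"]): r["value"] for r in d["mt_fold_change"]
            },
            intron_shift={(r["tissue"], r["time_h"]): r["value"] for r in d["intron_shift"]},
            ambient_umi_fraction={
                (r["tissue"], r["time_h"]): r["value"] for r in d["ambient_umi_fraction"]
            },
            storage_signature_genes=list(d["storage_signature_genes"]),
            signature_fold_by_time={float(k): v for k, v in d["signature_fold_by_time"].items()},
        )


@dataclass
class SimConfig:
    """Full description of a synthetic cold-storage experiment."""

    n_donors: int
    tissues: list[str]
    time_points_h: list[float]
    n_cells_per_sample: int
    n_genes: int
    n_ambient_droplets: int
    n_debris_droplets: int
    cell_type_profiles: dict[str, np.ndarray]
    cell_type_proportions: dict[str, dict[str, float]]
    mean_umis_per_cell: float = 20_000.0
    mean_umis_per_debris: float = 30.0
    mean_umis_per_ambient: float = 2.0
    baseline_mt_fraction: float = 0.05
    degradation: DegradationParams = field(default_factory=DegradationParams)
    seed: int = 0
    # secondary knobs (spread of the count model and the read-category model)
    umi_sigma_cell: float = 0.5
    umi_sigma_debris: float = 0.35
    umi_sigma_ambient: float = 0.45
    reads_per_umi: float = 4.0
    exonic_mean: float = 0.75
    intergenic_frac: float = 0.03
    beta_concentration: float = 100.0
    ambient_upweight_genes: list[int] = field(default_factory=list)
    ambient_upweight_factor: float = 1.0

    @property
    def donors(self) -> list[str]:
        return [f"D{i + 1}" for i in range(self.n_donors)]

    @property
    def cell_types(self) -> list[str]:
        return list(self.cell_type_profiles)

    @property
    def features(self) -> list[str]:
        return make_feature_names(self.n_genes)

    @property
    def mt_gene_indices(self) -> np.ndarray:
        return np.arange(min(len(MT_GENE_NAMES), self.n_genes))

    def validate(self) -> None:
        for name, v in (
            ("n_donors", self.n_donors),
            ("n_cells_per_sample", self.n_cells_per_sample),
            ("n_genes", self.n_genes),
        ):
            if v <= 0:
                raise ConfigurationError(f"{name} must be positive, got {v}")
        if self.n_ambient_droplets < 0 or self.n_debris_droplets < 0:
            raise ConfigurationError("droplet counts must be non-negative")
        for name, v in (
            ("mean_umis_per_cell", self.mean_umis_per_cell),
            ("mean_umis_per_debris", self.mean_umis_per_debris),
            ("mean_umis_per_ambient", self.mean_umis_per_ambient),
        ):
            if v <= 0:
                raise ConfigurationError(f"{name} must be positive, got {v}")
        if not 0 <= self.baseline_mt_fraction < 1:
            raise ConfigurationError("baseline_mt_fraction must be in [0, 1)")
        tps = list(self.time_points_h)
        if any(t < 0 for t in tps):
            raise ConfigurationError("time_points_h must be non-negative")
        if sorted(tps) != tps or len(set(tps)) != len(tps):
            raise ConfigurationError("time_points_h must be distinct and sorted")
        if not self.cell_type_profiles:
            raise ConfigurationError("cell_type_profiles must not be empty")
        for ct, p in self.cell_type_profiles.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (self.n_genes,):
                raise ConfigurationError(
                    f"cell_type_profiles[{ct!r}] has length {p.shape[0]}, expected n_genes={self.n_genes}"
                )
            if (p < 0).any():
                raise ConfigurationError(f"cell_type_profiles[{ct!r}] has negative entries")
            if not np.isclose(p.sum(), 1.0, atol=1e-6):
                raise ConfigurationError(f"cell_type_profiles[{ct!r}] must sum to 1, sums to {p.sum()}")
        donors = set(self.donors)
        if set(self.cell_type_proportions) != donors:
            raise ConfigurationError("cell_type_proportions must have one entry per donor")
        for donor, props in self.cell_type_proportions.items():
            if set(props) != set(self.cell_type_profiles):
                raise ConfigurationError(
                    f"cell_type_proportions[{donor!r}] keys must match cell_type_profiles"
                )
            total = sum(props.values())
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ConfigurationError(
                    f"cell_type_proportions[{donor!r}] must sum to 1, sums to {total}"
                )
        self.degradation.validate()

    # -- serialization ---------------------------------------------------

    def to_jsonable(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_donors", "tissues", "time_points_h", "n_cells_per_sample", "n_genes",
                "n_ambient_droplets", "n_debris_droplets", "mean_umis_per_cell",
                "mean_umis_per_debris", "mean_umis_per_ambient", "baseline_mt_fraction",
                "seed", "umi_sigma_cell", "umi_sigma_debris", "umi_sigma_ambient",
                "reads_per_umi", "exonic_mean", "intergenic_frac", "beta_concentration",
                "ambient_upweight_genes", "ambient_upweight_factor",
            )
        }
        d["cell_type_profiles"] = {k: np.asarray(v).tolist() for k, v in self.cell_type_profiles.items()}
        d["cell_type_proportions"] = self.cell_type_proportions
        d["degradation"] = self.degradation.to_jsonable()
        return d

    @classmethod
    def from_jsonable(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["cell_type_profiles"] = {k: np.asarray(v, dtype=float) for k, v in d["cell_type_profiles"].items()}
        d["degradation"] = DegradationParams.from_jsonable(d["degradation"])
        return cls(**d)

    @classmethod
    def default(
        cls,
        n_donors: int = 5,
        tissues: list[str] | None = None,
        time_points_h: list[float] | None = None,
        n_cells_per_sample: int = 1000,
        n_genes: int = 120,
        n_ambient_droplets: int = 4000,
        n_debris_droplets: int = 1500,
        n_cell_types: int = 3,
        seed: int = 0,
        **kwargs,
    ) -> "SimConfig":
        """Study-design defaults: 5 donors x 3 tissues x 4 time points, with
        marker-block cell-type profiles shared by all donors."""
        tissues = tissues if tissues is not None else ["lung", "esophagus", "spleen"]
        time_points_h = time_points_h if time_points_h is not None else [0.0, 12.0, 24.0, 72.0]
        # Keep the expected run total near 20M UMIs so the three classes sit at
        # their default normalized-UMI targets (~0.1 / ~1.5 / ~1000) whatever
        # the cell count; an explicit mean_umis_per_cell overrides this.
        kwargs.setdefault("mean_umis_per_cell", 2.0e7 / n_cells_per_sample)
        type_names = ["T_cell", "B_cell", "Monocyte", "Plasma_cell", "Epithelial"][:n_cell_types]
        profiles = default_profiles(n_genes, type_names)
        base = [0.45, 0.3, 0.25, 0.15, 0.1][:n_cell_types]
        props = np.asarray(base) / np.sum(base)
        proportions = {
            f"D{i + 1}": {t: float(p) for t, p in zip(type_names, props)} for i in range(n_donors)
        }
        return cls(
            n_donors=n_donors,
            tissues=list(tissues),
            time_points_h=[float(t) for t in time_points_h],
            n_cells_per_sample=n_cells_per_sample,
            n_genes=n_genes,
            n_ambient_droplets=n_ambient_droplets,
            n_debris_droplets=n_debris_droplets,
            cell_type_profiles=profiles,
            cell_type_proportions=proportions,
            seed=seed,
            **kwargs,
        )


def make_feature_names(n_genes: int) -> list[str]:
    named = MT_GENE_NAMES + STRESS_GENE_NAMES
    if n_genes <= len(named):
        return named[:n_genes]
    return named + [f"GENE{i:04d}" for i in range(n_genes - len(named))]


def default_profiles(n_genes: int, type_names: list[str], marker_weight: float = 20.0) -> dict[str, np.ndarray]:
    """Marker-block expression profiles: each type up-weights a disjoint
    block of the generic gene space over a uniform background. MT genes get
    zero base mass (it is injected at draw time)."""
    n_named = len(MT_GENE_NAMES) + len(STRESS_GENE_NAMES)
    if n_genes < n_named + 4 * len(type_names):
        raise ConfigurationError(
            f"n_genes={n_genes} too small for {len(type_names)} marker blocks"
        )
    n_mt = len(MT_GENE_NAMES)
    generic = np.arange(n_named, n_genes)
    block = len(generic) // (2 * len(type_names))
    profiles: dict[str, np.ndarray] = {}
    for i, name in enumerate(type_names):
        p = np.ones(n_genes)
        p[:n_mt] = 0.0  # MT mass handled by the degradation model
        markers = generic[i * block : (i + 1) * block]
        p[markers] *= marker_weight
        profiles[name] = p / p.sum()
    return profiles


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    donor: str
    tissue: str
    time_h: float


@dataclass
class SyntheticSample:
    meta: SampleMeta
    droplets: DropletTable
    read_categories: pd.DataFrame  # barcode-indexed: exonic, intronic, intergenic
    truth: pd.DataFrame  # barcode, droplet_class, cell_type
    truth_summary: dict


@dataclass
class SyntheticExperiment:
    config: SimConfig
    samples: list[SyntheticSample]

    def sample_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"sample_id": s.meta.sample_id, "donor": s.meta.donor,
                 "tissue": s.meta.tissue, "time_h": s.meta.time_h}
                for s in self.samples
            ]
        )

    def checksum(self) -> str:
        h = hashlib.sha256()
        for s in self.samples:
            h.update(s.meta.sample_id.encode())
            m = s.droplets.counts.tocoo()
            h.update(np.ascontiguousarray(m.row).tobytes())
            h.update(np.ascontiguousarray(m.col).tobytes())
            h.update(np.ascontiguousarray(m.data).tobytes())
            h.update(s.read_categories.to_csv().encode())
            h.update(s.truth.to_csv().encode())
        return h.hexdigest()


def _lognormal_totals(rng: np.random.Generator, n: int, mean: float, sigma: float) -> np.ndarray:
    """Integer UMI totals, log-normal with the given arithmetic mean; min 1."""
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    mu = np.log(mean) - sigma**2 / 2.0
    vals = np.rint(rng.lognormal(mu, sigma, size=n)).astype(np.int64)
    return np.maximum(vals, 1)


def _adjusted_profile(
    config: SimConfig, base: np.ndarray, tissue: str, cell_type: str | None, time_h: float
) -> np.ndarray:
    """Apply signature scaling and MT reallocation to a base profile."""
    p = np.asarray(base, dtype=float).copy()
    deg = config.degradation
    sig_factor = deg.signature_factor(time_h)
    if deg.storage_signature_genes and sig_factor != 1.0:
        idx = np.asarray(deg.storage_signature_genes, dtype=int)
        p[idx] *= sig_factor
    mt_idx = config.mt_gene_indices
    mt_frac = config.baseline_mt_fraction
    if cell_type is not None:
        mt_frac = min(mt_frac * deg.mt_factor(tissue, cell_type, time_h), 0.9)
    if len(mt_idx) and mt_frac > 0:
        non_mt = np.ones(len(p), dtype=bool)
        non_mt[mt_idx] = False
        p[mt_idx] = mt_frac / len(mt_idx)  # uniform within the MT block
        s = p[non_mt].sum()
        p[non_mt] *= (1.0 - mt_frac) / s
    else:
        p /= p.sum()
    return p


def _draw_counts(rng: np.random.Generator, totals: np.ndarray, profile: np.ndarray) -> np.ndarray:
    if len(totals) == 0:
        return np.zeros((0, len(profile)), dtype=np.int64)
    return rng.multinomial(totals, profile)


def _read_categories(
    config: SimConfig, rng: np.random.Generator, umi_totals: np.ndarray, shift: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-barcode confident-read counts split into exonic/intronic/intergenic.

    The exonic fraction is Beta-distributed at baseline and translated down
    by the intron shift; the intergenic share is a small constant; the
    intronic fraction absorbs the shift.
    """
    n = len(umi_totals)
    total_reads = rng.poisson(config.reads_per_umi * umi_totals)
    kappa = config.beta_concentration
    e0 = config.exonic_mean
    x = rng.beta(e0 * kappa, (1 - e0) * kappa, size=n) - shift
    x = np.clip(x, 0.0, 1.0 - config.intergenic_frac)
    exonic = rng.binomial(total_reads, x)
    rest = total_reads - exonic
    with np.errstate(invalid="ignore", divide="ignore"):
        p_inter_given_rest = np.where(x < 1.0, config.intergenic_frac / (1.0 - x), 1.0)
    intergenic = rng.binomial(rest, np.clip(p_inter_given_rest, 0.0, 1.0))
    intronic = rest - intergenic
    return exonic, intronic, intergenic


def _generate_sample(
    config: SimConfig, donor: str, tissue: str, time_h: float, rng: np.random.Generator
) -> SyntheticSample:
    deg = config.degradation
    types = config.cell_types
    props = np.array([config.cell_type_proportions[donor][t] for t in types])
    type_profiles = {
        t: _adjusted_profile(config, config.cell_type_profiles[t], tissue, t, time_h) for t in types
    }

    # cells
    n_per_type = rng.multinomial(config.n_cells_per_sample, props)
    cell_blocks, cell_types_per_droplet, cell_totals_list = [], [], []
    for t, k in zip(types, n_per_type):
        totals = _lognormal_totals(rng, int(k), config.mean_umis_per_cell, config.umi_sigma_cell)
        cell_blocks.append(_draw_counts(rng, totals, type_profiles[t]))
        cell_types_per_droplet.extend([t] * int(k))
        cell_totals_list.append(totals)

    # debris: damaged-cell fragments, same profiles at reduced depth
    n_deb = config.n_debris_droplets
    deb_types = rng.choice(len(types), size=n_deb, p=props) if n_deb else np.zeros(0, dtype=int)
    deb_totals = _lognormal_totals(rng, n_deb, config.mean_umis_per_debris, config.umi_sigma_debris)
    deb_counts = np.zeros((n_deb, config.n_genes), dtype=np.int64)
    if n_deb:
        for t_idx in np.unique(deb_types):
            mask = deb_types == t_idx
            deb_counts[mask] = _draw_counts(rng, deb_totals[mask], type_profiles[types[t_idx]])

    # ambient soup: UMI-weighted mixture of the (adjusted) type profiles
    soup = np.zeros(config.n_genes)
    for t, w in zip(types, props):
        soup += w * type_profiles[t]
    if config.ambient_upweight_genes and config.ambient_upweight_factor != 1.0:
        soup = soup.copy()
        soup[np.asarray(config.ambient_upweight_genes, dtype=int)] *= config.ambient_upweight_factor
    soup /= soup.sum()
    n_amb = config.n_ambient_droplets
    amb_target = deg.ambient_fraction_at(tissue, time_h)
    if amb_target is not None and n_amb > 0:
        expected_rest = (
            config.n_cells_per_sample * config.mean_umis_per_cell
            + n_deb * config.mean_umis_per_debris
        )
        mean_amb = amb_target * expected_rest / ((1.0 - amb_target) * n_amb)
        mean_amb = max(mean_amb, 1.0)
    else:
        mean_amb = config.mean_umis_per_ambient
    amb_totals = _lognormal_totals(rng, n_amb, mean_amb, config.umi_sigma_ambient)
    amb_counts = _draw_counts(rng, amb_totals, soup)

    counts = np.vstack([b for b in cell_blocks if len(b)] + [deb_counts, amb_counts]) \
        if (cell_blocks or n_deb or n_amb) else np.zeros((0, config.n_genes), dtype=np.int64)
    sample_id = f"{donor}-{tissue}-{int(time_h)}h"
    n_cells = int(n_per_type.sum())
    barcodes = (
        [f"{sample_id}:cell{i:05d}" for i in range(n_cells)]
        + [f"{sample_id}:debris{i:05d}" for i in range(n_deb)]
        + [f"{sample_id}:soup{i:05d}" for i in range(n_amb)]
    )
    table = DropletTable(sample_id, barcodes, config.features, sparse.csr_matrix(counts))

    shift = deg.intron_shift_at(tissue, time_h)
    exo, intro, inter = _read_categories(config, rng, table.umi_total, shift)
    read_cats = pd.DataFrame(
        {"barcode": barcodes, "exonic": exo, "intronic": intro, "intergenic": inter}
    ).set_index("barcode", drop=False)

    truth = pd.DataFrame(
        {
            "barcode": barcodes,
            "droplet_class": ["cellular"] * n_cells + ["debris"] * n_deb + ["ambient"] * n_amb,
            "cell_type": cell_types_per_droplet + [""] * (n_deb + n_amb),
        }
    ).set_index("barcode", drop=False)

    amb_umis = int(amb_totals.sum())
    summary = {
        "true_mt_mean": {
            t: min(config.baseline_mt_fraction * deg.mt_factor(tissue, t, time_h), 0.9) for t in types
        },
        "true_ambient_umi_fraction": amb_umis / max(int(table.umi_total.sum()), 1),
        "target_ambient_umi_fraction": amb_target,
        "true_exonic_mean": config.exonic_mean - shift,
        "intron_shift": shift,
        "n_cells": n_cells,
        "n_debris": n_deb,
        "n_ambient": n_amb,
    }
    meta = SampleMeta(sample_id, donor, tissue, float(time_h))
    return SyntheticSample(meta, table, read_cats, truth, summary)


def generate_experiment(config: SimConfig) -> SyntheticExperiment:
    """Generate one run per (donor, tissue, time point); deterministic in config.

    Randomness uses one global seed with per-sample substreams derived from
    (seed, donor index, tissue index, time index), so adding a tissue or a
    donor does not perturb the other samples.
    """
    config.validate()
    samples = []
    for d_i, donor in enumerate(config.donors):
        for t_i, tissue in enumerate(config.tissues):
            for p_i, time_h in enumerate(config.time_points_h):
                ss = np.random.SeedSequence(config.seed, spawn_key=(d_i, t_i, p_i))
                rng = np.random.default_rng(ss)
                samples.append(_generate_sample(config, donor, tissue, time_h, rng))
    return SyntheticExperiment(config, samples)


def generate_bulk(
    experiment: SyntheticExperiment,
    library_size: int,
    dissociation_log2fc: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Bulk RNA-seq counts (gene x sample) from the true tissue mixtures.

    Each sample's bulk library draws ``library_size`` reads from the donor's
    true cell-type mixture at that tissue/time — no dissociation bias.
    ``dissociation_log2fc`` optionally scales stated genes in the *bulk*
    profile by 2**log2fc, planting known positives for bulk vs pseudo-bulk
    differential expression (negative values = higher in single-cell).
    """
    if library_size <= 0:
        raise InputError("library_size must be a positive integer")
    config = experiment.config
    cols = {}
    for s_i, s in enumerate(experiment.samples):
        donor, tissue, time_h = s.meta.donor, s.meta.tissue, s.meta.time_h
        types = config.cell_types
        props = np.array([config.cell_type_proportions[donor][t] for t in types])
        mix = np.zeros(config.n_genes)
        for t, w in zip(types, props):
            mix += w * _adjusted_profile(config, config.cell_type_profiles[t], tissue, t, time_h)
        if dissociation_log2fc:
            for g, lfc in dissociation_log2fc.items():
                mix[int(g)] *= 2.0**lfc
        mix /= mix.sum()
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0xB0, s_i)))
        cols[s.meta.sample_id] = rng.multinomial(int(library_size), mix)
    return pd.DataFrame(cols, index=config.features)


# -- fixture serialization ----------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture(experiment: SyntheticExperiment, directory: str | Path) -> dict:
    """Serialize an experiment as per-sample MTX triplets + TSVs; returns the manifest.

    Layout: ``samples.tsv`` and ``config.json`` at the root, one directory
    per sample holding matrix.mtx (genes x barcodes, 1-based MatrixMarket),
    barcodes.tsv, features.tsv, read_categories.tsv and truth.tsv. The
    manifest lists every file with its sha256.
    """
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def _write_text(path: Path, text: str) -> None:
        path.write_text(text)
        files[str(path.relative_to(root))] = _sha256(path)

    samples_df = experiment.sample_table()
    _write_text(root / "samples.tsv", samples_df.to_csv(sep="\t", index=False))
    _write_text(root / "config.json", json.dumps(experiment.config.to_jsonable(), indent=1))
    summaries = {s.meta.sample_id: s.truth_summary for s in experiment.samples}
    _write_text(root / "truth_summary.json", json.dumps(summaries, indent=1))

    for s in experiment.samples:
        d = root / s.meta.sample_id
        d.mkdir(exist_ok=True)
        mtx = d / "matrix.mtx"
        # genes x barcodes orientation, as in the 10x convention
        spio.mmwrite(str(mtx), s.droplets.counts.T.tocoo(), field="integer")
        files[str(mtx.relative_to(root))] = _sha256(mtx)
        _write_text(d / "barcodes.tsv", "\n".join(s.droplets.barcodes) + "\n")
        _write_text(
            d / "features.tsv",
            "\n".join(f"{g}\t{g}\tGene Expression" for g in s.droplets.features) + "\n",
        )
        _write_text(d / "read_categories.tsv", s.read_categories.to_csv(sep="\t", index=False))
        _write_text(d / "truth.tsv", s.truth.to_csv(sep="\t", index=False))

    manifest = {"n_samples": len(experiment.samples), "files": files}
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_fixture(directory: str | Path) -> SyntheticExperiment:
    """Load an experiment written by :func:`write_fixture` (lossless round trip)."""
    from .io import load_count_matrix  # local import to avoid a cycle

    root = Path(directory)
    config = SimConfig.from_jsonable(json.loads((root / "config.json").read_text()))
    samples_df = pd.read_csv(root / "samples.tsv", sep="\t")
    summaries = json.loads((root / "truth_summary.json").read_text())
    samples = []
    for _, row in samples_df.iterrows():
        d = root / row["sample_id"]
        table = load_count_matrix(
            d / "matrix.mtx", d / "barcodes.tsv", d / "features.tsv", sample_id=row["sample_id"]
        )
        read_cats = pd.read_csv(d / "read_categories.tsv", sep="\t").set_index("barcode", drop=False)
        truth = pd.read_csv(d / "truth.tsv", sep="\t", keep_default_na=False).set_index(
            "barcode", drop=False
        )
        meta = SampleMeta(row["sample_id"], row["donor"], row["tissue"], float(row["time_h"]))
        samples.append(SyntheticSample(meta, table, read_cats, truth, summaries[row["sample_id"]]))
    return SyntheticExperiment(config, samples)
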