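"""End-to-end orchestration: droplets -> cells -> assign -> stats -> de.

The pipeline consumes an experiment directory in the fixture layout
(samples.tsv plus one directory per sample with matrix.mtx, barcodes.tsv,
features.tsv, read_categories.tsv and optionally truth.tsv carrying
cell-type labels), runs the enabled stages in dependency order and writes
one TSV per output table plus a manifest with the config hash and file
checksums. Identical config + inputs produce byte-identical outputs; every
masking or skip decision is recorded in the run log.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from anndata import AnnData
from scipy import sparse

from . import annotate, cellqc, droplets, expression, stability
from .cellqc import CellQcThresholds
from .errors import DependencyError, InputError
from .io import load_count_matrix, read_gene_set

__all__ = ["PipelineConfig", "StabilityReport", "run_pipeline", "default_dissociation_genes"]

STAGE_ORDER = ("droplets", "cells", "assign", "stats", "de")
STAGE_DEPS = {"cells": ("droplets",), "assign": ("cells",), "stats": ("assign",), "de": ("cells",)}


def default_dissociation_genes() -> list[str]:
    """The packaged dissociation-stress reference gene list."""
    text = resources.files("scstability.data").joinpath("dissociation_genes.txt").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: s != "de" for s in STAGE_ORDER}
    )
    thresholds: CellQcThresholds = field(default_factory=CellQcThresholds)
    mt_gene_prefix: str = "MT-"
    labels_source: str = "truth"  # "truth" | path to a barcode->label TSV
    bulk_path: str | None = None
    dissociation_genes_path: str | None = None
    seed: int = 0
    alpha: float = 0.05
    t0_label: float = 0.0
    late_label: float = 72.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "thresholds" in raw:
            raw["thresholds"] = CellQcThresholds(**raw["thresholds"])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = self.__dict__.copy()
        d["thresholds"] = self.thresholds.__dict__
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_jsonable(), sort_keys=True).encode()
        ).hexdigest()

    def validate(self) -> None:
        if not Path(self.input_dir).exists():
            raise InputError(f"input directory does not exist: {self.input_dir}")
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise InputError(f"unknown stages: {sorted(unknown)}")
        for stage, deps in STAGE_DEPS.items():
            if self.stages.get(stage):
                for dep in deps:
                    if not self.stages.get(dep):
                        raise DependencyError(f"stage {stage!r} requires stage {dep!r}")
        if self.stages.get("de") and not self.bulk_path:
            raise InputError("stage 'de' enabled but no bulk_path given")


@dataclass
class StabilityReport:
    tables: dict[str, pd.DataFrame]
    newick: str | None
    manifest: dict
    log: pd.DataFrame


def _log(records: list, stage: str, event: str, **detail) -> None:
    records.append({"stage": stage, "event": event, "detail": json.dumps(detail, sort_keys=True)})


def _load_samples(config: PipelineConfig) -> list[dict]:
    root = Path(config.input_dir)
    samples_df = pd.read_csv(root / "samples.tsv", sep="\t")
    out = []
    for _, row in samples_df.iterrows():
        d = root / row["sample_id"]
        table = load_count_matrix(
            d / "matrix.mtx", d / "barcodes.tsv", d / "features.tsv", sample_id=row["sample_id"]
        )
        rc_path = d / "read_categories.tsv"
        read_cats = (
            pd.read_csv(rc_path, sep="\t").set_index("barcode", drop=False)
            if rc_path.exists()
            else None
        )
        labels = None
        if config.labels_source == "truth":
            tpath = d / "truth.tsv"
            if tpath.exists():
                truth = pd.read_csv(tpath, sep="\t", keep_default_na=False)
                labels = truth.set_index("barcode")["cell_type"]
        out.append(
            {
                "meta": {k: row[k] for k in ("sample_id", "donor", "tissue", "time_h")},
                "table": table,
                "read_categories": read_cats,
                "labels": labels,
            }
        )
    if config.labels_source not in ("truth",):
        lab = pd.read_csv(config.labels_source, sep="\t").set_index("barcode")["label"]
        for s in out:
            s["labels"] = lab
    return out


def _stage_droplets(samples, config, tables, log):
    summaries, profiles = [], []
    for s in samples:
        norm = droplets.normalize_umi(s["table"])
        labels = droplets.classify_droplets(norm)
        s["norm"], s["class_labels"] = norm, labels
        summ = droplets.class_means(norm, labels, s["meta"]["sample_id"])
        for k, v in s["meta"].items():
            if k != "sample_id":
                summ[k] = v
        summaries.append(summ)
        try:
            prof = droplets.ambient_profile(s["table"], labels).head(20)
            prof.insert(0, "sample_id", s["meta"]["sample_id"])
            profiles.append(prof)
        except InputError:
            _log(log, "droplets", "no_ambient_droplets", sample=s["meta"]["sample_id"])
    summary = pd.concat(summaries, ignore_index=True)
    tables["droplet_class_summary"] = summary
    if profiles:
        tables["ambient_profile"] = pd.concat(profiles, ignore_index=True)

    rows = []
    for cls in (droplets.DEBRIS, droplets.CELLULAR):
        sub = summary[summary["droplet_class"] == cls]
        for tissue, tgrp in sub.groupby("tissue"):
            for other, paired in ((config.late_label, True), (24.0, False)):
                if other not in set(tgrp["time_h"]):
                    continue
                try:
                    res = droplets.compare_time_points(tgrp, config.t0_label, other, paired=paired)
                    rows.append(
                        {"droplet_class": cls, "tissue": tissue, "contrast": f"T0v{other}",
                         "paired": paired, "statistic": res.statistic, "pvalue": res.pvalue}
                    )
                except Exception as exc:
                    _log(log, "droplets", "test_skipped", tissue=tissue, cls=cls, reason=str(exc))
    tables["droplet_time_tests"] = pd.DataFrame(rows)


def _stage_cells(samples, config, tables, log):
    per_tissue: dict[str, AnnData] = {}
    for tissue in sorted({s["meta"]["tissue"] for s in samples}):
        blocks, obs_rows = [], []
        for s in samples:
            if s["meta"]["tissue"] != tissue:
                continue
            mask = s["class_labels"] == droplets.CELLULAR
            blocks.append(s["table"].counts[mask])
            for bc in np.asarray(s["table"].barcodes, dtype=object)[mask]:
                obs_rows.append({"barcode": bc, **s["meta"]})
        if not blocks:
            continue
        adata = AnnData(X=sparse.vstack(blocks).tocsr())
        obs = pd.DataFrame(obs_rows).set_index("barcode")
        adata.obs = obs
        adata.var_names = pd.Index(samples[0]["table"].features)
        adata = cellqc.filter_genes(adata, config.thresholds.min_cells_per_gene)
        per_tissue[tissue] = adata

    cell_rows, removal_logs, prefilter_rows = [], [], []
    filtered: dict[str, AnnData] = {}
    for tissue, adata in per_tissue.items():
        pre = cellqc.cell_metrics(adata)
        pre = pre.join(adata.obs)
        prefilter_rows.append(pre)
        kept, metrics, removal = cellqc.filter_cells(adata, tissue, config.thresholds)
        _log(log, "cells", "filtered", tissue=tissue, removed=int(len(removal)), kept=int(kept.n_obs))
        removal["tissue"] = tissue
        removal_logs.append(removal)
        metrics = metrics.join(kept.obs)
        cell_rows.append(metrics)
        filtered[tissue] = kept
    cell_table = pd.concat(cell_rows) if cell_rows else pd.DataFrame()
    prefilter = pd.concat(prefilter_rows) if prefilter_rows else pd.DataFrame()

    # merge read-category fractions onto kept cells
    rc_all = [
        cellqc.read_category_fractions(s["read_categories"])
        for s in samples
        if s["read_categories"] is not None
    ]
    if rc_all:
        rc = pd.concat(rc_all)
        cols = ["exonic_frac", "intronic_frac", "intergenic_frac", "total_reads", "flagged"]
        cell_table = cell_table.join(rc[cols], how="left")
        for metric in ("exonic", "intronic"):
            tables[f"quartile_extremes_{metric}"] = cellqc.quartile_extremes(
                cell_table.reset_index(drop=True), metric
            )
    tables["cell_table"] = cell_table
    tables["removal_log"] = pd.concat(removal_logs) if removal_logs else pd.DataFrame()
    tables["high_mito_rate"] = (
        cellqc.high_mito_rate(prefilter).rename("frac_cells_gt10pct_mt").reset_index()
    )
    metrics, trend = cellqc.sample_metrics(cell_table, t0_label=config.t0_label)
    tables["sample_metrics"] = metrics
    tables["sample_metric_tests"] = trend
    return per_tissue, filtered, prefilter


def _stage_assign(samples, config, tables, log, per_tissue, prefilter):
    labels_all = pd.concat([s["labels"] for s in samples if s["labels"] is not None])
    combined = []
    assignments = []
    for tissue, adata in per_tissue.items():
        metrics = cellqc.cell_metrics(adata)
        labels = labels_all.reindex(adata.obs_names).fillna("")
        known = labels != ""
        low = (metrics["mt_pct"] <= config.thresholds.max_mt_pct).to_numpy() & known.to_numpy()
        high = (metrics["mt_pct"] > config.thresholds.max_mt_pct).to_numpy()
        if low.sum() == 0:
            _log(log, "assign", "no_reference_cells", tissue=tissue)
            continue
        index = annotate.build_centroids(adata[low], labels[low].to_numpy())
        ct = pd.Series("", index=adata.obs_names, dtype=object)
        ct[low] = labels[low]
        if high.sum():
            res = annotate.assign_by_similarity(adata[high], index)
            assignments.append(res.assign(tissue=tissue))
            ct[high] = res["label"].to_numpy()
            _log(log, "assign", "reassigned", tissue=tissue,
                 n=int(high.sum()), unassigned=int((~res["assigned"]).sum()))
        meta = adata.obs.copy()
        meta["cell_type"] = ct
        meta = meta.join(metrics[["n_genes", "n_counts", "mt_pct"]])
        combined.append(meta[(ct != "") & (ct != "unassigned")])
    tables["assignments"] = (
        pd.concat(assignments, ignore_index=True) if assignments else pd.DataFrame()
    )
    combined_table = pd.concat(combined) if combined else pd.DataFrame()
    combined_table.index.name = "barcode"
    tables["combined_cell_table"] = combined_table.reset_index()
    return combined_table


def _stage_stats(config, tables, log, per_tissue, combined):
    cells = combined.reset_index()
    tables["fold_change"] = stability.mito_fold_change(cells, t0_label=config.t0_label)
    comp = stability.composition_proportions(cells)
    tables["composition"] = comp
    tables["composition_tests"] = stability.composition_time_tests(
        comp, t0_label=config.t0_label, late_label=config.late_label
    )
    anova, n_sig = stability.composition_donor_anova(comp)
    tables["composition_donor_anova"] = anova
    _log(log, "stats", "donor_anova", n_significant=n_sig)

    # variance partition on log-normalized expression of the combined cells
    rows = []
    for tissue, adata in per_tissue.items():
        idx = combined.index.intersection(adata.obs_names)
        if len(idx) < 10:
            _log(log, "stats", "variance_skipped", tissue=tissue, n=len(idx))
            continue
        sub = adata[idx]
        logx = annotate.log_normalize(sub.X)
        meta = combined.loc[idx]
        factors = pd.DataFrame(
            {
                "donor": meta["donor"].astype(str),
                "cell_type": meta["cell_type"].astype(str),
                "n_counts": meta["n_counts"].astype(float),
                "time_h": meta["time_h"].astype(float),
            },
            index=idx,
        )
        usable = [c for c in factors.columns if factors[c].nunique() > 1]
        r2 = stability.variance_explained(
            pd.DataFrame(logx, index=idx, columns=sub.var_names), factors[usable]
        )
        q = r2.quantile([0.25, 0.5, 0.75])
        q.insert(0, "tissue", tissue)
        rows.append(q.reset_index(names="quantile"))
    if rows:
        tables["variance_partition_summary"] = pd.concat(rows, ignore_index=True)

    # cross-organ dendrogram on the combined cells
    strata = cells.groupby(["cell_type", "tissue", "time_h", "donor"]).ngroups
    newick = None
    if strata >= 2 and len(per_tissue) >= 1:
        frames, metas = [], []
        genes = None
        for tissue, adata in per_tissue.items():
            idx = combined.index.intersection(adata.obs_names)
            sub = adata[idx]
            genes = sub.var_names if genes is None else genes.intersection(sub.var_names)
        for tissue, adata in per_tissue.items():
            idx = combined.index.intersection(adata.obs_names)
            sub = adata[idx][:, genes]
            frames.append(annotate.log_normalize(sub.X))
            metas.append(combined.loc[idx, ["cell_type", "tissue", "time_h", "donor"]])
        expr = np.vstack(frames)
        meta = pd.concat(metas).reset_index(drop=True)
        link, leaves = stability.crossorgan_dendrogram(expr, meta, seed=config.seed)
        tables["dendrogram_leaves"] = leaves
        newick = stability.linkage_to_newick(link, [f"leaf{i}" for i in range(len(leaves))])
    else:
        _log(log, "stats", "dendrogram_skipped", n_strata=int(strata))
    return newick


def _stage_de(samples, config, tables, log, filtered, combined):
    bulk = pd.read_csv(config.bulk_path, sep="\t", index_col=0)
    gene_list = (
        read_gene_set(config.dissociation_genes_path)
        if config.dissociation_genes_path
        else default_dissociation_genes()
    )
    de_rows, fisher_rows = [], []
    for tissue, adata in filtered.items():
        idx = combined.index.intersection(adata.obs_names)
        sub = adata[idx].copy()
        sub.obs["sample_id"] = combined.loc[idx, "sample_id"]
        pseudo = expression.make_pseudobulk(sub)
        shared = [c for c in pseudo.columns if c in set(bulk.columns)]
        if len(shared) < 2:
            _log(log, "de", "bulk_pseudobulk_skipped", tissue=tissue, shared=len(shared))
            continue
        de = expression.wilcoxon_de(bulk[shared], pseudo[shared], paired=True)
        de.insert(0, "tissue", tissue)
        de.insert(1, "comparison", "bulk_vs_pseudobulk")
        de_rows.append(de)
        strong = set(
            de[(de["p_adj"] < 0.01) & (de["median_log2_foldchange"] < -2)]["gene"]
        )
        universe = set(de["gene"])
        ref = set(gene_list) & universe
        if ref:
            oddsr, p, _ = expression.signature_overlap_fisher(strong, ref, universe)
            fisher_rows.append(
                {"tissue": tissue, "n_signature": len(strong), "n_reference": len(ref),
                 "odds_ratio": oddsr, "pvalue": p}
            )
    # bulk time-point DE, paired by donor within tissue
    meta = pd.DataFrame([s["meta"] for s in samples]).set_index("sample_id")
    for tissue, tgrp in meta.groupby("tissue"):
        base = tgrp[tgrp["time_h"] == config.t0_label]
        for tp in sorted(t for t in tgrp["time_h"].unique() if t != config.t0_label):
            other = tgrp[tgrp["time_h"] == tp]
            pairs = base.reset_index().merge(other.reset_index(), on="donor")
            cols_a = [c for c in pairs["sample_id_x"] if c in bulk.columns]
            cols_b = [c for c in pairs["sample_id_y"] if c in bulk.columns]
            if len(cols_a) < 2 or len(cols_a) != len(cols_b):
                _log(log, "de", "bulk_time_skipped", tissue=tissue, time=tp)
                continue
            a = bulk[cols_a].set_axis(pairs["donor"][: len(cols_a)], axis=1)
            b = bulk[cols_b].set_axis(pairs["donor"][: len(cols_b)], axis=1)
            de = expression.wilcoxon_de(a, b, paired=True)
            de.insert(0, "tissue", tissue)
            de.insert(1, "comparison", f"bulk_T0_vs_{tp}")
            de_rows.append(de)
    if de_rows:
        tables["differential_expression"] = pd.concat(de_rows, ignore_index=True)
    if fisher_rows:
        tables["dissociation_overlap"] = pd.DataFrame(fisher_rows)


def run_pipeline(config: PipelineConfig) -> StabilityReport:
    """Run all enabled stages; write tables, manifest and run log to output_dir."""
    config.validate()
    log: list[dict] = []
    tables: dict[str, pd.DataFrame] = {}
    samples = _load_samples(config)
    newick = None
    per_tissue = filtered = prefilter = combined = None
    if config.stages.get("droplets"):
        _stage_droplets(samples, config, tables, log)
    if config.stages.get("cells"):
        per_tissue, filtered, prefilter = _stage_cells(samples, config, tables, log)
    if config.stages.get("assign"):
        combined = _stage_assign(samples, config, tables, log, per_tissue, prefilter)
    if config.stages.get("stats"):
        newick = _stage_stats(config, tables, log, per_tissue, combined)
    if config.stages.get("de"):
        _stage_de(samples, config, tables, log, filtered, combined)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for name, df in tables.items():
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        checksums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    if newick:
        path = out / "dendrogram.nwk"
        path.write_text(newick + "\n")
        checksums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    log_df = pd.DataFrame(log, columns=["stage", "event", "detail"])
    log_df.to_csv(out / "run_log.tsv", sep="\t", index=False)
    manifest = {
        "config": config.to_jsonable(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "tables": checksums,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return StabilityReport(tables=tables, newick=newick, manifest=manifest, log=log_df)
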