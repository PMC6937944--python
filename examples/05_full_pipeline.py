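"""Run the full pipeline on a synthetic fixture directory.

Writes a two-donor spleen experiment (with mitochondrial inflation at 72 h)
to disk in the 10x-style MTX layout, then runs every stage: droplet
classification, cell QC, high-MT reassignment, degradation statistics and
bulk comparisons, producing one TSV per output table plus a manifest whose
checksums are reproducible for identical inputs.
"""

import tempfile
from pathlib import Path

from scstability.cellqc import CellQcThresholds
from scstability.pipeline import PipelineConfig, run_pipeline
from scstability.synthetic import (
    DegradationParams,
    SimConfig,
    generate_bulk,
    generate_experiment,
    write_fixture,
)

work = Path(tempfile.mkdtemp(prefix="scstability_"))
cfg = SimConfig.default(
    n_donors=2, tissues=["spleen"], time_points_h=[0.0, 72.0],
    n_cells_per_sample=300, n_genes=60, n_ambient_droplets=1200,
    n_debris_droplets=400, seed=9,
)
cfg.degradation = DegradationParams(
    mt_fold_change={("spleen", ct, 72.0): 3.0 for ct in cfg.cell_types}
)
exp = generate_experiment(cfg)
write_fixture(exp, work / "fixture")
generate_bulk(exp, 200_000).to_csv(work / "fixture" / "bulk.tsv", sep="\t")

config = PipelineConfig(
    input_dir=str(work / "fixture"),
    output_dir=str(work / "out"),
    stages={s: True for s in ("droplets", "cells", "assign", "stats", "de")},
    # synthetic gene panels are small, so the gene/UMI bounds are relaxed;
    # the 10% mitochondrial rule is the one under study and stays put
    thresholds=CellQcThresholds(min_genes=10, max_genes=5000, max_umi=10_000_000),
    bulk_path=str(work / "fixture" / "bulk.tsv"),
)
report = run_pipeline(config)

print(f"outputs in {config.output_dir}:")
for name, df in report.tables.items():
    print(f"  {name}.tsv  ({len(df)} rows)")
fc = report.tables["fold_change"]
late = fc[(fc["time_h"] == 72.0) & (fc["status"] == "ok")]
print("\nmitochondrial fold change at 72 h per cell type:")
print(late[["cell_type", "n_cells", "fold_change", "p_adj"]].to_string(index=False))
print(
    "\nThe ~3x fold changes recover the injected mitochondrial inflation after\n"
    "high-MT cells were reassigned to their types by centroid similarity."
)
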