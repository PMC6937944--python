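"""Recover an injected mitochondrial fold change per cell type.

One spleen donor at T0 and 72 h; the generator doubles the mitochondrial
UMI fraction of T cells at 72 h while B cells and monocytes stay at
baseline. The fold-change table should show FC close to 2 for T cells with
a small adjusted p, FC close to 1 elsewhere, and T0 rows fixed at 1.
"""

import numpy as np
import pandas as pd

from scstability.stability import mito_fold_change
from scstability.synthetic import DegradationParams, SimConfig, generate_experiment

cfg = SimConfig.default(
    n_donors=1, tissues=["spleen"], time_points_h=[0.0, 72.0],
    n_cells_per_sample=1500, n_genes=60, n_ambient_droplets=0,
    n_debris_droplets=0, seed=3, mean_umis_per_cell=2000.0,
)
cfg.cell_type_proportions = {"D1": {ct: 1 / 3 for ct in cfg.cell_types}}
cfg.degradation = DegradationParams(mt_fold_change={("spleen", "T_cell", 72.0): 2.0})
exp = generate_experiment(cfg)

rows = []
mt_idx = cfg.mt_gene_indices
for s in exp.samples:
    mask = (s.truth["droplet_class"] == "cellular").to_numpy()
    x = s.droplets.counts[mask].toarray()
    rows.append(
        pd.DataFrame(
            {
                "tissue": "spleen",
                "cell_type": s.truth.loc[mask, "cell_type"].to_numpy(),
                "time_h": s.meta.time_h,
                "mt_pct": 100 * x[:, mt_idx].sum(axis=1) / x.sum(axis=1),
                "donor": s.meta.donor,
                "sample_id": s.meta.sample_id,
            }
        )
    )
table = mito_fold_change(pd.concat(rows, ignore_index=True))
cols = ["cell_type", "time_h", "n_cells", "fold_change", "p_adj", "status", "stars"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print(
    "\nfold_change is mean mt% at t over mean mt% at T0 per cell type;\n"
    "the injected 2x inflation appears only in the T_cell row at 72 h."
)
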