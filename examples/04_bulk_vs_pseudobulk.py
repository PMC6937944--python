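"""Bulk vs single-cell pseudo-bulk differential expression with a planted
dissociation signature.

The generator plants a log2 fold change of -3 (bulk lower than single-cell)
on the immediate-early stress genes FOS, FOSB, JUN, JUNB plus two generic
genes. The paired Wilcoxon signed-rank comparison should flag exactly that
signature, and a Fisher exact test should show its overlap with the
packaged dissociation reference list to be far beyond chance.
"""

import numpy as np
import pandas as pd

from scstability.expression import signature_overlap_fisher, wilcoxon_de
from scstability.pipeline import default_dissociation_genes
from scstability.synthetic import SimConfig, generate_bulk, generate_experiment

cfg = SimConfig.default(
    n_donors=5, tissues=["spleen"], time_points_h=[0.0, 72.0],
    n_cells_per_sample=150, n_genes=60, n_ambient_droplets=0,
    n_debris_droplets=0, seed=61, mean_umis_per_cell=2000.0,
)
exp = generate_experiment(cfg)
features = cfg.features
planted = ["FOS", "FOSB", "JUN", "JUNB", "GENE0000", "GENE0001"]
bulk = generate_bulk(exp, 300_000, {features.index(g): -3.0 for g in planted})

pseudo = pd.DataFrame(
    {
        s.meta.sample_id: np.asarray(
            s.droplets.counts[(s.truth["droplet_class"] == "cellular").to_numpy()].sum(axis=0)
        ).ravel()
        for s in exp.samples
    },
    index=features,
)

de = wilcoxon_de(bulk, pseudo, paired=True)
hits = de[(de["p_adj"] < 0.05) & (de["median_log2_foldchange"] < -2)]
print("genes lower in bulk (p_adj < 0.05, median log2FC < -2):")
print(hits[["gene", "p_adj", "median_log2_foldchange"]].to_string(index=False))

oddsr, p, table = signature_overlap_fisher(
    set(hits["gene"]), set(default_dissociation_genes()) & set(features), set(features)
)
print(f"\nFisher overlap with the dissociation gene list: OR={oddsr:.1f}, p={p:.2e}")
print(
    "The recovered signature is the planted one; the small Fisher p says the\n"
    "overlap with the known dissociation genes is not a chance event."
)
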