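"""Classify droplets of a synthetic run into ambient / debris / cellular.

Generates a two-donor spleen study, computes the depth-normalized UMI
statistic (values of a run sum to one million) and prints per-class droplet
counts and mean normalized UMI next to the generator's truth labels.
"""

import pandas as pd

from scstability.droplets import class_means, classify_droplets, normalize_umi
from scstability.synthetic import SimConfig, generate_experiment

cfg = SimConfig.default(
    n_donors=2, tissues=["spleen"], time_points_h=[0.0, 72.0],
    n_cells_per_sample=300, n_genes=60,
    n_ambient_droplets=1200, n_debris_droplets=400, seed=1,
)
exp = generate_experiment(cfg)

rows = []
for s in exp.samples:
    norm = normalize_umi(s.droplets)
    labels = classify_droplets(norm)
    rows.append(class_means(norm, labels, s.meta.sample_id))
    acc = (labels == s.truth["droplet_class"].to_numpy()).mean()
    print(f"{s.meta.sample_id}: classification matches truth for {acc:.1%} of droplets")

print()
print(pd.concat(rows, ignore_index=True).to_string(index=False))
print()
print(
    "Ambient droplets sit at (0, 0.25] normalized UMI, debris at (0.25, 5] and\n"
    "cells above 5; the mean normalized UMI per class is the statistic compared\n"
    "across storage time points."
)
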