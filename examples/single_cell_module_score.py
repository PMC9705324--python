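"""Binned-control module score on clustered single-cell counts.

Simulates 4 clusters of droplet-style counts with one cluster expressing the
signature at 4x, then scores every cell: set-gene mean expression minus the
mean of expression-matched control genes.
"""

import numpy as np

from sigscore import (
    GeneSet,
    SyntheticSingleCellConfig,
    generate_single_cell_dataset,
    sc_module_score,
)

adata, obs, truth = generate_single_cell_dataset(SyntheticSingleCellConfig(seed=2))
table = sc_module_score(adata, GeneSet("SIG", truth.signature_genes), seed=2)
print(table.groupby("cluster", observed=True)["score"].agg(["mean", "std"]).round(3))

rng = np.random.default_rng(2)
random_set = GeneSet("RANDOM", tuple(rng.choice(adata.var_names, 30, replace=False)))
null = sc_module_score(adata, random_set, seed=2)
print("\nrandom-set cluster means:",
      null.groupby("cluster", observed=True)["score"].mean().round(3).to_dict())
print(
    f"\nThe activated cluster ({truth.activated_cluster}) stands out for the "
    "signature while a random set stays near 0 everywhere — the matched "
    "controls absorb depth and abundance effects."
)
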