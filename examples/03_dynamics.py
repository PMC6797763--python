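"""Tissue specificity, promoter switching and APA from an expression cohort.

Shows the entropy score S = log2(N) - H_obs on planted profiles and the
switch-score calls on simulated tag usage.
"""
import numpy as np

from isoforge import (
    SimParams,
    call_switch_genes,
    group_into_genes,
    simulate_expression,
    simulate_tags_and_junctions,
    simulate_truth,
    tissue_specificity,
)
from isoforge.dynamics import filter_usage_clusters
from isoforge.pipeline import build_site_usage, dynamics_clusters

truth = simulate_truth(SimParams(n_genes=30), seed=5)
expr = simulate_expression(truth, noise_cv=0.1, seed=6)

for role in ("specific", "uniform"):
    gid = truth.planted[role][0]
    s = tissue_specificity(expr.loc[gid].values)
    print(f"{role} gene {gid}: S = {s:.3f} (max possible {np.log2(16):.1f})")

tag5, _, _ = simulate_tags_and_junctions(truth, seed=7)
clusters = dynamics_clusters(tag5, "TSS")
genes = group_into_genes(truth.to_isoform_records())
usage = {
    g: filter_usage_clusters(u)
    for g, u in build_site_usage(genes, clusters, "TSS").items()
}
called = call_switch_genes(usage, w_min=0.3)
print(f"TSS-switch genes called: { {g: round(w, 2) for g, w in called.items()} }")
# A single-tissue gene scores S = 4 bits on 16 tissues; a flat profile
# scores ~0.  The switch calls name exactly the genes whose dominant TSS
# flips between tissue groups with W > 0.3.
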