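"""Scan an annotation for alternative-splicing hotspots.

The null model: distinct k-segment patterns per window follow a branching
process with E(X) = (1+p)^K.  A gene whose isoforms concentrate their
diversity in one window exceeds the three-fold cutoff.
"""
from isoforge import (
    SimParams,
    group_into_genes,
    null_pmf,
    scan_hotspots,
    simulate_truth,
    strings_from_genes,
)

null = null_pmf(p=0.2, K=5)
print(f"null E(X) = {null.expectation():.3f}  (closed form {(1.2)**5:.3f})")
print(f"P(X = 8 | p=0.2, K=5) = {null.prob(8):.2e}")

truth = simulate_truth(SimParams(n_genes=60, n_hotspot_genes=5), seed=9)
genes = group_into_genes(truth.to_isoform_records())
regions = scan_hotspots(strings_from_genes(genes), k_range=range(3, 11), fold=3.0)
print(f"hotspot regions: {len(regions)}")
for r in regions[:5]:
    print(
        f"  {r.gene_id}  {r.interval.chrom}:{r.interval.start}-{r.interval.end}"
        f"  k={r.k_values}  evidences={r.n_evidence}"
    )
# The five planted genes carry eight isoforms enumerating every combination
# of three adjacent cassette exons; their windows hold ~8 distinct patterns
# where the genome-wide null predicts ~1-2, so each gene is reported with
# evidence from several k values.
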