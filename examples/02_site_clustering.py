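"""Density-cluster 5' tag signal into TSS clusters.

A sharp promoter and a weak scattered site: the clustering keeps the
maximal-scoring, stable, sufficiently-supported segments only.
"""
from isoforge import cluster_tags

signal = {
    1000: 40, 1001: 55, 1002: 30,          # sharp promoter peak
    1500: 2, 1510: 3, 1520: 2,             # scattered background
    3000: 12, 3001: 15,                    # second promoter
}
clusters = cluster_tags(signal, min_value=20, max_length=200, min_density_fold=5)
for c in clusters:
    print(
        f"cluster {c.interval.start}-{c.interval.end}  total={c.total}"
        f"  summit={c.summit}"
    )
# Expected: the 1000-1002 peak (total 125) and the 3000-3001 peak (total 27)
# survive; the scattered tags never reach the minimum of 20 tags at a
# stable density, so they are discarded.
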