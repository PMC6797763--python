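"""TSS/TES tag clustering: density-based (paraclu-style) cluster calling,
cross-sample merging, reliability filtering, summit selection, and the two
cluster-distance rules (400 nt merge for assembly; 50 nt pruning for the
dynamics analyses).

The clustering primitive finds, on one strand, all tag-position runs that are
maximal-scoring segments for some density parameter d (score = total tags
minus d times the spanned length).  Candidate clusters form a laminar
hierarchy; each carries a minimum and maximum stability density, and is
retained iff

* total tags >= ``min_value`` (default 20),
* spanned length <= ``max_length`` (default 200 nt),
* max density / min density >= ``min_density_fold`` (default 5).

Retained clusters are then flattened to the disjoint maximal ones.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .core import GenomicInterval

KINDS = ("TSS", "TES")


@dataclass
class SiteCluster:
    """A TSS or TES tag cluster with per-sample signal and a summit.

    ``signal`` maps sample -> {position -> tag count}.  The summit is the
    position with the largest pooled signal (leftmost on ties).
    """

    kind: str
    interval: GenomicInterval
    signal: dict[str, dict[int, int]]
    per_sample_tpm: dict[str, float] = field(default_factory=dict)
    min_density: float = 0.0
    max_density: float = math.inf

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"cluster kind must be TSS or TES, got {self.kind!r}")

    def pooled_signal(self) -> dict[int, int]:
        pooled: dict[int, int] = {}
        for persample in self.signal.values():
            for pos, v in persample.items():
                pooled[pos] = pooled.get(pos, 0) + v
        return pooled

    @property
    def per_sample_count(self) -> dict[str, int]:
        return {s: sum(m.values()) for s, m in self.signal.items()}

    @property
    def total(self) -> int:
        return sum(sum(m.values()) for m in self.signal.values())

    @property
    def summit(self) -> int:
        return select_summit(self)


def select_summit(cluster: SiteCluster) -> int:
    """Position of maximum pooled signal; ties broken leftmost."""
    pooled = cluster.pooled_signal()
    if not pooled or all(v == 0 for v in pooled.values()):
        raise ValueError("cannot select a summit from an all-zero cluster")
    best = max(pooled.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]


# ---- core density clustering ------------------------------------------


def _removal_densities(pos: Sequence[int], val: Sequence[float], lo: int, hi: int):
    """Yield (density, break_index) for every proper prefix/suffix of the
    site run [lo, hi).  Prefix [lo, k) has density sum/(pos[k]-pos[lo]);
    suffix [k, hi) has density sum/(pos[hi-1]-pos[k-1])."""
    running = 0.0
    for k in range(lo + 1, hi):
        running += val[k - 1]
        yield running / (pos[k] - pos[lo]), k
    running = 0.0
    for k in range(hi - 1, lo, -1):
        running += val[k]
        yield running / (pos[hi - 1] - pos[k - 1]), k


def _recurse(pos, val, lo, hi, min_density, out):
    if lo >= hi:
        return
    total = sum(val[lo:hi])
    if hi - lo == 1:
        out.append((lo, hi, min_density, math.inf, total))
        return
    best_d, best_k = math.inf, None
    for d, k in _removal_densities(pos, val, lo, hi):
        if d < best_d:
            best_d, best_k = d, k
    out.append((lo, hi, min_density, best_d, total))
    child_min = max(min_density, best_d)
    _recurse(pos, val, lo, best_k, child_min, out)
    _recurse(pos, val, best_k, hi, child_min, out)


def cluster_tags(
    signal: Mapping[int, float],
    min_value: float = 20,
    max_length: int = 200,
    min_density_fold: float = 5.0,
    kind: str = "TSS",
    chrom: str = "chr",
    strand: str = ".",
    sample: str = "pooled",
) -> list[SiteCluster]:
    """Density-cluster a position->count signal on one strand.

    Returns the disjoint maximal retained clusters (see module docstring).
    Gaps in the signal do not split clusters per se; sparsity is penalised
    through the density score.
    """
    if min_value <= 0:
        raise ValueError("min_value must be positive")
    if max_length <= 0:
        raise ValueError("max_length must be positive")
    items = sorted((p, v) for p, v in signal.items() if v > 0)
    if any(v <= 0 for _, v in signal.items()):
        items = [(p, v) for p, v in sorted(signal.items()) if v > 0]
    if not items:
        return []
    pos = [p for p, _ in items]
    val = [float(v) for _, v in items]
    nodes: list[tuple[int, int, float, float, float]] = []
    _recurse(pos, val, 0, len(pos), 0.0, nodes)
    retained = []
    for lo, hi, mind, maxd, total in nodes:
        length = pos[hi - 1] - pos[lo] + 1
        if total < min_value or length > max_length:
            continue
        if mind > 0 and math.isfinite(maxd) and maxd / mind < min_density_fold:
            continue
        if mind > 0 and not math.isfinite(maxd):
            pass  # singleton-like: infinitely stable
        retained.append((lo, hi, mind, maxd, total))
    # flatten: keep maximal disjoint clusters, largest span first
    retained.sort(key=lambda t: (-(pos[t[1] - 1] - pos[t[0]]), t[0]))
    kept: list[tuple[int, int, float, float, float]] = []
    for cand in retained:
        if any(not (cand[1] <= k[0] or k[1] <= cand[0]) for k in kept):
            continue
        kept.append(cand)
    kept.sort(key=lambda t: t[0])
    out = []
    for lo, hi, mind, maxd, total in kept:
        iv = GenomicInterval(chrom, pos[lo], pos[hi - 1] + 1, strand)
        sig = {sample: {pos[i]: int(val[i]) for i in range(lo, hi)}}
        out.append(
            SiteCluster(kind, iv, sig, min_density=mind, max_density=maxd)
        )
    return out


# ---- merging and filtering --------------------------------------------


def _combine(clusters: Sequence[SiteCluster]) -> SiteCluster:
    kind = clusters[0].kind
    iv0 = clusters[0].interval
    start = min(c.interval.start for c in clusters)
    end = max(c.interval.end for c in clusters)
    sig: dict[str, dict[int, int]] = {}
    for c in clusters:
        for s, m in c.signal.items():
            dst = sig.setdefault(s, {})
            for p, v in m.items():
                dst[p] = dst.get(p, 0) + v
    return SiteCluster(kind, GenomicInterval(iv0.chrom, start, end, iv0.strand), sig)


def merge_across_samples(
    per_sample_clusters: Mapping[str, Sequence[SiteCluster]]
) -> list[SiteCluster]:
    """Union overlapping clusters (1 bp overlap suffices) across samples,
    summing per-sample signals.  All inputs must share one kind and strand."""
    allc = []
    for sample, clusters in per_sample_clusters.items():
        for c in clusters:
            if len(c.signal) == 1 and "pooled" in c.signal:
                c = SiteCluster(c.kind, c.interval, {sample: c.signal["pooled"]})
            allc.append(c)
    if not allc:
        return []
    kinds = {c.kind for c in allc}
    if len(kinds) > 1:
        raise ValueError(f"cannot merge clusters of mixed kinds {kinds}")
    strands = {(c.interval.chrom, c.interval.strand) for c in allc}
    out = []
    for chrom, strand in sorted(strands):
        group = sorted(
            (c for c in allc if (c.interval.chrom, c.interval.strand) == (chrom, strand)),
            key=lambda c: c.interval.start,
        )
        run: list[SiteCluster] = []
        run_end = -1
        for c in group:
            if run and c.interval.start < run_end:
                run.append(c)
                run_end = max(run_end, c.interval.end)
            else:
                if run:
                    out.append(_combine(run))
                run = [c]
                run_end = c.interval.end
        if run:
            out.append(_combine(run))
    return out


def attach_tpm(
    clusters: Iterable[SiteCluster], library_sizes: Mapping[str, int]
) -> None:
    """Compute per-sample TPM (cluster tag sum / library size x 1e6) in place."""
    for c in clusters:
        c.per_sample_tpm = {
            s: (sum(m.values()) / library_sizes[s] * 1e6 if library_sizes.get(s) else 0.0)
            for s, m in c.signal.items()
        }
        for s, lib in library_sizes.items():
            c.per_sample_tpm.setdefault(s, 0.0)


def filter_reliable(
    clusters: Sequence[SiteCluster],
    tpm_min: float = 0.5,
    top_signal_min: int = 10,
    min_samples: int = 3,
) -> list[SiteCluster]:
    """Reliable clusters: TPM >= tpm_min in >=1 sample AND per-base maximum
    signal >= top_signal_min in >= min_samples samples."""
    out = []
    for c in clusters:
        if not c.per_sample_tpm:
            raise ValueError("per-sample TPM not computed; call attach_tpm first")
        if not any(t >= tpm_min for t in c.per_sample_tpm.values()):
            continue
        n_strong = sum(
            1 for m in c.signal.values() if m and max(m.values()) >= top_signal_min
        )
        if n_strong < min_samples:
            continue
        out.append(c)
    return out


def merge_nearby_for_assembly(
    clusters: Sequence[SiteCluster], cutoff: int = 400
) -> list[SiteCluster]:
    """Single-linkage merge of same-strand clusters whose gap is < cutoff nt.

    The summit of a merged cluster is the position with the highest pooled
    signal across the merged span."""
    out = []
    keys = sorted({(c.interval.chrom, c.interval.strand) for c in clusters})
    for key in keys:
        group = sorted(
            (c for c in clusters if (c.interval.chrom, c.interval.strand) == key),
            key=lambda c: c.interval.start,
        )
        run: list[SiteCluster] = []
        run_end = -1
        for c in group:
            if run and c.interval.start - run_end < cutoff:
                run.append(c)
                run_end = max(run_end, c.interval.end)
            else:
                if run:
                    out.append(_merge_keep_tpm(run))
                run, run_end = [c], c.interval.end
        if run:
            out.append(_merge_keep_tpm(run))
    return out


def _merge_keep_tpm(run: list[SiteCluster]) -> SiteCluster:
    if len(run) == 1:
        return run[0]
    merged = _combine(run)
    tpm: dict[str, float] = {}
    for c in run:
        for s, t in c.per_sample_tpm.items():
            tpm[s] = tpm.get(s, 0.0) + t
    merged.per_sample_tpm = tpm
    return merged


def prune_within(clusters: Sequence[SiteCluster], cutoff: int = 50) -> list[SiteCluster]:
    """Among clusters whose summits lie within cutoff nt of each other, keep
    only the one with the larger total signal (greedy, by descending signal;
    equal totals keep the leftmost summit)."""
    order = sorted(clusters, key=lambda c: (-c.total, c.summit))
    kept: list[SiteCluster] = []
    for c in order:
        if any(
            k.interval.chrom == c.interval.chrom
            and k.interval.strand == c.interval.strand
            and abs(k.summit - c.summit) <= cutoff
            for k in kept
        ):
            continue
        kept.append(c)
    kept.sort(key=lambda c: (c.interval.chrom, c.interval.strand, c.interval.start))
    return kept
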