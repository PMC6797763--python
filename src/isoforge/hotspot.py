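"""Alternative-splicing hotspot detection via a branching-process null.

Each gene is divided into segments at the union of its isoforms' exon
boundaries; every isoform becomes a binary string over those segments
(1 = segment present).  For a substring length K, the number of distinct
K-length patterns in a window is modelled, under the null hypothesis that
splicing choices are independent, as the number of leaves of a
Galton-Watson tree of depth K in which each path independently bifurcates
with probability p at each step:

    P(xi = 2 | K=1) = p,  P(xi = 1 | K=1) = 1 - p
    P(xi = n | K=k+1) = sum_{i=ceil(n/2)}^{n} C(i, n-i) p^(n-i)
                        (1-p)^(2i-n) P(xi = i | K=k)

with expectation E(X) = (1+p)^K, which provides the moment estimator
p = mean(counts)^(1/K) - 1.  A genome shows hotspots when the observed
distinct-count frequency exceeds the null pmf three-fold at some n; the
smallest such n is the hotspot cutoff.  Windows at or above the cutoff are
hotspot evidence; per-gene evidence windows merge into regions, and regions
supported by more than ``min_evidence`` (gene, k, window) evidences are
reported.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import binom

from .core import GeneModel, GenomicInterval


@dataclass
class IsoformStringSet:
    """Binary segment-presence strings for one gene's isoforms."""

    gene_id: str
    boundaries: tuple[int, ...]  # sorted segment edges (genomic)
    strings: tuple[str, ...]  # one per isoform, all equal length
    chrom: str = ""
    strand: str = "+"

    @property
    def n_segments(self) -> int:
        return len(self.boundaries) - 1


def encode_isoform_strings(gene: GeneModel) -> IsoformStringSet:
    """Segment the gene span at the union of all isoform exon boundaries and
    encode each isoform as a presence string."""
    if len(gene.isoforms) < 2:
        raise ValueError(f"gene {gene.gene_id}: need >=2 isoforms to encode")
    edges = sorted(
        {b for iso in gene.isoforms for e in iso.exons.exons for b in (e.start, e.end)}
    )
    strings = []
    for iso in gene.isoforms:
        bits = []
        for a, b in zip(edges, edges[1:]):
            covered = any(
                e.start <= a and b <= e.end for e in iso.exons.exons
            )
            bits.append("1" if covered else "0")
        strings.append("".join(bits))
    return IsoformStringSet(
        gene.gene_id,
        tuple(edges),
        tuple(strings),
        gene.locus.chrom,
        gene.strand,
    )


def count_substring_types(strings: Sequence[str], k: int) -> list[int]:
    """Number of distinct k-length patterns per window of k consecutive
    segments across a gene's isoform strings."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not strings:
        return []
    n = len(strings[0])
    if any(len(s) != n for s in strings):
        raise ValueError("isoform strings must share one length")
    return [
        len({s[t : t + k] for s in strings}) for t in range(n - k + 1)
    ]


@dataclass
class HotspotNull:
    """The branching-process null pmf over distinct k-substring counts."""

    p: float
    K: int
    pmf: np.ndarray  # index 0 -> n=1, ..., index 2^K - 1 -> n=2^K

    def prob(self, n: int) -> float:
        if 1 <= n <= len(self.pmf):
            return float(self.pmf[n - 1])
        return 0.0

    def expectation(self) -> float:
        n = np.arange(1, len(self.pmf) + 1)
        return float(n @ self.pmf)


def null_pmf(p: float, K: int) -> HotspotNull:
    """Exact pmf of the number of distinct K-length patterns under the null.

    Computed by binomial-thinning convolution: a state of i distinct paths
    branches to i + Binomial(i, p) at the next level.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if K < 1:
        raise ValueError("K must be >= 1")
    pmf = np.zeros(2)
    pmf[0] = 1.0 - p  # n = 1
    pmf[1] = p  # n = 2
    for _ in range(K - 1):
        size = len(pmf)
        new = np.zeros(2 * size)
        for i in range(1, size + 1):
            mass = pmf[i - 1]
            if mass == 0.0:
                continue
            j = np.arange(i + 1)
            new[i + j - 1] += mass * binom.pmf(j, i, p)
        pmf = new
    return HotspotNull(p, K, pmf)


def estimate_p(observed_counts: Sequence[float], K: int) -> float:
    """Moment estimator from E(X) = (1+p)^K, clamped to [0, 1]."""
    counts = np.asarray(observed_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("no observed counts")
    if (counts < 1).any():
        raise ValueError("distinct-pattern counts must be >= 1")
    p = float(counts.mean() ** (1.0 / K)) - 1.0
    return min(1.0, max(0.0, p))


def simulate_null_counts(
    p: float, K: int, n_genes: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample distinct-count draws from the branching null (for calibration
    checks): each of n_genes windows starts with one path and grows by
    Binomial(paths, p) per level over K levels."""
    x = np.ones(n_genes, dtype=np.int64)
    for _ in range(K):
        x = x + rng.binomial(x, p)
    return x


def hotspot_cutoff(
    null: HotspotNull,
    observed_counts: Sequence[int],
    fold: float = 3.0,
) -> Optional[int]:
    """Smallest n whose observed frequency is >= fold x the null pmf (and
    positive); None when the genome shows no such excess."""
    counts = np.asarray(observed_counts)
    if counts.size == 0:
        return None
    for n in range(1, 2 ** null.K + 1):
        obs = float((counts == n).mean())
        if obs > 0 and obs >= fold * null.prob(n):
            return n
    return None


@dataclass
class HotspotRegion:
    gene_id: str
    interval: GenomicInterval
    k_values: tuple[int, ...]
    n_evidence: int
    segment_range: tuple[int, int]  # [first, last] segment index


def scan_hotspots(
    string_sets: Sequence[IsoformStringSet],
    k_range: Iterable[int] = range(3, 11),
    fold: float = 3.0,
    min_evidence: int = 3,
) -> list[HotspotRegion]:
    """Scan a genome's isoform strings for AS hotspots.

    For each k, p is estimated genome-wide from the window counts, the null
    pmf and the fold-excess cutoff are derived, and windows reaching the
    cutoff become evidence.  Per gene, evidence windows sharing a segment
    merge; regions with more than min_evidence (gene, k, window) evidences
    are reported in genomic coordinates.
    """
    evidences: dict[str, list[tuple[int, int, int]]] = {}  # gene -> (k, lo, hi)
    by_gene = {ss.gene_id: ss for ss in string_sets}
    for k in k_range:
        per_window: list[tuple[str, int, int]] = []  # gene, window index, count
        all_counts: list[int] = []
        for ss in string_sets:
            if ss.n_segments < k or len(ss.strings) < 2:
                continue
            counts = count_substring_types(ss.strings, k)
            for t, c in enumerate(counts):
                per_window.append((ss.gene_id, t, c))
                all_counts.append(c)
        if not all_counts:
            continue
        p_hat = estimate_p(all_counts, k)
        null = null_pmf(p_hat, min(k, 16))
        cutoff = hotspot_cutoff(null, all_counts, fold)
        if cutoff is None:
            continue
        for gid, t, c in per_window:
            if c >= cutoff:
                evidences.setdefault(gid, []).append((k, t, t + k - 1))
    regions = []
    for gid, evs in evidences.items():
        ss = by_gene[gid]
        evs.sort(key=lambda e: (e[1], e[2]))
        # merge windows sharing >= 1 segment
        merged: list[list] = []  # [lo, hi, [evidence...]]
        for k, lo, hi in evs:
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
                merged[-1][2].append((k, lo, hi))
            else:
                merged.append([lo, hi, [(k, lo, hi)]])
        for lo, hi, members in merged:
            if len(members) <= min_evidence:
                continue
            iv = GenomicInterval(
                ss.chrom or gid,
                ss.boundaries[lo],
                ss.boundaries[hi + 1],
                ss.strand,
            )
            regions.append(
                HotspotRegion(
                    gid,
                    iv,
                    tuple(sorted({k for k, _, _ in members})),
                    len(members),
                    (lo, hi),
                )
            )
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return regions


def strings_from_genes(genes: Iterable[GeneModel]) -> list[IsoformStringSet]:
    """Encode every gene with >= 2 isoforms; single-isoform genes are skipped."""
    out = []
    for g in genes:
        if len(g.isoforms) >= 2:
            out.append(encode_isoform_strings(g))
    return out
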