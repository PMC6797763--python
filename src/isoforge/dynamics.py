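"""Expression and site-usage dynamics across tissues.

Implements the entropy-based tissue-specificity score
``S = log2 N - H_obs`` (H_obs is the Shannon entropy of the row-normalised
expression profile), the expressed-tissue rule (> 20% of the row maximum),
per-tissue dominant sites (> 50% usage), the pairwise switch score
``W = P_i,d(i) + P_j,d(j) - 1`` for differing dominants, the weighted 3'UTR
length ``L_w = sum_s P_s * len_s``, and the alternative-polyadenylation
switch call (|delta L_w| > 100 nt with site TPM > 5 in both samples).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd


def compute_fpkm(count: float, length: int, library: int) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if length <= 0 or library <= 0:
        raise ValueError("length and library size must be positive")
    return count * 1e9 / (length * library)


def tissue_specificity(expr_row: Sequence[float], n_tissues: Optional[int] = None) -> float:
    """S = log2(N) - H_obs, with 0*log2(0) treated as 0.

    S is 0 for a uniform profile and log2(N) for single-tissue expression.
    """
    row = np.asarray(expr_row, dtype=float)
    if (row < 0).any():
        raise ValueError("negative expression values")
    total = row.sum()
    if total == 0:
        raise ValueError("all-zero expression row has no specificity score")
    n = n_tissues if n_tissues is not None else row.size
    p = row / total
    nz = p[p > 0]
    h_obs = float(-(nz * np.log2(nz)).sum())
    return float(np.log2(n)) - h_obs


def expressed_tissues(expr_row: Mapping[str, float] | Sequence[float], frac: float = 0.2):
    """Tissues whose level exceeds frac x the row maximum (strict >)."""
    if isinstance(expr_row, Mapping):
        mx = max(expr_row.values())
        return {t for t, v in expr_row.items() if v > frac * mx}
    row = np.asarray(expr_row, dtype=float)
    return set(np.nonzero(row > frac * row.max())[0])


def dominant_site(usage_row: Mapping[str, float]) -> Optional[str]:
    """The site with usage fraction > 0.5 in one tissue, if any (strict)."""
    for site, p in usage_row.items():
        if p > 0.5:
            return site
    return None


def switch_score(usage_i: Mapping[str, float], usage_j: Mapping[str, float]) -> float:
    """W = P_i,d(i) + P_j,d(j) - 1 when the dominant sites differ, else 0."""
    di, dj = dominant_site(usage_i), dominant_site(usage_j)
    if di is None or dj is None:
        raise ValueError("both tissues must have a dominant site")
    if di == dj:
        return 0.0
    return usage_i[di] + usage_j[dj] - 1.0


@dataclass
class SiteUsage:
    """Per-gene site-cluster signal across tissues.

    ``signal`` is a sites x tissues DataFrame of cluster tag signal (TPM);
    usage fractions are column-normalised.
    """

    gene_id: str
    signal: pd.DataFrame
    utr_lengths: dict[str, float] = field(default_factory=dict)

    def usage(self) -> pd.DataFrame:
        tot = self.signal.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = self.signal.div(tot, axis=1)
        return u.fillna(0.0)

    def tissue_usage(self, tissue: str) -> dict[str, float]:
        return self.usage()[tissue].to_dict()

    def dominants(self) -> dict[str, Optional[str]]:
        u = self.usage()
        return {t: dominant_site(u[t].to_dict()) for t in u.columns}

    def total_tpm(self, tissue: str) -> float:
        return float(self.signal[tissue].sum())


def filter_usage_clusters(
    usage: SiteUsage, tpm_min: float = 0.5, min_tissues: int = 2
) -> SiteUsage:
    """Dynamics prefilter: keep site clusters with TPM > tpm_min in at least
    min_tissues tissues AND average TPM > tpm_min across tissues."""
    sig = usage.signal
    keep = ((sig > tpm_min).sum(axis=1) >= min_tissues) & (sig.mean(axis=1) > tpm_min)
    return SiteUsage(
        usage.gene_id,
        sig.loc[keep],
        {s: l for s, l in usage.utr_lengths.items() if s in sig.index[keep]},
    )


def call_switch_genes(
    usages: Mapping[str, SiteUsage], w_min: float = 0.3
) -> dict[str, float]:
    """Genes with >= 2 distinct dominant sites across tissues and a maximal
    pairwise switch score strictly above w_min.  Returns gene -> max W."""
    called: dict[str, float] = {}
    for gid, su in usages.items():
        doms = su.dominants()
        have = {t: d for t, d in doms.items() if d is not None}
        if len(set(have.values())) < 2:
            continue
        u = su.usage()
        w_max = 0.0
        for ti, tj in itertools.combinations(have, 2):
            if have[ti] == have[tj]:
                continue
            w = u.loc[have[ti], ti] + u.loc[have[tj], tj] - 1.0
            w_max = max(w_max, w)
        if w_max > w_min:
            called[gid] = float(w_max)
    return called


def weighted_utr_length(
    usage_row: Mapping[str, float] | Sequence[float],
    utr_lengths: Mapping[str, float] | Sequence[float],
) -> float:
    """L_w = sum over TES sites of usage fraction x 3'UTR length."""
    if isinstance(usage_row, Mapping) != isinstance(utr_lengths, Mapping):
        raise ValueError("usage and lengths must use matching key types")
    if isinstance(usage_row, Mapping):
        if set(usage_row) != set(utr_lengths):
            raise ValueError("usage/length site sets differ")
        return float(sum(usage_row[s] * utr_lengths[s] for s in usage_row))
    u = np.asarray(usage_row, float)
    l = np.asarray(utr_lengths, float)
    if u.shape != l.shape:
        raise ValueError("usage/length dimension mismatch")
    return float(u @ l)


def call_apa_switch(
    usage: SiteUsage,
    sample_a: str,
    sample_b: str,
    delta_min: float = 100.0,
    tpm_min: float = 5.0,
) -> bool:
    """Alternative-3'UTR call between two samples: |L_w(a) - L_w(b)| strictly
    above delta_min and total TES signal strictly above tpm_min in both."""
    lw = {}
    for sample in (sample_a, sample_b):
        row = usage.tissue_usage(sample)
        lw[sample] = weighted_utr_length(row, {s: usage.utr_lengths[s] for s in row})
    if abs(lw[sample_a] - lw[sample_b]) <= delta_min:
        return False
    return usage.total_tpm(sample_a) > tpm_min and usage.total_tpm(sample_b) > tpm_min


def specificity_table(expr: pd.DataFrame) -> pd.Series:
    """S score per gene for a gene x tissue matrix (all-zero rows dropped)."""
    nz = expr.loc[expr.sum(axis=1) > 0]
    return nz.apply(lambda row: tissue_specificity(row.values), axis=1)
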