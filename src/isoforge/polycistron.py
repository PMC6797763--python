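"""Polycistronic (multi-ORF) transcript detection and follow-up statistics.

A polycistron is a transcript whose spliced sequence carries two or more
non-overlapping major ORFs (>= 100 codons by default).  Downstream
statistics: inter-CDS spliced distances, co-expression of member genes
contrasted against random same-chromosome gene pairs, and the cross-species
co-linearity rule (orthologs on the same strand of the same chromosome less
than 20 kb apart).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import IsoformRecord, spliced_sequence
from .features import STOPS


@dataclass
class PolycistronCall:
    transcript_id: str
    cds_list: list[tuple[int, int]]  # spliced coords, 5'->3', stop included
    member_gene_ids: list[str] = field(default_factory=list)

    @property
    def arity(self) -> int:
        return len(self.cds_list)

    def __post_init__(self) -> None:
        self.cds_list.sort()
        for (a1, b1), (a2, b2) in zip(self.cds_list, self.cds_list[1:]):
            if a2 < b1:
                raise ValueError("polycistron CDS regions must not overlap")
        if self.arity < 2:
            raise ValueError("polycistron requires >= 2 CDS regions")


def _all_orfs(seq: str, min_aa: int) -> list[tuple[int, int]]:
    orfs = []
    for frame in range(3):
        start: Optional[int] = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon == "ATG" and start is None:
                start = i
            elif codon in STOPS and start is not None:
                if (i - start) // 3 >= min_aa:
                    orfs.append((start, i + 3))
                start = None
    return orfs


def detect_polycistrons(
    isoforms: Sequence[IsoformRecord],
    genome: Mapping[str, str],
    min_aa: int = 100,
) -> list[PolycistronCall]:
    """Transcripts whose spliced sequence contains >= 2 non-overlapping
    major ORFs; ORFs are selected greedily by descending length with
    overlap exclusion."""
    calls = []
    for iso in isoforms:
        seq = spliced_sequence(iso.exons, genome).upper().replace("U", "T")
        orfs = _all_orfs(seq, min_aa)
        orfs.sort(key=lambda o: (-(o[1] - o[0]), o[0]))
        chosen: list[tuple[int, int]] = []
        for a, b in orfs:
            if any(a < d and c < b for c, d in chosen):
                continue
            chosen.append((a, b))
        if len(chosen) >= 2:
            calls.append(PolycistronCall(iso.id, sorted(chosen)))
    return calls


def intercds_distance(call: PolycistronCall) -> list[int]:
    """Spliced-coordinate gaps between the stop of ORF k and the start codon
    of ORF k+1."""
    return [b2[0] - b1[1] for b1, b2 in zip(call.cds_list, call.cds_list[1:])]


@dataclass
class CoexpressionContrast:
    paired_r: np.ndarray
    random_r: np.ndarray
    statistic: float
    pvalue: float


def coexpression_contrast(
    calls: Sequence[PolycistronCall],
    expr: pd.DataFrame,
    n_random: int = 1000,
    seed: int = 0,
    gene_chrom: Optional[Mapping[str, str]] = None,
) -> CoexpressionContrast:
    """Pearson correlation across tissues for within-polycistron member gene
    pairs versus random same-chromosome pairs, compared by a one-sided
    Wilcoxon rank-sum test (paired > random)."""
    rng = np.random.default_rng(seed)
    paired = []
    for call in calls:
        members = [g for g in call.member_gene_ids if g in expr.index]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a = expr.loc[members[i]].to_numpy(float)
                b = expr.loc[members[j]].to_numpy(float)
                if a.std() == 0 or b.std() == 0:
                    continue
                paired.append(float(np.corrcoef(a, b)[0, 1]))
    genes = list(expr.index)
    by_chrom: dict[str, list[str]] = {}
    for g in genes:
        chrom = gene_chrom.get(g, "chr") if gene_chrom else "chr"
        by_chrom.setdefault(chrom, []).append(g)
    random_r = []
    attempts = 0
    while len(random_r) < n_random and attempts < 20 * n_random:
        attempts += 1
        chrom = rng.choice([c for c, gs in by_chrom.items() if len(gs) >= 2])
        g1, g2 = rng.choice(by_chrom[chrom], size=2, replace=False)
        a = expr.loc[g1].to_numpy(float)
        b = expr.loc[g2].to_numpy(float)
        if a.std() == 0 or b.std() == 0:
            continue
        random_r.append(float(np.corrcoef(a, b)[0, 1]))
    paired_arr = np.array(paired)
    random_arr = np.array(random_r)
    if paired_arr.size and random_arr.size:
        res = stats.mannwhitneyu(paired_arr, random_arr, alternative="greater")
        stat, pval = float(res.statistic), float(res.pvalue)
    else:
        stat, pval = float("nan"), float("nan")
    return CoexpressionContrast(paired_arr, random_arr, stat, pval)


@dataclass(frozen=True)
class OrthologLocation:
    species: str
    chrom: str
    start: int
    end: int
    strand: str


def check_colinearity(
    call: PolycistronCall,
    ortholog_map: Mapping[str, Sequence[OrthologLocation]],
    max_dist: int = 20_000,
) -> dict[str, bool]:
    """Per-species co-linearity of the first member pair: both orthologs on
    the same strand of the same chromosome with a gap < max_dist."""
    if len(call.member_gene_ids) < 2:
        raise ValueError("co-linearity requires member gene ids")
    g1, g2 = call.member_gene_ids[:2]
    species = {
        loc.species
        for g in (g1, g2)
        for loc in ortholog_map.get(g, ())
    }
    out = {}
    for sp in sorted(species):
        loc1 = next((l for l in ortholog_map.get(g1, ()) if l.species == sp), None)
        loc2 = next((l for l in ortholog_map.get(g2, ()) if l.species == sp), None)
        if loc1 is None or loc2 is None:
            out[sp] = False
            continue
        same = loc1.chrom == loc2.chrom and loc1.strand == loc2.strand
        gap = max(loc1.start, loc2.start) - min(loc1.end, loc2.end)
        out[sp] = bool(same and gap < max_dist)
    return out


def read_ortholog_map(path: str) -> dict[str, list[OrthologLocation]]:
    """TSV columns: gene, species, chrom, start, end, strand."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[OrthologLocation]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["gene"]), []).append(
            OrthologLocation(
                str(row["species"]),
                str(row["chrom"]),
                int(row["start"]),
                int(row["end"]),
                str(row["strand"]),
            )
        )
    return out
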