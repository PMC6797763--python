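"""Short-read (NGS) transfrag post-processing and integration.

Externally assembled transfrags are filtered on expression (FPKM >= 0.5 for
single-exon, >= 0.2 for multi-exon fragments), their terminal boundaries are
snapped to nearby reliable TSS/TES cluster summits (within 500 bp, never
across the first/last splice junction), and the surviving models (isoN) fill
the loci that long reads did not cover.
"""
from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

from .core import ExonChain, GenomicInterval, GeneModel, IsoformRecord, group_into_genes
from .clustering import SiteCluster


def filter_transfrags(
    transfrags: Sequence[IsoformRecord],
    single_exon_min: float = 0.5,
    multi_exon_min: float = 0.2,
) -> list[IsoformRecord]:
    """Keep single-exon transfrags with FPKM >= single_exon_min and
    multi-exon transfrags with FPKM >= multi_exon_min (inclusive)."""
    out = []
    for t in transfrags:
        if "fpkm" not in t.attrs:
            raise ValueError(f"transfrag {t.id} has no FPKM attribute")
        cutoff = single_exon_min if len(t.exons.exons) == 1 else multi_exon_min
        if t.attrs["fpkm"] >= cutoff:
            out.append(t)
    return out


def _nearest_summit(
    clusters: Sequence[SiteCluster], chrom: str, strand: str, pos: int, max_dist: int
) -> Optional[int]:
    best = None
    for c in clusters:
        if c.interval.chrom != chrom or c.interval.strand != strand:
            continue
        s = c.summit
        d = abs(s - pos)
        if d <= max_dist and (best is None or d < abs(best - pos)):
            best = s
    return best


def fix_boundaries(
    transfrag: IsoformRecord,
    tss: Sequence[SiteCluster],
    tes: Sequence[SiteCluster],
    max_dist: int = 500,
) -> IsoformRecord:
    """Snap the 5' (3') terminal boundary to the nearest TSS (TES) cluster
    summit within max_dist; a move never crosses the first (last) splice
    junction."""
    chain = transfrag.exons
    blocks = [list(b) for b in chain.blocks()]
    chrom, strand = chain.chrom, chain.strand
    five_idx, three_idx = (0, -1) if strand == "+" else (-1, 0)
    five_pos = blocks[0][0] if strand == "+" else blocks[-1][1] - 1
    three_pos = blocks[-1][1] - 1 if strand == "+" else blocks[0][0]

    s = _nearest_summit(tss, chrom, strand, five_pos, max_dist)
    if s is not None:
        if strand == "+":
            blocks[0][0] = min(s, blocks[0][1] - 1)  # clamp at first junction
        else:
            blocks[-1][1] = max(s + 1, blocks[-1][0] + 1)
    s = _nearest_summit(tes, chrom, strand, three_pos, max_dist)
    if s is not None:
        if strand == "+":
            blocks[-1][1] = max(s + 1, blocks[-1][0] + 1)
        else:
            blocks[0][0] = min(s, blocks[0][1] - 1)
    new_chain = ExonChain.from_blocks(chrom, strand, [(a, b) for a, b in blocks])
    return replace(transfrag, exons=new_chain, cds=None)


LONG_READ_CLASSES = frozenset({"isoF", "isoR", "isoC"})


def integrate_annotation(
    long_read_genes: Sequence[GeneModel],
    transfrags: Sequence[IsoformRecord],
) -> list[GeneModel]:
    """Combine long-read-derived gene models with isoN transfrags.

    A locus with any long-read isoform keeps only the long-read classes
    (isoF, isoR, isoC); loci without long-read coverage take the isoN
    transfrags.  No locus mixes the two sources.
    """
    long_read_isos = [
        iso for g in long_read_genes for iso in g.isoforms if iso.cls in LONG_READ_CLASSES
    ]
    isoN = [replace(t, cls="isoN") for t in transfrags]
    combined = group_into_genes(long_read_isos + isoN, prefix="LOCUS")
    final: list[IsoformRecord] = []
    for gene in combined:
        has_long = any(i.cls in LONG_READ_CLASSES for i in gene.isoforms)
        for iso in gene.isoforms:
            if has_long and iso.cls in LONG_READ_CLASSES:
                final.append(iso)
            elif not has_long and iso.cls == "isoN":
                final.append(iso)
    return group_into_genes(final, prefix="GENE")
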