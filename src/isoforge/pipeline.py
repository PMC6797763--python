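"""End-to-end orchestration: tag tracks -> clusters -> linkage groups ->
assembled annotation, plus the bridge from clusters to the per-gene site
usage matrices consumed by the dynamics statistics."""
from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .core import ExonChain, GeneModel, GenomicInterval, group_into_genes
from .clustering import (
    SiteCluster,
    attach_tpm,
    cluster_tags,
    filter_reliable,
    merge_across_samples,
    merge_nearby_for_assembly,
    prune_within,
)
from .assembler import (
    SpliceJunction,
    assemble_locus,
    call_credible_junctions,
    find_linkage_groups,
)
from .dynamics import SiteUsage
from .io import RunConfig, TagSignal


def cluster_sites(
    tags: TagSignal, kind: str, config: RunConfig = RunConfig()
) -> list[SiteCluster]:
    """Per-sample density clustering, cross-sample merge, TPM attachment and
    the reliability filter, in the reference order."""
    per_sample: dict[str, list[SiteCluster]] = {}
    for sample, tracks in tags.data.items():
        clusters: list[SiteCluster] = []
        for (chrom, strand), posmap in tracks.items():
            clusters.extend(
                cluster_tags(
                    posmap,
                    min_value=config.cluster_min_value,
                    max_length=config.cluster_max_length,
                    min_density_fold=config.cluster_min_density_fold,
                    kind=kind,
                    chrom=chrom,
                    strand=strand,
                    sample=sample,
                )
            )
        per_sample[sample] = clusters
    merged = merge_across_samples(per_sample)
    attach_tpm(merged, tags.library_size)
    return filter_reliable(
        merged,
        tpm_min=config.reliable_tpm_min,
        top_signal_min=config.reliable_top_signal_min,
        min_samples=config.reliable_min_samples,
    )


def _in_group(iv: GenomicInterval, group: GenomicInterval) -> bool:
    return (
        iv.chrom == group.chrom
        and (iv.strand == group.strand or iv.strand == ".")
        and iv.start >= group.start
        and iv.end <= group.end
    )


def assemble_transcriptome(
    reads: Sequence[tuple[str, ExonChain]],
    tag5: TagSignal,
    tag3: TagSignal,
    junctions: Sequence[SpliceJunction],
    coverage: Iterable[GenomicInterval],
    config: RunConfig = RunConfig(),
) -> tuple[list[GeneModel], dict[str, int]]:
    """Run the full long-read assembly and return gene models plus a
    per-class report (isoF/isoC/isoM/isoR/isoP counts and locus count)."""
    tss_rel = cluster_sites(tag5, "TSS", config)
    tes_rel = cluster_sites(tag3, "TES", config)
    tss_asm = merge_nearby_for_assembly(tss_rel, config.assembly_merge_cutoff)
    tes_asm = merge_nearby_for_assembly(tes_rel, config.assembly_merge_cutoff)
    credible = call_credible_junctions(
        junctions, config.junction_min_reads, config.junction_min_samples
    )
    groups = find_linkage_groups(coverage, reads, config.linkage_window)
    report = {c: 0 for c in ("isoF", "isoC", "isoM", "isoR", "isoP")}
    report["loci"] = 0
    all_isoforms = []
    for n, group in enumerate(groups, start=1):
        giv = group.interval
        g_tss = [
            c
            for c in tss_asm
            if c.interval.chrom == giv.chrom
            and c.interval.strand == giv.strand
            and giv.contains(c.summit)
        ]
        g_tes = [
            c
            for c in tes_asm
            if c.interval.chrom == giv.chrom
            and c.interval.strand == giv.strand
            and giv.contains(c.summit)
        ]
        g_junc = [
            j
            for j in credible
            if j.chrom == giv.chrom
            and j.strand == giv.strand
            and giv.start <= j.donor
            and j.acceptor <= giv.end
        ]
        g_reads = [
            (rid, chain)
            for rid, chain in reads
            if _in_group(chain.span, giv)
        ]
        if not g_reads:
            continue
        genes, counts = assemble_locus(
            group, g_tss, g_tes, g_junc, g_reads, id_prefix=f"L{n:04d}"
        )
        for k, v in counts.items():
            report[k] += v
        report["loci"] += 1
        for gene in genes:
            all_isoforms.extend(gene.isoforms)
    final = group_into_genes(all_isoforms, prefix="GENE")
    for i, gene in enumerate(final, start=1):
        for k, iso in enumerate(gene.isoforms, start=1):
            iso.id = f"{gene.gene_id}.{k}"
    return final, report


# ---- cluster -> usage matrices ----------------------------------------


def dynamics_clusters(
    tags: TagSignal, kind: str, config: RunConfig = RunConfig()
) -> list[SiteCluster]:
    """Reliable clusters pruned at 50 nt summit distance, as used by the
    alternative TSS/TES usage analyses (no 400 nt assembly merge)."""
    return prune_within(cluster_sites(tags, kind, config), config.prune_cutoff)


def build_site_usage(
    genes: Sequence[GeneModel],
    clusters: Sequence[SiteCluster],
    kind: str,
    samples: Optional[Sequence[str]] = None,
) -> dict[str, SiteUsage]:
    """Per-gene sites x samples TPM matrices from cluster signal.

    Clusters are attributed to a gene when their summit falls inside the
    gene locus on the same strand.  For TES clusters, per-site 3'UTR lengths
    are derived from the closest-ending CDS-bearing isoform (spliced length
    minus CDS end)."""
    out: dict[str, SiteUsage] = {}
    for gene in genes:
        hits = [
            c
            for c in clusters
            if c.interval.chrom == gene.locus.chrom
            and c.interval.strand == gene.locus.strand
            and gene.locus.contains(c.summit)
        ]
        if not hits:
            continue
        cols = samples or sorted(
            {s for c in hits for s in c.per_sample_tpm}
        )
        rows = {}
        for c in hits:
            rows[str(c.summit)] = [c.per_sample_tpm.get(s, 0.0) for s in cols]
        sig = pd.DataFrame.from_dict(rows, orient="index", columns=list(cols))
        utr_lengths: dict[str, float] = {}
        if kind == "TES":
            for c in hits:
                best, best_d = None, None
                for iso in gene.isoforms:
                    if iso.cds is None:
                        continue
                    end3 = (
                        iso.exons.end - 1
                        if gene.strand == "+"
                        else iso.exons.start
                    )
                    d = abs(end3 - c.summit)
                    if best_d is None or d < best_d:
                        best, best_d = iso, d
                if best is not None:
                    utr_lengths[str(c.summit)] = float(
                        best.exons.spliced_length - best.cds[1]
                    )
        out[gene.gene_id] = SiteUsage(gene.gene_id, sig, utr_lengths)
    return out
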