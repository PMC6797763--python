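"""Readers and writers for the standard formats touched by the pipeline.

Internal coordinates are 0-based half-open; GTF/GFF3 use 1-based closed and
are converted at this boundary.  GTF and GFF3 are both accepted on input;
GFF3 is the only annotation output dialect.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .core import ExonChain, GenomicInterval, IsoformRecord, group_into_genes
from .assembler import SpliceJunction


# ---- run configuration -------------------------------------------------


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, with defaults reproducing the
    reference analysis parameters."""

    # site clustering
    cluster_min_value: float = 20.0
    cluster_max_length: int = 200
    cluster_min_density_fold: float = 5.0
    reliable_tpm_min: float = 0.5
    reliable_top_signal_min: int = 10
    reliable_min_samples: int = 3
    assembly_merge_cutoff: int = 400
    prune_cutoff: int = 50
    # assembler
    linkage_window: int = 100
    junction_min_reads: int = 3
    junction_min_samples: int = 1
    # NGS transfrag integration
    transfrag_single_exon_min_fpkm: float = 0.5
    transfrag_multi_exon_min_fpkm: float = 0.2
    boundary_fix_max_dist: int = 500
    # features
    microexon_max_len: int = 51
    rg4_min_tract: int = 4
    rg4_min_loop: int = 2
    urich_window: int = 10
    urich_min_frac: float = 0.8
    urich_min_len: int = 6
    uorf_min_aa: int = 2
    # dynamics
    expressed_frac: float = 0.2
    dynamics_tpm_min: float = 0.5
    dynamics_min_tissues: int = 2
    switch_w_min: float = 0.3
    apa_delta_min: float = 100.0
    apa_tpm_min: float = 5.0
    # hotspot
    hotspot_k_min: int = 3
    hotspot_k_max: int = 10
    hotspot_fold: float = 3.0
    hotspot_min_evidence: int = 3
    # polycistron
    polycistron_min_aa: int = 100
    colinear_max_dist: int = 20_000
    # misc
    seed: int = 0
    samples: dict = field(default_factory=dict)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


# ---- GTF / GFF3 --------------------------------------------------------


def read_transcripts(path: str) -> list[IsoformRecord]:
    """Read transcript models from GTF or GFF3.

    Exon chains are sorted and converted to 0-based half-open coordinates;
    an ``FPKM`` attribute, a ``cls`` attribute, and CDS features are
    retained when present.
    """
    from gffutils.feature import feature_from_line

    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            try:
                feat = feature_from_line(line.rstrip("\n"))
            except Exception as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from exc
            if feat.start is None or feat.end is None:
                raise ValueError(f"{path}:{lineno}: malformed line (no coordinates)")
            chrom, ftype, strand = feat.seqid, feat.featuretype, feat.strand
            start_i, end_i = feat.start - 1, feat.end
            attrs = {k: v[0] for k, v in feat.attributes.items() if v}
            if "ID" in attrs or "Parent" in attrs:  # GFF3 dialect
                tid = attrs.get("ID") if ftype in ("mRNA", "transcript") else attrs.get("Parent")
            else:
                tid = attrs.get("transcript_id")
            if tid is None:
                continue
            if ftype in ("mRNA", "transcript"):
                m = meta.setdefault(tid, {"chrom": chrom, "strand": strand})
                m["bounds"] = (start_i, end_i)
                if "FPKM" in attrs:
                    m["fpkm"] = float(attrs["FPKM"])
                if "cls" in attrs:
                    m["cls"] = attrs["cls"]
                if "gene_id" in attrs:
                    m["gene_id"] = attrs["gene_id"]
                if "Parent" in attrs and "ID" in attrs:
                    m["gene_id"] = attrs["Parent"]
                if tid not in order:
                    order.append(tid)
            elif ftype == "exon":
                meta.setdefault(tid, {"chrom": chrom, "strand": strand})
                if tid not in order:
                    order.append(tid)
                exons.setdefault(tid, []).append((start_i, end_i))
                if "FPKM" in attrs:
                    meta[tid].setdefault("fpkm", float(attrs["FPKM"]))
                if "gene_id" in attrs:
                    meta[tid].setdefault("gene_id", attrs["gene_id"])
            elif ftype == "CDS":
                cds.setdefault(tid, []).append((start_i, end_i))
    out = []
    for tid in order:
        if tid not in exons:
            continue
        m = meta[tid]
        chain = ExonChain.from_blocks(m["chrom"], m["strand"], exons[tid])
        if "bounds" in m:
            blo, bhi = m["bounds"]
            if chain.start < blo or chain.end > bhi:
                raise ValueError(f"transcript {tid}: exon outside transcript bounds")
        cds_spliced = None
        if tid in cds:
            blocks = sorted(cds[tid])
            lo = chain.genomic_to_spliced(
                blocks[0][0] if chain.strand == "+" else blocks[-1][1] - 1
            )
            hi = chain.genomic_to_spliced(
                blocks[-1][1] - 1 if chain.strand == "+" else blocks[0][0]
            )
            cds_spliced = (lo, hi + 1)
        attrs = {}
        if "fpkm" in m:
            attrs["fpkm"] = m["fpkm"]
        out.append(
            IsoformRecord(
                tid,
                chain,
                cls=m.get("cls", "isoF"),
                gene_id=m.get("gene_id", ""),
                cds=cds_spliced,
                attrs=attrs,
            )
        )
    return out


def write_transcripts(isoforms: Sequence[IsoformRecord], path: str) -> None:
    """Write isoforms as GFF3 (gene/mRNA/exon/CDS), deterministically ordered
    by (chrom, start, id).  The confidence class goes into a ``cls``
    attribute."""
    need_genes = any(not iso.gene_id for iso in isoforms)
    if need_genes:
        group_into_genes(list(isoforms))
    by_gene: dict[str, list[IsoformRecord]] = {}
    for iso in isoforms:
        by_gene.setdefault(iso.gene_id, []).append(iso)
    lines = ["##gff-version 3"]
    gene_order = sorted(
        by_gene.items(),
        key=lambda kv: (
            kv[1][0].exons.chrom,
            min(i.exons.start for i in kv[1]),
            kv[0],
        ),
    )
    for gid, isos in gene_order:
        chrom = isos[0].exons.chrom
        strand = isos[0].exons.strand
        gstart = min(i.exons.start for i in isos)
        gend = max(i.exons.end for i in isos)
        lines.append(
            f"{chrom}\tisoforge\tgene\t{gstart + 1}\t{gend}\t.\t{strand}\t.\tID={gid}"
        )
        for iso in sorted(isos, key=lambda i: (i.exons.start, i.id)):
            attrs = [f"ID={iso.id}", f"Parent={gid}", f"cls={iso.cls}"]
            if "fpkm" in iso.attrs:
                attrs.append(f"FPKM={iso.attrs['fpkm']:g}")
            lines.append(
                f"{chrom}\tisoforge\tmRNA\t{iso.exons.start + 1}\t{iso.exons.end}"
                f"\t.\t{strand}\t.\t{';'.join(attrs)}"
            )
            for k, e in enumerate(iso.exons.exons, start=1):
                lines.append(
                    f"{chrom}\tisoforge\texon\t{e.start + 1}\t{e.end}\t.\t{strand}"
                    f"\t.\tID={iso.id}.exon{k};Parent={iso.id}"
                )
            if iso.cds is not None:
                phase = 0
                for s, t in iso.exons.spliced_interval_to_genomic(*iso.cds):
                    lines.append(
                        f"{chrom}\tisoforge\tCDS\t{s + 1}\t{t}\t.\t{strand}\t{phase}"
                        f"\tID={iso.id}.cds;Parent={iso.id}"
                    )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---- tag signals (bedGraph) -------------------------------------------


@dataclass
class TagSignal:
    """Per-base 5' or 3' tag counts for a set of samples.

    ``data[sample][(chrom, strand)]`` is a sparse position->count map;
    ``library_size[sample]`` is the total tag count of the sample.
    """

    end: str  # "five_prime" | "three_prime"
    data: dict[str, dict[tuple[str, str], dict[int, int]]] = field(default_factory=dict)
    library_size: dict[str, int] = field(default_factory=dict)

    def add_bedgraph(self, sample: str, path: str, strand: str) -> None:
        counts = read_bedgraph(path)
        per = self.data.setdefault(sample, {})
        for chrom, posmap in counts.items():
            dst = per.setdefault((chrom, strand), {})
            for pos, v in posmap.items():
                if pos in dst:
                    raise ValueError(
                        f"{path}: overlapping intervals at {chrom}:{pos}"
                    )
                dst[pos] = v
        self.library_size[sample] = self.library_size.get(sample, 0) + sum(
            sum(m.values()) for m in counts.values()
        )

    def samples(self) -> list[str]:
        return sorted(self.data)


def read_bedgraph(path: str) -> dict[str, dict[int, int]]:
    """Read a bedGraph of integer tag counts into chrom -> {pos: count}."""
    out: dict[str, dict[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative value")
            iv = int(round(value))
            dst = out.setdefault(chrom, {})
            for pos in range(start, end):
                if pos in dst:
                    raise ValueError(f"{path}:{lineno}: overlapping intervals")
                if iv:
                    dst[pos] = iv
    return out


def read_tag_signal(
    manifest: Mapping[str, Sequence[tuple[str, str]]], end: str
) -> TagSignal:
    """Load per-sample bedGraphs; manifest maps sample -> [(path, strand)]."""
    sig = TagSignal(end=end)
    for sample, files in manifest.items():
        sig.library_size.setdefault(sample, 0)
        sig.data.setdefault(sample, {})
        for path, strand in files:
            sig.add_bedgraph(sample, path, strand)
    return sig


def write_bedgraph(posmap: Mapping[int, int], chrom: str, path: str) -> None:
    with open(path, "w") as fh:
        for pos in sorted(posmap):
            v = posmap[pos]
            if v:
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{v}\n")


# ---- junction table ----------------------------------------------------


def read_junction_table(path: str) -> list[SpliceJunction]:
    """Read a TSV with columns chrom, donor, acceptor, strand and one count
    column per sample; duplicate rows are summed."""
    df = pd.read_csv(path, sep="\t")
    required = ["chrom", "donor", "acceptor", "strand"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    samples = [c for c in df.columns if c not in required]
    merged: dict[tuple, dict[str, int]] = {}
    for _, row in df.iterrows():
        donor, acceptor = int(row["donor"]), int(row["acceptor"])
        if donor >= acceptor:
            raise ValueError(f"{path}: donor {donor} >= acceptor {acceptor}")
        key = (row["chrom"], donor, acceptor, row["strand"])
        dst = merged.setdefault(key, {s: 0 for s in samples})
        for s in samples:
            dst[s] += int(row[s])
    return [
        SpliceJunction(chrom, donor, acceptor, strand, counts)
        for (chrom, donor, acceptor, strand), counts in sorted(merged.items())
    ]


def write_junction_table(junctions: Sequence[SpliceJunction], path: str) -> None:
    samples = sorted({s for j in junctions for s in j.per_sample_count})
    rows = []
    for j in sorted(junctions, key=lambda j: j.key):
        row = {"chrom": j.chrom, "donor": j.donor, "acceptor": j.acceptor, "strand": j.strand}
        for s in samples:
            row[s] = j.per_sample_count.get(s, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---- BED12 long reads --------------------------------------------------


def read_bed12(path: str) -> list[tuple[str, ExonChain]]:
    """Read long-read alignments as exon-block records."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            out.append((name, ExonChain.from_blocks(chrom, strand, blocks)))
    return out


def write_bed12(reads: Sequence[tuple[str, ExonChain]], path: str) -> None:
    with open(path, "w") as fh:
        for name, chain in reads:
            blocks = chain.blocks()
            start = chain.start
            sizes = ",".join(str(e - s) for s, e in blocks)
            offs = ",".join(str(s - start) for s, _ in blocks)
            fh.write(
                f"{chain.chrom}\t{start}\t{chain.end}\t{name}\t0\t{chain.strand}"
                f"\t{start}\t{chain.end}\t0\t{len(blocks)}\t{sizes}\t{offs}\n"
            )


# ---- expression matrix -------------------------------------------------


def read_expression_matrix(path: str) -> pd.DataFrame:
    """Gene x sample FPKM table (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative expression values")
    return df


def write_expression_matrix(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t")


# ---- BED6 cluster output ----------------------------------------------


def write_clusters_bed6(clusters, path: str) -> None:
    """Clusters as BED6: name = kind/index, score = summit signal."""
    with open(path, "w") as fh:
        for n, c in enumerate(
            sorted(clusters, key=lambda c: (c.interval.chrom, c.interval.start)), 1
        ):
            pooled = c.pooled_signal()
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}"
                f"\t{c.kind}.{n}\t{pooled[c.summit]}\t{c.interval.strand}\n"
            )


# ---- FASTA -------------------------------------------------------------


def read_genome(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_genome(genome: Mapping[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
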