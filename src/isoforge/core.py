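"""Strand-aware genomic intervals, exon chains, and the transcript/gene data model.

All coordinates are 0-based, half-open ``[start, end)``.  Conversion to the
1-based closed convention happens only at GTF/GFF3 boundaries (see
:mod:`isoforge.io`).  Strand ``"."`` is permitted for signal tracks only,
never for isoforms.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

STRANDS = ("+", "-", ".")

#: isoform confidence classes, in decreasing reliability order.
#: isoF full-length, isoR rescued, isoC completed, isoM merged, isoP partial,
#: isoN short-read-only.
ISOFORM_CLASSES = ("isoF", "isoR", "isoC", "isoM", "isoP", "isoN")

CLASS_PRIORITY = {c: i for i, c in enumerate(ISOFORM_CLASSES)}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on one strand of one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def intersect(a: GenomicInterval, b: GenomicInterval) -> Optional[GenomicInterval]:
    """Overlap of two intervals, or None when disjoint (half-open: touching
    intervals do not intersect).  The result takes ``a``'s strand."""
    if a.chrom != b.chrom:
        raise ValueError(f"cannot intersect intervals on {a.chrom} and {b.chrom}")
    lo = max(a.start, b.start)
    hi = min(a.end, b.end)
    if lo >= hi:
        return None
    return GenomicInterval(a.chrom, lo, hi, a.strand)


@dataclass(frozen=True)
class ExonChain:
    """Ordered, disjoint exons on one chromosome and strand.

    Exons are stored in genomic order (sorted by start) regardless of strand;
    the gaps between consecutive exons are the introns.  Consecutive exons
    must be separated by at least 1 nt.
    """

    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("ExonChain requires at least one exon")
        chrom = self.exons[0].chrom
        strand = self.exons[0].strand
        if strand == ".":
            raise ValueError("isoform exon chains must be stranded")
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.chrom != chrom or cur.strand != strand:
                raise ValueError("all exons must share chrom and strand")
            if cur.start < prev.end + 1:
                raise ValueError(
                    f"exons not sorted/disjoint with >=1 nt gap: "
                    f"[{prev.start},{prev.end}) then [{cur.start},{cur.end})"
                )

    @classmethod
    def from_blocks(
        cls, chrom: str, strand: str, blocks: Iterable[tuple[int, int]]
    ) -> "ExonChain":
        ivs = tuple(
            GenomicInterval(chrom, s, e, strand) for s, e in sorted(blocks)
        )
        return cls(ivs)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons; empty for single-exon chains."""
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]

    def blocks(self) -> list[tuple[int, int]]:
        return [(e.start, e.end) for e in self.exons]

    # ---- spliced <-> genomic coordinate mapping (5'->3' orientation) ----

    def spliced_to_genomic(self, pos: int) -> int:
        """Map a spliced (mRNA, 5'->3') offset to a genomic base position."""
        if not (0 <= pos < self.spliced_length):
            raise ValueError(f"spliced position {pos} out of range")
        exons = self.exons if self.strand == "+" else self.exons[::-1]
        off = pos
        for e in exons:
            if off < e.length:
                return e.start + off if self.strand == "+" else e.end - 1 - off
            off -= e.length
        raise AssertionError("unreachable")

    def genomic_to_spliced(self, pos: int) -> int:
        """Map an exonic genomic base to a spliced offset (5'->3')."""
        exons = self.exons if self.strand == "+" else self.exons[::-1]
        off = 0
        for e in exons:
            if e.contains(pos):
                return off + (pos - e.start if self.strand == "+" else e.end - 1 - pos)
            off += e.length
        raise ValueError(f"position {pos} is not exonic")

    def spliced_interval_to_genomic(self, lo: int, hi: int) -> list[tuple[int, int]]:
        """Project a spliced half-open interval onto genomic blocks."""
        if not (0 <= lo < hi <= self.spliced_length):
            raise ValueError(f"bad spliced interval [{lo},{hi})")
        a = self.spliced_to_genomic(lo)
        b = self.spliced_to_genomic(hi - 1)
        glo, ghi = (a, b + 1) if self.strand == "+" else (b, a + 1)
        out = []
        for e in self.exons:
            s, t = max(e.start, glo), min(e.end, ghi)
            if s < t:
                out.append((s, t))
        return out


@dataclass
class IsoformRecord:
    """One transcript model: exon chain plus confidence class and optional
    CDS in spliced coordinates (half-open, stop codon included)."""

    id: str
    exons: ExonChain
    cls: str = "isoF"
    gene_id: str = ""
    tss_cluster: object = None
    tes_cluster: object = None
    cds: Optional[tuple[int, int]] = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cls not in ISOFORM_CLASSES:
            raise ValueError(f"unknown isoform class {self.cls!r}")
        if self.cds is not None:
            lo, hi = self.cds
            if not (0 <= lo < hi <= self.exons.spliced_length):
                raise ValueError("CDS outside spliced length")


@dataclass
class GeneModel:
    """A locus: isoforms connected by same-strand exonic overlap."""

    gene_id: str
    isoforms: list[IsoformRecord]
    locus: GenomicInterval

    def __post_init__(self) -> None:
        if not self.isoforms:
            raise ValueError("GeneModel requires >=1 isoform")

    @property
    def strand(self) -> str:
        return self.locus.strand


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def group_into_genes(
    isoforms: Sequence[IsoformRecord], prefix: str = "GENE"
) -> list[GeneModel]:
    """Partition isoforms into genes by transitive same-strand exonic overlap.

    Two isoforms belong to the same gene iff they are connected through the
    relation "same chrom, same strand, and >=1 bp exonic overlap".  Intronic
    containment without exon overlap does not connect.
    """
    uf = _UnionFind(len(isoforms))
    # sweep exons per (chrom, strand); overlapping exon runs connect isoforms
    exon_events: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for idx, iso in enumerate(isoforms):
        key = (iso.exons.chrom, iso.exons.strand)
        for e in iso.exons.exons:
            exon_events.setdefault(key, []).append((e.start, e.end, idx))
    for events in exon_events.values():
        events.sort()
        cur_end = -1
        rep = -1
        for start, end, idx in events:
            if start < cur_end:
                uf.union(rep, idx)
                cur_end = max(cur_end, end)
            else:
                rep, cur_end = idx, end
    groups: dict[int, list[IsoformRecord]] = {}
    order: list[int] = []
    for idx, iso in enumerate(isoforms):
        root = uf.find(idx)
        if root not in groups:
            groups[root] = []
            order.append(root)
        groups[root].append(iso)
    genes = []
    members = sorted(
        (min(i.exons.start for i in isos), root)
        for root, isos in groups.items()
    )
    for n, (_, root) in enumerate(members, start=1):
        isos = groups[root]
        chrom = isos[0].exons.chrom
        strand = isos[0].exons.strand
        locus = GenomicInterval(
            chrom,
            min(i.exons.start for i in isos),
            max(i.exons.end for i in isos),
            strand,
        )
        gid = f"{prefix}{n:05d}"
        for iso in isos:
            iso.gene_id = gid
        genes.append(GeneModel(gid, sorted(isos, key=lambda i: i.exons.start), locus))
    return genes


# ---- sequence helpers --------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def spliced_sequence(chain: ExonChain, genome: Mapping[str, str]) -> str:
    """mRNA-sense spliced sequence of a chain from a chrom->sequence mapping."""
    seq = "".join(str(genome[chain.chrom][e.start : e.end]) for e in chain.exons)
    return revcomp(seq) if chain.strand == "-" else seq
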