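"""Sequence-level features of final isoforms.

Covers longest-ORF CDS assignment, microexon detection (internal exons
<= 51 nt), distal/proximal/coding site classification relative to the
representative CDS, intronic-TSS/TES coupling events (Is: skipped terminal
exon; Ic: composite terminal exon), and the 5'/3'UTR motif scanners
(RNA G-quadruplex, U-rich elements, upstream ORFs).
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .core import ExonChain, GeneModel, IsoformRecord, spliced_sequence
from .clustering import SiteCluster

STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfCall:
    """An open reading frame in spliced coordinates (stop codon included)."""

    start: int
    end: int
    frame: int
    aa_length: int


def find_longest_orf(seq: str) -> Optional[OrfCall]:
    """Longest ATG-to-stop ORF across the three forward frames of the
    mRNA-sense sequence; ties resolved 5'-most."""
    seq = seq.upper().replace("U", "T")
    best: Optional[OrfCall] = None
    for frame in range(3):
        start: Optional[int] = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon == "ATG" and start is None:
                start = i
            elif codon in STOPS and start is not None:
                call = OrfCall(start, i + 3, frame, (i - start) // 3)
                if best is None or call.end - call.start > best.end - best.start or (
                    call.end - call.start == best.end - best.start
                    and call.start < best.start
                ):
                    best = call
                start = None
    return best


def assign_cds(
    isoforms: Sequence[IsoformRecord], genome: Mapping[str, str]
) -> None:
    """Set each isoform's CDS to its longest ORF (in place; None if no ORF)."""
    for iso in isoforms:
        orf = find_longest_orf(spliced_sequence(iso.exons, genome))
        iso.cds = (orf.start, orf.end) if orf else None


def detect_microexons(
    isoforms: Sequence[IsoformRecord], max_len: int = 51
) -> list[tuple[IsoformRecord, "object"]]:
    """Internal exons (neither first nor last) of length <= max_len."""
    hits = []
    for iso in isoforms:
        for exon in iso.exons.exons[1:-1]:
            if exon.length <= max_len:
                hits.append((iso, exon))
    return hits


# ---- DT / PT / CT site classification ---------------------------------


@dataclass(frozen=True)
class SiteRoleLabel:
    cluster: SiteCluster
    role: str  # DT | PT | CT


def _representative_cds_span(gene: GeneModel) -> tuple[int, int, ExonChain]:
    """Genomic span of the representative CDS: the longest ORF of the
    longest isoform (by spliced length)."""
    rep = max(gene.isoforms, key=lambda i: i.exons.spliced_length)
    if rep.cds is None:
        raise ValueError(f"gene {gene.gene_id}: no CDS on representative isoform")
    lo, hi = rep.cds
    g1 = rep.exons.spliced_to_genomic(lo)
    g2 = rep.exons.spliced_to_genomic(hi - 1)
    return min(g1, g2), max(g1, g2) + 1, rep.exons


def classify_sites(
    gene: GeneModel, clusters: Sequence[SiteCluster], kind: str
) -> list[SiteRoleLabel]:
    """Label each TSS (TES) cluster of a gene as coding (CT: summit within
    the CDS span), distal (DT: the site farthest 5' of the start codon —
    or 3' of the stop for TES), or proximal (PT: the rest)."""
    cds_lo, cds_hi, chain = _representative_cds_span(gene)
    strand = gene.strand
    # anchor = start codon for TSS, stop codon for TES (genomic position)
    if kind == "TSS":
        anchor = cds_lo if strand == "+" else cds_hi - 1
    else:
        anchor = cds_hi - 1 if strand == "+" else cds_lo
    labels: list[tuple[SiteCluster, str, int]] = []
    for c in clusters:
        s = c.summit
        if cds_lo <= s < cds_hi:
            labels.append((c, "CT", 0))
            continue
        # outside-CDS sites: upstream of start (TSS) / downstream of stop (TES)
        if kind == "TSS":
            outside = s < anchor if strand == "+" else s > anchor
        else:
            outside = s > anchor if strand == "+" else s < anchor
        if outside:
            labels.append((c, "PT", abs(s - anchor)))
        else:
            labels.append((c, "CT", 0))  # inside-gene, CDS-ward of the anchor
    non_ct = [t for t in labels if t[1] == "PT"]
    if non_ct:
        far = max(non_ct, key=lambda t: t[2])
        labels = [
            (c, "DT" if (c is far[0]) else role, d) for c, role, d in labels
        ]
    return [SiteRoleLabel(c, role) for c, role, _ in labels]


# ---- Is / Ic coupling events ------------------------------------------


@dataclass(frozen=True)
class CouplingEvent:
    end: str  # "5p" | "3p"
    type: str  # "Is" | "Ic"
    isoform: str  # isoform whose terminal site is intronic
    other: str  # isoform providing the intron


def detect_coupling_events(gene: GeneModel) -> list[CouplingEvent]:
    """Find isoform pairs where one isoform's TSS (TES) falls inside an
    intron of another: Is when its terminal exon stays within the intron and
    splices out via its own junction; Ic when the terminal exon runs
    continuously across the intron boundary into the other's exon."""
    events = []
    strand = gene.strand
    for a in gene.isoforms:
        exons = a.exons.exons
        term5 = exons[0] if strand == "+" else exons[-1]
        term3 = exons[-1] if strand == "+" else exons[0]
        tss = term5.start if strand == "+" else term5.end - 1
        tes = term3.end - 1 if strand == "+" else term3.start
        for b in gene.isoforms:
            if b is a:
                continue
            for intron in b.exons.introns():
                if intron.contains(tss):
                    ev = _classify_terminal(term5, intron, len(a.exons.exons))
                    if ev:
                        events.append(CouplingEvent("5p", ev, a.id, b.id))
                if intron.contains(tes):
                    ev = _classify_terminal(term3, intron, len(a.exons.exons))
                    if ev:
                        events.append(CouplingEvent("3p", ev, a.id, b.id))
    return events


def _classify_terminal(term, intron, n_exons: int) -> Optional[str]:
    inside = intron.start <= term.start and term.end <= intron.end
    if inside:
        return "Is" if n_exons > 1 else None
    # composite: exon starts (or ends) inside the intron and crosses a boundary
    crosses = (intron.contains(term.start) and term.end > intron.end) or (
        intron.contains(term.end - 1) and term.start < intron.start
    )
    return "Ic" if crosses else None


# ---- motif scanners ----------------------------------------------------


@dataclass(frozen=True)
class MotifHit:
    kind: str  # RG4 | U_rich | uORF
    start: int
    end: int
    detail: str = ""


def scan_rg4(seq: str, min_tract: int = 4, min_loop: int = 2) -> list[MotifHit]:
    """RNA G-quadruplex motifs: four G-tracts of equal length >= min_tract
    (>= min_tract stacked tetrads) separated by loops >= min_loop nt.
    Overlapping candidates resolve to the highest-scoring (longest tracts,
    then 5'-most, then shortest)."""
    s = seq.upper().replace("U", "T")
    max_tract = 0
    for m in re.finditer(r"G+", s):
        max_tract = max(max_tract, m.end() - m.start())
    candidates: list[tuple[int, int, int]] = []  # (tract_len, start, end)
    for t in range(min_tract, max_tract + 1):
        pat = re.compile(
            "(?=(G{%d}(?:[ACGT]{%d,}?G{%d}){3}))" % (t, min_loop, t)
        )
        for m in pat.finditer(s):
            candidates.append((t, m.start(1), m.start(1) + len(m.group(1))))
    # resolution: longest tracts first, then leftmost, then shortest span
    candidates.sort(key=lambda c: (-c[0], c[1], c[2] - c[1]))
    kept: list[tuple[int, int, int]] = []
    for t, a, b in candidates:
        if any(a < kb and ka < b for _, ka, kb in kept):
            continue
        kept.append((t, a, b))
    kept.sort(key=lambda c: c[1])
    return [MotifHit("RG4", a, b, f"tract={t}") for t, a, b in kept]


def scan_urich(
    seq: str, window: int = 10, min_frac: float = 0.8, min_len: int = 6
) -> list[MotifHit]:
    """U-rich elements: merged windows (length ``window``, clipped to the
    sequence) whose U fraction is >= min_frac, trimmed to U boundaries, kept
    when the trimmed run is >= min_len nt."""
    s = seq.upper().replace("T", "U")
    n = len(s)
    if n == 0:
        return []
    w = min(window, n)
    is_u = [c == "U" for c in s]
    prefix = [0]
    for u in is_u:
        prefix.append(prefix[-1] + u)
    qualifying = []
    for i in range(n - w + 1):
        if (prefix[i + w] - prefix[i]) / w >= min_frac:
            qualifying.append((i, i + w))
    hits = []
    run: Optional[list[int]] = None
    for a, b in qualifying:
        if run and a <= run[1]:
            run[1] = b
        else:
            if run:
                hits.append(tuple(run))
            run = [a, b]
    if run:
        hits.append(tuple(run))
    out = []
    for a, b in hits:
        while a < b and not is_u[a]:
            a += 1
        while b > a and not is_u[b - 1]:
            b -= 1
        if b - a >= min_len:
            out.append(MotifHit("U_rich", a, b, f"len={b - a}"))
    return out


def find_uorfs(five_utr_seq: str, min_aa: int = 2) -> list[MotifHit]:
    """All ATG-initiated ORFs fully contained in the 5'UTR, with a stop codon
    and >= min_aa codons (ATG included) before the stop."""
    s = five_utr_seq.upper().replace("U", "T")
    out = []
    for i in range(len(s) - 2):
        if s[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, len(s) - 2, 3):
            if s[j : j + 3] in STOPS:
                if (j - i) // 3 >= min_aa:
                    out.append(
                        MotifHit("uORF", i, j + 3, f"aa={(j - i) // 3}")
                    )
                break
    return out


def utr_motif_changes(
    utr_a: str, utr_b: str, scanner, **kwargs
) -> tuple[list[MotifHit], list[MotifHit]]:
    """Motifs gained/lost between two alternative UTR sequences, as the set
    difference of hits keyed by motif sequence content."""
    hits_a = scanner(utr_a, **kwargs)
    hits_b = scanner(utr_b, **kwargs)
    seqs_a = {utr_a[h.start : h.end] for h in hits_a}
    seqs_b = {utr_b[h.start : h.end] for h in hits_b}
    gained = [h for h in hits_b if utr_b[h.start : h.end] not in seqs_a]
    lost = [h for h in hits_a if utr_a[h.start : h.end] not in seqs_b]
    return gained, lost
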