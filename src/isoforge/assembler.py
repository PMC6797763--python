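"""Long-read isoform assembly against TSS/TES clusters and splice junctions.

The assembler works per *linkage group* (a maximal genomic region with
contiguous RNA signal).  Within a group, credible splice junctions and
TSS/TES cluster summits divide the region into indivisible segments; every
long read is projected onto the segments as a binary presence vector (1
exonic, 0 absent).  Paths are then validated against the evidence:

* isoF  — starts in a TSS segment, ends in a TES segment, every junction
          supported: a full-length isoform.
* isoC  — all junctions supported but a terminal missing; completed using
          the unique isoF that matches on the covered range.
* isoM  — two complementary uncompleted candidates (one with a TSS, one
          with a TES) merged when their overlap agrees.
* isoR  — a path with unsupported junctions corrected using the unique
          local isoF sub-path between supported anchors.
* isoP  — unsupported junctions removed and the gap refilled with the
          segment chain consistent with credible junctions (max short-read
          coverage on ties).

Junction support is evaluated on the read's own intron coordinates (exact
match against the credible set); the emitted models use segment-implied
coordinates, so boundary jitter and spurious-intron ("bubble") read errors
are detected and repaired rather than propagated.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .core import ExonChain, GenomicInterval, GeneModel, IsoformRecord, group_into_genes
from .clustering import SiteCluster

JunctionKey = tuple[str, int, int, str]  # chrom, donor, acceptor, strand


@dataclass
class SpliceJunction:
    """An intron: donor = intron start (0-based), acceptor = intron end
    (exclusive), with per-sample short-read support."""

    chrom: str
    donor: int
    acceptor: int
    strand: str
    per_sample_count: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.donor >= self.acceptor:
            raise ValueError(
                f"junction donor {self.donor} must precede acceptor {self.acceptor}"
            )

    @property
    def key(self) -> JunctionKey:
        return (self.chrom, self.donor, self.acceptor, self.strand)

    @property
    def total(self) -> int:
        return sum(self.per_sample_count.values())


@dataclass
class LinkageGroup:
    interval: GenomicInterval


@dataclass
class Segment:
    """An indivisible segment of a linkage group."""

    interval: GenomicInterval
    labels: frozenset[str] = frozenset()
    index: int = -1

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class IsoformPath:
    """A long read (or repaired read) as a binary segment-presence vector."""

    bits: tuple[int, ...]
    introns: tuple[tuple[int, int], ...]  # the read's own intron coordinates
    junction_support: tuple[bool, ...]  # per read intron, vs credible set
    implied: tuple[tuple[int, int], ...]  # segment-implied junctions (0-runs)
    starts_at_tss: bool
    ends_at_tes: bool
    read_ids: tuple[str, ...] = ()

    @property
    def consistent(self) -> bool:
        """Read introns coincide with the segment-implied junctions."""
        return self.introns == self.implied

    @property
    def fully_supported(self) -> bool:
        return self.consistent and all(self.junction_support)

    @property
    def covered(self) -> tuple[int, int]:
        ones = [i for i, b in enumerate(self.bits) if b]
        return ones[0], ones[-1]


# ---- linkage groups ----------------------------------------------------


def find_linkage_groups(
    coverage: Iterable[GenomicInterval],
    reads: Sequence[tuple[str, ExonChain]] = (),
    window: int = 100,
) -> list[LinkageGroup]:
    """Scan the genome in fixed windows; consecutive windows with any signal
    merge into maximal groups, and a long read spanning two groups forces
    those groups to merge."""
    active: dict[tuple[str, str], set[int]] = {}
    for iv in itertools.chain(
        coverage, (e for _, chain in reads for e in chain.exons)
    ):
        ws = active.setdefault((iv.chrom, iv.strand), set())
        ws.update(range(iv.start // window, (iv.end - 1) // window + 1))
    groups: list[list[int]] = []  # [chrom_strand_idx not needed]
    out: list[LinkageGroup] = []
    for (chrom, strand), ws in sorted(active.items()):
        runs: list[list[int]] = []
        for w in sorted(ws):
            if runs and w == runs[-1][1] + 1:
                runs[-1][1] = w
            else:
                runs.append([w, w])
        # bridge runs spanned by a single read
        merged = True
        while merged:
            merged = False
            for _, chain in reads:
                if (chain.chrom, chain.strand) != (chrom, strand):
                    continue
                lo_w = chain.start // window
                hi_w = (chain.end - 1) // window
                touched = [
                    i for i, (a, b) in enumerate(runs) if a <= hi_w and lo_w <= b
                ]
                if len(touched) > 1:
                    a = runs[touched[0]][0]
                    b = runs[touched[-1]][1]
                    runs = (
                        runs[: touched[0]] + [[a, b]] + runs[touched[-1] + 1 :]
                    )
                    merged = True
                    break
        for a, b in runs:
            out.append(
                LinkageGroup(
                    GenomicInterval(chrom, a * window, (b + 1) * window, strand)
                )
            )
    return out


def call_credible_junctions(
    junctions: Iterable[SpliceJunction],
    min_reads: int = 3,
    min_samples: int = 1,
) -> list[SpliceJunction]:
    """Junctions with >= min_reads short reads in >= min_samples samples."""
    return [
        j
        for j in junctions
        if sum(1 for v in j.per_sample_count.values() if v >= min_reads)
        >= min_samples
    ]


# ---- segmentation ------------------------------------------------------


def _summit_boundary(kind: str, strand: str, summit: int) -> int:
    # A transcript-start boundary falls on the summit itself; a
    # transcript-end boundary just after it, so that the summit base is the
    # last base of the terminal segment.
    if (kind == "TSS") == (strand == "+"):
        return summit
    return summit + 1


def segment_locus(
    group: LinkageGroup,
    tss: Sequence[SiteCluster],
    tes: Sequence[SiteCluster],
    junctions: Iterable[SpliceJunction],
) -> list[Segment]:
    """Divide a linkage group into indivisible segments at junction edges and
    TSS/TES summits; segments containing a summit are labelled."""
    iv = group.interval
    bounds = {iv.start, iv.end}
    for j in junctions:
        for b in (j.donor, j.acceptor):
            if not (iv.start <= b <= iv.end):
                raise ValueError(f"junction boundary {b} outside group {iv}")
            if iv.start < b < iv.end:
                bounds.add(b)
    summits: list[tuple[int, str]] = []
    for kind, clusters in (("TSS", tss), ("TES", tes)):
        for c in clusters:
            s = c.summit
            b = _summit_boundary(kind, iv.strand, s)
            if not (iv.start <= s < iv.end):
                raise ValueError(f"{kind} summit {s} outside group {iv}")
            if iv.start < b < iv.end:
                bounds.add(b)
            summits.append((s, kind))
    edges = sorted(bounds)
    segs = []
    for i, (a, b) in enumerate(zip(edges, edges[1:])):
        labels = {
            f"{kind}_SEG" for s, kind in summits if a <= s < b
        }
        segs.append(
            Segment(GenomicInterval(iv.chrom, a, b, iv.strand), frozenset(labels), i)
        )
    return segs


# ---- read projection ---------------------------------------------------


def _implied_junctions(
    bits: Sequence[int], segments: Sequence[Segment]
) -> tuple[tuple[int, int], ...]:
    out = []
    ones = [i for i, b in enumerate(bits) if b]
    for a, b in zip(ones, ones[1:]):
        if b > a + 1 or segments[b].interval.start > segments[a].interval.end:
            out.append((segments[a].interval.end, segments[b].interval.start))
    return tuple(out)


def _terminal_labels(
    bits: Sequence[int], segments: Sequence[Segment], strand: str
) -> tuple[bool, bool]:
    ones = [i for i, b in enumerate(bits) if b]
    left, right = ones[0], ones[-1]
    tss_seg = left if strand == "+" else right
    tes_seg = right if strand == "+" else left
    return (
        "TSS_SEG" in segments[tss_seg].labels,
        "TES_SEG" in segments[tes_seg].labels,
    )


def path_from_bits(
    bits: Sequence[int],
    segments: Sequence[Segment],
    credible: frozenset[JunctionKey],
    read_ids: tuple[str, ...] = (),
) -> IsoformPath:
    """Build a consistent path (introns = implied junctions) from a bit vector."""
    bits = tuple(int(b) for b in bits)
    if not any(bits):
        raise ValueError("empty path")
    strand = segments[0].interval.strand
    chrom = segments[0].interval.chrom
    implied = _implied_junctions(bits, segments)
    support = tuple((chrom, d, a, strand) in credible for d, a in implied)
    tssb, tesb = _terminal_labels(bits, segments, strand)
    return IsoformPath(bits, implied, support, implied, tssb, tesb, tuple(read_ids))


def project_read(
    read: ExonChain,
    segments: Sequence[Segment],
    credible: frozenset[JunctionKey],
    read_id: str = "",
) -> IsoformPath:
    """Project a long read into segment space: bit i is set iff the read's
    exonic overlap with segment i is at least half the segment length."""
    bits = []
    for seg in segments:
        ov = sum(e.overlap_len(seg.interval) for e in read.exons)
        bits.append(1 if 2 * ov >= seg.length else 0)
    if not any(bits):
        raise ValueError(f"read {read_id!r} overlaps no segment")
    bits = tuple(bits)
    implied = _implied_junctions(bits, segments)
    introns = tuple((i.start, i.end) for i in read.introns())
    support = tuple(
        (read.chrom, d, a, read.strand) in credible for d, a in introns
    )
    tssb, tesb = _terminal_labels(bits, segments, read.strand)
    return IsoformPath(
        bits, introns, support, implied, tssb, tesb, (read_id,) if read_id else ()
    )


# ---- classification and repair ----------------------------------------


@dataclass
class ClassifiedPaths:
    isoF: list[IsoformPath]
    candidates: list[IsoformPath]  # fully supported but a terminal missing
    conflicted: list[IsoformPath]


def classify_paths(paths: Iterable[IsoformPath]) -> ClassifiedPaths:
    isoF, cands, confl = [], [], []
    for p in paths:
        if not p.fully_supported:
            confl.append(p)
        elif p.starts_at_tss and p.ends_at_tes:
            isoF.append(p)
        else:
            cands.append(p)
    return ClassifiedPaths(isoF, cands, confl)


def _unique_extension(
    cand_bits: tuple[int, ...],
    isoF_paths: Sequence[IsoformPath],
    side: str,
) -> Optional[tuple[int, ...]]:
    ones = [i for i, b in enumerate(cand_bits) if b]
    f, l = ones[0], ones[-1]
    exts = set()
    for F in isoF_paths:
        fF, lF = F.covered
        if F.bits[f : l + 1] != cand_bits[f : l + 1]:
            continue
        if side == "left" and fF < f:
            exts.add(F.bits[:f])
        elif side == "right" and lF > l:
            exts.add(F.bits[l + 1 :])
    if len(exts) != 1:
        return None
    ext = exts.pop()
    if side == "left":
        return ext + cand_bits[f:]
    return cand_bits[: l + 1] + ext


def complete_partial(
    candidate: IsoformPath,
    isoF_paths: Sequence[IsoformPath],
    segments: Sequence[Segment],
    credible: frozenset[JunctionKey],
) -> Optional[IsoformPath]:
    """Complete a fully-supported path missing a terminal using the unique
    isoF that matches it on its covered range; ambiguity yields None."""
    strand = segments[0].interval.strand
    bits = candidate.bits
    # genomic side that is missing depends on strand
    need_left = (not candidate.starts_at_tss) if strand == "+" else (
        not candidate.ends_at_tes
    )
    need_right = (not candidate.ends_at_tes) if strand == "+" else (
        not candidate.starts_at_tss
    )
    if need_left:
        bits2 = _unique_extension(bits, isoF_paths, "left")
        if bits2 is None:
            return None
        bits = bits2
    if need_right:
        bits2 = _unique_extension(bits, isoF_paths, "right")
        if bits2 is None:
            return None
        bits = bits2
    path = path_from_bits(bits, segments, credible, candidate.read_ids)
    if not (path.starts_at_tss and path.ends_at_tes and path.fully_supported):
        return None
    return path


def merge_complementary(
    candidates: Sequence[IsoformPath],
    segments: Sequence[Segment],
    credible: frozenset[JunctionKey],
) -> list[IsoformPath]:
    """Merge complementary uncompleted candidates: one carrying the TSS, the
    other the TES, overlapping with identical bits on the overlap."""
    strand = segments[0].interval.strand
    lefts, rights = [], []
    for p in candidates:
        has_left = p.starts_at_tss if strand == "+" else p.ends_at_tes
        has_right = p.ends_at_tes if strand == "+" else p.starts_at_tss
        if has_left and not has_right:
            lefts.append(p)
        elif has_right and not has_left:
            rights.append(p)
    out: dict[tuple[int, ...], IsoformPath] = {}
    for A in lefts:
        fA, lA = A.covered
        for B in rights:
            fB, lB = B.covered
            if not (fA <= fB and lA <= lB and fB <= lA):
                continue
            lo, hi = max(fA, fB), min(lA, lB)
            if A.bits[lo : hi + 1] != B.bits[lo : hi + 1]:
                continue
            bits = tuple(
                A.bits[i] if i <= lA else B.bits[i] for i in range(len(A.bits))
            )
            path = path_from_bits(
                bits, segments, credible, tuple(A.read_ids) + tuple(B.read_ids)
            )
            if path.starts_at_tss and path.ends_at_tes and path.fully_supported:
                out.setdefault(bits, path)
    return list(out.values())


def _bad_intron_window(
    path: IsoformPath, segments: Sequence[Segment], intron: tuple[int, int]
) -> Optional[tuple[int, int]]:
    """Anchor segments flanking a bad intron: the last covered segment of the
    1-run before the implied gap it overlaps, and the first after.  A bubble
    intron inside a single covered segment anchors on that segment twice."""
    d, a = intron
    ones = [i for i, b in enumerate(path.bits) if b]
    runs: list[tuple[int, int]] = []
    for i in ones:
        if runs and i == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], i)
        else:
            runs.append((i, i))
    for (r1s, r1e), (r2s, r2e) in zip(runs, runs[1:]):
        gap_lo = segments[r1e].interval.end
        gap_hi = segments[r2s].interval.start
        if d < gap_hi and gap_lo < a:
            return (r1e, r2s)
    for i in ones:
        seg = segments[i].interval
        if seg.start <= d and a <= seg.end:
            return (i, i)
    return None


def rescue_conflict(
    path: IsoformPath,
    isoF_paths: Sequence[IsoformPath],
    segments: Sequence[Segment],
    credible: frozenset[JunctionKey],
) -> Optional[IsoformPath]:
    """Replace each unsupported junction's local sub-path with the unique isoF
    sub-path spanning the same flanking anchors.  Success requires every bad
    junction uniquely correctable and the corrected path full-length."""
    if not isoF_paths:
        return None
    bits = list(path.bits)
    bad = [iv for iv, ok in zip(path.introns, path.junction_support) if not ok]
    # introns that disagree with segment-implied coordinates are also suspect
    if not bad and not path.consistent:
        bad = [iv for iv in path.introns if iv not in path.implied]
    for intron in bad:
        window = _bad_intron_window(path, segments, intron)
        if window is None:
            return None
        aL, aR = window
        locals_ = {
            F.bits[aL : aR + 1]
            for F in isoF_paths
            if F.bits[aL] == 1 and F.bits[aR] == 1
        }
        if len(locals_) != 1:
            return None
        local = locals_.pop()
        bits[aL : aR + 1] = list(local)
    fixed = path_from_bits(bits, segments, credible, path.read_ids)
    if fixed.fully_supported and fixed.starts_at_tss and fixed.ends_at_tes:
        return fixed
    return None


def fill_partial(
    path: IsoformPath,
    segments: Sequence[Segment],
    credible: frozenset[JunctionKey],
    segment_coverage: Optional[Sequence[float]] = None,
    max_paths: int = 64,
) -> Optional[IsoformPath]:
    """Remove unsupported junctions and refill each gap with the segment
    chain consistent with credible junctions; on multiple consistent
    fillings, take the one maximising short-read exonic coverage."""
    chrom = segments[0].interval.chrom
    strand = segments[0].interval.strand
    bits = list(path.bits)
    bad = [iv for iv, ok in zip(path.introns, path.junction_support) if not ok]
    if not bad and not path.consistent:
        bad = [iv for iv in path.introns if iv not in path.implied]
    for intron in bad:
        window = _bad_intron_window(path, segments, intron)
        if window is None:
            return None
        aL, aR = window
        if aL == aR:
            continue  # bubble: dropping the intron restores the segment
        if aR - aL - 1 > 20:
            return None
        fillings = []

        def _dfs(last: int, chosen: list[int]):
            if len(fillings) >= max_paths:
                return
            if last == aR:
                fillings.append(tuple(chosen))
                return
            for nxt in range(last + 1, aR + 1):
                if nxt == last + 1 or (
                    chrom,
                    segments[last].interval.end,
                    segments[nxt].interval.start,
                    strand,
                ) in credible:
                    _dfs(nxt, chosen + [nxt])

        _dfs(aL, [aL])
        if not fillings or len(fillings) >= max_paths:
            return None
        if len(fillings) > 1:
            cov = segment_coverage or [seg.length for seg in segments]
            fillings.sort(
                key=lambda f: (-sum(cov[i] for i in f), len(f), f)
            )
        fill = set(fillings[0])
        for i in range(aL, aR + 1):
            bits[i] = 1 if i in fill else 0
    fixed = path_from_bits(bits, segments, credible, path.read_ids)
    if fixed.fully_supported:
        return fixed
    return None


# ---- path -> genomic model --------------------------------------------


def _cluster_for_segment(
    seg: Segment, clusters: Sequence[SiteCluster]
) -> Optional[SiteCluster]:
    hits = [c for c in clusters if seg.interval.contains(c.summit)]
    if not hits:
        return None
    return max(hits, key=lambda c: c.total)


def path_to_record(
    path: IsoformPath,
    cls: str,
    segments: Sequence[Segment],
    tss: Sequence[SiteCluster],
    tes: Sequence[SiteCluster],
    iso_id: str,
) -> IsoformRecord:
    """Convert a segment path to a genomic exon chain, anchoring labelled
    terminals on the TSS/TES cluster summits."""
    strand = segments[0].interval.strand
    chrom = segments[0].interval.chrom
    ones = [i for i, b in enumerate(path.bits) if b]
    blocks: list[list[int]] = []
    for i in ones:
        seg = segments[i].interval
        if blocks and seg.start == blocks[-1][1]:
            blocks[-1][1] = seg.end
        else:
            blocks.append([seg.start, seg.end])
    left_seg = segments[ones[0]]
    right_seg = segments[ones[-1]]
    tss_cluster = tes_cluster = None
    if path.starts_at_tss:
        seg = left_seg if strand == "+" else right_seg
        tss_cluster = _cluster_for_segment(seg, tss)
        if tss_cluster is not None:
            s = tss_cluster.summit
            if strand == "+":
                blocks[0][0] = max(blocks[0][0], min(s, blocks[0][1] - 1))
            else:
                blocks[-1][1] = min(blocks[-1][1], max(s + 1, blocks[-1][0] + 1))
    if path.ends_at_tes:
        seg = right_seg if strand == "+" else left_seg
        tes_cluster = _cluster_for_segment(seg, tes)
        if tes_cluster is not None:
            s = tes_cluster.summit
            if strand == "+":
                blocks[-1][1] = min(blocks[-1][1], max(s + 1, blocks[-1][0] + 1))
            else:
                blocks[0][0] = max(blocks[0][0], min(s, blocks[0][1] - 1))
    chain = ExonChain.from_blocks(chrom, strand, [(a, b) for a, b in blocks])
    return IsoformRecord(
        iso_id,
        chain,
        cls=cls,
        tss_cluster=tss_cluster,
        tes_cluster=tes_cluster,
        attrs={"read_ids": ",".join(path.read_ids)} if path.read_ids else {},
    )


# ---- per-locus orchestration ------------------------------------------

from .core import CLASS_PRIORITY  # noqa: E402  (kept close to its use)


def assemble_locus(
    group: LinkageGroup,
    tss: Sequence[SiteCluster],
    tes: Sequence[SiteCluster],
    junctions: Sequence[SpliceJunction],
    reads: Sequence[tuple[str, ExonChain]],
    segment_coverage: Optional[Sequence[float]] = None,
    id_prefix: str = "ISO",
) -> tuple[list[GeneModel], dict[str, int]]:
    """Assemble one linkage group end to end.

    Returns the gene models of the locus plus a per-class count report.
    Duplicate isoforms (identical exon chain) collapse to the best class
    (isoF > isoR > isoC > isoM > isoP).
    """
    credible = frozenset(j.key for j in junctions)
    segments = segment_locus(group, tss, tes, junctions)
    paths: dict[tuple, IsoformPath] = {}
    for rid, chain in reads:
        try:
            p = project_read(chain, segments, credible, rid)
        except ValueError:
            continue
        key = (p.bits, p.introns)
        if key in paths:
            old = paths[key]
            paths[key] = IsoformPath(
                old.bits,
                old.introns,
                old.junction_support,
                old.implied,
                old.starts_at_tss,
                old.ends_at_tes,
                old.read_ids + p.read_ids,
            )
        else:
            paths[key] = p
    cls_paths = classify_paths(paths.values())
    # deduplicate isoF by bits
    isoF: dict[tuple[int, ...], IsoformPath] = {}
    for p in cls_paths.isoF:
        isoF.setdefault(p.bits, p)
    isoF_list = list(isoF.values())
    results: list[tuple[IsoformPath, str]] = [(p, "isoF") for p in isoF_list]
    uncompleted = []
    seen_cand: set[tuple[int, ...]] = set()
    for p in cls_paths.candidates:
        if p.bits in seen_cand:
            continue
        seen_cand.add(p.bits)
        done = complete_partial(p, isoF_list, segments, credible)
        if done is not None:
            results.append((done, "isoC"))
        else:
            uncompleted.append(p)
    for m in merge_complementary(uncompleted, segments, credible):
        results.append((m, "isoM"))
    for p in cls_paths.conflicted:
        fixed = rescue_conflict(p, isoF_list, segments, credible)
        if fixed is not None:
            results.append((fixed, "isoR"))
            continue
        filled = fill_partial(p, segments, credible, segment_coverage)
        if filled is not None:
            results.append((filled, "isoP"))
    # dedupe by exon chain, keep best class
    records: dict[tuple, IsoformRecord] = {}
    counts = {c: 0 for c in ("isoF", "isoC", "isoM", "isoR", "isoP")}
    n = 0
    for path, cls in results:
        n += 1
        rec = path_to_record(
            path, cls, segments, tss, tes, f"{id_prefix}.{n:04d}"
        )
        key = tuple(rec.exons.blocks())
        old = records.get(key)
        if old is None or CLASS_PRIORITY[cls] < CLASS_PRIORITY[old.cls]:
            records[key] = rec
    for rec in records.values():
        counts[rec.cls] += 1
    genes = group_into_genes(list(records.values()), prefix=f"{id_prefix}.G")
    return genes, counts
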