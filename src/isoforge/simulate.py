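"""Ground-truth simulator for end-to-end testing of the whole pipeline.

The simulator writes a small genome with a known gene set and emits every
input the assembler and the dynamics analyses consume: long-read exon
chains (BED12), per-tissue 5'/3' tag signals (bedGraph), a splice-junction
support table, a gene x tissue expression matrix, and NGS transfrags.

Planted features (recorded in the truth object for recall scoring):

* TSS-switch genes — two TSS 500 nt apart whose usage (0.9/0.1) flips
  between the two tissue groups;
* APA genes — two TES whose usage flip shifts the weighted 3'UTR length by
  200 nt (callable) or 80 nt (sub-threshold);
* AS-hotspot genes — eight isoforms enumerating all presence combinations
  of three adjacent internal exons;
* polycistrons — one transcript carrying two major ORFs, with two member
  pseudo-genes sharing a latent expression factor;
* microexon genes — one internal exon <= 51 nt;
* single-tissue and uniform expression genes for the specificity score.

Long-read error processes mimic the dominant long-read artefact classes at
controllable rates: boundary jitter (one junction edge shifted 1-10 nt),
bubbles (a spurious 20-60 nt intron inside an exon), and 5' truncation
(a prefix removed, ending inside an exon).

mRNA sequence content is designed so that the planted CDS is provably the
longest ORF: UTRs and linkers are drawn from an A-free alphabet, CDS bodies
from G/C-only codons, so ATG occurs exactly at planted start codons.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import ExonChain, GenomicInterval, IsoformRecord, revcomp
from .assembler import SpliceJunction
from .hotspot import IsoformStringSet
from .io import TagSignal


@dataclass
class SimParams:
    """Study conditions for the synthetic cohort."""

    n_genes: int = 50
    n_tissues: int = 16
    max_isoforms: int = 10
    exon_count_range: tuple[int, int] = (3, 7)
    exon_len_range: tuple[int, int] = (100, 300)
    intron_len_range: tuple[int, int] = (80, 400)
    spacer: int = 2000
    terminal_pad: int = 700  # room for alternative-terminal extensions
    alt_tss_offset: int = 500
    apa_delta: int = 500  # TES shift of the callable APA gene
    apa_usage_major: float = 0.7  # => weighted-3'UTR shift 500*0.4 = 200 nt
    apa_small_delta: int = 450
    apa_small_usage_major: float = 0.58888888888889  # => shift 80 nt
    switch_usage_major: float = 0.9
    n_switch_genes: int = 2
    n_apa_genes: int = 1
    n_apa_small_genes: int = 1
    n_hotspot_genes: int = 2
    n_polycistron_genes: int = 2
    n_microexon_genes: int = 5
    n_specific_genes: int = 2
    n_uniform_genes: int = 2
    chrom: str = "chr1"


@dataclass
class ErrorRates:
    boundary_jitter_rate: float = 0.0
    bubble_rate: float = 0.0
    truncation_5p_rate: float = 0.0


@dataclass
class TruthIsoform:
    id: str
    gene_id: str
    chain: ExonChain
    share: np.ndarray  # per-tissue abundance fraction within the gene
    tss_site: int
    tes_site: int
    cds: Optional[tuple[int, int]] = None


@dataclass
class TruthGene:
    gene_id: str
    strand: str
    isoforms: list[TruthIsoform]
    tss_sites: list[int]
    tss_usage: np.ndarray  # sites x tissues
    tes_sites: list[int]
    tes_usage: np.ndarray
    expression: np.ndarray  # per-tissue base level
    role: str = "normal"

    def junctions(self) -> list[tuple[int, int]]:
        out = set()
        for iso in self.isoforms:
            for i in iso.chain.introns():
                out.add((i.start, i.end))
        return sorted(out)


@dataclass
class SyntheticTruth:
    params: SimParams
    genome: dict[str, str]
    genes: list[TruthGene]
    tissues: list[str]
    planted: dict[str, list[str]] = field(default_factory=dict)
    member_genes: dict[str, tuple[str, str]] = field(default_factory=dict)

    def to_isoform_records(self) -> list[IsoformRecord]:
        return [
            IsoformRecord(iso.id, iso.chain, cls="isoF", gene_id=g.gene_id, cds=iso.cds)
            for g in self.genes
            for iso in g.isoforms
        ]

    def coverage_intervals(self) -> list[GenomicInterval]:
        """Exonic coverage of the truth set, standing in for short-read signal."""
        return [
            e for g in self.genes for iso in g.isoforms for e in iso.chain.exons
        ]


@dataclass
class SimRead:
    id: str
    chain: ExonChain
    isoform_id: str
    errors: tuple[str, ...] = ()


# ---- sequence building blocks -----------------------------------------

_SAFE_CODONS = np.array(
    ["GGC", "GCC", "CCG", "CGG", "GCG", "CGC", "GGG", "CCC"]
)  # G/C only: no ATG, no stop in any frame


def _rand_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _utr_seq(rng: np.random.Generator, n: int) -> str:
    # A-free: cannot contain an ATG start codon
    return _rand_seq(rng, n, "CGT")


def _cds_seq(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + body + TAA, exactly 3*n_codons nt (n_codons - 1 aa before stop)."""
    body = "".join(rng.choice(_SAFE_CODONS, size=n_codons - 2))
    return "ATG" + body + "TAA"


# ---- truth construction ------------------------------------------------


def _assign_roles(params: SimParams, rng: np.random.Generator) -> list[str]:
    roles = (
        ["switch"] * params.n_switch_genes
        + ["apa"] * params.n_apa_genes
        + ["apa_small"] * params.n_apa_small_genes
        + ["hotspot"] * params.n_hotspot_genes
        + ["polycistron"] * params.n_polycistron_genes
        + ["microexon"] * params.n_microexon_genes
        + ["specific"] * params.n_specific_genes
        + ["uniform"] * params.n_uniform_genes
    )
    if len(roles) > params.n_genes:
        raise ValueError("more planted features than genes")
    roles += ["normal"] * (params.n_genes - len(roles))
    rng.shuffle(roles)
    return roles


def _subset_chain(
    chain: ExonChain, skip: frozenset[int]
) -> ExonChain:
    blocks = [b for i, b in enumerate(chain.blocks()) if i not in skip]
    return ExonChain.from_blocks(chain.chrom, chain.strand, blocks)


def _five_prime_pos(chain: ExonChain) -> int:
    return chain.start if chain.strand == "+" else chain.end - 1


def _three_prime_pos(chain: ExonChain) -> int:
    return chain.end - 1 if chain.strand == "+" else chain.start


def _extend_five(chain: ExonChain, delta: int) -> ExonChain:
    blocks = chain.blocks()
    if chain.strand == "+":
        blocks[0] = (blocks[0][0] - delta, blocks[0][1])
    else:
        blocks[-1] = (blocks[-1][0], blocks[-1][1] + delta)
    return ExonChain.from_blocks(chain.chrom, chain.strand, blocks)


def _extend_three(chain: ExonChain, delta: int) -> ExonChain:
    blocks = chain.blocks()
    if chain.strand == "+":
        blocks[-1] = (blocks[-1][0], blocks[-1][1] + delta)
    else:
        blocks[0] = (blocks[0][0] - delta, blocks[0][1])
    return ExonChain.from_blocks(chain.chrom, chain.strand, blocks)


def _group_usage(
    n_tissues: int, major: float
) -> np.ndarray:
    """Two-site usage matrix flipping between the two tissue halves."""
    u = np.empty((2, n_tissues))
    half = n_tissues // 2
    u[0, :half], u[1, :half] = major, 1 - major
    u[0, half:], u[1, half:] = 1 - major, major
    return u


def simulate_truth(params: SimParams = SimParams(), seed: int = 0) -> SyntheticTruth:
    """Build a reproducible ground-truth gene set and genome sequence."""
    rng = np.random.default_rng(seed)
    if params.exon_len_range[0] <= 0 or params.intron_len_range[0] <= 0:
        raise ValueError("exon and intron lengths must be positive")
    if params.exon_len_range[0] > params.exon_len_range[1]:
        raise ValueError("infeasible exon length range")
    roles = _assign_roles(params, rng)
    tissues = [f"T{i + 1:02d}" for i in range(params.n_tissues)]
    nT = params.n_tissues
    chrom = params.chrom
    genes: list[TruthGene] = []
    planted: dict[str, list[str]] = {}
    member_genes: dict[str, tuple[str, str]] = {}
    pieces: list[tuple[int, str]] = []  # (offset, sequence) to place
    cursor = params.spacer

    for g_idx, role in enumerate(roles):
        gid = f"G{g_idx + 1:04d}"
        strand = str(rng.choice(["+", "-"]))
        # --- exon/intron architecture
        if role == "hotspot":
            n_exons = 8
            exon_lens = rng.integers(*params.exon_len_range, size=n_exons)
        elif role == "polycistron":
            n_exons = 4
            exon_lens = None  # sized from the designed mRNA below
        else:
            n_exons = int(rng.integers(params.exon_count_range[0], params.exon_count_range[1] + 1))
            exon_lens = rng.integers(*params.exon_len_range, size=n_exons)
        if role == "microexon":
            me_idx = int(rng.integers(1, n_exons - 1))
            exon_lens[me_idx] = int(rng.integers(9, 52))
        if role == "polycistron":
            utr5, orf1, linker, orf2, utr3 = 120, 111, 60, 106, 150
            spliced_len = utr5 + 3 * orf1 + linker + 3 * orf2 + utr3
            exon_lens = np.full(4, spliced_len // 4)
            exon_lens[-1] += spliced_len - exon_lens.sum()
        intron_lens = rng.integers(*params.intron_len_range, size=len(exon_lens) - 1)
        start = cursor + params.terminal_pad
        blocks = []
        x = start
        for i, el in enumerate(exon_lens):
            blocks.append((x, x + int(el)))
            x += int(el)
            if i < len(intron_lens):
                x += int(intron_lens[i])
        primary = ExonChain.from_blocks(chrom, strand, blocks)
        cursor = primary.end + params.terminal_pad + params.spacer
        spliced_len = primary.spliced_length

        # --- mRNA sequence design (primary isoform layout)
        if role == "polycistron":
            mrna = (
                _utr_seq(rng, utr5)
                + _cds_seq(rng, orf1)
                + _utr_seq(rng, linker)
                + _cds_seq(rng, orf2)
                + _utr_seq(rng, utr3)
            )
            cds = None
            member_genes[gid] = (f"{gid}_m1", f"{gid}_m2")
        else:
            u5 = min(100, max(10, spliced_len // 5))
            u3 = min(120, max(10, spliced_len // 5))
            n_codons = (spliced_len - u5 - u3) // 3
            u3 = spliced_len - u5 - 3 * n_codons
            mrna = _utr_seq(rng, u5) + _cds_seq(rng, n_codons) + _utr_seq(rng, u3)
            cds = (u5, u5 + 3 * n_codons)
        assert len(mrna) == spliced_len

        # --- isoform set
        iso_specs: list[tuple[ExonChain, np.ndarray]] = []  # (chain, share)
        tss_sites = [_five_prime_pos(primary)]
        tes_sites = [_three_prime_pos(primary)]
        tss_usage = np.ones((1, nT))
        tes_usage = np.ones((1, nT))
        if role == "switch":
            long_chain = _extend_five(primary, params.alt_tss_offset)
            tss_usage = _group_usage(nT, params.switch_usage_major)
            tss_sites = [tss_sites[0], _five_prime_pos(long_chain)]
            iso_specs = [(primary, tss_usage[0]), (long_chain, tss_usage[1])]
        elif role in ("apa", "apa_small"):
            delta = params.apa_delta if role == "apa" else params.apa_small_delta
            major = (
                params.apa_usage_major
                if role == "apa"
                else params.apa_small_usage_major
            )
            long_chain = _extend_three(primary, delta)
            tes_usage = _group_usage(nT, major)
            tes_sites = [tes_sites[0], _three_prime_pos(long_chain)]
            iso_specs = [(primary, tes_usage[0]), (long_chain, tes_usage[1])]
        elif role == "hotspot":
            combos = [
                frozenset(i for i, bit in zip((2, 3, 4), pattern) if not bit)
                for pattern in np.ndindex(2, 2, 2)
            ]
            share = np.full(nT, 1.0 / len(combos))
            iso_specs = [(_subset_chain(primary, c), share) for c in combos]
        else:
            n_internal = len(primary.exons) - 2
            n_extra = int(rng.integers(0, min(3, max(0, n_internal)) + 1))
            skips: set[frozenset[int]] = set()
            while len(skips) < n_extra:
                k = int(rng.integers(1, n_internal + 1))
                idx = frozenset(
                    int(i) for i in rng.choice(np.arange(1, n_internal + 1), size=k, replace=False)
                )
                skips.add(idx)
            chains = [primary] + [_subset_chain(primary, s) for s in sorted(skips, key=sorted)]
            weights = np.array([2.0] + [1.0] * (len(chains) - 1))
            shares = weights / weights.sum()
            iso_specs = [(c, np.full(nT, s)) for c, s in zip(chains, shares)]

        # --- expression profile
        if role == "specific":
            expr = np.zeros(nT)
            expr[g_idx % nT] = 50.0
        elif role == "uniform":
            expr = np.full(nT, 20.0)
        else:
            expr = rng.lognormal(mean=np.log(20.0), sigma=0.5, size=nT)

        isoforms = []
        primary_blocks = tuple(primary.blocks())
        cds_given = False
        for k, (chain, share) in enumerate(iso_specs):
            is_primary = tuple(chain.blocks()) == primary_blocks
            isoforms.append(
                TruthIsoform(
                    f"{gid}.i{k + 1}",
                    gid,
                    chain,
                    np.asarray(share, float),
                    _five_prime_pos(chain),
                    _three_prime_pos(chain),
                    cds if (is_primary and not cds_given) else None,
                )
            )
            cds_given = cds_given or is_primary
        gene = TruthGene(
            gid, strand, isoforms, tss_sites, tss_usage, tes_sites, tes_usage, expr, role
        )
        genes.append(gene)
        planted.setdefault(role, []).append(gid)

        # --- place sequence: master chain covers every isoform's extent
        master_blocks = [list(b) for b in primary.blocks()]
        for iso in isoforms:
            master_blocks[0][0] = min(master_blocks[0][0], iso.chain.start)
            master_blocks[-1][1] = max(master_blocks[-1][1], iso.chain.end)
        master = ExonChain.from_blocks(
            chrom, strand, [(a, b) for a, b in master_blocks]
        )
        ext5 = master.spliced_length - spliced_len if role == "switch" else 0
        ext3 = master.spliced_length - spliced_len if role in ("apa", "apa_small") else 0
        master_mrna = _utr_seq(rng, ext5) + mrna + _utr_seq(rng, ext3)
        exon_order = master.exons if strand == "+" else master.exons[::-1]
        off = 0
        for e in exon_order:
            piece = master_mrna[off : off + e.length]
            off += e.length
            pieces.append((e.start, piece if strand == "+" else revcomp(piece)))

    genome_len = cursor + params.spacer
    arr = np.frombuffer(
        _rand_seq(rng, genome_len).encode(), dtype="S1"
    ).copy()
    for offset, seq in pieces:
        arr[offset : offset + len(seq)] = np.frombuffer(seq.encode(), dtype="S1")
    genome = {chrom: arr.tobytes().decode()}
    return SyntheticTruth(params, genome, genes, tissues, planted, member_genes)


# ---- long reads --------------------------------------------------------


def _jitter_chain(chain: ExonChain, rng: np.random.Generator) -> Optional[ExonChain]:
    introns = chain.introns()
    if not introns:
        return None
    blocks = [list(b) for b in chain.blocks()]
    i = int(rng.integers(len(introns)))
    delta = int(rng.integers(1, 11)) * (1 if rng.random() < 0.5 else -1)
    if rng.random() < 0.5:  # donor side: move end of exon i
        new_end = blocks[i][1] + delta
        if new_end - blocks[i][0] < 20 or blocks[i + 1][0] - new_end < 20:
            return None
        blocks[i][1] = new_end
    else:  # acceptor side: move start of exon i+1
        new_start = blocks[i + 1][0] + delta
        if blocks[i + 1][1] - new_start < 20 or new_start - blocks[i][1] < 20:
            return None
        blocks[i + 1][0] = new_start
    return ExonChain.from_blocks(chain.chrom, chain.strand, [(a, b) for a, b in blocks])


def _bubble_chain(chain: ExonChain, rng: np.random.Generator) -> Optional[ExonChain]:
    idx = [i for i, e in enumerate(chain.exons) if e.length >= 150]
    if not idx:
        return None
    i = int(rng.choice(idx))
    e = chain.exons[i]
    gap = int(rng.integers(20, 61))
    pos = int(rng.integers(e.start + 40, e.end - 40 - gap))
    blocks = chain.blocks()
    blocks[i : i + 1] = [(e.start, pos), (pos + gap, e.end)]
    return ExonChain.from_blocks(chain.chrom, chain.strand, blocks)


def _truncate_chain(chain: ExonChain, rng: np.random.Generator) -> Optional[ExonChain]:
    sl = chain.spliced_length
    if sl < 200:
        return None
    u = int(rng.integers(40, sl - 120))
    blocks = chain.spliced_interval_to_genomic(u, sl)
    # keep the cut strictly inside an exon
    if chain.strand == "+" and any(b[0] == blocks[0][0] for b in chain.blocks()):
        blocks[0] = (blocks[0][0] + 1, blocks[0][1])
    if chain.strand == "-" and any(b[1] == blocks[-1][1] for b in chain.blocks()):
        blocks[-1] = (blocks[-1][0], blocks[-1][1] - 1)
    return ExonChain.from_blocks(chain.chrom, chain.strand, blocks)


def simulate_long_reads(
    truth: SyntheticTruth,
    depth: int = 30,
    err: ErrorRates = ErrorRates(),
    seed: int = 0,
) -> list[SimRead]:
    """Sample long reads per isoform proportional to abundance (with a floor
    so every expressed isoform is represented) and apply the error
    processes at the configured rates."""
    for r in (err.boundary_jitter_rate, err.bubble_rate, err.truncation_5p_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("error rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    reads: list[SimRead] = []
    for gene in truth.genes:
        for iso in gene.isoforms:
            n = max(4, int(round(depth * float(iso.share.mean()))))
            for r_i in range(n):
                chain = iso.chain
                errors: list[str] = []
                if rng.random() < err.boundary_jitter_rate:
                    jc = _jitter_chain(chain, rng)
                    if jc is not None:
                        chain, errors = jc, errors + ["jitter"]
                if rng.random() < err.bubble_rate:
                    bc = _bubble_chain(chain, rng)
                    if bc is not None:
                        chain, errors = bc, errors + ["bubble"]
                if rng.random() < err.truncation_5p_rate:
                    tc = _truncate_chain(chain, rng)
                    if tc is not None:
                        chain, errors = tc, errors + ["truncation"]
                reads.append(
                    SimRead(f"{iso.id}.r{r_i + 1}", chain, iso.id, tuple(errors))
                )
    return reads


def reads_as_records(reads: Sequence[SimRead]) -> list[tuple[str, ExonChain]]:
    return [(r.id, r.chain) for r in reads]


# ---- tag signals and junctions ----------------------------------------


def simulate_tags_and_junctions(
    truth: SyntheticTruth,
    tag_depth: int = 2000,
    spread: int = 0,
    seed: int = 0,
    junction_depth: int = 50,
) -> tuple[TagSignal, TagSignal, list[SpliceJunction]]:
    """Per-tissue 5'/3' tag tracks around the true sites (multinomial over
    site usage, geometric positional scatter of the given spread) plus a
    deterministic junction-support table proportional to isoform abundance."""
    if spread < 0:
        raise ValueError("spread must be >= 0")
    rng = np.random.default_rng(seed)
    tag5 = TagSignal(end="five_prime")
    tag3 = TagSignal(end="three_prime")
    chrom = truth.params.chrom
    for t_i, tissue in enumerate(truth.tissues):
        for sig in (tag5, tag3):
            sig.data.setdefault(tissue, {})
            sig.library_size.setdefault(tissue, 0)
        for gene in truth.genes:
            key = (chrom, gene.strand)
            for sites, usage, sig in (
                (gene.tss_sites, gene.tss_usage, tag5),
                (gene.tes_sites, gene.tes_usage, tag3),
            ):
                counts = rng.multinomial(tag_depth, usage[:, t_i])
                dst = sig.data[tissue].setdefault(key, {})
                for site, c in zip(sites, counts):
                    if c == 0:
                        continue
                    if spread == 0:
                        dst[site] = dst.get(site, 0) + int(c)
                    else:
                        mags = rng.geometric(1.0 / (1 + spread), size=c) - 1
                        signs = rng.choice([-1, 1], size=c)
                        for pos in site + mags * signs:
                            dst[int(pos)] = dst.get(int(pos), 0) + 1
                    sig.library_size[tissue] += int(c)
    junctions: dict[tuple, SpliceJunction] = {}
    for gene in truth.genes:
        for d, a in gene.junctions():
            counts = {}
            for t_i, tissue in enumerate(truth.tissues):
                share = sum(
                    float(iso.share[t_i])
                    for iso in gene.isoforms
                    if (d, a) in {(i.start, i.end) for i in iso.chain.introns()}
                )
                counts[tissue] = int(round(junction_depth * share))
            j = SpliceJunction(chrom, d, a, gene.strand, counts)
            junctions[j.key] = j
    return tag5, tag3, sorted(junctions.values(), key=lambda j: j.key)


# ---- expression --------------------------------------------------------


def simulate_expression(
    truth: SyntheticTruth, noise_cv: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Gene x tissue FPKM-scale matrix: true base level times lognormal
    noise; polycistron member pseudo-genes share the gene's latent profile."""
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows = {}

    def noisy(base: np.ndarray) -> np.ndarray:
        if noise_cv == 0:
            return base.copy()
        return base * rng.lognormal(mean=0.0, sigma=noise_cv, size=base.size)

    for gene in truth.genes:
        rows[gene.gene_id] = noisy(gene.expression)
        if gene.gene_id in truth.member_genes:
            m1, m2 = truth.member_genes[gene.gene_id]
            rows[m1] = noisy(gene.expression)
            rows[m2] = noisy(gene.expression * 0.8)
    return pd.DataFrame.from_dict(rows, orient="index", columns=truth.tissues)


# ---- NGS transfrags ----------------------------------------------------


def simulate_transfrags(
    truth: SyntheticTruth,
    seed: int = 0,
    boundary_offset: int = 120,
    gene_subset: Optional[Sequence[str]] = None,
) -> list[IsoformRecord]:
    """Transfrags derived from the truth set: primary isoform chains with
    terminal boundaries displaced outward by ``boundary_offset`` nt and an
    FPKM attribute from the mean expression level."""
    rng = np.random.default_rng(seed)
    out = []
    wanted = set(gene_subset) if gene_subset is not None else None
    for gene in truth.genes:
        if wanted is not None and gene.gene_id not in wanted:
            continue
        iso = gene.isoforms[0]
        chain = _extend_five(_extend_three(iso.chain, boundary_offset), boundary_offset)
        fpkm = float(max(0.01, gene.expression.mean() * rng.uniform(0.5, 1.5)))
        out.append(
            IsoformRecord(
                f"{gene.gene_id}.t1",
                chain,
                cls="isoN",
                gene_id="",
                attrs={"fpkm": fpkm},
            )
        )
    return out


# ---- null-model string genes (hotspot calibration) ---------------------


def simulate_null_string_genes(
    n_genes: int,
    n_segments: int = 14,
    mean_isoforms: float = 4.0,
    inclusion: float = 0.8,
    seed: int = 0,
) -> list[IsoformStringSet]:
    """Isoform string sets under the independent-splicing null hypothesis:
    every isoform draws every segment independently (Bernoulli ``inclusion``
    per segment), with 1 + Poisson(mean_isoforms - 1) isoforms per gene.

    The isoform count matches the transcript-per-locus ratio of deeply
    sampled plant annotations (about 4); the inclusion probability reflects
    segments being mostly constitutive.  Because splicing choices are
    independent across segments and isoforms, no window carries clustered
    diversity and a hotspot scan should report (almost) nothing."""
    rng = np.random.default_rng(seed)
    out = []
    bounds = tuple(range(0, 10 * (n_segments + 1), 10))
    for g in range(n_genes):
        m = 1 + int(rng.poisson(max(0.0, mean_isoforms - 1)))
        strings = tuple(
            "".join(rng.choice(["0", "1"], p=[1 - inclusion, inclusion], size=n_segments))
            for _ in range(m)
        )
        out.append(
            IsoformStringSet(f"N{g + 1:05d}", bounds, strings, "chrN", "+")
        )
    return out


# ---- file emission -----------------------------------------------------


def write_all(
    truth: SyntheticTruth,
    reads: Sequence[SimRead],
    tag5: TagSignal,
    tag3: TagSignal,
    junctions: Sequence[SpliceJunction],
    expr: pd.DataFrame,
    outdir: str,
) -> dict[str, object]:
    """Write every pipeline input to ``outdir`` in its standard text format;
    returns the path manifest."""
    from . import io as fio

    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, object] = {}
    paths["genome"] = os.path.join(outdir, "genome.fa")
    fio.write_genome(truth.genome, paths["genome"])
    paths["truth_gff3"] = os.path.join(outdir, "truth.gff3")
    fio.write_transcripts(truth.to_isoform_records(), paths["truth_gff3"])
    paths["reads_bed12"] = os.path.join(outdir, "long_reads.bed")
    fio.write_bed12(reads_as_records(reads), paths["reads_bed12"])
    paths["junctions"] = os.path.join(outdir, "junctions.tsv")
    fio.write_junction_table(junctions, paths["junctions"])
    paths["expression"] = os.path.join(outdir, "expression.tsv")
    fio.write_expression_matrix(expr, paths["expression"])
    tag_manifest: dict[str, dict[str, list]] = {"five_prime": {}, "three_prime": {}}
    for label, sig in (("five_prime", tag5), ("three_prime", tag3)):
        for sample in sig.samples():
            files = []
            for (chrom, strand), posmap in sig.data[sample].items():
                tag = "plus" if strand == "+" else "minus"
                p = os.path.join(outdir, f"{sample}.{label}.{tag}.bedGraph")
                fio.write_bedgraph(posmap, chrom, p)
                files.append((p, strand))
            tag_manifest[label][sample] = files
    paths["tags"] = tag_manifest
    return paths
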