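# Methods

This note records the models, parameter choices, numerical conventions and
known limitations of `isoforge`. Coordinates are 0-based half-open
throughout; GTF/GFF3 conversion happens only at the I/O boundary. Strand
`"."` is allowed for signal tracks, never for isoforms.

## Site clustering

Tag clustering finds, per strand, all runs of tag positions that are
maximal-scoring segments for some density parameter d (score = total tags −
d × spanned nt). Candidates form a laminar hierarchy; each carries a
minimum density (the density at which it merges into its parent) and a
maximum density (its weakest prefix/suffix removal density). A candidate is
retained iff total ≥ `min_value` (20 tags), span ≤ `max_length` (200 nt)
and max/min density ≥ `min_density_fold` (5); retained candidates flatten
to the disjoint maximal ones. Singleton positions have infinite maximum
density and always count as stable. Summits are the position of maximal
pooled signal, ties broken leftmost (5'-most in genome coordinates) —
deterministically.

Reliability requires cluster-sum TPM ≥ 0.5 in at least one sample *and*
per-base maximum signal ≥ 10 in at least three samples. TPM is cluster tag
sum / library size × 1e6; the cluster-sum (not summit) TPM is used.

Two distance rules serve different stages: a 400 nt single-linkage merge
(gap < 400) simplifies clusters for assembly; a 50 nt prune (summit
distance ≤ 50, keep the stronger, greedy by descending signal, ties
leftmost) precedes the usage/dynamics analyses. The prune anchors on summit
distance because cluster edges are resolution-dependent.

## Assembly

The genome is scanned in 100 bp windows; windows with any exonic signal
merge into linkage groups, and a long read spanning two groups merges them.
Within a group, boundaries are the credible junction donors/acceptors plus
TSS/TES cluster summits; the boundary falls on the summit for the
transcript-start side and just after it for the transcript-end side, so the
summit base is the first (last) base of its segment. Segments containing a
summit are labelled TSS/TES segments.

A junction is credible with ≥ 3 short reads in ≥ 1 sample. Reads project
onto segments with a half-length rule (bit = 1 iff exonic overlap ≥ half
the segment length), which keeps small terminal jitter from flipping bits.
Junction *validation* however uses the read's own intron coordinates,
matched exactly against the credible set: this is what makes boundary
jitter (1–10 nt) and spurious short introns detectable even when the bit
vector is unaffected. Emitted models always use segment-implied
coordinates, with labelled terminals anchored on the cluster summit.

Repair is deliberately conservative: completion (isoC) and rescue (isoR)
require a *unique* isoF extension or local sub-path — ambiguity demotes the
read to the weaker class. Gap refilling (isoP) enumerates segment chains
consistent with credible junctions (bounded at 20 segments / 64 paths) and
takes the chain with maximal short-read coverage, then fewest segments,
then lexicographic order. Duplicate chains collapse to the best class
(isoF > isoR > isoC > isoM > isoP). Monoexonic reads classify on terminal
labels alone. The final integrated annotation keeps isoF/isoR/isoC at
long-read loci and isoN elsewhere; isoM/isoP are emitted with labels but
excluded from the final set.

NGS transfrags are filtered at FPKM ≥ 0.5 (single-exon) / ≥ 0.2
(multi-exon), both inclusive, and their terminal boundaries snap to the
nearest reliable summit within 500 bp, clamped so a move never crosses the
first/last junction.

## Dynamics

`S = log2 N − H_obs` uses all-N row normalisation with `0·log2 0 = 0`; the
20%-of-maximum expressed-tissue rule is a separate predicate, not part of
the normalisation. Dominant sites require usage strictly above 0.5; switch
calls require ≥ 2 distinct dominant sites and max pairwise W strictly above
0.3, computed on clusters that pass the dynamics prefilter (TPM > 0.5 in
≥ 2 tissues and mean TPM > 0.5) and the 50 nt prune. Per-site 3'UTR
lengths come from the CDS-bearing isoform whose 3' end is closest to the
cluster summit (spliced length − CDS end). APA calls are strict
inequalities on both |ΔL_w| > 100 nt and TPM > 5.

## Sequence features

The representative CDS of a gene for distal/proximal/coding (DT/PT/CT)
site classification is the longest ORF of the longest isoform. TSS
clusters with summits inside the CDS genomic span are CT, as are the rare
summits on the CDS-ward side of the anchor codon; among the upstream rest,
the site farthest from the start codon is DT, the others PT (mirror logic
for TES around the stop codon). ORF finding scans the three forward frames
of the mRNA sense strand, ties resolved 5'-most.

Microexons are internal exons ≤ 51 nt. Coupling events compare isoforms
pairwise: a terminal exon entirely inside another isoform's intron with its
own junction is an Is event; one running continuously across the intron's
inner boundary is Ic.

The RG4 scanner requires four G-tracts of equal length t ≥ 4 (≥ 4 stacked
tetrads) with loops ≥ 2 nt; among overlapping candidates the longest
tract wins, then the 5'-most, then the shortest span. The U-rich element
is defined operationally (no standard exists): windows of 10 nt (clipped
to the sequence) with U-fraction ≥ 0.8 merge, trim to U boundaries, and
are kept at ≥ 6 nt. uORFs are every ATG-initiated, stop-terminated ORF of
≥ 2 codons fully inside the 5'UTR.

## AS-hotspot model

The null pmf is computed by binomial-thinning convolution
(`i → i + Binomial(i, p)` per level), which matches the recursion
`P(ξ=n | K=k+1) = Σ C(i, n−i) p^{n−i} (1−p)^{2i−n} P(ξ=i | K=k)` exactly
(verified against an exact-rational generating-function enumeration,
total-variation < 1e-12 for K ≤ 8). `p` is estimated per k independently
from the window-count mean via `E(X) = (1+p)^K`, clamped to [0, 1].
The genome-level cutoff is the smallest n whose observed frequency is
positive and ≥ 3 × the null pmf at n, compared pointwise (not on tails) —
the most literal reading of a minimum count for a three-fold excess.
Evidence windows within a gene that share a segment merge into one region;
regions need more than 3 (gene, k, window) evidences. Genes with fewer
segments than k, or fewer than two isoforms, are skipped.

## Polycistrons

A polycistron is a transcript whose spliced sequence carries ≥ 2
non-overlapping ATG→stop ORFs of ≥ 100 codons ("major"; the threshold is
exposed in `RunConfig`), selected greedily by descending length.
Inter-CDS distances are spliced-coordinate stop→start gaps. Co-expression
contrasts Pearson correlations of member-gene pairs against random
same-chromosome pairs (one-sided Wilcoxon rank-sum, seeded and
bit-reproducible). Co-linearity in another species requires both orthologs
on the same strand of the same chromosome with a gap < 20 kb.

## Synthetic data: what it emulates and what it does not

The simulator is the package's study-conditions generator: 16 tissues, 50
genes by default (200 for the hotspot-recall experiment), up to 10
isoforms per gene, exons 100–300 nt, introns 80–400 nt, 2 kb intergenic
spacers. Planted features: TSS-switch genes (two TSS 500 nt apart, usage
0.9/0.1 flipped between tissue halves → W = 0.8), one callable APA gene
(TES shift 500 nt, usage 0.7/0.3 flip → ΔL_w = 200 nt) and one
sub-threshold APA gene (450 nt, flip chosen so ΔL_w = 80 nt), hotspot
genes (eight isoforms enumerating all combinations of three adjacent
cassette exons — diversity confined to a five-segment window),
read-through polycistrons with two ≥ 100-codon ORFs and co-expressed
member pseudo-genes, microexon genes, and single-tissue/uniform expression
genes. Alternative terminals are placed ≥ 400 nt apart so the assembly
merge cannot fuse distinct sites; this is a property of the planted
conditions, not of real promoters.

mRNA sequence content is designed, not sampled: UTRs and linkers come from
an A-free alphabet and CDS bodies from G/C-only codons, so ATG occurs
exactly at planted start codons and the planted CDS is provably the
longest ORF. Tag counts are multinomial over site usage per tissue
(depth 2000/gene/tissue/end) with optional geometric positional scatter
(default 0: tags sit on the exact sites); junction support is
deterministic and proportional to isoform abundance (depth 50). Long-read
depth is 30 per gene with a floor of 4 reads per isoform. Error processes
mimic the dominant long-read artefact classes: boundary jitter (one
junction edge ± 1–10 nt), bubbles (spurious 20–60 nt intron), 5'
truncation (prefix removed, cut inside an exon).

Deliberately not emulated: base-level sequencing errors and quality
strings, expression-coupled read/tag depth (tag depth is uniform across
genes, so reliability filtering never silences a tissue-specific gene's
sites — real CAGE depth tracks expression), overlapping genes, multi-locus
families, and positional tag biases. Passing tests therefore demonstrate
algorithmic correctness under controlled conditions, not robustness to
every artefact of real libraries.

The null cohort for the hotspot false-positive check draws, per gene,
1 + Poisson(3) isoforms with independent Bernoulli(0.8) segment choices —
the literal "splicing events independent" null, with the isoform count
matched to the ~4 transcripts-per-locus ratio of deeply sampled plant
annotations and the inclusion rate reflecting mostly-constitutive
segments. A single-root branching-tree sampler was considered and
rejected for this purpose: an early branch inflates diversity in every
window of the gene, which itself violates the independence null. The tree
process survives as `simulate_null_counts` (per-window draws of X) for the
moment-estimator calibration check.

## Problem sizes and determinism

The test suite and the acceptance script run the assembly at 50 genes
(~120 isoforms, ~1500 reads), the hotspot recall at 200 genes with 20
planted hotspots, the null false-positive rate at 3000 genes, and the
moment-estimator check at 10,000 draws — sizes at which every stochastic
criterion is stable across seeds while the whole battery completes in
seconds. All randomness flows through `numpy.random.default_rng` with
explicit seeds; assembly itself is seed-free and deterministic given its
inputs (sorted iteration orders, explicit tie-breaks).

## Known limitations

* Gene grouping uses same-strand exonic-overlap connected components;
  intronic containment without exon overlap splits genes.
* isoR requires both terminals present after correction; corrected but
  incomplete paths fall through to isoP or are dropped.
* The hotspot scan estimates p per k independently; sharing p across k
  would pool information but couple the tests.
* `fill_partial` gives up beyond 20 gap segments or 64 candidate chains.
* BED12 is the only long-read input; BAM support would require carrying
  alignment qualities that the model does not use.
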