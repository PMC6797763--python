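# isoforge

Multi-evidence transcript-isoform assembly and transcriptome-dynamics
statistics for bulk transcriptomes.

Long-read sequencing sees whole transcripts but with untrustworthy ends and
junctions; 5'-tag assays (CAGE-style) pin transcription start sites, 3'-tag
assays pin polyadenylation sites, and short-read RNA-seq nails splice
junctions. `isoforge` combines the four: it clusters the tag signals into
TSS/TES clusters, validates every long read against the cluster summits and
the credible junction set, and repairs what it can. The result is a graded
annotation:

| class | meaning |
|-------|---------|
| isoF  | read starts in a TSS segment, ends in a TES segment, all junctions supported |
| isoC  | junction-clean read missing a terminal, completed by the unique matching isoF |
| isoM  | two complementary partial reads merged without conflict |
| isoR  | read with a bad junction, corrected from the unique local isoF structure |
| isoP  | bad junctions removed, gap refilled from credible junctions |
| isoN  | short-read-only transfrag filling loci without long-read coverage |

On top of the annotation it implements the downstream analyses: an
entropy-based tissue-specificity score, alternative-promoter switch calls,
weighted-3'UTR / APA calls, microexon detection, intronic-terminal coupling
events (Is/Ic), a branching-process null model for alternative-splicing
hotspots, and polycistron detection — plus a synthetic-data simulator that
emits every input format, so the whole pipeline is testable end to end.

## The statistics at the core

**Tissue specificity.** For a gene with relative level `P_i` in tissue `i`
of `N`,

    S = H_max − H_obs = log2(N) − (−Σ_i P_i log2 P_i),

so `S = 0` for uniform expression and `S = log2 N` for single-tissue
expression.

**Promoter switching.** With `d(i)` the dominant TSS of tissue `i`
(usage > 50%), the switch score for tissues `i, j` is

    W = P_{i,d(i)} + P_{j,d(j)} − 1   if d(i) ≠ d(j), else 0,

and a switch gene has ≥ 2 distinct dominant sites with max W > 0.3. APA
calls use the usage-weighted 3'UTR length `L_w = Σ_s P_s · len_s`:
|ΔL_w| > 100 nt with site signal TPM > 5 in both samples.

**AS hotspots.** Each gene's isoforms become 0/1 strings over
exon-boundary segments. Under the null that splicing choices are
independent, the number of distinct k-segment patterns in a window follows
a branching process:

    P(ξ=2 | K=1) = p,  P(ξ=1 | K=1) = 1 − p
    P(ξ=n | K=k+1) = Σ_{i=⌈n/2⌉}^{n} C(i, n−i) p^{n−i} (1−p)^{2i−n} P(ξ=i | K=k)

with `E(X) = (1+p)^K`, which gives the moment estimator
`p̂ = mean(counts)^{1/K} − 1`. A genome has hotspots when observed window
counts exceed the null pmf three-fold at some `n`; windows at or above that
cutoff are evidence, and regions with more than three (gene, k, window)
evidences are reported.

## Worked example

```
python examples/01_assemble_isoforms.py
```

prints

```
class counts: {'isoF': 51, 'isoC': 0, 'isoM': 0, 'isoR': 0, 'isoP': 2, 'loci': 20}
true isoforms recovered chain-identical: 51/51
```

— a 20-gene simulated cohort with 10% junction-jitter on the long reads:
all 51 true isoforms come back with exactly the true exon chains and
terminal coordinates on the cluster summits (jittered reads are either
rescued or collapse onto the identical clean model; the two isoP records
are refilled variants of truncated damaged reads, which the final
annotation excludes). The other examples cover site clustering, the
dynamics statistics, the hotspot scan, and polycistron/motif analyses.

A thin CLI wraps the same functions:

```
isoforge simulate --seed 3 --n-genes 20 --out cohort/
isoforge assemble --data-dir cohort/ --out cohort/assembly.gff3
isoforge hotspot --annotation cohort/truth.gff3 --out cohort/hotspots.tsv
```

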