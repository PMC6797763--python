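import numpy as np
import pytest

from isoforge import (
    ErrorRates,
    SimParams,
    simulate_expression,
    simulate_long_reads,
    simulate_tags_and_junctions,
    simulate_truth,
    tissue_specificity,
)
from isoforge.features import find_longest_orf
from isoforge.core import spliced_sequence


class TestTruth:
    def test_fixed_seed_is_deterministic(self, small_truth):
        params = small_truth.params
        again = simulate_truth(params, seed=11)
        assert again.genome == small_truth.genome
        assert [
            (g.gene_id, g.strand, [i.chain.blocks() for i in g.isoforms])
            for g in again.genes
        ] == [
            (g.gene_id, g.strand, [i.chain.blocks() for i in g.isoforms])
            for g in small_truth.genes
        ]

    def test_requested_gene_count_is_emitted(self, small_truth):
        assert len(small_truth.genes) == small_truth.params.n_genes

    def test_planted_features_are_recorded(self, small_truth):
        p = small_truth.params
        assert len(small_truth.planted["switch"]) == p.n_switch_genes
        assert len(small_truth.planted["hotspot"]) == p.n_hotspot_genes
        assert len(small_truth.planted["polycistron"]) == p.n_polycistron_genes
        assert len(small_truth.member_genes) == p.n_polycistron_genes

    def test_infeasible_params_rejected(self):
        with pytest.raises(ValueError):
            simulate_truth(SimParams(n_genes=2), seed=0)  # planted > genes
        with pytest.raises(ValueError):
            simulate_truth(SimParams(exon_len_range=(300, 100)), seed=0)

    def test_planted_cds_is_the_longest_orf(self, small_truth):
        checked = 0
        for gene in small_truth.genes:
            for iso in gene.isoforms:
                if iso.cds is None:
                    continue
                seq = spliced_sequence(iso.chain, small_truth.genome)
                orf = find_longest_orf(seq)
                assert (orf.start, orf.end) == iso.cds
                checked += 1
        assert checked > 5


class TestLongReads:
    def test_zero_error_reads_match_truth_chains(self, small_truth):
        reads = simulate_long_reads(small_truth, depth=10, err=ErrorRates(), seed=3)
        truth_chains = {
            iso.id: iso.chain.blocks()
            for g in small_truth.genes
            for iso in g.isoforms
        }
        for r in reads:
            assert r.errors == ()
            assert r.chain.blocks() == truth_chains[r.isoform_id]

    def test_full_truncation_removes_every_tss(self, small_truth):
        reads = simulate_long_reads(
            small_truth, depth=10, err=ErrorRates(truncation_5p_rate=1.0), seed=4
        )
        tss = {
            (iso.tss_site, iso.id)
            for g in small_truth.genes
            for iso in g.isoforms
        }
        tss_pos = {t for t, _ in tss}
        truncated = [r for r in reads if "truncation" in r.errors]
        assert len(truncated) > 0.9 * len(reads)  # a few reads are too short to cut
        for r in truncated:
            five = r.chain.start if r.chain.strand == "+" else r.chain.end - 1
            assert five not in tss_pos

    def test_jitter_is_recorded_and_changes_a_junction(self, small_truth):
        reads = simulate_long_reads(
            small_truth, depth=10, err=ErrorRates(boundary_jitter_rate=1.0), seed=5
        )
        truth_introns = {
            iso.id: {(i.start, i.end) for i in iso.chain.introns()}
            for g in small_truth.genes
            for iso in g.isoforms
        }
        jittered = [r for r in reads if "jitter" in r.errors]
        assert jittered
        for r in jittered:
            got = {(i.start, i.end) for i in r.chain.introns()}
            assert got != truth_introns[r.isoform_id]


class TestTags:
    def test_usage_ratio_reflected_in_tag_mass(self, small_truth):
        tag5, _, _ = simulate_tags_and_junctions(small_truth, tag_depth=2000, seed=6)
        gene = next(g for g in small_truth.genes if g.role == "switch")
        t = small_truth.tissues[0]
        counts = tag5.data[t][(small_truth.params.chrom, gene.strand)]
        n_major = counts.get(gene.tss_sites[0], 0)
        n_minor = counts.get(gene.tss_sites[1], 0)
        # binomial check: usage 0.9/0.1 at depth 2000, 3 sigma
        p = gene.tss_usage[0, 0]
        sigma = np.sqrt(2000 * p * (1 - p))
        assert abs(n_major - 2000 * p) < 3 * sigma
        assert abs(n_minor - 2000 * (1 - p)) < 3 * sigma

    def test_zero_spread_puts_tags_on_the_sites(self, small_truth):
        tag5, tag3, _ = simulate_tags_and_junctions(small_truth, spread=0, seed=7)
        sites = {
            (small_truth.params.chrom, g.strand, s)
            for g in small_truth.genes
            for s in g.tss_sites
        }
        for sample, tracks in tag5.data.items():
            for (chrom, strand), posmap in tracks.items():
                for pos in posmap:
                    assert (chrom, strand, pos) in sites

    def test_junction_support_scales_with_abundance(self, small_truth):
        _, _, junctions = simulate_tags_and_junctions(small_truth, seed=8)
        assert junctions
        for j in junctions:
            assert max(j.per_sample_count.values()) >= 3


class TestExpression:
    def test_zero_noise_returns_exact_profiles(self, small_truth):
        expr = simulate_expression(small_truth, noise_cv=0.0, seed=9)
        g = small_truth.genes[0]
        assert np.allclose(expr.loc[g.gene_id].values, g.expression)

    def test_single_tissue_gene_has_maximal_specificity(self, small_truth):
        expr = simulate_expression(small_truth, noise_cv=0.0, seed=9)
        gid = small_truth.planted["specific"][0]
        s = tissue_specificity(expr.loc[gid].values)
        assert s == pytest.approx(np.log2(small_truth.params.n_tissues))

    def test_uniform_gene_scores_near_zero_even_with_noise(self, small_truth):
        expr = simulate_expression(small_truth, noise_cv=0.1, seed=10)
        gid = small_truth.planted["uniform"][0]
        assert tissue_specificity(expr.loc[gid].values) < 0.2

    def test_member_pseudo_genes_present(self, small_truth):
        expr = simulate_expression(small_truth, noise_cv=0.2, seed=11)
        for m1, m2 in small_truth.member_genes.values():
            assert m1 in expr.index and m2 in expr.index
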