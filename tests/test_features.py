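import numpy as np
import pytest

from isoforge import (
    ExonChain,
    GeneModel,
    GenomicInterval,
    IsoformRecord,
    detect_coupling_events,
    detect_microexons,
    classify_sites,
    find_longest_orf,
    find_uorfs,
    scan_rg4,
    scan_urich,
)
from conftest import mk_cluster
from oracles import longest_orf_bruteforce, rg4_bruteforce, uorfs_bruteforce, urich_bruteforce


def iso(name, blocks, strand="+", cds=None):
    return IsoformRecord(name, ExonChain.from_blocks("chr1", strand, blocks), cds=cds)


def gene(isoforms):
    from isoforge import group_into_genes

    return group_into_genes(isoforms)[0]


class TestLongestOrf:
    def test_minimal_orf(self):
        orf = find_longest_orf("ATGAAATAG")
        assert (orf.start, orf.end, orf.aa_length) == (0, 9, 2)

    def test_no_start_codon(self):
        assert find_longest_orf("CCCCCCTAG") is None

    def test_longest_wins(self):
        seq = "ATGAAATAG" + "ATG" + "GCT" * 8 + "TAA"
        orf = find_longest_orf(seq)
        assert (orf.start, orf.end) == (9, 9 + 30)

    def test_agrees_with_bruteforce_scanner(self):
        rng = np.random.default_rng(21)
        for _ in range(300):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(3, 600))))
            got = find_longest_orf(seq)
            exp = longest_orf_bruteforce(seq)
            assert (got is None) == (exp is None)
            if got:
                assert (got.start, got.end) == exp


class TestMicroexons:
    def test_length_threshold_fixture(self):
        rec = iso("a", [(0, 100), (200, 203), (300, 351), (400, 452), (500, 510)])
        hits = detect_microexons([rec])
        assert sorted(e.length for _, e in hits) == [3, 51]  # 52 nt excluded

    def test_terminal_exons_never_count(self):
        rec = iso("a", [(0, 10), (200, 300)])
        assert detect_microexons([rec]) == []

    def test_invariant_under_strand_flip(self):
        blocks = [(0, 100), (200, 230), (300, 400)]
        plus = iso("p", blocks, strand="+")
        minus = iso("m", blocks, strand="-")
        assert len(detect_microexons([plus])) == len(detect_microexons([minus]))


class TestSiteRoles:
    def _gene_plus(self):
        # CDS spans genomic [1000, 1600) on a single-exon isoform
        rec = iso("a", [(500, 2000)], cds=(500, 1100))
        return gene([rec])

    def test_dt_pt_ct_assignment(self):
        g = self._gene_plus()
        clusters = [mk_cluster("TSS", p) for p in (600, 800, 1200)]
        roles = {l.cluster.summit: l.role for l in classify_sites(g, clusters, "TSS")}
        assert roles == {600: "DT", 800: "PT", 1200: "CT"}

    def test_single_upstream_site_is_distal(self):
        g = self._gene_plus()
        (label,) = classify_sites(g, [mk_cluster("TSS", 700)], "TSS")
        assert label.role == "DT"

    def test_minus_strand_mirror(self):
        rec = iso("a", [(500, 2000)], strand="-", cds=(500, 1100))
        g = gene([rec])
        # minus strand: CDS occupies genomic [900, 1500); upstream = higher coords
        clusters = [mk_cluster("TSS", p, strand="-") for p in (1900, 1700, 1200)]
        roles = {l.cluster.summit: l.role for l in classify_sites(g, clusters, "TSS")}
        assert roles == {1900: "DT", 1700: "PT", 1200: "CT"}

    def test_exactly_one_distal_site(self):
        g = self._gene_plus()
        rng = np.random.default_rng(3)
        clusters = [mk_cluster("TSS", int(p)) for p in rng.integers(500, 1000, 6)]
        roles = [l.role for l in classify_sites(g, clusters, "TSS")]
        assert roles.count("DT") == 1

    def test_missing_cds_is_an_error(self):
        g = gene([iso("a", [(0, 100)])])
        with pytest.raises(ValueError):
            classify_sites(g, [mk_cluster("TSS", 10)], "TSS")

    def test_tes_roles_relative_to_stop(self):
        g = self._gene_plus()
        clusters = [mk_cluster("TES", p) for p in (1050, 1700, 1900)]
        roles = {l.cluster.summit: l.role for l in classify_sites(g, clusters, "TES")}
        assert roles == {1050: "CT", 1700: "PT", 1900: "DT"}


class TestCouplingEvents:
    def test_skipped_terminal_exon_is_event(self):
        host = iso("host", [(0, 100), (500, 600)])
        alt = iso("alt", [(200, 300), (500, 600)])  # starts inside host's intron
        events = detect_coupling_events(gene([host, alt]))
        assert [(e.end, e.type, e.isoform) for e in events] == [("5p", "Is", "alt")]

    def test_composite_terminal_exon_ic_event(self):
        host = iso("host", [(0, 100), (500, 600)])
        alt = iso("alt", [(200, 600)])  # runs across the intron boundary
        events = detect_coupling_events(gene([host, alt]))
        assert [(e.end, e.type) for e in events] == [("5p", "Ic")]

    def test_tss_inside_exon_is_no_event(self):
        host = iso("host", [(0, 300), (500, 600)])
        alt = iso("alt", [(100, 300), (500, 600)])
        assert detect_coupling_events(gene([host, alt])) == []

    def test_three_prime_events_on_minus_strand(self):
        host = iso("host", [(0, 100), (500, 600)], strand="-")
        # minus strand: the 3' terminal exon is the genomic-left one
        alt = iso("alt", [(200, 300), (500, 600)], strand="-")
        events = detect_coupling_events(gene([host, alt]))
        assert [(e.end, e.type) for e in events] == [("3p", "Is")]


class TestScanners:
    def test_rg4_examples(self):
        assert len(scan_rg4("GGGGAAGGGGAAGGGGAAGGGG")) == 1
        assert scan_rg4("GGGGAGGGGAGGGGAGGGG") == []  # 1 nt loops
        assert scan_rg4("GGGAAGGGAAGGGAAGGG") == []  # tracts of 3

    def test_urich_examples(self):
        assert len(scan_urich("UUUUUU")) == 1
        assert scan_urich("UAUAUA") == []
        assert scan_urich("AAAAAA") == []

    def test_uorf_examples(self):
        assert len(find_uorfs("ATGAAATGA")) == 1
        assert find_uorfs("ATGAAAAAA") == []  # no stop inside the UTR
        two = find_uorfs("ATGAAATGACCC" + "ATGCCCTAG")
        assert len(two) == 2

    def test_scanners_agree_with_bruteforce(self):
        rng = np.random.default_rng(31)
        for _ in range(150):
            seq = "".join(
                rng.choice(list("ACGT"), size=int(rng.integers(5, 80)), p=[0.2, 0.15, 0.45, 0.2])
            )
            assert sorted(
                (h.start, h.end) for h in scan_rg4(seq)
            ) == [(a, b) for a, b, _ in rg4_bruteforce(seq)]
            assert [(h.start, h.end) for h in scan_urich(seq)] == urich_bruteforce(seq)
            assert sorted((h.start, h.end) for h in find_uorfs(seq)) == sorted(
                uorfs_bruteforce(seq)
            )
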