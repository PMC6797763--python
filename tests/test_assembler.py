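import pytest

from isoforge import (
    ExonChain,
    GenomicInterval,
    LinkageGroup,
    SpliceJunction,
    assemble_locus,
    call_credible_junctions,
    classify_paths,
    complete_partial,
    fill_partial,
    find_linkage_groups,
    merge_complementary,
    project_read,
    rescue_conflict,
    segment_locus,
)
from isoforge.assembler import path_from_bits
from conftest import mk_cluster


def chain(blocks, strand="+"):
    return ExonChain.from_blocks("chr1", strand, blocks)


def jx(donor, acceptor, count=10, strand="+"):
    return SpliceJunction("chr1", donor, acceptor, strand, {"s1": count})


@pytest.fixture
def locus():
    """One plus-strand linkage group [0, 1000) with a TSS summit at 50, a
    TES summit at 900 and two credible junctions; seven segments:

        0:[0,50) 1:[50,200)TSS 2:[200,400) 3:[400,600) 4:[600,800)
        5:[800,901)TES 6:[901,1000)
    """
    group = LinkageGroup(GenomicInterval("chr1", 0, 1000, "+"))
    tss = [mk_cluster("TSS", 50, count=100)]
    tes = [mk_cluster("TES", 900, count=100)]
    junctions = [jx(200, 400), jx(600, 800)]
    segments = segment_locus(group, tss, tes, junctions)
    credible = frozenset(j.key for j in junctions)
    return dict(
        group=group, tss=tss, tes=tes, junctions=junctions,
        segments=segments, credible=credible,
    )


class TestLinkageGroups:
    def test_separated_signal_gives_two_groups(self):
        cov = [GenomicInterval("chr1", 0, 250, "+"), GenomicInterval("chr1", 500, 650, "+")]
        groups = find_linkage_groups(cov, window=100)
        assert [(g.interval.start, g.interval.end) for g in groups] == [(0, 300), (500, 700)]

    def test_adjacent_windows_merge(self):
        cov = [GenomicInterval("chr1", 0, 100, "+"), GenomicInterval("chr1", 100, 150, "+")]
        groups = find_linkage_groups(cov, window=100)
        assert [(g.interval.start, g.interval.end) for g in groups] == [(0, 200)]

    def test_bridging_read_forces_merge(self):
        cov = [GenomicInterval("chr1", 0, 100, "+"), GenomicInterval("chr1", 500, 600, "+")]
        bridge = [("r1", chain([(50, 90), (520, 580)]))]
        groups = find_linkage_groups(cov, reads=bridge, window=100)
        assert len(groups) == 1


class TestCredibleJunctions:
    def test_supported_kept(self):
        assert len(call_credible_junctions([jx(10, 20, count=5)])) == 1

    def test_weak_dropped(self):
        assert call_credible_junctions([jx(10, 20, count=2)]) == []

    def test_long_read_only_junction_dropped(self):
        assert call_credible_junctions([jx(10, 20, count=0)]) == []


class TestSegmentation:
    def test_boundaries_and_labels(self):
        group = LinkageGroup(GenomicInterval("chr1", 0, 1000, "+"))
        segs = segment_locus(
            group, [mk_cluster("TSS", 50)], [mk_cluster("TES", 900)], [jx(200, 400)]
        )
        assert len(segs) == 5
        assert [(s.interval.start, s.interval.end) for s in segs] == [
            (0, 50), (50, 200), (200, 400), (400, 901), (901, 1000),
        ]
        assert "TSS_SEG" in segs[1].labels  # contains the TSS summit
        assert "TES_SEG" in segs[3].labels  # contains position 900

    def test_no_elements_single_segment(self):
        group = LinkageGroup(GenomicInterval("chr1", 0, 1000, "+"))
        segs = segment_locus(group, [], [], [])
        assert len(segs) == 1 and segs[0].labels == frozenset()

    def test_shared_donor_boundaries_are_set_semantics(self):
        group = LinkageGroup(GenomicInterval("chr1", 0, 1000, "+"))
        segs = segment_locus(group, [], [], [jx(200, 400), jx(200, 600)])
        edges = sorted({s.interval.start for s in segs} | {segs[-1].interval.end})
        assert edges == [0, 200, 400, 600, 1000]

    def test_boundary_outside_group_is_an_error(self):
        group = LinkageGroup(GenomicInterval("chr1", 0, 500, "+"))
        with pytest.raises(ValueError):
            segment_locus(group, [], [], [jx(200, 600)])


class TestProjection:
    def test_contiguous_read(self, locus):
        p = project_read(chain([(50, 400)]), locus["segments"], locus["credible"])
        assert p.bits == (0, 1, 1, 0, 0, 0, 0)
        assert p.introns == () and p.implied == ()

    def test_spliced_read_implies_supported_junction(self, locus):
        p = project_read(chain([(50, 200), (400, 600)]), locus["segments"], locus["credible"])
        assert p.bits == (0, 1, 0, 1, 0, 0, 0)
        assert p.implied == ((200, 400),)
        assert p.junction_support == (True,)

    def test_light_brush_does_not_set_the_bit(self, locus):
        p = project_read(chain([(50, 200), (400, 440)]), locus["segments"], locus["credible"])
        assert p.bits == (0, 1, 0, 0, 0, 0, 0)  # 40/200 < half of segment 3

    def test_read_outside_all_segments_is_an_error(self, locus):
        with pytest.raises(ValueError):
            project_read(chain([(2000, 2100)]), locus["segments"], locus["credible"])


def full_path(locus, bits):
    return path_from_bits(bits, locus["segments"], locus["credible"])


class TestClassification:
    def test_three_way_split(self, locus):
        iso_f = project_read(
            chain([(50, 200), (400, 600), (800, 901)]), locus["segments"], locus["credible"]
        )
        candidate = project_read(
            chain([(400, 600), (800, 901)]), locus["segments"], locus["credible"]
        )
        conflicted = project_read(
            chain([(50, 203), (400, 600), (800, 901)]), locus["segments"], locus["credible"]
        )
        out = classify_paths([iso_f, candidate, conflicted])
        assert out.isoF == [iso_f]
        assert out.candidates == [candidate]
        assert out.conflicted == [conflicted]
        assert iso_f.starts_at_tss and iso_f.ends_at_tes and iso_f.fully_supported
        assert not candidate.starts_at_tss and candidate.ends_at_tes


class TestCompletion:
    def test_unique_completion(self, locus):
        iso_f = full_path(locus, (0, 1, 0, 1, 0, 1, 0))
        cand = project_read(
            chain([(400, 600), (800, 901)]), locus["segments"], locus["credible"]
        )
        done = complete_partial(cand, [iso_f], locus["segments"], locus["credible"])
        assert done is not None and done.bits == iso_f.bits

    def test_no_matching_isoform_gives_nothing(self, locus):
        cand = project_read(
            chain([(400, 600), (800, 901)]), locus["segments"], locus["credible"]
        )
        assert complete_partial(cand, [], locus["segments"], locus["credible"]) is None

    def test_ambiguous_completion_gives_nothing(self):
        group = LinkageGroup(GenomicInterval("chr1", 0, 1000, "+"))
        tss = [mk_cluster("TSS", 20), mk_cluster("TSS", 100)]
        tes = [mk_cluster("TES", 900)]
        junctions = [jx(200, 400), jx(600, 800)]
        segments = segment_locus(group, tss, tes, junctions)
        credible = frozenset(j.key for j in junctions)
        f1 = project_read(chain([(20, 200), (400, 600), (800, 901)]), segments, credible)
        f2 = project_read(chain([(100, 200), (400, 600), (800, 901)]), segments, credible)
        assert f1.starts_at_tss and f2.starts_at_tss
        cand = project_read(chain([(400, 600), (800, 901)]), segments, credible)
        assert complete_partial(cand, [f1, f2], segments, credible) is None


class TestMergeComplementary:
    def test_complementary_halves_merge(self, locus):
        left = project_read(chain([(50, 200), (400, 600)]), locus["segments"], locus["credible"])
        right = project_read(chain([(400, 600), (800, 901)]), locus["segments"], locus["credible"])
        (m,) = merge_complementary([left, right], locus["segments"], locus["credible"])
        assert m.bits == (0, 1, 0, 1, 0, 1, 0)
        assert m.starts_at_tss and m.ends_at_tes

    def test_conflicting_overlap_blocks_merge(self, locus):
        left = project_read(chain([(50, 200), (400, 600)]), locus["segments"], locus["credible"])
        right = full_path(locus, (0, 0, 1, 0, 0, 1, 0))
        assert merge_complementary([left, right], locus["segments"], locus["credible"]) == []

    def test_disjoint_ranges_do_not_merge(self, locus):
        left = project_read(chain([(50, 200)]), locus["segments"], locus["credible"])
        right = project_read(chain([(800, 901)]), locus["segments"], locus["credible"])
        assert merge_complementary([left, right], locus["segments"], locus["credible"]) == []


class TestRescue:
    def jittered(self, locus):
        # donor of the first junction shifted +3 nt: intron (203,400) is not
        # in the credible set, but the projected bits match the true path
        return project_read(
            chain([(50, 203), (400, 600), (800, 901)]), locus["segments"], locus["credible"]
        )

    def test_jitter_rescued_by_unique_isoform(self, locus):
        p = self.jittered(locus)
        assert not p.fully_supported
        iso_f = full_path(locus, (0, 1, 0, 1, 0, 1, 0))
        fixed = rescue_conflict(p, [iso_f], locus["segments"], locus["credible"])
        assert fixed is not None and fixed.bits == iso_f.bits
        assert fixed.fully_supported

    def test_two_candidate_corrections_fail(self, locus):
        p = self.jittered(locus)
        f1 = full_path(locus, (0, 1, 0, 1, 0, 1, 0))
        f2 = full_path(locus, (0, 1, 1, 1, 0, 1, 0))  # retained-intron variant
        assert rescue_conflict(p, [f1, f2], locus["segments"], locus["credible"]) is None

    def test_no_isoform_at_locus_fails(self, locus):
        assert rescue_conflict(self.jittered(locus), [], locus["segments"], locus["credible"]) is None


class TestFillPartial:
    def bad_path(self, locus):
        # read with a mis-mapped junction across segment 2
        return project_read(
            chain([(50, 203), (400, 600), (800, 901)]), locus["segments"], locus["credible"]
        )

    def test_fill_prefers_high_coverage_chain(self, locus):
        p = self.bad_path(locus)
        cov_high_exon2 = [0, 10, 100, 10, 0, 10, 0]
        filled = fill_partial(p, locus["segments"], locus["credible"], cov_high_exon2)
        assert filled is not None and filled.bits == (0, 1, 1, 1, 0, 1, 0)

    def test_fill_uses_credible_junction_when_better_supported(self, locus):
        p = self.bad_path(locus)
        cov_low_exon2 = [0, 10, 0, 10, 0, 10, 0]
        filled = fill_partial(p, locus["segments"], locus["credible"], cov_low_exon2)
        assert filled is not None and filled.bits == (0, 1, 0, 1, 0, 1, 0)

    def test_unique_filling_when_no_junction_available(self, locus):
        p = self.bad_path(locus)
        credible = frozenset({("chr1", 600, 800, "+")})  # (200,400) removed
        p2 = project_read(
            chain([(50, 203), (400, 600), (800, 901)]), locus["segments"], credible
        )
        filled = fill_partial(p2, locus["segments"], credible)
        assert filled is not None and filled.bits == (0, 1, 1, 1, 0, 1, 0)


class TestAssembleLocus:
    def test_duplicate_reads_collapse(self, locus):
        reads = [
            ("r1", chain([(50, 200), (400, 600), (800, 901)])),
            ("r2", chain([(50, 200), (400, 600), (800, 901)])),
        ]
        genes, counts = assemble_locus(
            locus["group"], locus["tss"], locus["tes"], locus["junctions"], reads
        )
        assert counts["isoF"] == 1
        (gene,) = genes
        (iso,) = gene.isoforms
        assert iso.exons.blocks() == [(50, 200), (400, 600), (800, 901)]

    def test_terminals_anchor_on_summits(self, locus):
        reads = [("r1", chain([(60, 200), (400, 600), (800, 895)]))]
        genes, counts = assemble_locus(
            locus["group"], locus["tss"], locus["tes"], locus["junctions"], reads
        )
        (iso,) = genes[0].isoforms
        assert iso.exons.start == 50 and iso.exons.end == 901

    def test_deterministic(self, locus):
        reads = [
            ("r1", chain([(50, 200), (400, 600), (800, 901)])),
            ("r2", chain([(50, 203), (400, 600), (800, 901)])),
            ("r3", chain([(400, 600), (800, 901)])),
        ]
        def run():
            genes, counts = assemble_locus(
                locus["group"], locus["tss"], locus["tes"], locus["junctions"], reads
            )
            return [
                (iso.exons.blocks(), iso.cls) for g in genes for iso in g.isoforms
            ], counts
        assert run() == run()
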