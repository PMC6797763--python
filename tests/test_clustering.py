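import numpy as np
import pytest

from isoforge import (
    attach_tpm,
    cluster_tags,
    filter_reliable,
    merge_across_samples,
    merge_nearby_for_assembly,
    prune_within,
    select_summit,
)
from conftest import mk_cluster
from oracles import paraclu_oracle


def spans(clusters):
    return sorted((c.interval.start, c.interval.end, c.total) for c in clusters)


class TestClusterTags:
    def test_singleton_above_threshold(self):
        assert spans(cluster_tags({100: 25}, min_value=20)) == [(100, 101, 25)]

    def test_singleton_below_threshold(self):
        assert cluster_tags({100: 10}, min_value=20) == []

    def test_distant_site_splits_off(self):
        got = spans(cluster_tags({100: 30, 101: 30, 500: 30}, max_length=200))
        assert got == [(100, 102, 60), (500, 501, 30)]

    def test_overlong_cluster_rejected(self):
        sig = {p: 30 for p in range(0, 300, 10)}
        for start, end, _ in spans(cluster_tags(sig, max_length=200)):
            assert end - start <= 200

    @pytest.mark.parametrize("bad", [{"min_value": 0}, {"max_length": 0}])
    def test_invalid_thresholds(self, bad):
        with pytest.raises(ValueError):
            cluster_tags({1: 5}, **bad)

    def test_matches_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            n = int(rng.integers(1, 31))
            positions = rng.choice(np.arange(0, 400), size=n, replace=False)
            sig = {int(p): int(rng.integers(1, 41)) for p in positions}
            assert spans(cluster_tags(sig)) == paraclu_oracle(sig)


class TestMergeAcrossSamples:
    def test_overlapping_clusters_union(self):
        a = mk_cluster("TSS", 100, count=30, width=50, sample="A")
        b = mk_cluster("TSS", 140, count=20, width=40, sample="B")
        (m,) = merge_across_samples({"A": [a], "B": [b]})
        assert (m.interval.start, m.interval.end) == (100, 180)
        assert set(m.signal) == {"A", "B"}

    def test_disjoint_clusters_unchanged(self):
        a = mk_cluster("TSS", 100, sample="A")
        b = mk_cluster("TSS", 500, sample="B")
        assert len(merge_across_samples({"A": [a], "B": [b]})) == 2

    def test_chained_overlaps_collapse_to_one(self):
        cs = {
            "A": [mk_cluster("TSS", 100, width=50, sample="A")],
            "B": [mk_cluster("TSS", 140, width=50, sample="B")],
            "C": [mk_cluster("TSS", 180, width=50, sample="C")],
        }
        (m,) = merge_across_samples(cs)
        assert (m.interval.start, m.interval.end) == (100, 230)

    def test_mixed_kinds_rejected(self):
        with pytest.raises(ValueError):
            merge_across_samples(
                {"A": [mk_cluster("TSS", 100)], "B": [mk_cluster("TES", 100)]}
            )

    def test_total_signal_is_conserved(self):
        rng = np.random.default_rng(2)
        per_sample = {}
        total = 0
        for s in ("A", "B", "C"):
            cl = []
            for _ in range(5):
                c = mk_cluster("TES", int(rng.integers(0, 500)), count=int(rng.integers(5, 50)), width=int(rng.integers(1, 30)), sample=s)
                total += c.total
                cl.append(c)
            per_sample[s] = cl
        merged = merge_across_samples(per_sample)
        assert sum(c.total for c in merged) == total


class TestFilterReliable:
    def _cluster(self, tpm, strong_samples):
        c = mk_cluster("TSS", 100)
        c.signal = {f"s{i}": {100: 12} for i in range(strong_samples)}
        c.signal["weak"] = {100: 2}
        c.per_sample_tpm = {s: tpm for s in c.signal}
        return c

    def test_kept_when_both_rules_pass(self):
        assert filter_reliable([self._cluster(0.6, 3)]) != []

    def test_dropped_with_too_few_strong_samples(self):
        assert filter_reliable([self._cluster(0.6, 2)]) == []

    def test_dropped_when_tpm_low_everywhere(self):
        assert filter_reliable([self._cluster(0.4, 3)]) == []

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(8)
        clusters = []
        for i in range(30):
            c = mk_cluster("TSS", i * 10)
            c.signal = {f"s{j}": {i * 10: int(rng.integers(1, 30))} for j in range(4)}
            c.per_sample_tpm = {s: float(rng.uniform(0, 2)) for s in c.signal}
            clusters.append(c)
        base = {id(c) for c in filter_reliable(clusters, 0.5, 10, 2)}
        for kwargs in ({"tpm_min": 1.0}, {"top_signal_min": 20}, {"min_samples": 3}):
            tighter = {
                id(c)
                for c in filter_reliable(
                    clusters,
                    kwargs.get("tpm_min", 0.5),
                    kwargs.get("top_signal_min", 10),
                    kwargs.get("min_samples", 2),
                )
            }
            assert tighter <= base


class TestSummit:
    def test_maximum_wins(self):
        c = mk_cluster("TSS", 100)
        c.signal = {"s": {100: 5, 101: 9}}
        assert select_summit(c) == 101

    def test_tie_breaks_leftmost(self):
        c = mk_cluster("TSS", 100)
        c.signal = {"s": {100: 5, 101: 5}}
        assert select_summit(c) == 100

    def test_singleton(self):
        assert select_summit(mk_cluster("TES", 42)) == 42

    def test_all_zero_is_an_error(self):
        c = mk_cluster("TSS", 100)
        c.signal = {"s": {100: 0}}
        with pytest.raises(ValueError):
            select_summit(c)


class TestAssemblyMerge:
    def test_gap_399_merges(self):
        a = mk_cluster("TSS", 100)  # ends 101
        b = mk_cluster("TSS", 500)  # gap 399
        assert len(merge_nearby_for_assembly([a, b], cutoff=400)) == 1

    def test_gap_400_does_not_merge(self):
        a = mk_cluster("TSS", 100)
        b = mk_cluster("TSS", 501)
        assert len(merge_nearby_for_assembly([a, b], cutoff=400)) == 2

    def test_chain_of_three_single_linkage(self):
        cs = [mk_cluster("TSS", p) for p in (0, 390, 780)]
        (m,) = merge_nearby_for_assembly(cs, cutoff=400)
        assert (m.interval.start, m.interval.end) == (0, 781)

    def test_merged_summit_is_highest_signal_position(self):
        a = mk_cluster("TSS", 100, count=10)
        b = mk_cluster("TSS", 300, count=80)
        (m,) = merge_nearby_for_assembly([a, b], cutoff=400)
        assert m.summit == 300


class TestPruneWithin:
    def test_weaker_of_close_pair_dropped(self):
        a = mk_cluster("TSS", 100, count=100)
        b = mk_cluster("TSS", 130, count=40)
        kept = prune_within([a, b], cutoff=50)
        assert [c.summit for c in kept] == [100]

    def test_distant_pair_kept(self):
        a = mk_cluster("TSS", 100, count=100)
        b = mk_cluster("TSS", 161, count=40)
        assert len(prune_within([a, b], cutoff=50)) == 2

    def test_equal_totals_keep_leftmost(self):
        a = mk_cluster("TSS", 100, count=40)
        b = mk_cluster("TSS", 130, count=40)
        kept = prune_within([a, b], cutoff=50)
        assert [c.summit for c in kept] == [100]


def test_tpm_attachment_uses_library_size():
    c = mk_cluster("TSS", 100, count=50, sample="A")
    attach_tpm([c], {"A": 1_000_000, "B": 500})
    assert c.per_sample_tpm["A"] == pytest.approx(50.0)
    assert c.per_sample_tpm["B"] == 0.0
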