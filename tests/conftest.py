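import numpy as np
import pytest

from isoforge import (
    ErrorRates,
    GenomicInterval,
    SimParams,
    SiteCluster,
    simulate_long_reads,
    simulate_tags_and_junctions,
    simulate_truth,
)
from isoforge.simulate import reads_as_records


def mk_cluster(kind, pos, count=50, chrom="chr1", strand="+", sample="s1", width=1):
    """A site cluster whose summit is at ``pos``."""
    signal = {sample: {pos + i: (count if i == 0 else 1) for i in range(width)}}
    iv = GenomicInterval(chrom, pos, pos + width, strand)
    return SiteCluster(kind, iv, signal)


@pytest.fixture(scope="session")
def small_truth():
    params = SimParams(
        n_genes=12,
        n_switch_genes=1,
        n_apa_genes=1,
        n_apa_small_genes=1,
        n_hotspot_genes=1,
        n_polycistron_genes=1,
        n_microexon_genes=2,
        n_specific_genes=1,
        n_uniform_genes=1,
    )
    return simulate_truth(params, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    reads = simulate_long_reads(small_truth, depth=30, err=ErrorRates(), seed=12)
    tag5, tag3, junctions = simulate_tags_and_junctions(small_truth, seed=13)
    return {
        "truth": small_truth,
        "reads": reads_as_records(reads),
        "tag5": tag5,
        "tag3": tag3,
        "junctions": junctions,
    }


def truth_chain_set(truth):
    return {
        tuple(iso.chain.blocks()) + (iso.chain.strand,)
        for g in truth.genes
        for iso in g.isoforms
    }


def assembled_chain_classes(genes):
    return {
        tuple(iso.exons.blocks()) + (iso.exons.strand,): iso.cls
        for g in genes
        for iso in g.isoforms
    }
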