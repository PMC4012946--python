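import numpy as np
import pytest

from epicmarkers.genome_io import IntronRecord
from epicmarkers.intron_filters import FilterConfig, OrthologousIntronSet

ANCHORS = ("mus", "rat", "cavia", "homo")


@pytest.fixture(scope="session")
def filter_cfg():
    return FilterConfig(anchor_order=ANCHORS)


def make_record(
    species,
    gene="g0",
    idx=1,
    intron="A" * 500,
    up="C" * 100,
    down="G" * 100,
    chrom="chr1",
    start=1000,
    gene_start=0,
    gene_end=5000,
):
    return IntronRecord(
        gene_id=gene,
        species=species,
        intron_index=idx,
        intron_seq=intron,
        upstream_exon_seq=up,
        downstream_exon_seq=down,
        genomic_interval=(chrom, start, start + len(intron)),
        gene_span=(chrom, gene_start, gene_end),
    )


def make_set(
    marker="g0-1",
    lengths=None,
    introns=None,
    flanks=None,
    idx=1,
    ref_interval=None,
):
    """Build a four-species orthologous intron set from per-species intron
    sequences (or plain lengths) and optional (up, down) flank lengths."""
    lengths = lengths or {sp: 500 for sp in ANCHORS}
    records = {}
    for i, sp in enumerate(ANCHORS):
        seq = (
            introns[sp]
            if introns and sp in introns
            else "ACGT" * (lengths[sp] // 4) + "A" * (lengths[sp] % 4)
        )
        up_len, down_len = (flanks or {}).get(sp, (100, 100))
        start = 1000 if (ref_interval is None or i > 0) else ref_interval[1]
        chrom = "chr1" if (ref_interval is None or i > 0) else ref_interval[0]
        records[sp] = make_record(
            sp,
            gene=marker.split("-")[0],
            idx=idx,
            intron=seq,
            up="C" * up_len,
            down="G" * down_len,
            chrom=chrom,
            start=start,
        )
    return OrthologousIntronSet(marker_id=marker, records=records, intron_index=idx)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def sim_dataset():
    """One moderately sized simulated dataset shared across tests."""
    from epicmarkers.simdata import SimulationConfig, simulate_genomes

    return simulate_genomes(SimulationConfig(n_genes=20, seed=7))
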