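import pytest

from l1locus.io_formats import AlignmentRecord, GenomicInterval, TEAnnotationRecord
from l1locus.synthetic_data import SimConfig, build_toy_genome, simulate_reads


def make_element(
    element_id,
    start,
    end,
    strand="+",
    contig="chr1",
    subfamily="L1HS",
):
    return TEAnnotationRecord(
        interval=GenomicInterval(contig, start, end, strand),
        element_id=element_id,
        subfamily=subfamily,
    )


def make_read(
    read_id,
    start,
    length=150,
    contig="chr1",
    flag=0,
    n_hits=1,
    mismatches=0,
    cell_barcode=None,
    umi=None,
):
    return AlignmentRecord(
        read_id=read_id,
        flag=flag,
        interval=GenomicInterval(
            contig, start, start + length, "-" if flag & 0x10 else "+"
        ),
        n_hits=n_hits,
        mismatches=mismatches,
        mapped_length=length,
        cell_barcode=cell_barcode,
        umi=umi,
    )


@pytest.fixture(scope="session")
def default_sim():
    """The default simulated study: 2 samples, 4 clusters (2 L1-active),
    ~200 cells, ~200k single-nucleus reads plus 30k bulk pairs/sample."""
    genome = build_toy_genome(SimConfig(seed=1))
    return simulate_reads(genome)


@pytest.fixture(scope="session")
def default_genome(default_sim):
    return default_sim.genome
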