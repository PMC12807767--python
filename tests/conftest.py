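import numpy as np
import pytest

from actghap.gene_model import GenomicInterval, TranscriptModel, partition_regions
from actghap.synthetic import PanelSpec, make_gene_model, make_panel


@pytest.fixture
def toy_model():
    """Two-exon coding gene: exons 1-based [100,139] and [200,239],
    CDS [120,139] + [200,219], + strand."""
    return TranscriptModel(
        gene_symbol="TOY1",
        transcript_id="TOYTX1",
        gene_id="TOY1.g",
        contig="chrT",
        strand="+",
        exons=[
            GenomicInterval("chrT", 99, 139),
            GenomicInterval("chrT", 199, 239),
        ],
        cds=[
            GenomicInterval("chrT", 119, 139),
            GenomicInterval("chrT", 199, 219),
        ],
    )


@pytest.fixture
def toy_partition(toy_model):
    return partition_regions(toy_model, flank=50)


@pytest.fixture
def small_gene():
    """Seeded small synthetic coding gene plus reference contig."""
    model, reference = make_gene_model(
        n_exons=3,
        cds_span=90,
        utr_spans=(40, 40),
        seed=11,
        flank=200,
        homopolymers=[("A", 8, "intron")],
    )
    return model, reference


@pytest.fixture
def small_panel(small_gene):
    model, reference = small_gene
    spec = PanelSpec(
        n_haploids=20,
        frequency_spectrum=(0.5, 0.3, 0.2),
        variants_per_level={"A": 1, "C": 1, "T": 1, "G": 1},
        seed=5,
    )
    return make_panel(model, spec, reference, flank=200)


def random_model(rng: np.random.Generator, flank: int = 80):
    """Random small gene model for property tests."""
    n_exons = int(rng.integers(1, 4))
    cds_span = int(rng.integers(4, 20)) * 3
    utr5 = int(rng.integers(5, 25))
    utr3 = int(rng.integers(5, 25))
    strand = "+" if rng.random() < 0.5 else "-"
    coding = rng.random() < 0.8
    return make_gene_model(
        n_exons=n_exons,
        cds_span=cds_span,
        utr_spans=(utr5, utr3),
        strand=strand,
        seed=int(rng.integers(0, 2**31)),
        intron_span=int(rng.integers(20, 40)),
        flank=flank,
        coding=coding,
    )
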