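import numpy as np
import pytest

from haplomosaic import simgenome as sg
from haplomosaic.genome import AnnotatedGenome, GeneModel


@pytest.fixture(scope="session")
def small_config():
    return sg.SimulationConfig(
        seed=7,
        chromosome_lengths={"chr1": 1_000_000},
        genetic_lengths_cm={"chr1": 120.0},
        founders={"A": "Kafir", "B": "Durra", "C": "Caudatum"},
        race_sharing=0.0)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return sg.build_reference(small_config)


@pytest.fixture(scope="session")
def small_landscape(small_config):
    return sg.build_landscape(small_config)


@pytest.fixture(scope="session")
def small_panel(small_config, small_genome, small_landscape):
    return sg.simulate_founder_variants(
        small_genome, small_landscape, small_config.founders,
        small_config.seed, small_config)


def make_toy_gene(chrom_seq, start, orf, strand="+", gene_id="g1",
                  chrom="chr1", utr5=6, utr3=6):
    """Single-exon gene whose CDS is `orf`, written into the sequence.

    Returns (sequence, GeneModel). The ORF is placed on the forward strand
    for '+' and reverse-complemented in place for '-'.
    """
    comp = str.maketrans("ACGT", "TGCA")
    written = orf if strand == "+" else orf.translate(comp)[::-1]
    cds_start = start + utr5
    cds_end = cds_start + len(orf)
    seq = (chrom_seq[:cds_start] + written + chrom_seq[cds_end:])
    gene = GeneModel(gene_id, chrom, strand,
                     exons=[(start, cds_end + utr3)],
                     cds=[(cds_start, cds_end)],
                     utr5=[(start, cds_start)] if strand == "+" else
                          [(cds_end, cds_end + utr3)],
                     utr3=[(cds_end, cds_end + utr3)] if strand == "+" else
                          [(start, cds_start)])
    return seq, gene


@pytest.fixture()
def toy_genome():
    """120-bp chromosome with one plus-strand gene, CDS ATG GCC TAA."""
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=120))
    seq, gene = make_toy_gene(seq, 40, "ATGGCCTAA")
    return AnnotatedGenome({"chr1": seq}, [gene])
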