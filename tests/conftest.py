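import time

import pytest
from Bio.Seq import Seq

from landvar.genome_io import GeneModel, GenomeSequence
from landvar.report import run_synthetic_pipeline
from landvar.synthetic_data import SimulationConfig, simulate

#: 11 codons: ATG GCT TGG GAA AAA CCC GGG TTT CAT TGC TAA (no internal stop)
DEFAULT_CDS = "ATGGCTTGGGAAAAACCCGGGTTTCATTGCTAA"


def build_gene(
    strand: str = "+",
    cds_seq: str = DEFAULT_CDS,
    u5: int = 10,
    split: int = 15,
    intron_len: int = 80,
    u3: int = 10,
    pad: int = 20,
    chrom: str = "chrT",
    gene_id: str = "gT",
) -> tuple[GenomeSequence, GeneModel]:
    """Hand-rolled two-exon gene constructor, independent of the package's
    own simulator: coordinates are derived by explicit piece-wise layout.

    Transcript = u5 x 'C' + cds_seq + u3 x 'A'; the intron (GT..AG) splits
    the CDS after ``split`` coding bases.
    """
    utr5_seq, utr3_seq = "C" * u5, "A" * u3
    exon1_t = utr5_seq + cds_seq[:split]
    exon2_t = cds_seq[split:] + utr3_seq
    intron = "GT" + "T" * (intron_len - 4) + "AG"
    assembled = exon1_t + intron + exon2_t
    glen = len(assembled)
    gene_seq = assembled if strand == "+" else str(Seq(assembled).reverse_complement())
    chrom_seq = "G" * pad + gene_seq + "G" * pad
    start = pad + 1

    def conv(i1: int, i2: int) -> tuple[int, int]:
        if strand == "+":
            return (start + i1, start + i2)
        return (start + glen - 1 - i2, start + glen - 1 - i1)

    e1 = (0, len(exon1_t) - 1)
    e2 = (len(exon1_t) + intron_len, glen - 1)
    c1 = (u5, u5 + split - 1)
    c2 = (len(exon1_t) + intron_len, len(exon1_t) + intron_len + len(cds_seq) - split - 1)
    u5_iv = (0, u5 - 1)
    u3_iv = (c2[1] + 1, glen - 1)
    genome = GenomeSequence({chrom: chrom_seq})
    gene = GeneModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.t1",
        chrom=chrom,
        strand=strand,
        exons=sorted([conv(*e1), conv(*e2)]),
        cds_segments=sorted([conv(*c1), conv(*c2)]),
        utr5=[conv(*u5_iv)],
        utr3=[conv(*u3_iv)],
    )
    return genome, gene


@pytest.fixture(scope="session")
def sim_dataset():
    return simulate(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def pipeline():
    """Full synthetic pipeline at the default study-scale conditions,
    with its wall-clock runtime."""
    t0 = time.time()
    result = run_synthetic_pipeline(SimulationConfig(seed=11))
    return result, time.time() - t0


@pytest.fixture()
def fwd_gene():
    return build_gene("+")


@pytest.fixture()
def rev_gene():
    return build_gene("-")
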