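import numpy as np
import pytest

from harbormine.genome_model import GeneRecord, GenomeAnnotation, GenomeSequence
from harbormine.synthetic_data import SimulationConfig, simulate_dataset


def make_annotation(genes, chrom_lengths=None):
    """GenomeAnnotation from (chrom, start1, end1, gene_id, strand) tuples."""
    recs = [
        GeneRecord(chrom=c, start0=s1 - 1, end0=e1, gene_id=g, strand=st)
        for c, s1, e1, g, st in genes
    ]
    if chrom_lengths is None:
        chrom_lengths = {}
        for r in recs:
            chrom_lengths[r.chrom] = max(chrom_lengths.get(r.chrom, 0), r.end0 + 1000)
    return GenomeAnnotation(genes=recs, chrom_lengths=chrom_lengths)


def random_annotation(rng, max_genes=50, max_chrom_len=100_000, n_chroms=2):
    """Random annotation with overlaps and nesting allowed."""
    genes = []
    lengths = {}
    for ci in range(n_chroms):
        chrom = f"c{ci}"
        L = int(rng.integers(5_000, max_chrom_len))
        lengths[chrom] = L
        n = int(rng.integers(0, max_genes + 1))
        for gi in range(n):
            start0 = int(rng.integers(0, L - 1))
            glen = int(rng.integers(1, min(5_000, L - start0) + 1))
            genes.append(
                GeneRecord(
                    chrom=chrom,
                    start0=start0,
                    end0=start0 + glen,
                    gene_id=f"{chrom}g{gi:03d}",
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
    return GenomeAnnotation(genes=genes, chrom_lengths=lengths)


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study: 2 chromosomes, ~400 genes, 6 libraries,
    8 planted neutral loci, 3 decoys per class, seed 42."""
    return simulate_dataset(SimulationConfig(seed=42))


@pytest.fixture()
def toy_genome():
    """One 2-kb chromosome with a known sequence and two genes."""
    rng = np.random.default_rng(123)
    seq = random_seq(rng, 2000)
    ann = make_annotation(
        [("chr1", 301, 800, "gA", "+"), ("chr1", 1001, 1600, "gB", "-")],
        chrom_lengths={"chr1": 2000},
    )
    return ann, GenomeSequence({"chr1": seq})
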