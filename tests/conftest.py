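import pandas as pd
import pytest

from convergeomics.io import Gene, GenomeAnnotation, OrthologCountMatrix
from convergeomics.simulate import SimulationConfig


@pytest.fixture
def small_config() -> SimulationConfig:
    """A small but fully-featured study: 2 focal + 2 outgroup species."""
    return SimulationConfig(
        n_genes=200,
        outgroup_species=("ferret", "dog"),
        n_convergent_up=20,
        n_convergent_down=20,
        n_hypo_promoters=20,
        n_hyper_promoters=20,
        library_size_range=(80_000, 120_000),
        gene_length_range=(500, 1500),
        cg_only_reports=True,
        seed=1,
    )


@pytest.fixture
def tiny_matrix() -> OrthologCountMatrix:
    """3 genes x 4 samples (2 species), hand-set counts."""
    samples = pd.DataFrame(
        {
            "species": ["panda", "panda", "ferret", "ferret"],
            "tissue": ["stomach"] * 4,
            "group": ["focal", "focal", "outgroup", "outgroup"],
        },
        index=pd.Index(["p1", "p2", "f1", "f2"], name="sample_id"),
    )
    counts = pd.DataFrame(
        [[10, 12, 9, 11], [20, 18, 22, 19], [70, 75, 68, 72]],
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        columns=samples.index,
    )
    lengths = pd.Series([1000, 2000, 7000], index=counts.index, name="length_bp")
    return OrthologCountMatrix(counts=counts, gene_lengths=lengths, samples=samples)


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Two genes on opposite strands with hand-set coordinates."""
    plus = Gene(
        gene_id="gplus", chrom="chr1", strand="+", start=5000, end=7000,
        exons=((5000, 5600), (6200, 7000)),
    )
    minus = Gene(
        gene_id="gminus", chrom="chr1", strand="-", start=10000, end=12000,
        exons=((10000, 10800), (11400, 12000)),
    )
    return GenomeAnnotation(genes=[plus, minus], chrom_sizes={"chr1": 20000})


def make_report(rows, sample_id="s1"):
    """Build a CytosineReport from (chrom, pos, strand, context, mc, uc) tuples."""
    from convergeomics.io import CytosineReport

    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "mc", "uc"])
    return CytosineReport(data=df, sample_id=sample_id)
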