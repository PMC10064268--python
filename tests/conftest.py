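import numpy as np
import pytest

from replitax import synthetic
from replitax.model import GeneRecord, GenomeAssembly, ProteinRecord, Replicon


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_assembly():
    """Two replicons, two genes (one per strand), proteome from table."""
    r1 = Replicon(id="chr", sequence="ATGAAATTTGGGTAA" + "ACGT" * 30)
    r2 = Replicon(id="pA", sequence="GGCC" * 20)
    genes = [
        GeneRecord(gene_id="g1", replicon_id="chr", start=1, end=15, strand="+"),
        GeneRecord(gene_id="g2", replicon_id="pA", start=5, end=16, strand="-"),
    ]
    prot = [
        ProteinRecord(gene_id="g1", aa_sequence="MKFG"),
        ProteinRecord(gene_id="g2", aa_sequence="PGPG"),
    ]
    return GenomeAssembly(strain="toy", replicons=[r1, r2], genes=genes, proteome=prot)


@pytest.fixture(scope="session")
def small_pangenome():
    """3+2 strain pan-genome with known truth, reused by several suites."""
    spec = synthetic.PangenomeSpec(
        n_strains_a=3,
        n_strains_b=2,
        n_core=8,
        n_a_specific=4,
        n_b_specific=4,
        n_cloud=3,
        aa_divergence_within=0.02,
        aa_divergence_between=0.08,
        protein_length=300,
    )
    return synthetic.simulate_pangenome(spec, seed=7)
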