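import numpy as np
import pytest
from hypothesis import settings

from dktax import BuildParams, CodecParams, ErrorModel, build_database, simulate_reads
from dktax.simulate import simulate_taxonomy_and_genomes
from dktax.taxonomy import TaxonomyTree

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ecoli_tree() -> TaxonomyTree:
    """Hand-built Enterobacteriaceae-like subtree with real NCBI taxids:
    Escherichia (coli, albertii), Klebsiella (pneumoniae)."""
    parent = {
        1: 1,
        543: 1,      # Enterobacteriaceae
        561: 543,    # Escherichia
        562: 561,    # E. coli
        208962: 561, # E. albertii
        570: 543,    # Klebsiella
        573: 570,    # K. pneumoniae
    }
    rank = {
        1: "no rank",
        543: "family",
        561: "genus",
        562: "species",
        208962: "species",
        570: "genus",
        573: "species",
    }
    name = {
        1: "root",
        543: "Enterobacteriaceae",
        561: "Escherichia",
        562: "Escherichia coli",
        208962: "Escherichia albertii",
        570: "Klebsiella",
        573: "Klebsiella pneumoniae",
    }
    tree = TaxonomyTree(parent=parent, rank=rank, name=name, root=1)
    tree.validate()
    return tree


@pytest.fixture(scope="session")
def community():
    """10-genus × 2-species synthetic community, 5 kb genomes, 20% of each
    genome shared within its genus."""
    return simulate_taxonomy_and_genomes(
        n_genera=10, species_per_genus=2, genome_length=5000,
        shared_fraction=0.2, seed=101,
    )


@pytest.fixture(scope="session")
def community_params() -> BuildParams:
    return BuildParams(codec=CodecParams(n=10, m=6), x_percent=15.0)


@pytest.fixture(scope="session")
def community_db(community, community_params):
    tree, genomes, seqtax = community
    return build_database(genomes, seqtax, tree, community_params)


@pytest.fixture(scope="session")
def community_reads(community):
    """10 reads per genome, nominal length 1000, 10% uniform errors."""
    tree, genomes, seqtax = community
    model = ErrorModel(rate=0.10, seed=202)
    rng = np.random.default_rng(202)
    reads = []
    for seq_id in sorted(genomes):
        reads.extend(
            simulate_reads(
                genomes[seq_id], 10, 1000, model, rng=rng,
                taxid=seqtax[seq_id], genome_id=seq_id,
            )
        )
    return reads
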