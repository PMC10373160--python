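import pytest

from ksphos import dataset, modeling, synthetic
from ksphos.encoding import load_blosum62
from ksphos.windowing import ResidueClass


@pytest.fixture(scope="session")
def blosum():
    return load_blosum62()


@pytest.fixture(scope="session")
def motif_cluster():
    """A planted-motif cluster: informative positions -5/-3 at
    concentration 0.9, 200 unique positive sites, pipeline negatives."""
    motif = synthetic.make_motif(
        [-5, -3], ResidueClass.ST, concentration=0.9, seed=1
    )
    frag = synthetic.plant_sites(
        motif, n_proteins=100, protein_length=200, sites_per_protein=2, seed=1
    )
    cluster = dataset.assemble_cluster(
        frag.sites,
        frag.proteins,
        cluster_id="PLANTED",
        level="family",
        residue_class=ResidueClass.ST,
        config=dataset.ReductionConfig(seed=1),
    )
    assert isinstance(cluster, dataset.SiteCluster)
    return cluster, frag, motif


@pytest.fixture(scope="session")
def trained_gbtree(motif_cluster):
    cluster, _, _ = motif_cluster
    return modeling.train(cluster, modeling.ModelSpec(algorithm="gbtree", seed=1))
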