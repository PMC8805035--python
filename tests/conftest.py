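import pytest

from mtrscan.forge import ClusterArchitecture, ForgeSpec, forge_genomes


@pytest.fixture(scope="session")
def forged_dataset():
    """A mid-sized forged dataset: 12 genomes, 5 planted clusters (one with
    an accessory omcA and a ccm flank), decoys and MAGs."""
    spec = ForgeSpec(
        n_genomes=12,
        planted_clusters=(
            ClusterArchitecture("C,A,B", (200,), "none", 0),
            ClusterArchitecture("A,B,C", (150,), "none", 2),
            ClusterArchitecture("C,A,B,omcA", (200,), "none", 4),
            ClusterArchitecture("C,A,B,ccmA-I", (180,), "none", 6),
            ClusterArchitecture("B,C,A", (250,), "tandem_tRNA", 9),
        ),
        decoy_rate=0.5,
        metagenome_fraction=0.25,
        seed=42,
    )
    return spec, forge_genomes(spec)
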