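import numpy as np
import pytest

from wzgenefate.simulate import (
    SimulationConfig,
    extract_sequences,
    simulate_coverage_all,
    simulate_expression,
    simulate_genome,
)


@pytest.fixture(scope="session")
def small_config():
    """A compact but complete ZW genome: 2 autosomes + Z + W, short genes."""
    return SimulationConfig(
        seed=7,
        n_autosomes=2,
        chrom_length_bp=60_000,
        genes_per_chromosome=8,
        cds_codons_range=(80, 160),
        exons_per_gene_range=(1, 5),
        n_w_duplicates=12,
        retro_fraction=0.4,
        pseudogene_fraction=0.4,
        target_ds_distribution={"name": "exponential", "mean": 0.25},
        samples_per_sex=3,
        mean_depth_x=20.0,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    genome, genes, truth = simulate_genome(small_config)
    return {"config": small_config, "genome": genome, "genes": genes, "truth": truth}


@pytest.fixture(scope="session")
def small_sequences(small_sim):
    cds_map, prot_map = extract_sequences(small_sim["genome"], small_sim["genes"])
    return cds_map, prot_map


@pytest.fixture(scope="session")
def small_coverage(small_sim):
    tracks, manifest = simulate_coverage_all(small_sim["genome"], small_sim["config"])
    return tracks, manifest


@pytest.fixture(scope="session")
def small_fpkm(small_sim):
    return simulate_expression(small_sim["genes"], small_sim["truth"], small_sim["config"])


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
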