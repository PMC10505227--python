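import pytest

from breakspan import SimulationConfig, make_genome, simulate_chip_reads


@pytest.fixture(scope="session")
def small_sim():
    """A small deterministic simulated experiment shared across tests."""
    cfg = SimulationConfig(
        seed=11,
        n_contigs=1,
        contig_length=200_000,
        n_sites=40,
        min_site_spacing=4000,
        reads_per_site_mean=80,
        spanning_fraction=0.3,
        background_rate=0.2,
        n_promoters=3,
        promoter_reads_mean=30,
    )
    ref, sites = make_genome(cfg)
    reads, truth = simulate_chip_reads(ref, sites, cfg)
    return cfg, ref, sites, reads, truth
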