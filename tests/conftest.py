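import pytest

from mlpaseq.simulate import SimulationConfig, simulate_design, table1_design


@pytest.fixture(scope="session")
def small_design():
    """3 target genes x 4 exons x 2 probes (one per mix) + 4 reference genes."""
    return simulate_design(
        n_genes=3, exons_per_gene=4, probes_per_exon=2, n_reference=4, seed=101
    )


@pytest.fixture(scope="session")
def amp_design():
    """Small panel including an amplification-assayed gene."""
    return simulate_design(
        n_genes=2, exons_per_gene=3, probes_per_exon=2, n_reference=4,
        n_amplification=1, seed=202,
    )


@pytest.fixture(scope="session")
def table1():
    return table1_design(seed=7)


@pytest.fixture()
def noiseless_config():
    """Deterministic generator: no noise, no Poisson, unit efficiencies."""
    return SimulationConfig(
        seed=0, probe_noise_sd=0.0, probe_efficiency_spread=0.0, poisson=False
    )
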