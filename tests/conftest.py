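import pytest

from domseln import synthetic_data as sd
from domseln import variant_classify as vc


@pytest.fixture(scope="session")
def small_sim_config():
    return sd.SimConfig(n_genes=40, theta=0.03, seed=11)


@pytest.fixture(scope="session")
def small_proteome(small_sim_config):
    return sd.generate_proteome(small_sim_config)


@pytest.fixture(scope="session")
def small_variants(small_proteome, small_sim_config):
    return sd.simulate_variants(small_proteome, small_sim_config)


@pytest.fixture(scope="session")
def small_classified(small_proteome, small_variants):
    variants, _ = small_variants
    classified, qc = vc.classify_variants(
        list(small_proteome.coding.values()), small_proteome.partitions, variants
    )
    return classified, qc
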