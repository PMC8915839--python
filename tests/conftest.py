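import pytest

from medipchip import synthgen
from medipchip.synthgen import NoiseModel


@pytest.fixture(scope="session")
def small_universe():
    return synthgen.generate_universe(n_genes=60, max_probes_per_island=4, seed=7)


@pytest.fixture(scope="session")
def planted_truth(small_universe):
    return synthgen.plant_effects(
        small_universe,
        frac_coupled=0.2,
        frac_meth_only=0.1,
        frac_expr_only=0.1,
        effect_fold=2.0,
        n_categories=10,
        n_enriched=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def noiseless():
    return NoiseModel(log_sigma_signal=0.0, p_detect_fail=0.0)


@pytest.fixture(scope="session")
def noiseless_probes(small_universe, planted_truth, noiseless):
    return synthgen.simulate_methylation_array(
        small_universe, planted_truth, noiseless, seed=2, sex="male"
    )


@pytest.fixture(scope="session")
def noiseless_expression(small_universe, planted_truth, noiseless):
    return synthgen.simulate_expression_array(
        small_universe, planted_truth, noiseless, seed=3, sex="male"
    )
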