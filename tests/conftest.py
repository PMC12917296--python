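import pytest

from rxtraject import GeneratorConfig, generate_population, run_pipeline


@pytest.fixture(scope="session")
def small_sim():
    """A modest synthetic database with ground-truth labels."""
    cfg = GeneratorConfig(n_patients=800, seed=11)
    patients, dispensing, labels = generate_population(cfg)
    return patients, dispensing, labels


@pytest.fixture(scope="session")
def small_pipeline(small_sim):
    patients, dispensing, _labels = small_sim
    return run_pipeline(dispensing, patients)
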