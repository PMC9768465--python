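import pytest

from corrlit import GeneratorConfig, generate_records


@pytest.fixture(scope="session")
def small_literature():
    """A modest synthetic literature with default reporting biases."""
    cfg = GeneratorConfig(n_studies=40, seed=11)
    return generate_records(cfg)


@pytest.fixture(scope="session")
def clean_literature():
    """A synthetic literature with every reporting bias switched off."""
    cfg = GeneratorConfig(
        n_studies=60,
        text_emphasis_odds=1.0,
        misreport_rate=0.0,
        unspecified_rate=0.0,
        seed=5,
    )
    return generate_records(cfg)
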