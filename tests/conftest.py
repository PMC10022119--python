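import pytest

from vaxqc import GeneratorConfig, generate_dataset
from vaxqc.records import CountryAttributes, StudyConfig


@pytest.fixture(scope="session")
def study_config():
    return StudyConfig()


@pytest.fixture(scope="session")
def clean_dataset():
    """Small clean synthetic dataset (no anomalies injected)."""
    cfg = GeneratorConfig(seed=11, n_countries=12, anomaly_rates={})
    ds, _ = generate_dataset(cfg)
    return ds


@pytest.fixture(scope="session")
def injected_dataset():
    """Default-scale dataset with anomalies planted at rate 0.02."""
    cfg = GeneratorConfig(seed=202)
    return generate_dataset(cfg)


@pytest.fixture
def plain_attrs():
    def make(country="AAA", **kw):
        return CountryAttributes(country=country, who_region="AFR", **kw)

    return make
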