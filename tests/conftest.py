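import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from cislnc.simulate import (  # noqa: E402
    TruthConfig,
    generate_annotation,
    generate_expression,
)


@pytest.fixture(scope="session")
def zero_noise_cfg() -> TruthConfig:
    return TruthConfig(seed=11, noise_sd_log2=0.0)


@pytest.fixture(scope="session")
def zero_noise_annotation(zero_noise_cfg):
    return generate_annotation(zero_noise_cfg)


@pytest.fixture(scope="session")
def zero_noise_sim(zero_noise_annotation):
    return generate_expression(zero_noise_annotation)


@pytest.fixture(scope="session")
def noisy_cfg() -> TruthConfig:
    return TruthConfig(seed=7, noise_sd_log2=0.3)


@pytest.fixture(scope="session")
def noisy_sim(noisy_cfg):
    return generate_expression(generate_annotation(noisy_cfg))


@pytest.fixture(scope="session")
def table1():
    from cislnc.io import load_table1

    return load_table1()
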