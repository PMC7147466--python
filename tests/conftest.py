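import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from nhpredict.pipeline import patient_instances, prepare_patient
from nhpredict.synthetic import SimConfig, simulate_patient

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_config() -> SimConfig:
    return SimConfig(n_days=14, seed=42)


@pytest.fixture(scope="session")
def demo_raw(demo_config):
    return simulate_patient(demo_config)


@pytest.fixture(scope="session")
def demo_prepared(demo_raw):
    return prepare_patient("S01", demo_raw)


@pytest.fixture(scope="session")
def demo_instances(demo_prepared):
    return patient_instances(demo_prepared)
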