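import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_study():
    """One paper-default synthetic study shared across tests (seed 1)."""
    from n2oflux import synth

    return synth.generate_study(seed=1)


@pytest.fixture(scope="session")
def default_rates(default_study) -> pd.DataFrame:
    from n2oflux import fluxcalc

    return fluxcalc.rates_from_gas_table(default_study.gas)


@pytest.fixture(scope="session")
def campaign_rates(default_rates) -> pd.DataFrame:
    return default_rates[default_rates["day"].isin((3, 15, 30))]
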