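import numpy as np
import pandas as pd
import pytest

from hydroniche import isotope
from hydroniche.synthetic import generate_true_roots, paper_like_scenario


def make_flat_weather(n_days, precip=None, zero_et=False):
    """Constant synthetic forcing; ``zero_et`` makes ET0 exactly zero."""
    return pd.DataFrame(
        {
            "date": pd.date_range("2011-01-01", periods=n_days).strftime("%Y-%m-%d"),
            "precip_cm": np.zeros(n_days) if precip is None else np.asarray(precip, float),
            "tmin_C": np.full(n_days, 20.0 if zero_et else 18.0),
            "tmax_C": np.full(n_days, 20.0 if zero_et else 30.0),
            "rh_mean_pct": np.full(n_days, 100.0 if zero_et else 60.0),
            "wind_m_s": np.full(n_days, 0.0 if zero_et else 2.0),
            "solar_MJ_m2": np.full(n_days, 0.0 if zero_et else 24.0),
        }
    )


@pytest.fixture(scope="session")
def scenario():
    return paper_like_scenario()


@pytest.fixture(scope="session")
def tree_roots():
    return generate_true_roots(22.0)


@pytest.fixture()
def flat_weather():
    return make_flat_weather


@pytest.fixture(scope="session")
def campaign_replicates(scenario):
    """Replicate proportions from one synthetic six-depth campaign."""
    from hydroniche.synthetic import simulate_tracer_campaign

    rng = np.random.default_rng(42)
    table = simulate_tracer_campaign(scenario, 0, 0, rng)
    treated, controls = isotope.split_controls(table)
    excess, _raw = isotope.summarize_controls(controls, "water")
    result = isotope.proportional_uptake(
        isotope.add_deuterium_excess(treated), excess
    )
    return result["replicates"]
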