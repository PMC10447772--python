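import numpy as np
import pandas as pd
import pytest

from gunpanel import GeneratorConfig, PanelTable, build_model_data, simulate_panel


@pytest.fixture
def toy_panel_df() -> pd.DataFrame:
    """Balanced 2-state x 2-year panel with hand-friendly numbers."""
    return pd.DataFrame(
        {
            "state": ["A", "A", "B", "B"],
            "year": [2000, 2001, 2000, 2001],
            "deaths": [10, 12, 40, 35],
            "population": [100_000, 100_000, 500_000, 500_000],
            "gun_ownership": [20.0, 24.0, 50.0, 46.0],
            "violent_crime_rate": [300.0, 310.0, 400.0, 390.0],
            "property_crime_rate": [2500.0, 2600.0, 3100.0, 3000.0],
        }
    )


@pytest.fixture
def toy_panel(toy_panel_df) -> PanelTable:
    return PanelTable(toy_panel_df)


@pytest.fixture
def small_sim_panel():
    """A quick 10-state x 6-year synthetic panel plus its truth."""
    return simulate_panel(GeneratorConfig(n_states=10, n_years=6, seed=202))


@pytest.fixture
def small_model_data(small_sim_panel):
    panel, _ = small_sim_panel
    return build_model_data(panel, "mundlak", adjusted=True)


@pytest.fixture
def rng():
    return np.random.default_rng(8675309)
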