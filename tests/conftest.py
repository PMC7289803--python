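import pandas as pd
import pytest

from carnitrack.synth import SimulationConfig, SpeciesParams, simulate


@pytest.fixture(scope="session")
def small_survey():
    """120 units, 10 years, one species with known hurdle parameters."""
    cfg = SimulationConfig(
        n_units=120,
        year_start=2000,
        year_end=2009,
        species_params={
            "lynx": SpeciesParams(
                gamma0=-0.5, gamma_pa=0.5, beta_pa=0.3,
                sigma_b0=0.7, sigma_b1=0.4, sigma=0.7,
            )
        },
        seed=42,
    )
    units, obs = simulate(cfg)
    return cfg, units, obs


@pytest.fixture()
def toy_pairs():
    """Three matched pairs with hand-checkable observation series."""
    pairs = pd.DataFrame(
        {"treated_id": [1, 2, 3], "control_id": [11, 12, 13],
         "distance": 0.0, "propensity_gap": 0.0}
    )
    rows = []
    series = {
        1: {2000: 1.0, 2001: 2.0},
        11: {2000: 0.5, 2001: 1.0},
        2: {2000: 0.0, 2001: 3.0},
        12: {2000: 1.0, 2001: 1.0},
        3: {2000: 4.0, 2001: 0.0},
        13: {2000: 0.0, 2001: 2.0},
    }
    for uid, by_year in series.items():
        for year, val in by_year.items():
            rows.append({"unit_id": uid, "year": year, "species": "wolf", "index": val})
    return pairs, pd.DataFrame(rows)
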