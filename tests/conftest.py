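import dataclasses
import datetime as dt

import pytest

from migradar.simulate import (
    ScenarioConfig,
    simulate_season,
    _default_inland_site,
    _default_shoreline_site,
)


def small_scenario(seed: int = 3, nights: int = 8, night_base_rate: float = 80.0,
                   **overrides) -> ScenarioConfig:
    """A scaled-down season: fewer nights and lower intensity than the
    full study so end-to-end tests stay fast."""
    end = dt.date(2014, 4, 23) + dt.timedelta(days=nights - 1)
    shore = dataclasses.replace(_default_shoreline_site(), date_end=end)
    inland = dataclasses.replace(_default_inland_site(), date_end=end)
    overrides.setdefault("hsr_rate_factor", 1.5)
    return ScenarioConfig(
        shoreline_site=shore,
        inland_site=inland,
        night_base_rate=night_base_rate,
        seed=seed,
        **overrides,
    )


@pytest.fixture(scope="session")
def season():
    """One small simulated season shared across tests (read-only)."""
    cfg = small_scenario()
    vsr, hsr, truth = simulate_season(cfg)
    return {"config": cfg, "vsr": vsr, "hsr": hsr, "truth": truth}
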