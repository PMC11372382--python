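import numpy as np
import pandas as pd
import pytest

from meanscast import counterfactual, pipeline, synthetic

BUNDLE_SEED = 12345


@pytest.fixture(scope="session")
def mimic_bundle():
    """The 33-country study-topology bundle used across the suite."""
    return synthetic.generate_bundle(synthetic.paper_mimic_config(seed=BUNDLE_SEED))


@pytest.fixture(scope="session")
def forecast_stage(mimic_bundle):
    """(forecast table, ForecastSeries dict, joinpoint table, decision log)."""
    return pipeline.run_forecast_stage(mimic_bundle.panel)


@pytest.fixture(scope="session")
def scenario40(mimic_bundle, forecast_stage):
    _, fc_objs, _, _ = forecast_stage
    b = mimic_bundle
    return pipeline.run_scenario_stage(
        fc_objs, b.panel, b.profiles, b.schedules, b.population,
        b.base_age_rates, b.base_asr,
        counterfactual.ScenarioConfig(threshold=0.40))


class StubForecast:
    """Minimal forecast stand-in for eligibility/scenario algebra tests."""

    def __init__(self, country, sex, years, point, raw_point=None):
        self.country = country
        self.sex = sex
        self.years = np.asarray(years)
        self.point = np.asarray(point, dtype=float)
        self.raw_point = self.point if raw_point is None else np.asarray(raw_point, float)
        self.lo = self.point * 0.9
        self.hi = self.point * 1.1
        self.floored = self.raw_point < 0

    @property
    def has_negative_raw(self):
        return bool((self.raw_point < 0).any())


@pytest.fixture
def stub_forecast():
    return StubForecast


def tiny_population(countries, years=(2019,), count=1e6):
    rows = []
    for c in countries:
        for sex in ("male", "female"):
            for y in years:
                rows.append({"country": c, "sex": sex, "age_group": "0-4",
                             "year": int(y), "count": count})
    return pd.DataFrame(rows)
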