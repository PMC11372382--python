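import numpy as np
import pandas as pd
import pytest

from meanscast import deaths


def _make_tables(m_a, counts_by_year, base_asr, country="XX", sex="male"):
    bands = [f"b{i}" for i in range(len(m_a))]
    age = pd.DataFrame([{"country": country, "sex": sex, "age_group": b, "rate": m}
                        for b, m in zip(bands, m_a)])
    pop = pd.DataFrame([{"country": country, "sex": sex, "age_group": b,
                         "year": y, "count": n}
                        for y, counts in counts_by_year.items()
                        for b, n in zip(bands, counts)])
    basr = pd.DataFrame([{"country": country, "sex": sex, "asr": base_asr}])
    return age, pop, basr


def brute_force_deaths(m_a, counts, asr_t, asr_base):
    """Independent age-by-age loop for deaths under the mirroring assumption."""
    total = 0.0
    for m, n in zip(m_a, counts):
        total += m * (asr_t / asr_base) * n / 100_000.0
    return total


class TestDeathsFromAsr:
    def test_worked_two_band_example(self):
        # m = (10, 50), N = (100000, 50000), ASR ratio 0.9 -> 31.5 deaths
        age, pop, basr = _make_tables([10.0, 50.0], {2021: [100_000, 50_000]}, 5.0)
        factors = deaths.death_factors(age, pop, basr, np.array([2021]))
        rates = pd.DataFrame([{"country": "XX", "sex": "male", "year": 2021,
                               "counterfactual": 4.5}])  # ratio 0.9
        out = deaths.deaths_from_asr(rates, factors)
        assert out["deaths"].iloc[0] == pytest.approx(31.5, abs=1e-9)

    def test_unchanged_asr_and_static_population_gives_constant_deaths(self):
        age, pop, basr = _make_tables([10.0, 20.0],
                                      {y: [1e5, 1e5] for y in (2021, 2022)}, 6.0)
        factors = deaths.death_factors(age, pop, basr, np.array([2021, 2022]))
        rates = pd.DataFrame([{"country": "XX", "sex": "male", "year": y,
                               "counterfactual": 6.0} for y in (2021, 2022)])
        out = deaths.deaths_from_asr(rates, factors)
        assert np.allclose(out["deaths"], 30.0)

    def test_halving_asr_halves_deaths(self):
        age, pop, basr = _make_tables([10.0, 20.0], {2021: [1e5, 1e5]}, 6.0)
        factors = deaths.death_factors(age, pop, basr, np.array([2021]))
        full = deaths.deaths_from_asr(pd.DataFrame(
            [{"country": "XX", "sex": "male", "year": 2021, "counterfactual": 6.0}]),
            factors)["deaths"].iloc[0]
        half = deaths.deaths_from_asr(pd.DataFrame(
            [{"country": "XX", "sex": "male", "year": 2021, "counterfactual": 3.0}]),
            factors)["deaths"].iloc[0]
        assert half == pytest.approx(full / 2)

    def test_zero_base_asr_rejected(self):
        age, pop, basr = _make_tables([10.0], {2021: [1e5]}, 0.0)
        with pytest.raises(ValueError, match="zero base-year ASR"):
            deaths.death_factors(age, pop, basr, np.array([2021]))

    def test_agrees_with_age_loop_oracle_on_random_tables(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            n_bands = int(rng.integers(2, 6))
            m_a = rng.uniform(0.5, 80, n_bands)
            counts = rng.uniform(1e3, 1e6, n_bands)
            asr_base = float(rng.uniform(1, 30))
            asr_t = float(rng.uniform(0.1, 40))
            age, pop, basr = _make_tables(list(m_a), {2021: list(counts)}, asr_base)
            factors = deaths.death_factors(age, pop, basr, np.array([2021]))
            got = deaths.deaths_from_asr(pd.DataFrame(
                [{"country": "XX", "sex": "male", "year": 2021,
                  "counterfactual": asr_t}]), factors)["deaths"].iloc[0]
            want = brute_force_deaths(m_a, counts, asr_t, asr_base)
            assert got == pytest.approx(want, rel=1e-9)


class TestAvoided:
    def _series(self, values):
        return pd.DataFrame([{"country": "XX", "sex": "male", "year": 2020 + i,
                              "deaths": v} for i, v in enumerate(values, start=1)])

    def test_identical_series_gives_zero(self):
        base = self._series([100] * 10)
        out = deaths.avoided_deaths(base, base.copy())
        assert (out["avoided"] == 0).all()

    def test_constant_reduction_cumulates(self):
        out = deaths.avoided_deaths(self._series([100] * 10), self._series([90] * 10))
        assert out["avoided"].sum() == pytest.approx(-100)

    def test_sign_change_from_substitution_preserved(self):
        base = self._series([100, 100, 100, 100])
        cf = self._series([112, 104, 96, 88])  # substitution first, net benefit later
        out = deaths.avoided_deaths(base, cf).sort_values("year")
        assert (out["avoided"].to_numpy() == pytest.approx([12, 4, -4, -12]))

    def test_misaligned_years_rejected(self):
        base = self._series([100] * 3)
        cf = self._series([90] * 4)
        with pytest.raises(ValueError, match="misaligned"):
            deaths.avoided_deaths(base, cf)


class TestAggregation:
    def _rates(self, values):
        return pd.DataFrame([{"country": c, "sex": "male", "year": 2021,
                              "baseline": v, "counterfactual": v}
                             for c, v in values.items()])

    def _pop(self, weights):
        return pd.DataFrame([{"country": c, "sex": "male", "age_group": "0-4",
                              "year": 2021, "count": w} for c, w in weights.items()])

    def test_equal_weights_give_mean(self):
        out = deaths.aggregate_rates(self._rates({"A": 10, "B": 20}),
                                     self._pop({"A": 1e6, "B": 1e6}),
                                     {"A": "S", "B": "S"})
        assert out.loc[out["scope"] == "S", "baseline"].iloc[0] == pytest.approx(15)

    def test_unequal_weights(self):
        out = deaths.aggregate_rates(self._rates({"A": 10, "B": 20}),
                                     self._pop({"A": 3e6, "B": 1e6}),
                                     {"A": "S", "B": "S"})
        assert out.loc[out["scope"] == "S", "baseline"].iloc[0] == pytest.approx(12.5)

    def test_single_country_scope_is_identity(self):
        out = deaths.aggregate_rates(self._rates({"A": 13.7}), self._pop({"A": 1e6}),
                                     {"A": "S"})
        assert np.allclose(out["baseline"], 13.7)

    def test_aggregate_within_member_range(self, scenario40):
        agg = scenario40["rates_aggregated"]
        rates = scenario40["rates_country"]
        from meanscast import panel_io
        mapping = panel_io.subregion_map()
        by_scope = rates.assign(scope=rates["country"].map(mapping))
        for (scope, sex, year), grp in by_scope.groupby(["scope", "sex", "year"]):
            row = agg[(agg["scope"] == scope) & (agg["sex"] == sex) & (agg["year"] == year)]
            v = row["baseline"].iloc[0]
            assert grp["baseline"].min() - 1e-9 <= v <= grp["baseline"].max() + 1e-9

    def test_unmapped_country_rejected(self):
        with pytest.raises(KeyError, match="without a subregion"):
            deaths.aggregate_rates(self._rates({"A": 10}), self._pop({"A": 1e6}), {})

    def test_region_deaths_additive_over_subregions_and_countries(self, scenario40):
        avoided_country = scenario40["avoided_country"]
        scoped = scenario40["avoided"]
        region = scoped[scoped["scope"] == "Region"]["avoided"].sum()
        subs = scoped[scoped["scope"] != "Region"]["avoided"].sum()
        assert region == pytest.approx(avoided_country["avoided"].sum(), abs=1e-6)
        assert subs == pytest.approx(region, abs=1e-6)
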