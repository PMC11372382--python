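import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from meanscast import counterfactual, synthetic
from meanscast.counterfactual import ScenarioConfig

from conftest import StubForecast, tiny_population

HORIZON = np.arange(2020, 2031)


def _profiles(rows):
    return pd.DataFrame([
        {"country": c, "sex": s, "prop_firearm": pf, "prop_pesticide": pp,
         "reference_year": 2019}
        for c, s, pf, pp in rows
    ])


def _panel_2019(rates):
    rows = []
    for c, (m, f) in rates.items():
        for y in range(2000, 2020):
            rows.append({"country": c, "sex": "male", "year": y, "asr": m})
            rows.append({"country": c, "sex": "female", "year": y, "asr": f})
    return pd.DataFrame(rows)


def _stub_forecasts(rates, negative=()):
    out = {}
    for c, (m, f) in rates.items():
        for sex, level in (("male", m), ("female", f)):
            raw = np.full(11, level - 20.0 if c in negative and sex == "male" else level)
            out[(c, sex)] = StubForecast(c, sex, HORIZON, np.maximum(raw, 0), raw)
    return out


class TestEligibility:
    RATES = {"USA": (20.0, 6.0), "SLV": (10.0, 4.0), "LOW": (2.0, 1.0),
             "NOP": (9.0, 3.0), "NEG": (8.0, 3.0), "MID": (9.0, 3.0)}
    PROFILES = _profiles([
        ("USA", "male", 0.55, 0.01), ("USA", "female", 0.31, 0.02),
        ("SLV", "male", 0.10, 0.30), ("SLV", "female", 0.03, 0.42),
        ("LOW", "male", 0.10, 0.60), ("LOW", "female", 0.05, 0.55),
        ("NEG", "male", 0.05, 0.25), ("NEG", "female", 0.05, 0.30),
        ("MID", "male", 0.06, 0.22), ("MID", "female", 0.04, 0.28),
    ])

    def _run(self, threshold):
        panel = _panel_2019(self.RATES)
        pop = tiny_population(self.RATES)
        fcs = _stub_forecasts(self.RATES, negative={"NEG"})
        return counterfactual.determine_eligibility(
            self.PROFILES, panel, fcs, pop, ScenarioConfig(threshold=threshold))

    def test_threshold_40_restricts_high_proportion_countries(self):
        dec = self._run(0.40)
        assert dec["USA"].decision == "restrict_firearm"
        assert dec["SLV"].decision == "restrict_pesticide"
        assert dec["MID"].decision == "not_eligible"
        assert dec["MID"].reasons == ["below_threshold"]

    def test_low_rate_dominates_even_with_high_proportion(self):
        dec = self._run(0.40)
        assert dec["LOW"].decision == "not_eligible"
        assert dec["LOW"].reasons == ["below_min_rate"]

    def test_missing_profile_blocks_restriction(self):
        dec = self._run(0.40)
        assert dec["NOP"].reasons == ["no_profile"]

    def test_negative_forecast_blocks_at_lower_threshold(self):
        dec = self._run(0.20)
        assert dec["NEG"].decision == "not_eligible"
        assert dec["NEG"].reasons == ["negative_forecast"]
        assert dec["MID"].decision == "restrict_pesticide"

    def test_missing_2019_observation_raises(self):
        panel = _panel_2019(self.RATES)
        panel = panel[~((panel["country"] == "USA") & (panel["year"] == 2019))]
        with pytest.raises(ValueError, match="missing 2019"):
            counterfactual.determine_eligibility(
                self.PROFILES, panel, _stub_forecasts(self.RATES),
                tiny_population(self.RATES), ScenarioConfig())


class TestDecomposeApply:
    @pytest.mark.parametrize("asr,prop,expected", [
        (10.0, 0.4, (4.0, 6.0)),
        (10.0, 0.0, (0.0, 10.0)),
        (0.0, 0.7, (0.0, 0.0)),
    ])
    def test_decompose_arithmetic(self, asr, prop, expected):
        assert counterfactual.decompose_rate(asr, prop) == pytest.approx(expected)

    def test_decompose_rejects_bad_proportion(self):
        with pytest.raises(ValueError):
            counterfactual.decompose_rate(10.0, 1.5)

    def test_unit_rate_ratios_are_identity(self):
        assert counterfactual.apply_restriction(4.0, 6.0, 1.0, 1.0) == pytest.approx(10.0)

    def test_substitution_arithmetic(self):
        assert counterfactual.apply_restriction(4.0, 6.0, 0.5, 1.2) == pytest.approx(9.2)

    def test_substitution_can_exceed_baseline_when_means_rare(self):
        cf = counterfactual.apply_restriction(0.5, 9.5, 0.5, 1.1)
        assert cf == pytest.approx(10.7)
        assert cf > 10.0

    def test_nonpositive_k_rejected(self):
        sched = synthetic.default_true_schedules()
        with pytest.raises(ValueError, match=">= 1"):
            counterfactual.schedule_lookup(sched, "firearm", 0)

    def test_schedule_carries_last_k_forward(self):
        sched = synthetic.default_true_schedules()
        last = counterfactual.schedule_lookup(sched, "firearm", 10)
        beyond = counterfactual.schedule_lookup(sched, "firearm", 25)
        assert beyond["rr_target"] == last["rr_target"]


class TestRunScenario:
    def _inputs(self):
        rates = {"AAA": (10.0, 10.0), "BBB": (8.0, 3.0)}
        profiles = _profiles([
            ("AAA", "male", 0.0, 0.5), ("AAA", "female", 0.0, 0.5),
            ("BBB", "male", 0.1, 0.1), ("BBB", "female", 0.1, 0.1),
        ])
        fcs = _stub_forecasts(rates)
        elig = {"AAA": counterfactual.EligibilityDecision("AAA", "restrict_pesticide",
                                                          ["eligible_pesticide"]),
                "BBB": counterfactual.EligibilityDecision("BBB", "not_eligible",
                                                          ["below_threshold"])}
        return fcs, profiles, elig

    def _schedule(self, rr_target, rr_other):
        rows = [("pesticide", k, rr_target, rr_target, rr_target,
                 rr_other, rr_other, rr_other) for k in range(1, 11)]
        from meanscast import panel_io
        return pd.DataFrame(rows, columns=panel_io.SCHEDULE_COLUMNS)

    def test_unit_schedule_reproduces_baseline_everywhere(self):
        fcs, profiles, elig = self._inputs()
        cf = counterfactual.run_scenario(fcs, profiles, self._schedule(1.0, 1.0),
                                         elig, ScenarioConfig())
        assert np.allclose(cf["counterfactual"], cf["baseline"])

    def test_constant_baseline_known_reduction(self):
        fcs, profiles, elig = self._inputs()
        cf = counterfactual.run_scenario(fcs, profiles, self._schedule(0.8, 1.0),
                                         elig, ScenarioConfig())
        aaa = cf[(cf["country"] == "AAA") & (cf["year"] > 2020)]
        # p = 0.5: cf = 10 * (0.5*0.8 + 0.5*1.0) = 9.0 every post year
        assert np.allclose(aaa["counterfactual"], 9.0)
        bbb = cf[cf["country"] == "BBB"]
        assert np.allclose(bbb["counterfactual"], bbb["baseline"])

    def test_decomposition_conserves_baseline(self):
        fcs, profiles, elig = self._inputs()
        cf = counterfactual.run_scenario(fcs, profiles, self._schedule(0.7, 1.1),
                                         elig, ScenarioConfig())
        r = cf[cf["restricted"]]
        assert np.allclose(r["means_rate"] + r["other_rate"], r["baseline"], atol=1e-9)

    def test_missing_schedule_for_granted_means_raises(self):
        fcs, profiles, elig = self._inputs()
        sched = self._schedule(0.8, 1.0)
        sched = sched[sched["means"] != "pesticide"]
        with pytest.raises(KeyError, match="pesticide"):
            counterfactual.run_scenario(fcs, profiles, sched, elig, ScenarioConfig())

    def test_lowering_rr_target_never_raises_counterfactual(self):
        fcs, profiles, elig = self._inputs()
        hi = counterfactual.run_scenario(fcs, profiles, self._schedule(0.9, 1.05),
                                         elig, ScenarioConfig())
        lo = counterfactual.run_scenario(fcs, profiles, self._schedule(0.6, 1.05),
                                         elig, ScenarioConfig())
        assert (lo["counterfactual"] <= hi["counterfactual"] + 1e-12).all()


@settings(max_examples=50, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_eligible_set_monotone_in_threshold(seed):
    """eligible(0.20) is always a superset of eligible(0.40) on random inputs."""
    rng = np.random.default_rng(seed)
    codes = [f"C{i:02d}" for i in range(8)]
    rates = {c: (float(rng.uniform(1, 25)), float(rng.uniform(0.5, 8))) for c in codes}
    prof_rows = []
    for c in codes[:6]:  # last two countries lack profiles
        for s in ("male", "female"):
            pf = float(rng.uniform(0, 0.6))
            pp = float(rng.uniform(0, 1 - pf))
            prof_rows.append((c, s, pf, pp))
    profiles = _profiles(prof_rows)
    negative = {c for c in codes if rng.random() < 0.2}
    panel = _panel_2019(rates)
    pop = tiny_population(rates)
    fcs = _stub_forecasts(rates, negative=negative)
    sets = {}
    for thr in (0.40, 0.20):
        dec = counterfactual.determine_eligibility(
            profiles, panel, fcs, pop, ScenarioConfig(threshold=thr))
        sets[thr] = {c for c, d in dec.items() if d.decision != "not_eligible"}
    assert sets[0.40] <= sets[0.20]
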