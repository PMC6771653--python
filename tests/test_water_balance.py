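import datetime

import numpy as np
import pytest

from cropwater.crop import get_crop
from cropwater.meteorology import SiteInfo
from cropwater.soil import SoilHydraulics
from cropwater.synthetic_weather import climate_preset, generate_weather
from cropwater.water_balance import (
    BalanceOptions,
    DailyState,
    DayForcing,
    IrrigationMethod,
    IrrigationPlan,
    MoistureClass,
    expand_irrigation,
    initial_depletion,
    interception,
    resolve_date_class,
    runoff,
    simulate_season,
    step_day,
    water_stress,
)

from _oracles import step_day_oracle

SOIL = SoilHydraulics(theta_wp=0.10, theta_fc=0.25, theta_sat=0.45)


def make_state(dr, zr=0.5, taw=None, soil=SOIL):
    taw = taw if taw is not None else soil.available_water_capacity * zr * 1000.0
    theta = soil.theta_fc - dr / (zr * 1000.0)
    return DailyState(day_index=0, date=datetime.date(2015, 5, 1), dr=dr,
                      theta=theta, zr=zr, taw=taw, raw=0.5 * taw, kc=1.0,
                      ks=1.0, et0=0.0, etc=0.0, eta=0.0, int_p=0.0,
                      int_i=0.0, ro=0.0, dp=0.0, p=0.0, i=0.0,
                      storage_added=0.0)


class TestConventions:
    @pytest.mark.parametrize("timing,day", [("early", 5), ("mid", 15), ("late", 25)])
    def test_date_classes(self, timing, day):
        assert resolve_date_class(5, 2014, timing) == datetime.date(2014, 5, day)

    def test_invalid_timing_rejected(self):
        with pytest.raises(ValueError):
            resolve_date_class(5, 2014, "sometime")

    @pytest.mark.parametrize("cls,expected", [("high", 0.0), ("mid", 50.0), ("low", 100.0)])
    def test_initial_moisture_classes(self, cls, expected):
        assert initial_depletion(cls, 150.0) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "method,fw,above",
        [("drip", 0.35, False), ("furrow", 0.5, False), ("flood", 1.0, False),
         ("pivot", 1.0, True), ("rain_gun", 1.0, True)],
    )
    def test_method_conventions(self, method, fw, above):
        m = IrrigationMethod(method)
        assert m.wetted_fraction == fw
        assert m.above_canopy is above


class TestExpandIrrigation:
    def test_single_event_on_start_date(self):
        plan = IrrigationPlan(method="flood", total_depth=100.0, n_events=1,
                              start_date=datetime.date(2015, 6, 1),
                              end_date=datetime.date(2015, 7, 1))
        events = expand_irrigation(plan)
        assert len(events) == 1
        assert events[0].date == datetime.date(2015, 6, 1)
        assert events[0].depth == 100.0

    def test_even_spacing_over_period(self):
        plan = IrrigationPlan(method="flood", total_depth=100.0, n_events=5,
                              start_date=datetime.date(2015, 6, 1),
                              end_date=datetime.date(2015, 7, 11))  # 40-day span
        events = expand_irrigation(plan)
        offsets = [(e.date - datetime.date(2015, 6, 1)).days for e in events]
        assert offsets == [0, 10, 20, 30, 40]
        assert all(e.depth == pytest.approx(20.0) for e in events)

    def test_drip_event_flags(self):
        plan = IrrigationPlan(method="drip", total_depth=60.0, n_events=3,
                              start_date=datetime.date(2015, 6, 1),
                              end_date=datetime.date(2015, 6, 21))
        for e in expand_irrigation(plan):
            assert e.above_canopy is False
            assert e.fw == 0.35

    def test_no_depth_means_no_events(self):
        assert expand_irrigation(IrrigationPlan(method="drip")) == []


class TestInterception:
    def test_bare_soil_intercepts_nothing(self):
        assert interception(0.0, 12.0, 5.0) == (0.0, 0.0, 0.0)
        assert interception(3.0, 0.0, 0.0) == (0.0, 0.0, 0.0)

    def test_saturates_at_canopy_capacity(self):
        tot, _, _ = interception(3.0, 1e7, 0.0)
        assert tot == pytest.approx(0.25 * 3.0, rel=1e-5)

    def test_rain_only_day(self):
        tot, int_p, int_i = interception(3.0, 10.0, 0.0)
        # frozen from a one-line evaluation: 0.75 * (1 - 1/(1 + 10/0.75))
        assert tot == pytest.approx(0.6976744186046512, abs=1e-12)
        assert int_p == tot
        assert int_i == 0.0

    def test_partition_follows_relative_fractions(self):
        tot, int_p, int_i = interception(2.0, 6.0, 4.0)
        assert int_p == pytest.approx(0.6 * tot)
        assert int_i == pytest.approx(0.4 * tot)

    def test_never_exceeds_incident_water(self):
        for ptot in (0.01, 0.1, 1.0, 5.0):
            tot, _, _ = interception(4.0, ptot, 0.0)
            assert 0.0 <= tot <= ptot

    def test_cover_fraction_capped_at_full_cover(self):
        # beyond LAI=3 the cover term saturates; interception still grows
        # only through the a*LAI capacity
        tot_lo, _, _ = interception(3.0, 5.0, 0.0)
        tot_hi, _, _ = interception(6.0, 5.0, 0.0)
        assert tot_hi > tot_lo
        assert tot_hi <= 5.0


class TestRunoff:
    def test_wilting_point_sheds_nothing(self):
        assert runoff(20.0, SOIL.theta_wp, SOIL) == 0.0

    def test_saturation_sheds_everything(self):
        assert runoff(20.0, SOIL.theta_sat, SOIL) == pytest.approx(20.0)

    def test_linear_at_midpoint(self):
        theta_mid = 0.5 * (SOIL.theta_wp + SOIL.theta_sat)
        assert runoff(20.0, theta_mid, SOIL) == pytest.approx(10.0)

    def test_exponent_reduces_runoff_below_saturation(self):
        theta_mid = 0.5 * (SOIL.theta_wp + SOIL.theta_sat)
        assert runoff(20.0, theta_mid, SOIL, beta=2.0) == pytest.approx(5.0)


class TestWaterStress:
    def test_unstressed_within_raw(self):
        assert water_stress(0.0, 150.0, 75.0) == 1.0
        assert water_stress(75.0, 150.0, 75.0) == 1.0

    def test_exhausted_storage(self):
        assert water_stress(150.0, 150.0, 75.0) == 0.0

    def test_linear_decline(self):
        assert water_stress(100.0, 150.0, 75.0) == pytest.approx(50.0 / 75.0)


class TestStepDay:
    def forcing(self, **kw):
        base = dict(day_index=1, date=datetime.date(2015, 5, 2), et0=5.0,
                    precip=0.0, irrigation=0.0, irrigation_above=0.0,
                    kc=1.0, zr=0.5, lai=2.0)
        base.update(kw)
        return DayForcing(**base)

    def test_fully_depleted_bucket_stays_put(self):
        taw = SOIL.available_water_capacity * 0.5 * 1000.0
        prev = make_state(dr=taw)
        state = step_day(prev, self.forcing(), SOIL, p_tab=0.5, dr0_rel=1.0)
        assert state.eta == 0.0
        assert state.dr == pytest.approx(taw)
        assert state.ks == 0.0

    def test_tipping_bucket_overflow_drains_same_day(self):
        prev = make_state(dr=10.0)
        state = step_day(prev, self.forcing(precip=50.0, et0=0.0, lai=0.0),
                         SOIL, p_tab=0.5, dr0_rel=0.0)
        assert state.dr == 0.0
        assert state.dp == pytest.approx(50.0 - state.ro - 10.0)
        assert state.eta == 0.0

    def test_root_growth_carries_initial_status(self):
        prev = make_state(dr=37.5, zr=0.5)  # half depleted of 75 mm
        state = step_day(prev, self.forcing(zr=0.6, et0=0.0), SOIL,
                         p_tab=0.5, dr0_rel=0.5)
        added_taw = SOIL.available_water_capacity * 0.1 * 1000.0
        assert state.storage_added == pytest.approx(0.5 * added_taw)
        assert state.dr == pytest.approx(37.5 + 0.5 * added_taw)

    def test_non_finite_forcing_names_the_day(self):
        prev = make_state(dr=10.0)
        with pytest.raises(ValueError, match="2015-05-02"):
            step_day(prev, self.forcing(et0=float("nan")), SOIL, p_tab=0.5, dr0_rel=0.0)

    def test_matches_brute_force_oracle_on_random_states(self):
        """State-for-state agreement with an independently coded day loop."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            wp = rng.uniform(0.05, 0.2)
            fc = wp + rng.uniform(0.05, 0.2)
            sat = fc + rng.uniform(0.05, 0.25)
            soil = SoilHydraulics(theta_wp=wp, theta_fc=fc, theta_sat=sat)
            prev_zr = rng.uniform(0.1, 1.2)
            zr = prev_zr + rng.uniform(0.0, 0.05)
            taw_prev = (fc - wp) * prev_zr * 1000.0
            dr_prev = rng.uniform(0.0, taw_prev)
            prev = make_state(dr=dr_prev, zr=prev_zr, soil=soil)
            i = rng.choice([0.0, rng.uniform(0.0, 40.0)])
            i_above = i if rng.random() < 0.5 else 0.0
            f = self.forcing(
                et0=rng.uniform(0.0, 9.0), precip=rng.choice([0.0, rng.uniform(0.0, 60.0)]),
                irrigation=i, irrigation_above=i_above, kc=rng.uniform(0.1, 1.3),
                zr=zr, lai=rng.uniform(0.0, 6.0),
            )
            p_tab = rng.uniform(0.2, 0.7)
            dr0_rel = rng.uniform(0.0, 1.0)
            state = step_day(prev, f, soil, p_tab=p_tab, dr0_rel=dr0_rel)
            exp = step_day_oracle(dr_prev, prev.theta, prev_zr, zr, f.lai, f.et0,
                                  f.kc, f.precip, f.irrigation, f.irrigation_above,
                                  wp, fc, sat, p_tab, dr0_rel)
            for key in ("dr", "theta", "taw", "raw", "ks", "eta", "etc",
                        "int_p", "int_i", "ro", "dp"):
                assert getattr(state, key) == pytest.approx(exp[key], abs=1e-9), key


class TestSimulateSeason:
    site = SiteInfo(latitude=40.0, elevation=100.0)
    sowing = datetime.date(2015, 4, 15)
    harvest = datetime.date(2015, 8, 22)  # 130 days

    def weather(self, regime="temperate", seed=5, **overrides):
        spec = climate_preset(regime, seed=seed, **overrides)
        return generate_weather(spec, self.sowing, 130)

    def run(self, weather=None, irrigation=None, moisture="mid", crop="maize"):
        return simulate_season(
            weather=weather if weather is not None else self.weather(),
            site=self.site, soil=SOIL, crop=get_crop(crop),
            sowing=self.sowing, harvest=self.harvest,
            moisture_class=moisture, irrigation=irrigation,
        )

    def test_deterministic_reruns_are_bit_identical(self):
        w = self.weather()
        t1 = self.run(weather=w).trace
        t2 = self.run(weather=w).trace
        assert t1.equals(t2)

    def test_daily_heavy_irrigation_removes_stress(self):
        plan = IrrigationPlan(method="flood", total_depth=15.0 * 130, n_events=130,
                              start_date=self.sowing, end_date=self.harvest)
        res = self.run(weather=self.weather("arid"), irrigation=plan)
        t = res.trace
        assert (t["ks"] == 1.0).all()
        assert t["eta"].sum() == t["etc"].sum()

    def test_drought_bounded_by_available_storage(self):
        res = self.run(weather=self.weather("arid", wet_day_prob=0.0), moisture="low")
        t = res.trace
        assert (np.diff(t["dr"]) >= -1e-9).all()
        available = (res.taw0 - res.dr0) + float(
            ((t["zr"].diff().fillna(0.0)) * SOIL.available_water_capacity * 1000.0
             - t["storage_added"]).clip(lower=0.0).sum()
        )
        assert t["eta"].sum() <= available + 1e-6
        # depletion approaches capacity asymptotically; near TAW the daily
        # draw is bounded by the shrinking remainder
        exhausted = t[t["dr"] >= t["taw"] - 0.05]
        assert len(exhausted) > 1
        assert (exhausted["eta"].iloc[1:] <= 0.05).all()

    def test_state_invariants_every_day(self):
        plan = IrrigationPlan(method="rain_gun", total_depth=200.0, n_events=6,
                              start_date=datetime.date(2015, 5, 15),
                              end_date=datetime.date(2015, 7, 25))
        t = self.run(weather=self.weather("arid"), irrigation=plan).trace
        assert ((t["dr"] >= -1e-9) & (t["dr"] <= t["taw"] + 1e-9)).all()
        assert ((t["ks"] >= 0) & (t["ks"] <= 1)).all()
        assert (t["eta"] <= t["etc"] + 1e-12).all()
        for col in ("eta", "ro", "dp", "int_p", "int_i"):
            assert (t[col] >= 0).all()
        assert np.allclose(t["theta"], SOIL.theta_fc - t["dr"] / (t["zr"] * 1000.0))

    def test_mass_balance_closes(self):
        plan = IrrigationPlan(method="pivot", total_depth=180.0, n_events=5,
                              start_date=datetime.date(2015, 5, 15),
                              end_date=datetime.date(2015, 7, 25))
        res = self.run(irrigation=plan)
        assert abs(res.mass_balance_residual()) < 1e-6

    def test_weather_gap_is_reported(self):
        w = self.weather()
        del w[40]
        with pytest.raises(ValueError, match="missing"):
            self.run(weather=[d for d in w])

    def test_event_outside_season_rejected(self):
        plan = IrrigationPlan(method="flood", total_depth=50.0, n_events=2,
                              start_date=datetime.date(2015, 3, 1),
                              end_date=datetime.date(2015, 5, 1))
        with pytest.raises(ValueError, match="outside the growing period"):
            self.run(irrigation=plan)

    def test_more_irrigation_never_reduces_eta(self):
        w = self.weather("arid", seed=13)
        etas = []
        for depth in (0.0, 100.0, 250.0, 500.0):
            plan = None
            if depth > 0:
                plan = IrrigationPlan(method="flood", total_depth=depth, n_events=8,
                                      start_date=datetime.date(2015, 5, 1),
                                      end_date=datetime.date(2015, 8, 1))
            etas.append(self.run(weather=w, irrigation=plan).trace["eta"].sum())
        assert all(b >= a - 1e-9 for a, b in zip(etas, etas[1:]))

    def test_wetter_start_never_reduces_eta(self):
        w = self.weather("arid", seed=19)
        eta = {m: self.run(weather=w, moisture=m).trace["eta"].sum()
               for m in ("high", "mid", "low")}
        assert eta["high"] >= eta["mid"] - 1e-9 >= eta["low"] - 2e-9
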