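"""Village demography: competition law, alpha driver, schedules, regulation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pmbpop.synthetic import RainSeries, gen_rainfall
from pmbpop.village import (
    CarryingCapacityDriver,
    ReleaseSchedule,
    VillageConfig,
    VillageSimulation,
    alpha_series,
    calibrate_alpha,
    competition_daily_survival,
    make_schedule,
    run_village,
)


def test_competition_survival_closed_forms():
    assert competition_daily_survival(0, 1000.0) == 1.0
    assert competition_daily_survival(1000, 1000.0) == pytest.approx(2 ** (-0.1), rel=1e-12)
    with pytest.raises(ValueError):
        competition_daily_survival(10, 0.0)
    with pytest.raises(ValueError):
        competition_daily_survival(-1, 10.0)


@given(
    j=st.integers(min_value=0, max_value=10_000_000),
    alpha=st.floats(min_value=1.0, max_value=1e6),
)
def test_ten_day_composition_law(j, alpha):
    """Daily competition survival composes to alpha/(alpha+J) over development."""
    daily = competition_daily_survival(j, alpha, development_days=10)
    assert daily**10 == pytest.approx(alpha / (alpha + j), rel=1e-12)
    # and at J = alpha the cumulative competition death probability is one half
    assert 1 - competition_daily_survival(alpha, alpha) ** 10 == pytest.approx(
        0.5, rel=1e-9
    )


def test_alpha_series_dry_floor_and_linearity():
    driver = CarryingCapacityDriver(
        water_course_length_km=2.0, rain_coefficient=0.5, global_scale=100.0
    )
    dry = RainSeries(day=np.arange(0, 70, 7), mm=np.zeros(10))
    alpha = alpha_series(dry, driver)
    assert np.allclose(alpha, 100.0 * 2.0)  # constant water-course floor
    wet = RainSeries(day=np.arange(0, 70, 7), mm=np.full(10, 10.0))
    doubled = RainSeries(day=np.arange(0, 70, 7), mm=np.full(10, 20.0))
    a1 = alpha_series(wet, driver) - alpha
    a2 = alpha_series(doubled, driver) - alpha
    assert np.allclose(a2, 2 * a1)  # rain term exactly linear
    with pytest.raises(ValueError):
        alpha_series(dry, driver, n_days=1000)  # rainfall span too short


def test_alpha_peak_lags_rain_peak_within_trailing_window():
    driver = CarryingCapacityDriver(trailing_window=14)
    rain = gen_rainfall(1, noise_cv=0.0)
    alpha = alpha_series(rain, driver)
    rain_peak = int(np.argmax(rain.daily()[:365]))
    alpha_peak = int(np.argmax(alpha[:365]))
    assert 0 <= alpha_peak - rain_peak <= driver.trailing_window


def test_empty_population_is_absorbing():
    config = VillageConfig(init_mated_females=0, init_males=0)
    sim = VillageSimulation(config, alpha=np.full(100, 1e4), rng=0)
    series = sim.run(100)
    assert (series.frame[["females", "males", "juveniles"]] == 0).all().all()


def test_density_independent_juvenile_survival_limit():
    """With no crowding (J << alpha), 10-day juvenile survival -> 0.95**10."""
    config = VillageConfig(init_mated_females=0, init_males=0)
    sim = VillageSimulation(config, alpha=np.full(20, 1e12), rng=1)
    n0 = 400_000
    sim.juveniles[0, 0, 0] = n0
    for _ in range(9):
        sim.step()
    expected = n0 * 0.95**9  # nine thinnings so far, emergence on the tenth
    assert sim.j_total == pytest.approx(expected, rel=0.01)
    before = sim.j_total
    sim.step()
    assert sim.j_total == 0  # cohort emerged (females, stay unmated: no males)
    assert sim._records[-1]["females"] == pytest.approx(before * 0.95 * 0.875, rel=0.02)


def test_transgenics_decay_after_releases_stop():
    config = VillageConfig()
    config.driver.global_scale = 200.0
    schedule = ReleaseSchedule.regular(500, "weekly", start_day=50, horizon_days=100)
    sim = VillageSimulation(config, alpha=np.full(600, 200.0 * 5), schedule=schedule, rng=4)
    series = sim.run(600).frame
    at_stop = series.iloc[160]["transgenic_males"]
    later = series.iloc[400]["transgenic_males"]
    assert at_stop > 0
    assert later < 0.35 * at_stop
    assert series.iloc[599]["transgenic_males"] <= later


def test_make_schedule_equal_cumulative_totals():
    per_quarter = 65_000
    totals = {}
    for interval in ("weekly", "fortnightly", "monthly", "quarterly"):
        schedule = make_schedule(per_quarter, interval)
        totals[interval] = schedule.total
        assert all(day >= 731 for day, _ in schedule.events)
    assert len(set(totals.values())) == 1
    assert totals["weekly"] == 4 * per_quarter
    weekly = make_schedule(per_quarter, "weekly")
    assert weekly.events[0] == (731, 5000)  # 52 weekly events of 65000*4/52
    quarterly = make_schedule(per_quarter, "quarterly")
    assert [n for _, n in quarterly.events] == [65_000] * 4


def test_regulation_recovers_from_one_off_cull():
    """Density dependence compensates a 50% cull within weeks."""
    config = VillageConfig()
    config.driver.global_scale = 2000.0
    rain = gen_rainfall(2, seed=9)
    alpha = alpha_series(rain, config.driver, n_days=640)

    def females_at(day, cull_day=None):
        sim = VillageSimulation(config, alpha, rng=12)
        target = cull_day if cull_day is not None else day
        sim.run(cull_day or day)
        if cull_day is not None:
            sim.juveniles //= 2
            sim.males //= 2
            sim.mated //= 2
            sim.unmated //= 2
            sim.run(day)
        return sim._records[day - 1]["females"]

    baseline = females_at(620)
    culled = females_at(620, cull_day=560)
    assert culled == pytest.approx(baseline, rel=0.10)


def test_calibration_hits_target_and_scale_is_monotone():
    rain = gen_rainfall(3, seed=3, noise_cv=0.0)
    config = VillageConfig()
    result = calibrate_alpha(
        config, rain, target_females=8000, n_replicates=2, seed=5, tol=0.05
    )
    assert result.achieved_females == pytest.approx(8000, rel=0.05)
    # doubling the scale roughly doubles the population (monotone, near-linear)
    from dataclasses import replace

    eval_day = config.burn_in_days + 304
    def run_at(scale):
        cfg = replace(config, driver=replace(config.driver, global_scale=scale))
        s = run_village(cfg, rain, seed=5, n_days=eval_day + 1)
        return float(s.at_day(eval_day)["females"])

    low, high = run_at(result.global_scale), run_at(2 * result.global_scale)
    assert 1.5 * low < high < 2.6 * low
    with pytest.raises(ValueError):
        calibrate_alpha(config, rain, target_females=0)


def test_run_village_deterministic_and_null_release():
    rain = gen_rainfall(1, seed=2)
    config = VillageConfig(burn_in_days=0)
    config.driver.global_scale = 500.0
    a = run_village(config, rain, years=1, seed=8).frame
    b = run_village(config, rain, years=1, seed=8).frame
    assert a.equals(b)
    empty = ReleaseSchedule(events=[], interval="none")
    c = run_village(config, rain, schedule=empty, years=1, seed=8).frame
    assert a.equals(c)
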