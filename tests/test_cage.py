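"""Cage protocol construction, daily stepping, and the mean-field oracle."""

import numpy as np
import pytest

from pmbpop.cage import (
    CageProtocol,
    CageState,
    build_protocol,
    mate_female,
    mean_field_equilibrium,
    run_cage,
    sample_restock,
    step_day,
)
from pmbpop.genetics import BroodCounts, Genotype


def test_trial23_protocol_schedule():
    protocol = build_protocol("trial23", "3:1")
    assert protocol.release_size == 150
    assert [(f, m) for _, f, m in protocol.establishment] == [(50, 50)] * 8
    # twice-weekly additions land on Tuesdays/Fridays over the 4-week build-up
    assert [d for d, *_ in protocol.establishment] == [1, 4, 8, 11, 15, 18, 22, 25]
    assert protocol.release_start_day == 28
    assert not protocol.is_release_day(28)  # a Monday
    assert protocol.is_release_day(29) and protocol.is_release_day(32)
    assert protocol.duration_days == 148  # 4 months of releases after 4 weeks


def test_trial23_control_is_same_establishment_no_releases():
    protocol = build_protocol("trial23", "control")
    assert protocol.establishment == build_protocol("trial23", "3:1").establishment
    assert protocol.release_size == 0
    assert not any(protocol.is_release_day(d) for d in range(protocol.duration_days))


def test_trial1_protocol_schedule():
    protocol = build_protocol("trial1", "1:1")
    assert protocol.establishment[0] == (0, 300, 178)
    assert protocol.stable_init
    sizes = [(f, m) for _, f, m in protocol.establishment[1:]]
    assert sizes == [(60, 60)] * 6 + [(50, 50)] * 6
    assert protocol.release_size == 50
    assert protocol.release_start_day == 42
    assert protocol.duration_days == 102


def test_protocol_yaml_round_trip(tmp_path):
    protocol = build_protocol("trial23", "1:1")
    path = tmp_path / "protocol.yaml"
    protocol.to_yaml(path)
    assert CageProtocol.from_yaml(path) == protocol


def test_run_is_deterministic_under_fixed_seed():
    protocol = build_protocol("trial23", "control")
    a = run_cage(protocol, 11).samples
    b = run_cage(protocol, 11).samples
    assert a.equals(b)


def test_empty_cage_yields_zero_eggs_and_proceeds():
    protocol = build_protocol("trial23", "control")
    protocol.establishment = []
    series = run_cage(protocol, 0)
    assert (series.samples["eggs_laid"] == 0).all()
    assert (series.census["adult_males"] == 0).all()


def test_wildtype_population_is_absorbing_state():
    series = run_cage(build_protocol("trial23", "control"), 5)
    laid = series.samples[series.samples["eggs_laid"] > 0]
    assert (laid["transgene_freq"] == 0).all()
    assert (series.census["transgenic_males"] == 0).all()


def test_restock_never_exceeds_sample_size_or_eggs():
    series = run_cage(build_protocol("trial23", "1:1"), 2)
    s = series.samples
    restocked = s["restock_female"] + s["restock_male"]
    assert (restocked <= np.minimum(100, s["eggs_laid"])).all()
    big = s["eggs_laid"] >= 100
    assert (restocked[big] == 100).all()


def test_mating_is_uniform_over_males(rng):
    males = np.array([1] * 50 + [0] * 50, dtype=np.int8)  # 50 HEMI + 50 WT
    mates = mate_female(10_000, males, rng)
    assert np.mean(mates == 1) == pytest.approx(0.5, abs=0.015)
    assert (mate_female(100, np.zeros(10, np.int8), rng) == 0).all()
    with pytest.raises(ValueError, match="no males"):
        mate_female(1, np.empty(0, np.int8), rng)


def test_unmated_female_retries_next_day(rng):
    protocol = build_protocol("trial23", "control")
    protocol.establishment = [(1, 5, 0), (4, 0, 5)]  # females arrive before males
    state = CageState()
    for _ in range(4):
        step_day(state, protocol, rng)
    assert state.um_geno.size == 5 and state.mf_geno.size == 0
    step_day(state, protocol, rng)  # day 4: males added, backlog mates
    assert state.um_geno.size == 0 and state.mf_geno.size == 5


def test_female_lays_only_from_day_after_mating(rng):
    protocol = build_protocol("trial23", "control")
    protocol.establishment = [(7, 20, 20)]  # a Monday: mate on an oviposition day
    state = CageState()
    samples: list[dict] = []
    for _ in range(8):
        step_day(state, protocol, rng, sample_log=samples)
    day7 = [s for s in samples if s["day"] == 7]
    assert day7[0]["eggs_laid"] == 0  # mated today, eligible tomorrow
    for _ in range(3):
        step_day(state, protocol, rng, sample_log=samples)
    day10 = [s for s in samples if s["day"] == 10]
    assert day10[0]["eggs_laid"] > 0


def test_restock_sampling_exhaustive_and_unbiased(rng):
    pool = BroodCounts(np.array([[50, 50], [0, 0], [0, 0]]))
    assert sample_restock(pool, 100, rng) == pool           # k equals pool
    assert sample_restock(pool, 500, rng) == pool           # undersized pool
    with pytest.raises(ValueError):
        sample_restock(pool, 0, rng)
    # hypergeometric mean: 1000-egg pool at 30% female, k=100
    pool = BroodCounts(np.array([[300, 700], [0, 0], [0, 0]]))
    females = [sample_restock(pool, 100, rng).n_female for _ in range(10_000)]
    assert np.mean(females) == pytest.approx(30.0, abs=0.5)


def test_mean_field_equilibrium_against_quadratic_roots():
    mf = mean_field_equilibrium(200, 0)
    assert (mf.p, mf.female_fraction, mf.transgene_frequency) == (0.0, 0.5, 0.0)
    for O, R, p_expected in [(200, 100, 0.6214), (200, 300, 0.7964)]:
        # independent root: numpy polynomial solver on the same balance equation
        roots = np.roots([0.45 * O, 0.025 * O + R, -R])
        p_root = float(roots[(roots >= 0) & (roots <= 1)][0])
        mf = mean_field_equilibrium(O, R)
        assert mf.p == pytest.approx(p_root, abs=1e-12)
        assert mf.p == pytest.approx(p_expected, abs=5e-4)
        assert mf.female_fraction == pytest.approx(0.5 - 0.45 * p_root, abs=1e-12)
        assert mf.transgene_frequency == pytest.approx(0.5 * p_root, abs=1e-12)
    with pytest.raises(ValueError):
        mean_field_equilibrium(0, 10)


def test_stable_init_population_persists_and_lays(rng):
    series = run_cage(build_protocol("trial1", "control"), 9)
    # 300 pre-mated stable-age females are oviposition-eligible immediately,
    # so the day-0 collection already yields a full laying (~300 x 9 eggs)
    first = series.samples.iloc[0]
    assert first["day"] == 0 and first["eggs_laid"] > 1500
    assert series.census.iloc[0]["adult_males"] == 178
    assert series.census.iloc[0]["adult_females"] == 300
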