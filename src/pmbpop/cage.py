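"""Daily-step stochastic simulation of the 16 m3 large-cage release trials.

The simulated week is anchored so that day 0 is a Monday.  Oviposition (and
hence offspring sampling) happens on Mondays and Thursdays; adult additions —
target-population establishment, restocked offspring and transgenic-male
releases — happen on Tuesdays and Fridays, matching the twice-weekly cadence
of the experiments.

Every adult is tracked individually.  Adults receive a Weibull lifespan at
recruitment and are removed on the first day their age exceeds it.  Unmated
females mate with a male chosen uniformly at random among all living males on
the day of their emergence (all males equally competitive); the mate's
genotype is recorded permanently (single mating) and the female becomes
oviposition-eligible from the following day.  On each oviposition day every
eligible mated female lays a Poisson(9) number of viable eggs; a random
sample of 100 of the day's eggs (multivariate hypergeometric across
genotype-by-sex classes) is kept, survives juvenile development with no
mortality, and joins the adult population 10 days after oviposition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .genetics import (
    DEFAULT_MALE_BIAS,
    BroodCounts,
    Genotype,
    sample_brood,
)
from .lifehistory import LifespanModel, default_lifespans, sample_lifespan

__all__ = [
    "CageProtocol",
    "CageState",
    "CageSeries",
    "MeanFieldEquilibrium",
    "build_protocol",
    "step_day",
    "mate_female",
    "sample_restock",
    "run_cage",
    "mean_field_equilibrium",
]

MONDAY, TUESDAY, WEDNESDAY, THURSDAY, FRIDAY = 0, 1, 2, 3, 4
OVIPOSITION_WEEKDAYS = frozenset({MONDAY, THURSDAY})
ADDITION_WEEKDAYS = frozenset({TUESDAY, FRIDAY})

_WT = Genotype.WT.index
_HEMI = Genotype.HEMI.index


def _weekday(day: int) -> int:
    return day % 7


@dataclass
class CageProtocol:
    """Full dated schedule for one cage trial arm.

    ``establishment`` lists (day, n_females, n_males) additions of wild-type
    adults.  If ``stable_init`` is true the day-0 addition represents a draw
    from a pre-existing stable-age population: ages come from the stationary
    residual-lifetime distribution of the Weibull lifespans and the females
    arrive already mated to wild-type males.
    """

    trial_style: str
    treatment: str
    establishment: list[tuple[int, int, int]]
    release_size: int
    release_start_day: int
    duration_days: int
    stable_init: bool = False
    restock_sample_size: int = 100
    development_days: int = 10
    eggs_per_female: float = 9.0
    male_bias: float = DEFAULT_MALE_BIAS
    oviposition_weekdays: frozenset[int] = OVIPOSITION_WEEKDAYS
    addition_weekdays: frozenset[int] = ADDITION_WEEKDAYS
    male_lifespan: LifespanModel = field(default_factory=lambda: default_lifespans()[0])
    female_lifespan: LifespanModel = field(default_factory=lambda: default_lifespans()[1])

    def __post_init__(self) -> None:
        if self.restock_sample_size <= 0:
            raise ValueError("restock_sample_size must be positive")
        if self.development_days < 1:
            raise ValueError("development_days must be >= 1")
        if self.release_size < 0:
            raise ValueError("release_size must be non-negative")

    def is_release_day(self, day: int) -> bool:
        return (
            self.release_size > 0
            and day >= self.release_start_day
            and _weekday(day) in self.addition_weekdays
        )

    def to_yaml(self, path) -> None:
        data = {
            "trial_style": self.trial_style,
            "treatment": self.treatment,
            "establishment": [list(e) for e in self.establishment],
            "release_size": self.release_size,
            "release_start_day": self.release_start_day,
            "duration_days": self.duration_days,
            "stable_init": self.stable_init,
            "restock_sample_size": self.restock_sample_size,
            "development_days": self.development_days,
            "eggs_per_female": self.eggs_per_female,
            "male_bias": self.male_bias,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CageProtocol":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["establishment"] = [tuple(e) for e in data["establishment"]]
        return cls(**data)


_TREATMENT_ALIASES = {
    "control": "control",
    "ratio_1_1": "ratio_1_1",
    "1:1": "ratio_1_1",
    "ratio_3_1": "ratio_3_1",
    "3:1": "ratio_3_1",
}
_RELEASE_SIZES = {"control": 0, "ratio_1_1": 50, "ratio_3_1": 150}


def _addition_days(start_week: int, n_weeks: int) -> list[int]:
    """Tuesday/Friday calendar days for ``n_weeks`` weeks from ``start_week``."""
    days = []
    for week in range(start_week, start_week + n_weeks):
        days.extend([7 * week + TUESDAY, 7 * week + FRIDAY])
    return days


def build_protocol(
    trial_style: str,
    treatment: str,
    release_months_days: int | None = None,
    **overrides,
) -> CageProtocol:
    """Construct the dated protocol for a trial arm.

    trial1: a day-0 draw of 300 females + 178 males from a stable-age
    population, then 60+60 twice weekly for 3 weeks and 50+50 twice weekly
    for 3 weeks; releases start 6 weeks after initiation (day 42) and run for
    2 months.  trial23: 50+50 twice weekly for 4 weeks; releases start after
    4 weeks (day 28) and run for 4 months.  Months are counted as 30 days of
    releases after the first release day (configurable via
    ``release_months_days``).
    """
    treatment = _TREATMENT_ALIASES[treatment]
    release_size = _RELEASE_SIZES[treatment]
    if trial_style == "trial1":
        establishment = [(0, 300, 178)]
        establishment += [(d, 60, 60) for d in _addition_days(0, 3)]
        establishment += [(d, 50, 50) for d in _addition_days(3, 3)]
        release_start = 42
        release_days = release_months_days if release_months_days is not None else 60
        stable_init = True
    elif trial_style == "trial23":
        establishment = [(d, 50, 50) for d in _addition_days(0, 4)]
        release_start = 28
        release_days = release_months_days if release_months_days is not None else 120
        stable_init = False
    else:
        raise ValueError(f"unknown trial_style {trial_style!r}")
    return CageProtocol(
        trial_style=trial_style,
        treatment=treatment,
        establishment=establishment,
        release_size=release_size,
        release_start_day=release_start,
        duration_days=release_start + release_days,
        stable_init=stable_init,
        **overrides,
    )


@dataclass
class CageState:
    """Mutable population bookkeeping for one simulated cage.

    Adults are stored structure-of-arrays.  ``death_day`` is the absolute day
    an individual is removed: for a lifespan ``T`` drawn at recruitment on day
    ``b``, removal happens at the start of day ``b + floor(T) + 1``, the first
    day its age exceeds the drawn lifespan.
    """

    day: int = 0
    # adult males
    male_geno: np.ndarray = field(default_factory=lambda: np.empty(0, np.int8))
    male_death: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    # unmated adult females
    um_geno: np.ndarray = field(default_factory=lambda: np.empty(0, np.int8))
    um_death: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    # mated adult females
    mf_geno: np.ndarray = field(default_factory=lambda: np.empty(0, np.int8))
    mf_mate: np.ndarray = field(default_factory=lambda: np.empty(0, np.int8))
    mf_death: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    mf_mated_day: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    # juvenile cohorts: (emergence_day, BroodCounts)
    cohorts: list[tuple[int, BroodCounts]] = field(default_factory=list)

    @property
    def n_males(self) -> int:
        return self.male_geno.size

    @property
    def n_females(self) -> int:
        return self.um_geno.size + self.mf_geno.size


@dataclass
class CageSeries:
    """Observable output of one cage run.

    ``samples``: one row per oviposition (collection) day with the day's total
    egg count, the restocked sample composition and derived proportions.
    ``census``: daily adult counts.
    """

    samples: pd.DataFrame
    census: pd.DataFrame
    protocol: CageProtocol | None = None
    seed: int | None = None

    def to_csv(self, path) -> None:
        merged = self.samples.merge(self.census, on="day", how="left")
        merged.to_csv(path, index=False)


def _death_days(model: LifespanModel, n: int, birth_day: int, rng) -> np.ndarray:
    lifespans = sample_lifespan(model, rng, size=n)
    return birth_day + np.floor(lifespans).astype(np.int64) + 1


def _stationary_ages(model: LifespanModel, n: int, rng) -> np.ndarray:
    """Sample ages from the stationary age distribution (density prop. to S(a))."""
    grid = np.linspace(0.0, model.scale * 3.0, 2048)
    s = np.exp(-((grid / model.scale) ** model.shape))
    cdf = np.cumsum(s)
    cdf /= cdf[-1]
    u = rng.random(n)
    return np.interp(u, cdf, grid)


def _stationary_death_days(model: LifespanModel, n: int, day: int, rng) -> np.ndarray:
    """Removal days for adults of stationary age alive at ``day``.

    Residual lifetime given age ``a`` uses the conditional Weibull law:
    ``r = scale * ((a/scale)**shape + E)**(1/shape) - a`` with E ~ Exp(1).
    """
    ages = _stationary_ages(model, n, rng)
    e = rng.exponential(size=n)
    total = model.scale * ((ages / model.scale) ** model.shape + e) ** (1.0 / model.shape)
    residual = total - ages
    return day + np.floor(residual).astype(np.int64) + 1


def mate_female(n_new: int, male_geno: np.ndarray, rng) -> np.ndarray:
    """Mate genotypes for ``n_new`` females, each a uniform draw over males.

    All males are equally competitive regardless of genotype or age.  Raises
    if no males are present (callers keep such females unmated and retry the
    next day).
    """
    if male_geno.size == 0:
        raise ValueError("no males present")
    idx = rng.integers(0, male_geno.size, size=n_new)
    return male_geno[idx]


def sample_restock(egg_pool: BroodCounts, k: int, rng) -> BroodCounts:
    """Sample ``min(k, total)`` eggs without replacement from the day's pool."""
    if k <= 0:
        raise ValueError("k must be positive")
    total = egg_pool.total
    if total <= k:
        return BroodCounts(egg_pool.counts.copy())
    flat = egg_pool.counts.reshape(-1)
    sample = rng.multivariate_hypergeometric(flat, k)
    return BroodCounts(sample.reshape(3, 2))


def _add_males(state: CageState, geno: np.ndarray, death: np.ndarray) -> None:
    state.male_geno = np.concatenate([state.male_geno, geno.astype(np.int8)])
    state.male_death = np.concatenate([state.male_death, death])


def _add_unmated(state: CageState, geno: np.ndarray, death: np.ndarray) -> None:
    state.um_geno = np.concatenate([state.um_geno, geno.astype(np.int8)])
    state.um_death = np.concatenate([state.um_death, death])


def step_day(
    state: CageState,
    protocol: CageProtocol,
    rng: np.random.Generator,
    sample_log: list | None = None,
    census_log: list | None = None,
) -> CageState:
    """Advance the cage by one day (mutates and returns ``state``).

    Daily order: deaths; emergences (new females mate immediately); scheduled
    establishment additions and transgenic-male releases (newly added virgin
    females also mate the same day); oviposition and restock sampling on
    Mondays/Thursdays; record observables.
    """
    day = state.day

    # 1. deaths
    keep = state.male_death > day
    state.male_geno, state.male_death = state.male_geno[keep], state.male_death[keep]
    keep = state.um_death > day
    state.um_geno, state.um_death = state.um_geno[keep], state.um_death[keep]
    keep = state.mf_death > day
    state.mf_geno = state.mf_geno[keep]
    state.mf_mate = state.mf_mate[keep]
    state.mf_death = state.mf_death[keep]
    state.mf_mated_day = state.mf_mated_day[keep]

    # 2. emergences
    due = [c for c in state.cohorts if c[0] == day]
    if due:
        state.cohorts = [c for c in state.cohorts if c[0] != day]
        for _, brood in due:
            by_geno = brood.counts
            for g in range(3):
                n_f, n_m = int(by_geno[g, 0]), int(by_geno[g, 1])
                if n_m:
                    _add_males(
                        state,
                        np.full(n_m, g, np.int8),
                        _death_days(protocol.male_lifespan, n_m, day, rng),
                    )
                if n_f:
                    _add_unmated(
                        state,
                        np.full(n_f, g, np.int8),
                        _death_days(protocol.female_lifespan, n_f, day, rng),
                    )

    # 3. scheduled additions and releases
    for add_day, n_f, n_m in protocol.establishment:
        if add_day != day:
            continue
        if protocol.stable_init and add_day == 0:
            # draw from a pre-existing stable-age population: stationary ages,
            # females already mated to wild-type males
            if n_m:
                _add_males(
                    state,
                    np.zeros(n_m, np.int8),
                    _stationary_death_days(protocol.male_lifespan, n_m, day, rng),
                )
            if n_f:
                state.mf_geno = np.concatenate([state.mf_geno, np.zeros(n_f, np.int8)])
                state.mf_mate = np.concatenate([state.mf_mate, np.zeros(n_f, np.int8)])
                state.mf_death = np.concatenate(
                    [state.mf_death, _stationary_death_days(protocol.female_lifespan, n_f, day, rng)]
                )
                state.mf_mated_day = np.concatenate(
                    [state.mf_mated_day, np.full(n_f, -1, np.int64)]
                )
        else:
            if n_m:
                _add_males(
                    state,
                    np.zeros(n_m, np.int8),
                    _death_days(protocol.male_lifespan, n_m, day, rng),
                )
            if n_f:
                _add_unmated(
                    state,
                    np.zeros(n_f, np.int8),
                    _death_days(protocol.female_lifespan, n_f, day, rng),
                )
    if protocol.is_release_day(day):
        n = protocol.release_size
        _add_males(
            state,
            np.full(n, _HEMI, np.int8),
            _death_days(protocol.male_lifespan, n, day, rng),
        )

    # mating: every unmated female (emerged or added today, or left over from
    # a male-less day) picks a uniform random male; single lifetime mating
    if state.um_geno.size and state.male_geno.size:
        mates = mate_female(state.um_geno.size, state.male_geno, rng)
        state.mf_geno = np.concatenate([state.mf_geno, state.um_geno])
        state.mf_mate = np.concatenate([state.mf_mate, mates])
        state.mf_death = np.concatenate([state.mf_death, state.um_death])
        state.mf_mated_day = np.concatenate(
            [state.mf_mated_day, np.full(state.um_geno.size, day, np.int64)]
        )
        state.um_geno = np.empty(0, np.int8)
        state.um_death = np.empty(0, np.int64)

    # 4. oviposition and restock sampling
    if _weekday(day) in protocol.oviposition_weekdays:
        eligible = state.mf_mated_day < day
        pair_code = state.mf_geno[eligible].astype(np.int64) * 3 + state.mf_mate[eligible]
        pair_counts = np.bincount(pair_code, minlength=9)
        pool = BroodCounts.zero()
        for code in np.nonzero(pair_counts)[0]:
            n_females = int(pair_counts[code])
            eggs = int(rng.poisson(protocol.eggs_per_female * n_females))
            pool = pool + sample_brood(
                eggs,
                father=list(Genotype)[code % 3],
                mother=list(Genotype)[code // 3],
                rng=rng,
                male_bias=protocol.male_bias,
            )
        restock = sample_restock(pool, protocol.restock_sample_size, rng)
        if restock.total:
            state.cohorts.append((day + protocol.development_days, restock))
        if sample_log is not None:
            total = restock.total
            sample_log.append(
                {
                    "day": day,
                    "eggs_laid": pool.total,
                    "restock_female": restock.n_female,
                    "restock_male": restock.n_male,
                    "restock_transgenic": restock.n_transgenic,
                    "prop_female": restock.n_female / total if total else math.nan,
                    "transgene_freq": restock.n_transgenic / total if total else math.nan,
                }
            )

    # 5. daily census
    if census_log is not None:
        census_log.append(
            {
                "day": day,
                "adult_males": state.n_males,
                "adult_females": state.n_females,
                "mated_females": state.mf_geno.size,
                "transgenic_males": int((state.male_geno > 0).sum()),
                "transgenic_females": int((state.um_geno > 0).sum() + (state.mf_geno > 0).sum()),
            }
        )

    state.day += 1
    return state


def run_cage(protocol: CageProtocol, seed: int | np.random.Generator) -> CageSeries:
    """Run one full cage trial; deterministic given the seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = CageState()
    samples: list[dict] = []
    census: list[dict] = []
    for _ in range(protocol.duration_days + 1):
        step_day(state, protocol, rng, sample_log=samples, census_log=census)
    return CageSeries(
        samples=pd.DataFrame(samples),
        census=pd.DataFrame(census),
        protocol=protocol,
        seed=seed if isinstance(seed, int) else None,
    )


@dataclass(frozen=True)
class MeanFieldEquilibrium:
    """Deterministic equilibrium approximation of the cage model.

    Used as an independent oracle for ensemble means.  Neglects transgenic
    mothers, homozygotes and age structure.
    """

    p: float
    female_fraction: float
    transgene_frequency: float


def mean_field_equilibrium(
    weekly_offspring: float,
    weekly_release: float,
    male_bias: float = DEFAULT_MALE_BIAS,
) -> MeanFieldEquilibrium:
    """Equilibrium transgenic male fraction under constant weekly flows.

    With O offspring recruited per week, R released males per week, and all
    mothers wild-type, the transgenic fraction p of the male pool satisfies

        (b - 1/2) O p^2 + ((1 - b)/2 O + R) p - R = 0,   b = male_bias,

    which for b = 0.95 is 0.45 O p^2 + (0.025 O + R) p - R = 0.  The offspring
    female fraction is F = 1/2 - (b - 1/2) p and the offspring transgene
    frequency is q = p / 2 (half of a transgenic father's progeny inherit).
    """
    O, R = float(weekly_offspring), float(weekly_release)
    if O <= 0:
        raise ValueError("weekly_offspring must be positive")
    if R < 0:
        raise ValueError("weekly_release must be non-negative")
    b = male_bias
    if R == 0:
        p = 0.0
    else:
        a = (b - 0.5) * O
        bb = (1.0 - b) / 2.0 * O + R
        c = -R
        p = (-bb + math.sqrt(bb * bb - 4.0 * a * c)) / (2.0 * a)
    p = min(max(p, 0.0), 1.0)
    return MeanFieldEquilibrium(
        p=p,
        female_fraction=0.5 - (b - 0.5) * p,
        transgene_frequency=0.5 * p,
    )
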