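"""Daily-step stochastic model of a single village mosquito population.

The demographic core is shared with the cage model (10-day juvenile
development, random mating on the day of emergence, Poisson(9) daily
fecundity, Mendelian genotypes with paternal sex-ratio distortion) but
mortality differs.  Juveniles die from density-independent causes
(probability 0.05 per day) and from larval competition whose daily survival
is (alpha(t) / (alpha(t) + J_T))**(1/10), so the cumulative competition
survival over the 10-day development at fixed crowding is
alpha / (alpha + J_T): alpha(t) is the juvenile count at which the
probability of death from competition over development is one half.  Adults
have constant (age-independent) daily survival: males 0.69-0.87 (mean 0.77,
mark-release-recapture estimates), females 0.875.

alpha(t) tracks rainfall: the default driver is a pluggable linear form,
alpha(t) = c * (L + r * trailing-14-day-mean rainfall), with a water-course
floor L so the dry-season population persists, and a global scale c that is
calibrated against a target unperturbed end-of-rainy-season female count
rather than set a priori.

Simulations run a 2-year burn-in from an arbitrary all-wild-type start before
any releases; hemizygous transgenic males are released on a schedule in the
third year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genetics import DEFAULT_MALE_BIAS, Genotype, sample_brood

__all__ = [
    "CarryingCapacityDriver",
    "VillageConfig",
    "VillageSeries",
    "ReleaseSchedule",
    "VillageSimulation",
    "CalibrationResult",
    "competition_daily_survival",
    "alpha_series",
    "make_schedule",
    "run_village",
    "calibrate_alpha",
]

GENOTYPE_LIST = list(Genotype)
_HEMI = Genotype.HEMI.index

SEASON_END_DAY = 304   # Oct 31: default "end of rainy season" day-of-year
YEAR_END_DAY = 365

INTERVAL_DAYS = {"weekly": 7, "fortnightly": 14, "monthly": 28, "quarterly": 91}


def competition_daily_survival(j_total: float, alpha: float, development_days: int = 10) -> float:
    """Daily survival from larval competition at crowding ``j_total``.

    Composing this over the ``development_days`` of development at fixed
    crowding gives cumulative competition survival alpha / (alpha + J_T).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if j_total < 0:
        raise ValueError("j_total must be non-negative")
    return (alpha / (alpha + j_total)) ** (1.0 / development_days)


@dataclass
class CarryingCapacityDriver:
    """Rainfall-to-carrying-capacity link alpha(t).

    Default form: ``alpha(t) = global_scale * (water_course_length_km +
    rain_coefficient * mean rainfall over the trailing window)``.  The
    water-course term keeps alpha positive through the dry season; the rain
    term makes alpha strictly increasing in trailing rainfall.  ``global_scale``
    carries the units (juveniles per km-equivalent) and is normally set by
    :func:`calibrate_alpha`.
    """

    water_course_length_km: float = 2.0
    rain_coefficient: float = 0.5
    trailing_window: int = 14
    global_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.water_course_length_km <= 0 or self.global_scale <= 0:
            raise ValueError("driver must yield strictly positive alpha")
        if self.rain_coefficient < 0 or self.trailing_window < 1:
            raise ValueError("invalid driver parameters")

    def alpha_from_daily_rain(self, daily_rain: np.ndarray) -> np.ndarray:
        trailing = (
            pd.Series(np.asarray(daily_rain, dtype=float))
            .rolling(self.trailing_window, min_periods=1)
            .mean()
            .to_numpy()
        )
        return self.global_scale * (
            self.water_course_length_km + self.rain_coefficient * trailing
        )


def alpha_series(rainfall, driver: CarryingCapacityDriver, n_days: int | None = None) -> np.ndarray:
    """Daily alpha(t) from a rainfall series (weekly series repeat per day)."""
    daily = rainfall.daily()
    if n_days is not None:
        if daily.size < n_days:
            raise ValueError(
                f"rainfall covers {daily.size} days but {n_days} are required"
            )
        daily = daily[:n_days]
    return driver.alpha_from_daily_rain(daily)


@dataclass
class VillageConfig:
    """Parameters of the village demographic model (rates per day)."""

    di_juvenile_mortality: float = 0.05
    development_days: int = 10
    eggs_per_day: float = 9.0
    male_daily_survival: float = 0.77
    female_daily_survival: float = 0.875
    male_bias: float = DEFAULT_MALE_BIAS
    burn_in_days: int = 730
    driver: CarryingCapacityDriver = field(default_factory=CarryingCapacityDriver)
    # arbitrary all-wild-type start, erased by the burn-in
    init_mated_females: int = 1000
    init_males: int = 1000

    def __post_init__(self) -> None:
        for p in (
            self.di_juvenile_mortality,
            self.male_daily_survival,
            self.female_daily_survival,
        ):
            if not 0.0 < p < 1.0:
                raise ValueError("daily probabilities must lie in (0, 1)")
        if self.development_days < 1:
            raise ValueError("development_days must be >= 1")


@dataclass
class ReleaseSchedule:
    """Dated releases of zero-age hemizygous transgenic males."""

    events: list[tuple[int, int]]
    interval: str = "custom"

    @property
    def total(self) -> int:
        return sum(n for _, n in self.events)

    def by_day(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for day, n in self.events:
            out[day] = out.get(day, 0) + n
        return out

    @classmethod
    def none(cls) -> "ReleaseSchedule":
        return cls(events=[], interval="none")

    @classmethod
    def regular(
        cls, size_per_event: int, interval: str, start_day: int, horizon_days: int = 364
    ) -> "ReleaseSchedule":
        step = INTERVAL_DAYS[interval]
        events = [(d, size_per_event) for d in range(start_day, start_day + horizon_days, step)]
        return cls(events=events, interval=interval)


def make_schedule(
    total_per_quarter: int,
    interval: str,
    start_day: int = 731,
    horizon_days: int = 364,
) -> ReleaseSchedule:
    """Schedule with a fixed cumulative total regardless of release interval.

    The yearly total (4 quarters) is split equally across the interval's
    events; any remainder goes to the final event, so cumulative numbers
    released are identical across weekly/fortnightly/monthly/quarterly
    choices.
    """
    step = INTERVAL_DAYS[interval]
    days = list(range(start_day, start_day + horizon_days, step))
    total_year = 4 * total_per_quarter
    per_event = total_year // len(days)
    sizes = [per_event] * len(days)
    sizes[-1] += total_year - per_event * len(days)
    return ReleaseSchedule(events=list(zip(days, sizes)), interval=interval)


@dataclass
class VillageSeries:
    """Daily totals from one village run."""

    frame: pd.DataFrame

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def at_day(self, day: int) -> pd.Series:
        return self.frame.set_index("day").loc[day]


class VillageSimulation:
    """Stepping engine for the village model.

    Exposes per-day stepping so experiments (culls, ad-hoc releases) can
    manipulate the state between days.  Counts are aggregated, not
    individual: juveniles by (age 0..9, genotype, sex), adult males and
    unmated females by genotype, mated females by (own genotype, mate
    genotype).  Adult male age is demographically inert under constant daily
    survival, so it is not tracked.
    """

    def __init__(
        self,
        config: VillageConfig,
        alpha: np.ndarray,
        schedule: ReleaseSchedule | None = None,
        rng: np.random.Generator | int | None = None,
    ) -> None:
        self.config = config
        self.alpha = np.asarray(alpha, dtype=float)
        if (self.alpha <= 0).any():
            raise ValueError("alpha(t) must be strictly positive")
        self.releases = (schedule or ReleaseSchedule.none()).by_day()
        self.rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        self.day = 0
        dev = config.development_days
        self.juveniles = np.zeros((dev, 3, 2), dtype=np.int64)
        self.males = np.zeros(3, dtype=np.int64)
        self.unmated = np.zeros(3, dtype=np.int64)
        self.mated = np.zeros((3, 3), dtype=np.int64)      # [own, mate]
        self.mated_new = np.zeros((3, 3), dtype=np.int64)  # mated today; lay from tomorrow
        self._init_population()
        self._records: list[dict] = []

    def _init_population(self) -> None:
        cfg = self.config
        self.mated[0, 0] = cfg.init_mated_females
        self.males[0] = cfg.init_males
        # juveniles proportional to the initial egg flow, split evenly by age/sex
        per_cell = int(cfg.eggs_per_day * cfg.init_mated_females / (2 * cfg.development_days))
        self.juveniles[:, 0, :] = per_cell

    # -- state summaries -------------------------------------------------
    @property
    def j_total(self) -> int:
        return int(self.juveniles.sum())

    @property
    def n_females(self) -> int:
        return int(self.mated.sum() + self.mated_new.sum() + self.unmated.sum())

    @property
    def n_transgenic_females(self) -> int:
        return int(
            self.mated[1:, :].sum() + self.mated_new[1:, :].sum() + self.unmated[1:].sum()
        )

    @property
    def n_transgenic_males(self) -> int:
        return int(self.males[1:].sum())

    def step(self) -> None:
        cfg, rng = self.config, self.rng
        day = self.day
        if day >= self.alpha.size:
            raise ValueError("alpha(t) series does not cover the simulation span")
        alpha = self.alpha[day]

        # 1. juvenile survival (synchronous: crowding is the start-of-day total)
        p_juv = (1.0 - cfg.di_juvenile_mortality) * competition_daily_survival(
            self.j_total, alpha, cfg.development_days
        )
        self.juveniles = rng.binomial(self.juveniles, p_juv)

        # 2. emergence of the oldest cohort; new females mate the same day
        emerging = self.juveniles[-1].copy()
        self.juveniles[1:] = self.juveniles[:-1].copy()
        self.juveniles[0] = 0
        self.males += emerging[:, 1]
        self.unmated += emerging[:, 0]
        n_males = int(self.males.sum())
        if n_males > 0 and self.unmated.sum() > 0:
            probs = self.males / n_males
            for g in range(3):
                if self.unmated[g]:
                    self.mated_new[g] += rng.multinomial(int(self.unmated[g]), probs)
                    self.unmated[g] = 0

        # 3. adult survival (constant daily probabilities)
        self.males = rng.binomial(self.males, cfg.male_daily_survival)
        self.mated = rng.binomial(self.mated, cfg.female_daily_survival)
        self.mated_new = rng.binomial(self.mated_new, cfg.female_daily_survival)
        self.unmated = rng.binomial(self.unmated, cfg.female_daily_survival)

        # 4. releases of zero-age hemizygous males
        released = self.releases.get(day, 0)
        if released:
            self.males[_HEMI] += released

        # 5. oviposition: established mated females lay Poisson(9) each
        for own in range(3):
            for mate in range(3):
                n = int(self.mated[own, mate])
                if not n:
                    continue
                eggs = int(rng.poisson(cfg.eggs_per_day * n))
                brood = sample_brood(
                    eggs,
                    father=GENOTYPE_LIST[mate],
                    mother=GENOTYPE_LIST[own],
                    rng=rng,
                    male_bias=cfg.male_bias,
                )
                self.juveniles[0] += brood.counts

        # females mated today join the laying pool for tomorrow
        self.mated += self.mated_new
        self.mated_new[:] = 0

        self._records.append(
            {
                "day": day,
                "females": self.n_females,
                "transgenic_females": self.n_transgenic_females,
                "males": int(self.males.sum()),
                "transgenic_males": self.n_transgenic_males,
                "juveniles": self.j_total,
                "alpha": alpha,
            }
        )
        self.day += 1

    def run(self, n_days: int) -> VillageSeries:
        for _ in range(n_days - self.day):
            self.step()
        return VillageSeries(frame=pd.DataFrame(self._records))


def run_village(
    config: VillageConfig,
    rainfall,
    schedule: ReleaseSchedule | None = None,
    years: int = 3,
    seed: int | np.random.Generator | None = None,
    n_days: int | None = None,
) -> VillageSeries:
    """Run the village model for ``years`` (burn-in included in the span)."""
    n_days = n_days if n_days is not None else 365 * years
    alpha = alpha_series(rainfall, config.driver, n_days=n_days)
    sim = VillageSimulation(config, alpha, schedule=schedule, rng=seed)
    return sim.run(n_days)


@dataclass
class CalibrationResult:
    global_scale: float
    achieved_females: float
    target_females: float
    n_iterations: int
    driver: CarryingCapacityDriver

    @property
    def relative_error(self) -> float:
        return abs(self.achieved_females - self.target_females) / self.target_females


def calibrate_alpha(
    config: VillageConfig,
    rainfall,
    target_females: int = 35500,
    season_end_day: int = SEASON_END_DAY,
    n_replicates: int = 5,
    tol: float = 0.05,
    seed: int = 0,
    bracket: tuple[float, float] = (10.0, 1e7),
    max_iter: int = 40,
) -> CalibrationResult:
    """Bisection on log global_scale to hit the unperturbed baseline.

    The objective is the mean (over ``n_replicates`` seeded unperturbed runs)
    adult-female count at the end of the rainy season of the release year
    (day ``burn_in_days + season_end_day``), matched to ``target_females``
    within ``tol``.  The same replicate seeds are reused at every iteration so
    the search sees an (almost surely) monotone function of the scale.
    """
    if target_females <= 0:
        raise ValueError("target_females must be positive")
    eval_day = config.burn_in_days + season_end_day
    n_days = eval_day + 1
    seeds = [seed + i for i in range(n_replicates)]

    def measure(scale: float) -> float:
        driver = replace(config.driver, global_scale=scale)
        cfg = replace(config, driver=driver)
        vals = []
        for s in seeds:
            series = run_village(cfg, rainfall, schedule=None, seed=s, n_days=n_days)
            vals.append(float(series.at_day(eval_day)["females"]))
        return float(np.mean(vals))

    lo, hi = bracket
    f_lo, f_hi = measure(lo), measure(hi)
    if not (f_lo < target_females < f_hi):
        raise ValueError(
            "bracket does not enclose the target: "
            f"females({lo:g})={f_lo:g}, females({hi:g})={f_hi:g}, target={target_females}"
        )
    best = (lo, f_lo)
    for it in range(1, max_iter + 1):
        mid = math.exp(0.5 * (math.log(lo) + math.log(hi)))
        f_mid = measure(mid)
        if abs(f_mid - target_females) < abs(best[1] - target_females):
            best = (mid, f_mid)
        if abs(f_mid - target_females) / target_females <= tol:
            driver = replace(config.driver, global_scale=mid)
            return CalibrationResult(mid, f_mid, target_females, it, driver)
        if f_mid < target_females:
            lo = mid
        else:
            hi = mid
    scale, achieved = best
    if abs(achieved - target_females) / target_females <= tol:
        driver = replace(config.driver, global_scale=scale)
        return CalibrationResult(scale, achieved, target_females, max_iter, driver)
    raise RuntimeError(
        f"calibration did not reach {tol:.0%} of target after {max_iter} iterations "
        f"(best: scale={scale:g}, females={achieved:g})"
    )
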