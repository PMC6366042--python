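"""Synthetic inputs: survival-experiment tables, rainfall, observation noise.

Every input the pipeline consumes can be generated here without downloads.
Each generator is deterministic under a fixed seed and records its
distributional assumptions in the returned object's metadata.

The rainfall generator emulates a Burkina Faso-like unimodal wet season
(single Gaussian bump peaking around the start of August, ~60 mm/week at the
peak, ~1 mm/week in the dry season) with multiplicative lognormal noise.  It
is a stand-in for reanalysis rainfall series; it does not reproduce dry
spells, storm clustering, or interannual trends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cage import CageSeries
from .lifehistory import DEFAULT_CENSOR_DAY, DailyDeaths, LifespanModel, sample_lifespan

__all__ = [
    "RainSeries",
    "ObservedSeries",
    "gen_survival_experiment",
    "gen_rainfall",
    "gen_observed_series",
]


@dataclass
class RainSeries:
    """Rainfall depths at a daily or weekly cadence.

    ``day`` holds the first simulation day each value applies to; weekly
    values are expanded to daily resolution by repetition.
    """

    day: np.ndarray
    mm: np.ndarray
    freq: str = "W"  # "W" weekly or "D" daily
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.day = np.asarray(self.day, dtype=int)
        self.mm = np.asarray(self.mm, dtype=float)
        if (self.mm < 0).any():
            raise ValueError("rainfall must be non-negative")
        if self.freq not in ("W", "D"):
            raise ValueError("freq must be 'W' or 'D'")

    def daily(self) -> np.ndarray:
        if self.freq == "D":
            return self.mm
        return np.repeat(self.mm, 7)

    @property
    def n_days(self) -> int:
        return self.daily().size

    def to_csv(self, path) -> None:
        pd.DataFrame({"day": self.day, "mm": self.mm}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RainSeries":
        frame = pd.read_csv(path)
        day = frame["day"].to_numpy()
        freq = "W" if (day.size > 1 and int(day[1] - day[0]) == 7) else "D"
        return cls(day=day, mm=frame["mm"].to_numpy(), freq=freq)


def gen_rainfall(
    years: int,
    peak_day: int = 213,
    peak_mm: float = 60.0,
    dry_mm: float = 1.0,
    width_days: float = 60.0,
    noise_cv: float = 0.3,
    seed: int | np.random.Generator | None = None,
) -> RainSeries:
    """Weekly synthetic monsoon rainfall for ``years`` years.

    The seasonal mean is a Gaussian bump in day-of-year (wrapped at the year
    boundary) peaking at ``peak_day`` (default Aug 1) with standard deviation
    ``width_days``, riding on a dry-season floor.  Multiplicative lognormal
    noise with coefficient of variation ``noise_cv`` (unit mean) perturbs each
    week independently; ``noise_cv=0`` gives the deterministic, exactly
    periodic profile.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    days = np.arange(0, 365 * years, 7)
    doy = days % 365
    dist = np.minimum(np.abs(doy - peak_day), 365 - np.abs(doy - peak_day))
    mean = dry_mm + (peak_mm - dry_mm) * np.exp(-(dist**2) / (2.0 * width_days**2))
    if noise_cv > 0:
        sigma2 = np.log(1.0 + noise_cv**2)
        noise = rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=days.size)
        mm = np.maximum(mean * noise, 0.0)
    else:
        mm = mean
    return RainSeries(
        day=days,
        mm=mm,
        freq="W",
        metadata={
            "generator": "gen_rainfall",
            "profile": "wrapped Gaussian bump + dry floor, weekly",
            "peak_day": peak_day,
            "peak_mm": peak_mm,
            "dry_mm": dry_mm,
            "width_days": width_days,
            "noise": f"multiplicative lognormal, cv={noise_cv}, unit mean",
        },
    )


def gen_survival_experiment(
    models: tuple[LifespanModel, LifespanModel] | dict[str, LifespanModel],
    cages: int = 12,
    n_per_sex_per_cage: int = 30,
    censor_day: int = DEFAULT_CENSOR_DAY,
    seed: int | np.random.Generator | None = None,
) -> dict[str, DailyDeaths]:
    """Emulate the adult survival experiment: daily death counts per cage.

    Default design: 12 cages each holding 30 males and 30 females, checked
    daily, right-censored at 42 days.  Each adult's lifespan is a Weibull
    draw from its sex's model; a death is counted on the first day the age
    exceeds the lifespan.  Returns pooled per-sex tables with cage-level
    records attached.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(models, dict):
        pairs = list(models.items())
    else:
        male, female = models
        pairs = [("male", male), ("female", female)]
    out: dict[str, DailyDeaths] = {}
    for sex, model in pairs:
        rows = []
        pooled: dict[int, int] = {}
        for cage in range(1, cages + 1):
            lifespans = sample_lifespan(model, rng, size=n_per_sex_per_cage)
            death_days = np.floor(lifespans).astype(int) + 1
            death_days = death_days[death_days <= censor_day]
            days, counts = np.unique(death_days, return_counts=True)
            for d, c in zip(days, counts):
                rows.append({"cage_id": f"cage{cage:02d}", "day": int(d), "deaths": int(c)})
                pooled[int(d)] = pooled.get(int(d), 0) + int(c)
        out[sex] = DailyDeaths(
            deaths_by_day=pooled,
            initial_n=cages * n_per_sex_per_cage,
            censor_day=censor_day,
            sex_label=sex,
            records=pd.DataFrame(rows, columns=["cage_id", "day", "deaths"]),
        )
    return out


@dataclass
class ObservedSeries:
    """Observation-noise-corrupted cage measurements.

    One row per collection day: the egg count, a hatch sample (n eggs
    examined, k hatched) and an offspring screen (n individuals screened, f
    female, g transgenic).  Emulates the experimental measurement design of
    ~200-egg hatch samples and ~100-individual restocking screens.
    """

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = self.frame
        if (f["hatch_k"] > f["hatch_n"]).any():
            raise ValueError("hatched count exceeds hatch sample size")
        if (f["screen_f"] > f["screen_n"]).any() or (f["screen_g"] > f["screen_n"]).any():
            raise ValueError("screen counts exceed screen sample size")

    @property
    def days(self) -> np.ndarray:
        return self.frame["day"].to_numpy()

    def prop_female(self) -> np.ndarray:
        return (self.frame["screen_f"] / self.frame["screen_n"]).to_numpy()

    def transgene_freq(self) -> np.ndarray:
        return (self.frame["screen_g"] / self.frame["screen_n"]).to_numpy()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def gen_observed_series(
    true_series: CageSeries,
    seed: int | np.random.Generator | None = None,
    egg_sample_n: int = 200,
    screen_n: int = 100,
    hatch_rate: float = 0.87,
    overdispersion: float | None = None,
) -> ObservedSeries:
    """Apply binomial observation noise to a simulated cage series.

    The screen of each collection day draws ``screen_n`` individuals
    binomially at the true sample proportions, so the observation model is
    unbiased.  ``hatch_rate`` is a fixed nuisance probability for the hatch
    sample (hatch dynamics are not a model output).  ``overdispersion``, if
    given, is a beta-binomial intra-class correlation rho in (0, 1) applied
    to the screen, anticipating overdispersed field-style data.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for rec in true_series.samples.itertuples():
        p_f = rec.prop_female
        p_g = rec.transgene_freq
        if np.isnan(p_f):
            p_f, p_g = 0.0, 0.0
        if overdispersion:
            rho = overdispersion
            a = (1.0 / rho - 1.0)
            p_f = rng.beta(max(p_f * a, 1e-9), max((1 - p_f) * a, 1e-9))
            p_g = rng.beta(max(p_g * a, 1e-9), max((1 - p_g) * a, 1e-9))
        rows.append(
            {
                "day": rec.day,
                "egg_count": rec.eggs_laid,
                "hatch_n": egg_sample_n,
                "hatch_k": int(rng.binomial(egg_sample_n, hatch_rate)),
                "screen_n": screen_n,
                "screen_f": int(rng.binomial(screen_n, p_f)),
                "screen_g": int(rng.binomial(screen_n, p_g)),
            }
        )
    return ObservedSeries(
        frame=pd.DataFrame(rows),
        metadata={
            "generator": "gen_observed_series",
            "screen_noise": "binomial" if not overdispersion else f"beta-binomial rho={overdispersion}",
            "hatch_rate": hatch_rate,
        },
    )
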