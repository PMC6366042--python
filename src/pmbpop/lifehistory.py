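"""Weibull adult-lifespan models and right-censored fitting from daily counts.

Adult survival in the cage model is age-dependent: each adult receives a
Weibull-distributed lifespan at recruitment.  The survival experiments that
parameterize it record daily death counts per cage until a 42-day censor
point, so the likelihood treats a death during day ``d`` as interval-censored
on ``(d-1, d]`` and adults alive at the censor day as right-censored.

Default models use shape 4.0 for both sexes with scales chosen so the medians
equal the experimental medians of 28 d (males) and 30 d (females); under
shape 4 only ~3% of males and ~7% of females survive to the 42-day censor,
consistent with the near-complete mortality the experiment was run to.

Larval-stage life-table constants measured alongside the adult experiment are
recorded here for the synthetic-data generators; the cage model itself applies
no juvenile mortality (every restocked egg survives to emergence).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "LifespanModel",
    "DailyDeaths",
    "weibull_survival",
    "default_lifespans",
    "sample_lifespan",
    "fit_weibull_censored",
    "read_daily_deaths_csv",
    "write_daily_deaths_csv",
    "LARVAL_MORTALITY",
    "LARVAL_DURATION_MEDIAN_DAYS",
    "PUPAL_MORTALITY",
]

# Immature-stage life-table constants (experimental; used by synthetic data
# generation and documentation, not by the cage model, which assumes all
# restocked juveniles survive).
LARVAL_MORTALITY = 0.085
LARVAL_DURATION_MEDIAN_DAYS = 7.0
PUPAL_MORTALITY = 0.066

DEFAULT_SHAPE = 4.0
DEFAULT_MALE_MEDIAN = 28.0
DEFAULT_FEMALE_MEDIAN = 30.0
DEFAULT_CENSOR_DAY = 42

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class LifespanModel:
    """Weibull lifespan model: S(t) = exp(-(t/scale)**shape)."""

    shape: float
    scale: float
    sex_label: str = ""

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be strictly positive")

    @property
    def median(self) -> float:
        return self.scale * _LN2 ** (1.0 / self.shape)

    @property
    def mean(self) -> float:
        return self.scale * math.gamma(1.0 + 1.0 / self.shape)

    def survival(self, t):
        return weibull_survival(t, self)

    def to_json(self) -> str:
        return json.dumps(
            {"shape": self.shape, "scale": self.scale, "sex_label": self.sex_label}
        )

    @classmethod
    def from_json(cls, text: str) -> "LifespanModel":
        return cls(**json.loads(text))


def weibull_survival(t, model: LifespanModel):
    """Weibull survival function S(t) = exp(-(t/scale)**shape); t in days."""
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("t must be non-negative")
    out = np.exp(-((t / model.scale) ** model.shape))
    return float(out) if out.ndim == 0 else out


def default_lifespans(
    shape: float = DEFAULT_SHAPE,
    male_median: float = DEFAULT_MALE_MEDIAN,
    female_median: float = DEFAULT_FEMALE_MEDIAN,
) -> tuple[LifespanModel, LifespanModel]:
    """Per-sex default models with medians matching the survival experiment.

    The scale is the closed-form inversion of the median:
    ``scale = median / (ln 2)**(1/shape)``.
    """
    male = LifespanModel(shape, male_median / _LN2 ** (1.0 / shape), "male")
    female = LifespanModel(shape, female_median / _LN2 ** (1.0 / shape), "female")
    return male, female


def sample_lifespan(model: LifespanModel, rng: np.random.Generator, size=None):
    """Draw Weibull lifespans (days, continuous) from ``model``."""
    return model.scale * rng.weibull(model.shape, size=size)


@dataclass
class DailyDeaths:
    """Daily death counts for one group (typically one sex, cages pooled).

    ``deaths_by_day`` maps day (1..censor_day) to the number of deaths counted
    on that day; individuals alive at ``censor_day`` are right-censored.
    """

    deaths_by_day: dict[int, int]
    initial_n: int
    censor_day: int = DEFAULT_CENSOR_DAY
    sex_label: str = ""
    records: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.initial_n <= 0:
            raise ValueError("initial_n must be positive")
        if any(d < 1 or d > self.censor_day for d in self.deaths_by_day):
            raise ValueError("death days must lie in 1..censor_day")
        if any(c < 0 for c in self.deaths_by_day.values()):
            raise ValueError("death counts must be non-negative")
        if self.total_deaths > self.initial_n:
            raise ValueError("more deaths than initial individuals")

    @property
    def total_deaths(self) -> int:
        return int(sum(self.deaths_by_day.values()))

    @property
    def survivors_at_censor(self) -> int:
        return self.initial_n - self.total_deaths


def fit_weibull_censored(data: DailyDeaths) -> LifespanModel:
    """Maximum-likelihood Weibull fit to daily-interval death counts.

    A death counted on day ``d`` contributes ``S(d-1) - S(d)`` (the lifespan
    fell somewhere within that day); each survivor at the censor day
    contributes ``S(censor_day)``.  Optimised over (log shape, log scale) with
    Nelder-Mead, which is robust for this smooth two-parameter surface.
    """
    days = np.array(sorted(d for d, c in data.deaths_by_day.items() if c > 0))
    counts = np.array([data.deaths_by_day[d] for d in days], dtype=float)
    if counts.sum() == 0:
        raise ValueError("no events: all individuals censored")
    if len(days) < 2:
        raise ValueError(
            "non-identifiable shape: need at least 2 distinct death days"
        )
    n_cens = data.survivors_at_censor
    censor = float(data.censor_day)

    def nll(params: np.ndarray) -> float:
        shape = math.exp(params[0])
        scale = math.exp(params[1])
        s_hi = np.exp(-(((days - 1) / scale) ** shape))
        s_lo = np.exp(-((days / scale) ** shape))
        p = np.clip(s_hi - s_lo, 1e-300, None)
        ll = float(np.dot(counts, np.log(p)))
        if n_cens:
            ll += n_cens * (-((censor / scale) ** shape))
        return -ll

    # Moment-style start: mean observed death day (interval midpoint) as scale.
    mean_day = float(np.dot(counts, days - 0.5) / counts.sum())
    x0 = np.array([math.log(1.5), math.log(max(mean_day, 1.0))])
    res = optimize.minimize(nll, x0, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    if not res.success:
        raise RuntimeError(f"Weibull fit did not converge: {res.message}")
    shape, scale = math.exp(res.x[0]), math.exp(res.x[1])
    return LifespanModel(shape=shape, scale=scale, sex_label=data.sex_label)


def write_daily_deaths_csv(path, groups: dict[str, DailyDeaths]) -> None:
    """Write per-sex daily death tables to one CSV.

    First line is a ``#`` metadata header (JSON) carrying initial_n per group
    and the censor day; the table has columns cage_id, sex, day, deaths.
    Groups without cage-level records are written with cage_id 'pooled'.
    """
    meta = {
        "initial_n": {sex: g.initial_n for sex, g in groups.items()},
        "censor_day": next(iter(groups.values())).censor_day,
    }
    frames = []
    for sex, g in groups.items():
        if g.records is not None:
            frames.append(g.records.assign(sex=sex))
        else:
            frames.append(
                pd.DataFrame(
                    {
                        "cage_id": "pooled",
                        "sex": sex,
                        "day": list(g.deaths_by_day),
                        "deaths": list(g.deaths_by_day.values()),
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)[["cage_id", "sex", "day", "deaths"]]
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        table.to_csv(fh, index=False)


def read_daily_deaths_csv(path) -> dict[str, DailyDeaths]:
    """Read a CSV written by :func:`write_daily_deaths_csv`."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("missing metadata header line")
        meta = json.loads(header.lstrip("# ").strip())
        table = pd.read_csv(fh)
    out: dict[str, DailyDeaths] = {}
    for sex, group in table.groupby("sex"):
        pooled = group.groupby("day")["deaths"].sum()
        out[str(sex)] = DailyDeaths(
            deaths_by_day={int(d): int(c) for d, c in pooled.items() if c > 0},
            initial_n=int(meta["initial_n"][str(sex)]),
            censor_day=int(meta["censor_day"]),
            sex_label=str(sex),
            records=group[["cage_id", "day", "deaths"]].reset_index(drop=True),
        )
    return out
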