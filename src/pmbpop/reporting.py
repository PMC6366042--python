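"""Ensemble envelopes and validation summaries for simulated series.

Replicate simulations are summarised by pointwise empirical percentile
envelopes (default 2.5th-97.5th, i.e. a 95% band over 100 replicates) plus
the pointwise mean; post-threshold summaries average the twice-weekly
offspring-sample observables over collection days after day 45, the window
used to compare treatments once the release effect has developed.  All
summaries are pure functions of their input series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cage import CageProtocol, CageSeries, run_cage

__all__ = [
    "EnsembleSummary",
    "CageEnsemble",
    "CoverageResult",
    "TrendSlope",
    "ensemble",
    "cage_ensemble",
    "post45_summary",
    "envelope_coverage",
    "trend_slope",
]

DEFAULT_VARIABLES = ("prop_female", "transgene_freq", "eggs_laid")
POST_THRESHOLD_DAY = 45


@dataclass
class EnsembleSummary:
    """Pointwise percentile envelope and mean over replicate series."""

    days: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_replicates: int
    values: np.ndarray  # (n_replicates, n_days), retained for re-summaries

    def __post_init__(self) -> None:
        ok = ~np.isnan(self.mean)
        if not ((self.lower[ok] <= self.mean[ok] + 1e-12).all() and (self.mean[ok] <= self.upper[ok] + 1e-12).all()):
            raise ValueError("envelope must satisfy lower <= mean <= upper")

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower


def summarize_replicates(
    days: np.ndarray,
    values: np.ndarray,
    lower_pct: float = 2.5,
    upper_pct: float = 97.5,
) -> EnsembleSummary:
    """Order-statistics band: pointwise percentiles plus mean (NaN-aware)."""
    values = np.asarray(values, dtype=float)
    # time points where every replicate is NaN (e.g. pre-establishment
    # collection days with no eggs) legitimately summarise to NaN
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return EnsembleSummary(
            days=np.asarray(days),
            mean=np.nanmean(values, axis=0),
            lower=np.nanpercentile(values, lower_pct, axis=0),
            upper=np.nanpercentile(values, upper_pct, axis=0),
            n_replicates=values.shape[0],
            values=values,
        )


@dataclass
class CageEnsemble:
    """Replicate cage runs plus their per-variable envelopes."""

    protocol: CageProtocol
    summaries: dict[str, EnsembleSummary]
    seeds: list[int]
    series: list[CageSeries]

    @property
    def n_replicates(self) -> int:
        return len(self.seeds)

    def __getitem__(self, variable: str) -> EnsembleSummary:
        return self.summaries[variable]


def cage_ensemble(
    protocol: CageProtocol,
    n: int = 100,
    base_seed: int = 0,
    variables: tuple[str, ...] = DEFAULT_VARIABLES,
) -> CageEnsemble:
    """Run ``n`` independent cage replicates with seeds base_seed..base_seed+n-1."""
    if n < 2:
        raise ValueError("an ensemble needs at least 2 replicates")
    seeds = [base_seed + i for i in range(n)]
    series = [run_cage(protocol, seed) for seed in seeds]
    days = series[0].samples["day"].to_numpy()
    summaries = {
        var: summarize_replicates(
            days, np.vstack([s.samples[var].to_numpy(dtype=float) for s in series])
        )
        for var in variables
    }
    return CageEnsemble(protocol=protocol, summaries=summaries, seeds=seeds, series=series)


def ensemble(target, n: int = 100, base_seed: int = 0, **kwargs):
    """Ensemble dispatcher: a CageProtocol or a ``runner(seed) -> (days, values)``.

    For a callable, returns a single :class:`EnsembleSummary`; for a cage
    protocol, a :class:`CageEnsemble` over the standard observables.
    """
    if isinstance(target, CageProtocol):
        return cage_ensemble(target, n=n, base_seed=base_seed, **kwargs)
    if callable(target):
        if n < 2:
            raise ValueError("an ensemble needs at least 2 replicates")
        out = [target(base_seed + i) for i in range(n)]
        days = np.asarray(out[0][0])
        values = np.vstack([np.asarray(v, dtype=float) for _, v in out])
        return summarize_replicates(days, values)
    raise TypeError(f"cannot build an ensemble from {type(target)!r}")


def post45_summary(
    obj: CageSeries | CageEnsemble,
    threshold_day: int = POST_THRESHOLD_DAY,
    variables: tuple[str, ...] = ("prop_female", "transgene_freq"),
) -> pd.DataFrame:
    """Mean and standard error over collection days after ``threshold_day``.

    For a single run the SE is over qualifying collection days.  For an
    ensemble each replicate is first reduced to its own post-threshold mean
    and the SE is over replicates.
    """
    if isinstance(obj, CageEnsemble):
        rows = {}
        for var in variables:
            summ = obj.summaries[var]
            mask = summ.days > threshold_day
            if not mask.any():
                raise ValueError(f"series ends at day {summ.days.max()}, before day {threshold_day}")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                per_rep = np.nanmean(summ.values[:, mask], axis=1)
            rows[var] = {
                "mean": float(np.mean(per_rep)),
                "se": float(np.std(per_rep, ddof=1) / np.sqrt(per_rep.size)),
                "n": per_rep.size,
            }
        return pd.DataFrame(rows).T
    samples = obj.samples
    qual = samples[samples["day"] > threshold_day]
    if qual.empty:
        raise ValueError(f"series ends at day {samples['day'].max()}, before day {threshold_day}")
    rows = {}
    for var in variables:
        vals = qual[var].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        rows[var] = {
            "mean": float(vals.mean()),
            "se": float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0,
            "n": vals.size,
        }
    return pd.DataFrame(rows).T


@dataclass
class CoverageResult:
    """Fraction of observed points inside a pointwise envelope."""

    fraction: float
    n_inside: int
    n_above: int
    n_below: int

    @property
    def n_total(self) -> int:
        return self.n_inside + self.n_above + self.n_below


def envelope_coverage(
    observed_days: np.ndarray,
    observed_values: np.ndarray,
    summary: EnsembleSummary,
) -> CoverageResult:
    """Compare observations against a model envelope at common time points."""
    observed_days = np.asarray(observed_days)
    observed_values = np.asarray(observed_values, dtype=float)
    band = pd.DataFrame(
        {"lower": summary.lower, "upper": summary.upper}, index=summary.days
    )
    common = band.index.intersection(pd.Index(observed_days))
    if len(common) == 0:
        raise ValueError("no common time points between observations and envelope")
    obs = pd.Series(observed_values, index=observed_days).loc[common]
    lower = band.loc[common, "lower"]
    upper = band.loc[common, "upper"]
    above = int((obs > upper).sum())
    below = int((obs < lower).sum())
    inside = len(common) - above - below
    return CoverageResult(
        fraction=inside / len(common), n_inside=inside, n_above=above, n_below=below
    )


@dataclass
class TrendSlope:
    """Ordinary least-squares trend of a series against day."""

    slope: float
    ci_lower: float
    ci_upper: float
    stderr: float
    pvalue: float


def trend_slope(days: np.ndarray, values: np.ndarray, alpha: float = 0.05) -> TrendSlope:
    """Least-squares linear slope with its (1 - alpha) confidence interval."""
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if days.size < 3:
        raise ValueError("need at least 3 points for a trend")
    fit = sm.OLS(values, sm.add_constant(days)).fit()
    ci = fit.conf_int(alpha=alpha)
    return TrendSlope(
        slope=float(fit.params[1]),
        ci_lower=float(ci[1][0]),
        ci_upper=float(ci[1][1]),
        stderr=float(fit.bse[1]),
        pvalue=float(fit.pvalues[1]),
    )
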