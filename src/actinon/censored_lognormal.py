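"""Censored-lognormal statistics via regression on order statistics (ROS).

Exhaled-concentration results are a mix of point values, right-censored
greater-than values (instrument range exceeded) and a left-censored
less-than value (below the evaluability limit).  Under a lognormal
population model the log-values are normal, so a q-q plot of ln(value)
against standard-normal quantiles is linear; an ordinary least-squares fit
over the *measured* entries yields the log-location (intercept) and
log-scale (slope), from which the censored entries are imputed at their
ranks' quantiles and summary statistics are formed:

* geometric mean  GM  = exp(mean of ln over real + imputed values),
* geometric SD    GSD = exp(slope)  (distributional)
                  or exp(sample SD of the combined ln values) (empirical),
* 95th percentile     = exp(intercept + 1.645 * slope)  (distributional)
                  or the empirical 95th percentile of the combined values.

Right-censored entries occupy the highest ranks (their true values exceed
bounds that themselves sit near the top of the sample); they are excluded
from the fit.  The less-than entry enters the fit at its bound — a
conservative choice that keeps the left tail represented; ``strict_less_than``
excludes it instead.

Plotting-position conventions: Hazen (i - 0.5)/n (default), Weibull
i/(n + 1), Blom (i - 0.375)/(n + 0.25).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .physics import CensoredValue, CensorStatus

__all__ = [
    "PLOTTING_POSITIONS",
    "RankedEntry",
    "RankedDataset",
    "QQFit",
    "SummaryStats",
    "InsufficientDataError",
    "DegenerateFitError",
    "rank_dataset",
    "qq_fit",
    "impute_censored",
    "summarize",
    "naive_stats",
    "qq_table",
]

#: rank -> probability conventions for q-q plots
PLOTTING_POSITIONS = {
    "hazen": lambda i, n: (i - 0.5) / n,
    "weibull": lambda i, n: i / (n + 1.0),
    "blom": lambda i, n: (i - 0.375) / (n + 0.25),
}

#: z-score of the 95th percentile of the standard normal
Z_95 = stats.norm.ppf(0.95)


class InsufficientDataError(ValueError):
    """Too few entries to rank or fit."""


class DegenerateFitError(ValueError):
    """The regression design has no variance (cannot fit a line)."""


@dataclass(frozen=True)
class RankedEntry:
    value: float
    status: CensorStatus
    rank: int  # 1..n
    plotting_position: float  # in (0, 1)
    normal_quantile: float

    @property
    def in_fit(self) -> bool:
        """Right-censored entries are excluded from the regression."""
        return self.status is not CensorStatus.GREATER_THAN


@dataclass(frozen=True)
class RankedDataset:
    """Results ordered for a lognormal q-q plot."""

    entries: tuple[RankedEntry, ...]
    convention: str

    @property
    def n(self) -> int:
        return len(self.entries)

    @property
    def n_censored(self) -> int:
        return sum(e.status is CensorStatus.GREATER_THAN for e in self.entries)

    @property
    def n_real(self) -> int:
        """Measured entries: points plus any less-than entry at its bound."""
        return self.n - self.n_censored


@dataclass(frozen=True)
class QQFit:
    """OLS fit of ln(value) on normal quantile over the measured entries."""

    intercept: float  # ln(kBq/l) at quantile 0 — the fitted log-median
    slope: float  # ln-units per quantile — the fitted log-scale
    r_squared: float
    n_fit: int

    def predict_log(self, quantile: float | np.ndarray) -> float | np.ndarray:
        return self.intercept + self.slope * np.asarray(quantile)


@dataclass(frozen=True)
class SummaryStats:
    n_total: int
    n_real: int
    n_censored: int
    geometric_mean: float
    geometric_sd: float
    percentile_95: float
    method: str  # distributional | empirical


def rank_dataset(
    results: Sequence[CensoredValue],
    convention: str = "hazen",
    *,
    strict_less_than: bool = False,
) -> RankedDataset:
    """Assign ranks, plotting positions and normal quantiles.

    Measured entries (points, and less-than entries at their bounds) are
    sorted ascending into ranks 1..k; greater-than entries take the top
    ranks k+1..n ordered by bound.  Ties keep input order (stable sort).
    With ``strict_less_than`` the less-than entries are dropped entirely.
    """
    if convention not in PLOTTING_POSITIONS:
        raise ValueError(
            f"unknown plotting-position convention {convention!r}; "
            f"choose from {sorted(PLOTTING_POSITIONS)}"
        )
    if strict_less_than:
        results = [r for r in results if r.status is not CensorStatus.LESS_THAN]
    n = len(results)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 results, got {n}")

    measured = [r for r in results if r.status is not CensorStatus.GREATER_THAN]
    censored = [r for r in results if r.status is CensorStatus.GREATER_THAN]
    measured.sort(key=lambda r: r.value)  # stable: ties keep input order
    censored.sort(key=lambda r: r.value)

    position = PLOTTING_POSITIONS[convention]
    entries = []
    for rank, r in enumerate(measured + censored, start=1):
        p = position(rank, n)
        entries.append(
            RankedEntry(
                value=r.value,
                status=r.status,
                rank=rank,
                plotting_position=p,
                normal_quantile=float(stats.norm.ppf(p)),
            )
        )
    return RankedDataset(tuple(entries), convention)


def qq_fit(ranked: RankedDataset) -> QQFit:
    """Least-squares line through (normal quantile, ln value) of the
    measured entries; greater-than entries are excluded."""
    fit_entries = [e for e in ranked.entries if e.in_fit]
    if len(fit_entries) < 3:
        raise InsufficientDataError(
            f"need at least 3 measured entries to fit, got {len(fit_entries)}"
        )
    q = np.array([e.normal_quantile for e in fit_entries])
    logv = np.log([e.value for e in fit_entries])
    if np.ptp(q) == 0.0:
        raise DegenerateFitError("zero variance in normal quantiles")
    res = stats.linregress(q, logv)
    if res.slope < 0:
        warnings.warn(
            f"negative fitted log-scale ({res.slope:.3g}): data are not "
            "consistent with an increasing quantile relation",
            stacklevel=2,
        )
    return QQFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue**2),
        n_fit=len(fit_entries),
    )


def impute_censored(
    ranked: RankedDataset, fit: QQFit
) -> list[tuple[int, float]]:
    """Impute each greater-than entry from the fitted line at its quantile.

    Returns ``(rank, imputed value)`` pairs.  An imputation below its
    censoring bound contradicts the bound and triggers a warning (the value
    is still returned; downstream statistics use it as-is).
    """
    imputed: list[tuple[int, float]] = []
    for e in ranked.entries:
        if e.status is not CensorStatus.GREATER_THAN:
            continue
        value = float(np.exp(fit.predict_log(e.normal_quantile)))
        if value < e.value:
            warnings.warn(
                f"imputation {value:.3g} at rank {e.rank} lies below its "
                f"censoring bound {e.value:.3g}",
                stacklevel=2,
            )
        imputed.append((e.rank, value))
    return imputed


def _combined_log_values(ranked: RankedDataset, fit: QQFit) -> np.ndarray:
    """ln of measured values plus imputations, in rank order."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        imputations = dict(impute_censored(ranked, fit))
    return np.array(
        [
            np.log(imputations[e.rank])
            if e.status is CensorStatus.GREATER_THAN
            else np.log(e.value)
            for e in ranked.entries
        ]
    )


def summarize(
    ranked: RankedDataset, fit: QQFit, method: str = "distributional"
) -> SummaryStats:
    """Geometric mean, geometric SD and 95th percentile of the population.

    The geometric mean is exp of the mean log over measured-plus-imputed
    values under both methods.  ``distributional`` takes GSD and the 95th
    percentile from the fitted line (exp(slope), exp(intercept + 1.645 *
    slope)); ``empirical`` computes them from the combined sample.
    """
    if method not in ("distributional", "empirical"):
        raise ValueError(f"unknown summary method {method!r}")
    logs = _combined_log_values(ranked, fit)
    gm = float(np.exp(logs.mean()))
    if method == "distributional":
        gsd = float(np.exp(fit.slope))
        p95 = float(np.exp(fit.intercept + Z_95 * fit.slope))
    else:
        gsd = float(np.exp(logs.std(ddof=1)))
        p95 = float(np.percentile(np.exp(logs), 95))
    return SummaryStats(
        n_total=ranked.n,
        n_real=ranked.n_real,
        n_censored=ranked.n_censored,
        geometric_mean=gm,
        geometric_sd=gsd,
        percentile_95=p95,
        method=method,
    )


def naive_stats(
    results: Sequence[CensoredValue],
) -> tuple[float, float, float, int]:
    """(median, min, max, n) of the uncensored point values only."""
    points = [r.value for r in results if r.is_point]
    if not points:
        raise InsufficientDataError("no uncensored point values")
    arr = np.array(points)
    return float(np.median(arr)), float(arr.min()), float(arr.max()), len(points)


def qq_table(
    ranked: RankedDataset, fit: QQFit | None = None, path: str | Path | None = None
) -> pd.DataFrame:
    """Export the q-q construction (and fit, if given) as a table.

    Columns: rank, plotting position, normal quantile, value, ln value,
    censor status, fitted ln value and imputed value where applicable.
    Written as tab-separated text when ``path`` is given.
    """
    imputations: dict[int, float] = {}
    if fit is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            imputations = dict(impute_censored(ranked, fit))
    rows = []
    for e in ranked.entries:
        rows.append(
            {
                "rank": e.rank,
                "plotting_position": e.plotting_position,
                "normal_quantile": e.normal_quantile,
                "value": e.value,
                "ln_value": np.log(e.value),
                "status": e.status.value,
                "fitted_ln": None
                if fit is None
                else float(fit.predict_log(e.normal_quantile)),
                "imputed_value": imputations.get(e.rank),
            }
        )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
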