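"""Equilibration detection for property timeseries: MSER truncation and the
augmented Dickey-Fuller stationarity check.

Per-aggregate properties are first reduced to one mean value per time step
(averaged over the aggregates coexisting at that step, aggregation number
>= 5).  The marginal-standard-error rule picks the truncation index k*
minimizing

    MSE(k) = 1/(n-k)^2 * sum_{i=k}^{n-1} (Y_i - Ybar_{n,k})^2

and the remaining segment is accepted as equilibrated when an ADF test
rejects the unit-root null at the requested confidence (default 99%).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptySeriesError, SeriesTooShortError

logger = logging.getLogger(__name__)

#: Properties reduced by default from the per-aggregate tables.
DEFAULT_PROPERTIES = (
    "sa_to_volume", "area_per_surfactant", "volume_per_surfactant", "r_g", "N",
)


@dataclass
class PropertyTimeseries:
    """One property's per-timestep mean across coexisting aggregates."""

    name: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class EquilibrationResult:
    """MSER/ADF summary for one property series."""

    name: str
    k_star: int
    truncation_time: float
    eq_mean: float
    eq_std: float
    mse_curve: np.ndarray
    adf_statistic: float
    adf_pvalue: float
    stationary: bool
    degenerate: bool = False


def mser_truncation(values, k_max: int | None = None) -> tuple[int, np.ndarray]:
    """Optimal truncation index k* minimizing MSE(k); ties break to smaller k.

    ``k_max`` defaults to floor(3n/4), guarding the (n-k)^-2 prefactor from
    degenerating as k approaches n.  Returns (k*, the full MSE curve for
    k = 0..k_max).
    """
    y = np.asarray(values, dtype=float).ravel()
    n = y.size
    if n < 4:
        raise SeriesTooShortError(f"MSER needs at least 4 points, got {n}")
    if k_max is None:
        k_max = (3 * n) // 4
    k_max = min(k_max, n - 1)

    # suffix sums: SSE(k) = S2(k) - S1(k)^2 / (n-k), computed right-to-left
    s1 = np.cumsum(y[::-1])[::-1]
    s2 = np.cumsum((y ** 2)[::-1])[::-1]
    k = np.arange(0, k_max + 1)
    m = n - k
    sse = s2[k] - s1[k] ** 2 / m
    sse = np.maximum(sse, 0.0)  # guard tiny negative round-off
    mse = sse / m.astype(float) ** 2
    k_star = int(np.argmin(mse))  # argmin returns the first (smallest k) tie
    return k_star, mse


def adf_stationarity(values, confidence: float = 0.99) -> tuple[float, float, bool, bool]:
    """ADF unit-root test on a (truncated) series.

    Regression with a constant term, lag order selected by AIC up to
    floor((n-1)^(1/3)).  Returns (statistic, p-value, stationary, degenerate);
    the series is stationary when the statistic falls below the critical
    value at the given confidence.  A zero-variance series is trivially
    treated as stationary (degenerate=True, with a warning).
    """
    from statsmodels.tsa.stattools import adfuller

    y = np.asarray(values, dtype=float).ravel()
    n = y.size
    if n < 20:
        raise SeriesTooShortError(f"ADF needs at least 20 points, got {n}")
    if np.ptp(y) == 0 or np.std(y) < 1e-12 * max(1.0, abs(np.mean(y))):
        warnings.warn("zero-variance series: ADF undefined; treating as stationary")
        return float("-inf"), 0.0, True, True

    maxlag = int(np.floor((n - 1) ** (1.0 / 3.0)))
    stat, pvalue, _usedlag, _nobs, crit, _ = adfuller(
        y, maxlag=maxlag, regression="c", autolag="AIC"
    )
    key = {0.99: "1%", 0.95: "5%", 0.90: "10%"}.get(round(confidence, 2))
    if key is not None:
        stationary = bool(stat < crit[key])
    else:
        stationary = bool(pvalue < 1.0 - confidence)
    return float(stat), float(pvalue), stationary, False


def equilibrium_statistics(series: PropertyTimeseries,
                           confidence: float = 0.99,
                           k_max: int | None = None) -> EquilibrationResult:
    """MSER truncation + ADF verdict + equilibrium mean/std for one series."""
    k_star, mse = mser_truncation(series.values, k_max=k_max)
    seg = series.values[k_star:]
    eq_mean = float(np.mean(seg))
    eq_std = float(np.std(seg, ddof=1)) if seg.size > 1 else 0.0
    try:
        stat, pvalue, stationary, degenerate = adf_stationarity(seg, confidence)
    except SeriesTooShortError:
        stat, pvalue, stationary, degenerate = float("nan"), float("nan"), False, True
        warnings.warn(
            f"{series.name}: equilibrated segment too short for ADF; "
            "stationarity unverified"
        )
    return EquilibrationResult(
        name=series.name,
        k_star=k_star,
        truncation_time=float(series.times[k_star]),
        eq_mean=eq_mean,
        eq_std=eq_std,
        mse_curve=mse,
        adf_statistic=stat,
        adf_pvalue=pvalue,
        stationary=stationary,
        degenerate=degenerate,
    )


def reduce_aggregate_properties(table: pd.DataFrame, min_n: int = 5,
                                properties: tuple[str, ...] | None = None
                                ) -> dict[str, PropertyTimeseries]:
    """Reduce a per-aggregate table to per-property system timeseries.

    ``table`` needs columns ``time`` and ``N`` plus one column per property;
    aggregates with N < min_n are excluded before the per-timestep mean.
    Time steps at which no aggregate qualifies are dropped (logged).
    """
    if properties is None:
        properties = tuple(p for p in DEFAULT_PROPERTIES if p in table.columns)
    missing = [p for p in properties if p not in table.columns]
    if missing:
        raise KeyError(f"table lacks property columns {missing}")
    qual = table[table["N"] >= min_n]
    if qual.empty:
        raise EmptySeriesError(
            f"no aggregates with N >= {min_n}; nothing to reduce"
        )
    n_dropped = table["time"].nunique() - qual["time"].nunique()
    if n_dropped:
        logger.info("%d time step(s) had no qualifying aggregate and were dropped",
                    n_dropped)
    out: dict[str, PropertyTimeseries] = {}
    for prop in properties:
        g = qual.groupby("time", sort=True)[prop].mean().dropna()
        if g.empty:
            raise EmptySeriesError(f"property {prop!r} empty after reduction")
        out[prop] = PropertyTimeseries(
            name=prop, times=g.index.to_numpy(float), values=g.to_numpy(float)
        )
    return out


def convergence_report(series_set: dict[str, PropertyTimeseries],
                       confidence: float = 0.99) -> dict:
    """Equilibration summary across properties.

    The system convergence time is the maximum truncation time over the
    property set (every property must have equilibrated by then).
    """
    results = {name: equilibrium_statistics(s, confidence=confidence)
               for name, s in series_set.items()}
    final_time = max(r.truncation_time for r in results.values())
    return {
        "properties": {
            name: {
                "k_star": r.k_star,
                "truncation_time": r.truncation_time,
                "eq_mean": r.eq_mean,
                "eq_std": r.eq_std,
                "adf_statistic": r.adf_statistic,
                "adf_pvalue": r.adf_pvalue,
                "stationary": r.stationary,
                "degenerate": r.degenerate,
            }
            for name, r in results.items()
        },
        "final_convergence_time": final_time,
        "confidence": confidence,
    }


def bin_timeseries(series: PropertyTimeseries, bin_width: float = 100.0,
                   n_boot: int = 1000, seed: int | None = None,
                   confidence: float = 0.95) -> pd.DataFrame:
    """Binned means with seeded percentile-bootstrap confidence intervals.

    Bins are [t0 + j*w, t0 + (j+1)*w); empty bins are skipped with a log
    record.  Returns columns bin_start, bin_center, mean, ci_lo, ci_hi, count.
    """
    if series.n == 0:
        raise EmptySeriesError("cannot bin an empty series")
    rng = np.random.default_rng(seed)
    t0 = series.times[0]
    idx = np.floor((series.times - t0) / bin_width).astype(int)
    alpha = 100.0 * (1.0 - confidence) / 2.0
    rows = []
    for j in range(idx.max() + 1):
        vals = series.values[idx == j]
        if vals.size == 0:
            logger.info("bin %d empty; skipped", j)
            continue
        boots = rng.choice(vals, size=(n_boot, vals.size), replace=True).mean(axis=1)
        rows.append({
            "bin_start": t0 + j * bin_width,
            "bin_center": t0 + (j + 0.5) * bin_width,
            "mean": float(vals.mean()),
            "ci_lo": float(np.percentile(boots, alpha)),
            "ci_hi": float(np.percentile(boots, 100.0 - alpha)),
            "count": int(vals.size),
        })
    return pd.DataFrame(rows)
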