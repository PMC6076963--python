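"""Local moment statistics of activity in windows positioned around EMA prompts.

A window is a ``(location, size)`` pair in minutes: it covers the half-open
span ``[prompt + location, prompt + location + size)``, so ``location=-60,
size=10`` is the 10 minutes from 60 to 50 minutes before the prompt, and a
60-min window on 1-min epochs contains exactly 60 data points.

Before computing second and higher moments the window can be detrended by a
least-squares polynomial (default off; order 2 emulates removing a slow
diurnal trend inside a 2-hour window).  Non-wear and missing epochs are
dropped, and a window is declared missing when fewer than ``min_coverage`` of
its expected epochs survive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    DegenerateFitError,
    UndefinedStatisticError,
    ValidationError,
)
from .io import EmaObservation, EpochSeries

__all__ = [
    "WindowSpec",
    "LocalStatConfig",
    "LocalStatValue",
    "extract_window",
    "detrend",
    "moment",
    "compute_local_stat",
    "feature_table",
]

STATISTICS = ("mean", "sd", "skewness", "kurtosis")

#: minimum number of points for each moment to be defined
_MIN_N = {"mean": 1, "sd": 2, "skewness": 3, "kurtosis": 4}


@dataclass(frozen=True)
class WindowSpec:
    """Window start offset (minutes, signed, relative to the prompt) and duration."""

    location: float
    size: float

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValidationError("window size must be positive")

    def n_epochs(self, epoch_length: float) -> int:
        k = self.size / epoch_length
        if abs(k - round(k)) > 1e-9:
            raise ValidationError(
                f"window size {self.size} is not a multiple of epoch length {epoch_length}"
            )
        return int(round(k))


@dataclass
class LocalStatConfig:
    """Which moment to compute and how to preprocess the window.

    detrend_order None disables detrending; an integer fits that order
    polynomial to the retained epochs (on the index axis) and uses the
    residuals.  detrend_scope "window" fits inside each window; "day" fits one
    polynomial per calendar day of the series and extracts windows from the
    day-level residuals.
    """

    statistic: str = "mean"
    detrend_order: Optional[int] = None
    min_coverage: float = 0.8
    detrend_scope: str = "window"

    def __post_init__(self) -> None:
        if self.statistic not in STATISTICS:
            raise ValidationError(f"unknown statistic {self.statistic!r}")
        if not (0 < self.min_coverage <= 1):
            raise ValidationError("min_coverage must be in (0, 1]")
        if self.detrend_order is not None and self.detrend_order < 0:
            raise ValidationError("detrend_order must be >= 0 or None")
        if self.detrend_scope not in ("window", "day"):
            raise ValidationError("detrend_scope must be 'window' or 'day'")


@dataclass
class LocalStatValue:
    """One local statistic: missing (NaN) when coverage fails or the moment is undefined."""

    subject_id: str
    prompt_time: pd.Timestamp
    window: WindowSpec
    value: float
    n_epochs_used: int

    @property
    def is_missing(self) -> bool:
        return np.isnan(self.value)


def extract_window(
    series: EpochSeries, prompt_time, spec: WindowSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Counts and wear flags of the epochs covering the window.

    Always returns exactly ``size / epoch_length`` epochs; epochs falling
    outside the recorded span come back as NaN counts with wear False.
    """
    prompt_time = pd.Timestamp(prompt_time)
    n = spec.n_epochs(series.epoch_length)
    loc_k = spec.location / series.epoch_length
    if abs(loc_k - round(loc_k)) > 1e-9:
        raise ValidationError(
            f"window location {spec.location} is not a multiple of epoch length"
        )
    elapsed = (prompt_time - series.start_time) / pd.Timedelta(minutes=1)
    p = int(np.floor(elapsed / series.epoch_length + 1e-9))
    i0 = p + int(round(loc_k))

    values = np.full(n, np.nan)
    wear = np.zeros(n, dtype=bool)
    lo = max(i0, 0)
    hi = min(i0 + n, len(series))
    if hi > lo:
        values[lo - i0 : hi - i0] = series.counts[lo:hi]
        wear[lo - i0 : hi - i0] = series.wear[lo:hi]
    return values, wear


def detrend(values: Iterable[float], order: int) -> np.ndarray:
    """Residuals of a least-squares polynomial of given order on the index axis.

    Includes the constant term, so residuals sum to zero (numerically).
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1:
        raise ValidationError("detrend expects a 1-D sequence")
    if np.isnan(y).any():
        raise ValidationError("detrend input must not contain missing values")
    if len(y) <= order:
        raise DegenerateFitError(
            f"cannot fit order-{order} polynomial to {len(y)} points"
        )
    x = np.arange(len(y), dtype=float)
    coeffs = np.polynomial.polynomial.polyfit(x, y, deg=order)
    return y - np.polynomial.polynomial.polyval(x, coeffs)


def moment(values: Iterable[float], statistic: str) -> float:
    """Sample moment of a window: mean, SD (n−1), skewness (adjusted
    Fisher–Pearson G1) or excess kurtosis (bias-adjusted G2).

    Raises :class:`UndefinedStatisticError` when too few points are available
    or, for the standardized moments, when the sample variance is zero.
    """
    if statistic not in STATISTICS:
        raise ValidationError(f"unknown statistic {statistic!r}")
    y = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                   dtype=float)
    n = len(y)
    if n < _MIN_N[statistic]:
        raise UndefinedStatisticError(
            f"{statistic} requires >= {_MIN_N[statistic]} points, got {n}"
        )
    if statistic == "mean":
        return float(np.mean(y))
    if statistic == "sd":
        return float(np.std(y, ddof=1))
    if float(np.std(y, ddof=1)) == 0.0:
        raise UndefinedStatisticError(f"{statistic} undefined for zero-variance window")
    if statistic == "skewness":
        return float(sps.skew(y, bias=False))
    return float(sps.kurtosis(y, fisher=True, bias=False))


def _day_residual_series(series: EpochSeries, order: int) -> np.ndarray:
    """Counts with a per-calendar-day polynomial trend removed (wear epochs only)."""
    out = np.full(len(series), np.nan)
    idx = np.arange(len(series))
    times = series.start_time + idx * series.epoch
    days = pd.DatetimeIndex(times).normalize()
    valid = series.wear & ~np.isnan(series.counts)
    for day in pd.unique(days):
        m = (days == day) & valid
        k = int(m.sum())
        if k == 0:
            continue
        x = idx[m].astype(float)
        y = series.counts[m]
        if k <= order:
            out[m] = y - y.mean()
            continue
        coeffs = np.polynomial.polynomial.polyfit(x, y, deg=order)
        out[m] = y - np.polynomial.polynomial.polyval(x, coeffs)
    return out


def compute_local_stat(
    series: EpochSeries,
    prompt: EmaObservation,
    spec: WindowSpec,
    config: LocalStatConfig,
    _day_residuals: Optional[np.ndarray] = None,
) -> LocalStatValue:
    """Local statistic of activity in one window around one prompt.

    Missing / non-wear epochs are dropped before detrending and moment
    computation; the value is missing when the retained fraction is below
    ``min_coverage`` or the moment is undefined.
    """
    values, wear = extract_window(series, prompt.prompt_time, spec)
    valid = wear & ~np.isnan(values)
    n_expected = len(values)
    n_used = int(valid.sum())
    result = LocalStatValue(
        subject_id=series.subject_id,
        prompt_time=pd.Timestamp(prompt.prompt_time),
        window=spec,
        value=np.nan,
        n_epochs_used=n_used,
    )
    if n_used / n_expected < config.min_coverage:
        return result

    if config.detrend_order is not None and config.detrend_scope == "day":
        day_res = (
            _day_residuals
            if _day_residuals is not None
            else _day_residual_series(series, config.detrend_order)
        )
        res_win = _slice_like(day_res, series, prompt.prompt_time, spec)
        y = res_win[valid]
    else:
        y = values[valid]
        if config.detrend_order is not None:
            if len(y) <= config.detrend_order:
                return result
            y = detrend(y, config.detrend_order)

    try:
        result.value = moment(y, config.statistic)
    except UndefinedStatisticError:
        pass
    return result


def _slice_like(arr: np.ndarray, series: EpochSeries, prompt_time, spec: WindowSpec):
    """Window-slice an array that is index-aligned with ``series.counts``."""
    n = spec.n_epochs(series.epoch_length)
    prompt_time = pd.Timestamp(prompt_time)
    elapsed = (prompt_time - series.start_time) / pd.Timedelta(minutes=1)
    p = int(np.floor(elapsed / series.epoch_length + 1e-9))
    i0 = p + int(round(spec.location / series.epoch_length))
    out = np.full(n, np.nan)
    lo, hi = max(i0, 0), min(i0 + n, len(arr))
    if hi > lo:
        out[lo - i0 : hi - i0] = arr[lo:hi]
    return out


def feature_table(
    activity: dict[str, EpochSeries],
    ema: list[EmaObservation],
    windows: Iterable[WindowSpec],
    config: LocalStatConfig,
) -> pd.DataFrame:
    """One row per (subject, prompt, window): the exported local-feature table."""
    rows = []
    windows = list(windows)
    for obs in ema:
        series = activity.get(obs.subject_id)
        if series is None:
            continue
        for spec in windows:
            v = compute_local_stat(series, obs, spec, config)
            rows.append(
                {
                    "subject": obs.subject_id,
                    "prompt_time": v.prompt_time,
                    "location": spec.location,
                    "size": spec.size,
                    "statistic": config.statistic,
                    "value": v.value,
                    "n_epochs_used": v.n_epochs_used,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject", "prompt_time", "location", "size",
            "statistic", "value", "n_epochs_used",
        ],
    )
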