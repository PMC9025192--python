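"""Forecasting tumor volume from a truncated treatment-time series.

The procedure: fit a growth law to the observations up to a cutoff day and
extrapolate the closed-form solution to later times — e.g. predicting the
post-treatment evolution from the data collected during the course, as a
quantitative aid for scheduling surgery.  Forecasts are reported as ratios
``V(t)/V(0)`` so they are scale free.

When the prefix fit is exponential-degenerate (bound status), the forecast
uses the refit constrained to the profile floor and is flagged
``exponential_regime=True``: with too few points a Gompertz/logistic curve
cannot be disentangled from a plain exponential, and the long-horizon
saturation level is then an extrapolation of a one-sided limit, not an
estimate.

:func:`minimum_prefix_study` runs the open design question — how few points
suffice for a reliable forecast — on synthetic cohorts with known truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError
from .model import GrowthCurveModel, GrowthCurveResults
from .series import VolumeSeries
from .simulate import SyntheticCohortSpec, generate_cohort

__all__ = ["ForecastResult", "forecast", "minimum_prefix_study", "PrefixStudy"]


@dataclass
class ForecastResult:
    """A truncated fit and its extrapolation."""

    cutoff_day: float
    fit_on_prefix: GrowthCurveResults
    horizon_days: np.ndarray
    predicted_ratio: np.ndarray  # V(t) / V(first observation)
    observed_ratio: np.ndarray | None
    abs_errors: np.ndarray | None
    exponential_regime: bool

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"day": self.horizon_days, "predicted_ratio": self.predicted_ratio})
        if self.observed_ratio is not None:
            df["observed_ratio"] = self.observed_ratio
            df["abs_error"] = self.abs_errors
        return df


def forecast(series: VolumeSeries, cutoff_day: float, horizon,
             law: str = "gompertz", fix_rate: float | None = None,
             fix_v0: bool = True) -> ForecastResult:
    """Fit on ``times <= cutoff_day`` and predict ``V(t)/V(0)`` at ``horizon``.

    ``horizon`` days must be at or beyond the cutoff.  Where the full series
    has observations at horizon times, observed ratios and absolute errors
    are attached.  ``fix_rate`` pins the rate constant so only the carrying
    capacity is re-estimated from the prefix.
    """
    horizon = np.atleast_1d(np.asarray(horizon, dtype=float))
    if np.any(horizon < cutoff_day - 1e-9):
        raise DomainError("horizon days must be >= cutoff_day")
    prefix = series.prefix(cutoff_day)
    if prefix.nobs < 3:
        raise InsufficientDataError(
            f"only {prefix.nobs} observations at or before day {cutoff_day}; "
            "at least 3 are needed to tell a saturating law from an exponential")
    res = GrowthCurveModel(prefix, law=law, fix_v0=fix_v0).fit(fixed_rate=fix_rate)
    predicted = res.predict(horizon) / series.volumes[0]

    observed = abs_err = None
    obs_map = {round(t, 9): v for t, v in zip(series.times, series.volumes)}
    hits = [obs_map.get(round(t, 9)) for t in horizon]
    if any(v is not None for v in hits):
        observed = np.array([np.nan if v is None else v / series.volumes[0] for v in hits])
        abs_err = np.abs(predicted - observed)
    return ForecastResult(
        cutoff_day=float(cutoff_day), fit_on_prefix=res, horizon_days=horizon,
        predicted_ratio=predicted, observed_ratio=observed, abs_errors=abs_err,
        exponential_regime=(res.status == "bound"),
    )


@dataclass
class PrefixStudy:
    """Forecast-error distribution versus prefix size over a synthetic cohort."""

    table: pd.DataFrame
    smallest_cutoff: int | None
    error_budget: float
    horizon_day: float


def minimum_prefix_study(spec: SyntheticCohortSpec, error_budget: float,
                         law: str = "gompertz", cutoff_sizes=None,
                         horizon_day: float | None = None) -> PrefixStudy:
    """Smallest data subset giving reliable forecasts, on synthetic truth.

    For each cutoff size ``m`` (number of leading points used), every cohort
    subject is refit on its first ``m`` observations and the relative error
    of the predicted ratio at ``horizon_day`` (default: the last scheduled
    day) against the subject's *noiseless* truth is recorded.  The table
    reports the median and 90th percentile per cutoff size; the smallest
    cutoff whose median error meets ``error_budget`` is returned (None if
    none qualifies).
    """
    cohort = generate_cohort(spec)
    schedule = spec.resolved_schedule()
    n_points = len(schedule)
    if horizon_day is None:
        horizon_day = float(schedule[-1])
    if cutoff_sizes is None:
        cutoff_sizes = range(3, n_points + 1)
    rows = []
    for m in cutoff_sizes:
        if not 3 <= m <= n_points:
            raise DomainError(f"cutoff size {m} outside [3, {n_points}]")
        errors = []
        for rec in cohort:
            t0 = rec.observed.times[0]
            truth = float(rec.true_params.volume(horizon_day - t0)) / rec.true_params.V0
            fc = forecast(rec.observed, cutoff_day=float(rec.observed.times[m - 1]),
                          horizon=[horizon_day], law=law)
            pred = float(fc.predicted_ratio[0]) * rec.observed.volumes[0] / rec.true_params.V0
            errors.append(abs(pred - truth) / truth)
        errors = np.asarray(errors)
        rows.append({
            "cutoff_size": int(m),
            "cutoff_day": float(schedule[m - 1]),
            "median_rel_error": float(np.median(errors)),
            "p90_rel_error": float(np.quantile(errors, 0.9)),
        })
    table = pd.DataFrame(rows)
    ok = table[table["median_rel_error"] <= error_budget]
    smallest = int(ok["cutoff_size"].iloc[0]) if len(ok) else None
    return PrefixStudy(table=table, smallest_cutoff=smallest,
                       error_budget=float(error_budget), horizon_day=float(horizon_day))
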