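"""Growth-law fitting with identifiability-aware reporting.

The estimation problem: given a volume time series, estimate the carrying
capacity ratio ``Vinf/V0`` and the rate constant of a Gompertz or logistic
law.  The loss is the unweighted sum of squared residuals in *log volume*
(measurement error on tumor volumes is multiplicative), with ``V0`` fixed to
the first observation by default.

Regressing tumors whose measurements look exponential sit on an
identifiability ridge: only the composite rate ``k |ln(Vinf/V0)|`` (Gompertz)
or ``lambda`` (logistic) is determined, while ``Vinf/V0`` and the rate
individually are not.  :meth:`GrowthCurveModel.fit` therefore profiles the
objective over ``b = ln(Vinf/V0)`` on a grid reaching ``|b| = 16``
(``Vinf/V0 ~ 1e-7``) and reports

* ``status="point_estimate"`` when the profile has a well-defined interior
  minimum, or
* ``status="bound"`` when the objective at the grid floor is within the
  flatness threshold of the minimum: then ``Vinf/V0`` and the rate carry only
  one-sided limits (taken at the flatness contour) and the composite rate is
  reported as the point estimate, from a refit constrained to the floor.

The flatness threshold scales with the residual degrees of freedom
(``4/(n-p)`` relative, a ~2-sigma profile-likelihood criterion) so the
classification is stable under multiplicative measurement noise.  Ties are
resolved toward ``bound`` (conservative reporting).  The optimizer uses a
deterministic multi-start list (no RNG).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DomainError, FitError, InsufficientDataError, InvalidParameterError
from .laws import LAWS, GrowthLawParams, composite_rate
from .series import VolumeSeries

__all__ = [
    "GrowthCurveModel",
    "GrowthCurveResults",
    "BoundInfo",
    "fit_growth_law",
    "two_point_solve",
    "goodness_of_fit",
]

LN_RATIO_LIMIT = 16.0  # profile floor: |ln(Vinf/V0)| <= 16, i.e. Vinf/V0 >= ~1.1e-7
RATE_MIN = 1e-5
RATE_MAX = 2.0
_DECADE = math.log(10.0)
# deterministic multi-start list: 5 log-spaced CC ratios x 3 rates
_START_RATIOS = (1e-5, 1e-3, 0.1, 3.0, 30.0)
_START_RATES = (0.01, 0.05, 0.2)


def _log_curve(law: str, t, b, rate):
    """``ln V(t) - ln V0`` for CC log-ratio ``b`` and rate constant ``rate``."""
    if law == "gompertz":
        return b * (-np.expm1(-rate * t))
    eb = np.exp(b)
    return np.log(eb - (eb - 1.0) * np.exp(-rate * t))


def two_point_solve(r1: float, r2: float, t1: float):
    """Closed-form Gompertz through ``(0, 1), (t1, r1), (2 t1, r2)``.

    With ``x = e^{-k t1}`` the Gompertz law gives ``ln r2 / ln r1 = 1 + x``,
    so ``x = ln r2 / ln r1 - 1``, ``k = -ln(x)/t1`` and
    ``ln Vinf = ln r1 / (1 - x)``.  Returns ``None`` (no solution) when
    ``ln r2 / ln r1`` is outside ``(1, 2)``: no Gompertz with ``V0 = 1``
    passes through the two ratios.

    Used both as the exact interpolation oracle for three-point series on a
    geometric ``(0, t1, 2 t1)`` grid and to seed the least-squares starts.
    """
    if not (r1 > 0 and r2 > 0):
        raise DomainError("ratios must be > 0")
    if not (t1 > 0):
        raise DomainError("t1 must be > 0")
    if r1 == 1.0:
        return None
    rho = math.log(r2) / math.log(r1)
    if not (1.0 < rho < 2.0):
        return None
    x = rho - 1.0
    k = -math.log(x) / t1
    ln_vinf = math.log(r1) / (1.0 - x)
    return GrowthLawParams("gompertz", V0=1.0, Vinf=math.exp(ln_vinf), rate=k)


def goodness_of_fit(series: VolumeSeries, params: GrowthLawParams,
                    sigma_rel: float = 0.10, n_free_params: int = 2) -> float:
    """Reduced chi-square under a relative measurement error ``sigma_rel``.

    ``chi2/dof = sum[ ((V_obs - V_model) / (sigma_rel V_obs))^2 ] / (n - p)``.
    The 10% default matches the declared uncertainty of the built-in
    xenograft ratio table.
    """
    if not sigma_rel > 0:
        raise InvalidParameterError("sigma_rel must be > 0")
    n, p = series.nobs, n_free_params
    if n <= p:
        raise InsufficientDataError(f"chi2/dof undefined: n={n} <= p={p}")
    model = params.volume(series.times - series.times[0])
    z = (series.volumes - model) / (sigma_rel * series.volumes)
    return float(np.sum(z * z) / (n - p))


@dataclass(frozen=True)
class BoundInfo:
    """One-sided limits reported for exponential-degenerate fits.

    Each bound is a ``(direction, value)`` pair, e.g. ``("<", 0.53)`` for
    ``Vinf/V0 < 0.53``.  ``composite_rate`` is the point estimate of
    ``k |ln(Vinf/V0)|`` (Gompertz) or ``lambda`` (logistic) from the
    constrained refit at the profile floor.
    """

    vinf_ratio_bound: tuple[str, float]
    rate_bound: tuple[str, float]
    composite_rate: float


@dataclass
class GrowthCurveResults:
    """Results of :meth:`GrowthCurveModel.fit` (statsmodels-style)."""

    model: "GrowthCurveModel"
    law: str
    params: GrowthLawParams
    status: str  # "point_estimate" | "bound"
    bound_info: BoundInfo | None
    composite_rate: float
    sse: float
    chi2_per_dof: float
    resid: np.ndarray  # per-point log-volume residuals
    nobs: int
    df_resid: int
    profile_b: np.ndarray
    profile_sse: np.ndarray
    flatness: float

    @property
    def vinf_ratio(self) -> float:
        return self.params.Vinf / self.params.V0

    def predict(self, times) -> np.ndarray:
        """Model volume at absolute ``times`` (same origin as the data)."""
        t = np.asarray(times, dtype=float) - self.model.series.times[0]
        if np.any(t < 0):
            raise DomainError("cannot predict before the fit origin")
        return np.asarray(self.params.volume(t))

    def predict_ratio(self, times) -> np.ndarray:
        """Predicted ``V(t) / V(first observation)``."""
        return self.predict(times) / self.model.series.volumes[0]

    def to_record(self) -> dict:
        """JSON-ready record (full precision; schema shipped in the package)."""
        rec = {
            "subject_id": self.model.series.subject_id,
            "law": self.law,
            "status": self.status,
            "V0": self.params.V0,
            "Vinf": self.params.Vinf,
            "vinf_ratio": self.vinf_ratio,
            "rate_per_day": self.params.rate,
            "composite_rate_per_day": self.composite_rate,
            "chi2_per_dof": self.chi2_per_dof,
            "sse_log": self.sse,
            "n_obs": self.nobs,
        }
        if self.bound_info is not None:
            d, v = self.bound_info.vinf_ratio_bound
            rec["vinf_ratio_bound"] = {"direction": d, "value": v}
            d, v = self.bound_info.rate_bound
            rec["rate_bound"] = {"direction": d, "value": v}
        return rec

    def summary(self) -> str:
        lines = [
            "Growth-curve fit",
            "=" * 58,
            f"subject:            {self.model.series.subject_id}",
            f"law:                {self.law}",
            f"n obs / df resid:   {self.nobs} / {self.df_resid}",
            f"status:             {self.status}",
            f"V0 (fit origin):    {self.params.V0:.6g}",
        ]
        if self.status == "bound":
            assert self.bound_info is not None
            dv, vv = self.bound_info.vinf_ratio_bound
            dr, vr = self.bound_info.rate_bound
            lines += [
                f"Vinf/V0:            {dv} {vv:.3g}  (one-sided limit)",
                f"rate [1/day]:       {dr} {vr:.3g}  (one-sided limit)",
                f"composite rate:     {self.composite_rate:.4g} /day  (point estimate)",
            ]
        else:
            lines += [
                f"Vinf/V0:            {self.vinf_ratio:.4g}",
                f"Vinf:               {self.params.Vinf:.4g}",
                f"rate [1/day]:       {self.params.rate:.4g}",
                f"composite rate:     {self.composite_rate:.4g} /day",
            ]
        lines += [
            f"chi2 / dof:         {self.chi2_per_dof:.4g}",
            f"SSE (log volume):   {self.sse:.4g}",
            "=" * 58,
        ]
        return "\n".join(lines)


class GrowthCurveModel:
    """Gompertz/logistic growth-curve model for one volume series.

    Parameters
    ----------
    series : VolumeSeries
    law : {"gompertz", "logistic"}
    fix_v0 : bool
        Fix ``V0`` to the first observation (default; series are normalized
        to their first measurement).  ``False`` frees ``ln V0`` as a third
        parameter for sensitivity checks.

    Examples
    --------
    >>> from tumorgrowth import GrowthCurveModel, VolumeSeries
    >>> s = VolumeSeries("L3-NT", [0, 15, 30], [1.0, 1.6, 1.9])
    >>> res = GrowthCurveModel(s, law="gompertz").fit()
    >>> round(res.params.Vinf, 2), round(res.params.rate, 3)
    (2.1, 0.067)
    """

    def __init__(self, series: VolumeSeries, law: str = "gompertz", fix_v0: bool = True):
        if law not in LAWS:
            raise InvalidParameterError(f"unknown law {law!r}")
        self.series = series
        self.law = law
        self.fix_v0 = fix_v0

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, law: str = "gompertz",
                       subject: str | None = None, **kwargs) -> "GrowthCurveModel":
        return cls(VolumeSeries.from_frame(df, subject_id=subject), law=law, **kwargs)

    # -- internals ---------------------------------------------------------

    def _design(self):
        t = self.series.times - self.series.times[0]
        y = np.log(self.series.volumes)
        return t, y

    def _sse_grid(self, t, y, b, rate):
        """Vectorized SSE over broadcastable ``b``, ``rate`` arrays."""
        curve = _log_curve(self.law, t, b[..., None], rate[..., None])
        if self.fix_v0:
            lnv0 = y[0]
        else:
            lnv0 = (y - curve).mean(axis=-1, keepdims=True)
        r = y - lnv0 - curve
        return np.sum(r * r, axis=-1)

    def profile(self, b_values, fixed_rate: float | None = None):
        """Profile objective over ``b = ln(Vinf/V0)``.

        Returns ``(sse, rate)`` arrays: for each ``b`` the inner optimum over
        the rate (golden-section on ``ln rate``) and, if ``fix_v0=False``,
        the closed-form optimal ``ln V0``.
        """
        t, y = self._design()
        b = np.atleast_1d(np.asarray(b_values, dtype=float))
        if fixed_rate is not None:
            rate = np.full(b.shape, float(fixed_rate))
            return self._sse_grid(t, y, b, rate), rate
        lo = np.full(b.shape, math.log(RATE_MIN))
        hi = np.full(b.shape, math.log(RATE_MAX))
        invphi = (math.sqrt(5.0) - 1.0) / 2.0
        x1 = hi - invphi * (hi - lo)
        x2 = lo + invphi * (hi - lo)
        f1 = self._sse_grid(t, y, b, np.exp(x1))
        f2 = self._sse_grid(t, y, b, np.exp(x2))
        for _ in range(64):
            take = f1 < f2
            hi = np.where(take, x2, hi)
            lo = np.where(take, lo, x1)
            x1 = hi - invphi * (hi - lo)
            x2 = lo + invphi * (hi - lo)
            f1 = self._sse_grid(t, y, b, np.exp(x1))
            f2 = self._sse_grid(t, y, b, np.exp(x2))
        rate = np.exp(0.5 * (lo + hi))
        return self._sse_grid(t, y, b, rate), rate

    def _least_squares(self, t, y, starts):
        """Deterministic multi-start nonlinear least squares on (b, ln rate[, ln V0])."""
        if self.fix_v0:
            def resid(x):
                return y - y[0] - _log_curve(self.law, t, x[0], math.exp(x[1]))
            lower = [-LN_RATIO_LIMIT, math.log(RATE_MIN)]
            upper = [LN_RATIO_LIMIT, math.log(RATE_MAX)]
        else:
            def resid(x):
                return y - x[2] - _log_curve(self.law, t, x[0], math.exp(x[1]))
            lower = [-LN_RATIO_LIMIT, math.log(RATE_MIN), y.min() - 5.0]
            upper = [LN_RATIO_LIMIT, math.log(RATE_MAX), y.max() + 5.0]
        best, diagnostics = None, []
        for x0 in starts:
            x0 = np.clip(x0, np.asarray(lower) + 1e-9, np.asarray(upper) - 1e-9)
            try:
                sol = least_squares(resid, x0, bounds=(lower, upper),
                                    ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=400)
            except Exception as exc:  # pragma: no cover - defensive
                diagnostics.append({"x0": list(x0), "error": str(exc)})
                continue
            diagnostics.append({"x0": list(x0), "cost": 2 * sol.cost, "success": bool(sol.success)})
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise FitError("all optimizer starts failed", diagnostics)
        return best, diagnostics

    def _starts(self, t, y):
        starts = []
        for ratio in _START_RATIOS:
            for rate in _START_RATES:
                x0 = [math.log(ratio), math.log(rate)]
                if not self.fix_v0:
                    x0.append(y[0])
                starts.append(np.asarray(x0))
        # closed-form seed for 3-point series on a (0, tau, 2 tau) grid
        if self.law == "gompertz" and self.fix_v0 and len(t) == 3 and t[0] == 0.0:
            if math.isclose(t[2], 2.0 * t[1], rel_tol=1e-9):
                exact = two_point_solve(self.series.ratios[1], self.series.ratios[2], t[1])
                if exact is not None and abs(exact.log_ratio) < LN_RATIO_LIMIT \
                        and RATE_MIN < exact.rate < RATE_MAX:
                    starts.append(np.asarray([exact.log_ratio, math.log(exact.rate)]))
        return starts

    # -- fitting -----------------------------------------------------------

    def fit(self, flatness: float | None = None, sigma_rel: float = 0.10,
            fixed_rate: float | None = None) -> GrowthCurveResults:
        """Estimate the growth-law parameters.

        Parameters
        ----------
        flatness : float, optional
            Relative profile-flatness threshold for the bound classification;
            default ``4 / (n - p)``.
        sigma_rel : float
            Relative measurement error used for the reported chi2/dof.
        fixed_rate : float, optional
            Pin the rate constant and fit only the CC ratio (used e.g. to
            re-fit a forecast with a known ``k``).
        """
        t, y = self._design()
        n = len(t)
        p = (1 if fixed_rate is not None else 2) + (0 if self.fix_v0 else 1)
        if n < 3:
            raise InsufficientDataError(
                f"need >= 3 observations for a {p}-parameter fit (got {n}); for two "
                "post-baseline ratios on a (t1, 2 t1) grid use two_point_solve"
            )

        if fixed_rate is not None:
            grid = np.linspace(-LN_RATIO_LIMIT, LN_RATIO_LIMIT, 1601)
            sse_grid, _ = self.profile(grid, fixed_rate=fixed_rate)
            i = int(np.argmin(sse_grid))
            lo = grid[max(i - 1, 0)]
            hi = grid[min(i + 1, len(grid) - 1)]
            from scipy.optimize import minimize_scalar
            opt = minimize_scalar(
                lambda bb: float(self.profile([bb], fixed_rate=fixed_rate)[0][0]),
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-10})
            b_hat, rate_hat, sse_hat = float(opt.x), float(fixed_rate), float(opt.fun)
            lnv0_hat = y[0] if self.fix_v0 else float(
                (y - _log_curve(self.law, t, b_hat, rate_hat)).mean())
        else:
            best, diagnostics = self._least_squares(t, y, self._starts(t, y))
            b_hat, rate_hat = float(best.x[0]), math.exp(best.x[1])
            lnv0_hat = y[0] if self.fix_v0 else float(best.x[2])
            sse_hat = float(2.0 * best.cost)

        # direction of the CC change; perfectly flat data degenerate to Vinf = V0
        if abs(b_hat) > 1e-9:
            direction = math.copysign(1.0, b_hat)
        elif y[-1] != y[0]:
            direction = math.copysign(1.0, y[-1] - y[0])
        else:
            direction = -1.0

        # profile over ln(Vinf/V0) toward the degenerate floor
        grid = direction * np.concatenate(([0.01, 0.05, 0.1], np.arange(0.2, LN_RATIO_LIMIT + 1e-9, 0.2)))
        prof_sse, prof_rate = self.profile(grid, fixed_rate=fixed_rate)
        i_best = int(np.argmin(prof_sse))
        if fixed_rate is None and prof_sse[i_best] < sse_hat:
            # refine from the best grid point
            x0 = [grid[i_best], math.log(prof_rate[i_best])]
            if not self.fix_v0:
                x0.append(lnv0_hat)
            refined, _ = self._least_squares(t, y, [np.asarray(x0)])
            if 2.0 * refined.cost < sse_hat:
                b_hat, rate_hat = float(refined.x[0]), math.exp(refined.x[1])
                lnv0_hat = y[0] if self.fix_v0 else float(refined.x[2])
                sse_hat = float(2.0 * refined.cost)

        sse_min = min(sse_hat, float(prof_sse.min()))
        dof = max(n - p, 1)
        eta = float(flatness) if flatness is not None else 4.0 / dof
        threshold = sse_min * (1.0 + eta) + 1e-12 * n

        i_floor = int(np.argmax(np.abs(grid)))  # |b| = 16 endpoint
        is_bound = bool(prof_sse[i_floor] <= threshold)

        V0 = float(self.series.volumes[0]) if self.fix_v0 else float(np.exp(lnv0_hat))
        if is_bound:
            # One-sided limits at the flatness contour: the innermost |b| of
            # the admissible region touching the floor.  The point values
            # (params, composite rate) stay at the constrained optimum on the
            # ridge — the best fit the data admit.
            order = np.argsort(np.abs(grid))[::-1]  # floor first
            i_contour = i_floor
            for j in order:
                if prof_sse[j] <= threshold:
                    i_contour = j
                else:
                    break
            b_contour, rate_contour = float(grid[i_contour]), float(prof_rate[i_contour])
            if prof_sse.min() < sse_hat:
                i_opt = int(np.argmin(prof_sse))
                b_rep, rate_rep = float(grid[i_opt]), float(prof_rate[i_opt])
            else:
                b_rep, rate_rep = b_hat, rate_hat
            # On the degenerate ridge the data identify only the exponential
            # rate: report it (log-linear slope), not the ill-determined
            # product at an arbitrary ridge point.
            if self.fix_v0:
                comp = abs(float(np.dot(t, y - y[0]) / np.dot(t, t)))
            else:
                comp = abs(float(np.polyfit(t, y, 1)[0]))
            bound_info = BoundInfo(
                vinf_ratio_bound=("<" if direction < 0 else ">", math.exp(b_contour)),
                rate_bound=("<", rate_contour),
                composite_rate=comp,
            )
            params = GrowthLawParams(self.law, V0=V0, Vinf=V0 * math.exp(b_rep), rate=rate_rep)
            sse_rep = sse_min
            status = "bound"
        else:
            params = GrowthLawParams(self.law, V0=V0, Vinf=V0 * math.exp(b_hat), rate=rate_hat)
            comp = composite_rate(params) if self.law == "gompertz" else params.rate
            bound_info = None
            sse_rep = sse_hat
            status = "point_estimate"

        curve = _log_curve(self.law, t, params.log_ratio, params.rate)
        resid = y - math.log(V0) - curve
        chi2 = goodness_of_fit(self.series, params, sigma_rel=sigma_rel, n_free_params=p) \
            if n > p else float("nan")
        return GrowthCurveResults(
            model=self, law=self.law, params=params, status=status, bound_info=bound_info,
            composite_rate=comp, sse=sse_rep, chi2_per_dof=chi2, resid=resid,
            nobs=n, df_resid=n - p, profile_b=grid, profile_sse=prof_sse, flatness=eta,
        )


def fit_growth_law(series: VolumeSeries, law: str = "gompertz",
                   fix_v0: bool = True, **fit_kwargs) -> GrowthCurveResults:
    """Functional wrapper: ``GrowthCurveModel(series, law, fix_v0).fit(...)``."""
    return GrowthCurveModel(series, law=law, fix_v0=fix_v0).fit(**fit_kwargs)
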