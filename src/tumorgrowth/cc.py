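"""Inverting post-treatment volume ratios into carrying-capacity changes.

After a fractionated course ending at ``t*``, the Gompertz restart gives

``V(t)/V(t*) = exp( ln[Vinf(d)/V(t*)] * (1 - e^{-k (t - t*)}) )``

so a measured ratio at ``dt = t - t*`` days inverts in closed form to the
dose-modified carrying capacity,

``ln[Vinf(d)/V(t*)] = ln(ratio) / (1 - e^{-k dt})``.

The rate ``k`` is held at the matching untreated line's fitted value for all
doses of that line (volume variations are moderate and the CC enters only
logarithmically, so ``k ~ constant`` is the working assumption); a per-dose
``k`` can be supplied for sensitivity analysis.  A (line, dose) is a
*responder* when the combined ``Vinf(d)/V(t*) < 1``: the tumor keeps
regressing after the end of therapy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .model import GrowthCurveModel, GrowthCurveResults
from .series import VolumeSeries

__all__ = [
    "DoseObservation",
    "CCInferenceResult",
    "invert_cc",
    "infer_line",
    "dose_response_table",
    "untreated_rate",
    "analyze_ratio_table",
]


@dataclass(frozen=True)
class DoseObservation:
    """Normalized volume ratios for one (cell line, dose).

    ``ratios`` maps days after the end of treatment to ``V/V(t*)``;
    ``dose == 0`` marks the untreated control of the line.
    """

    cell_line: str
    dose: float
    ratios: dict[float, float]

    def __post_init__(self):
        if self.dose < 0:
            raise DomainError("dose must be >= 0 Gy")
        for dt, r in self.ratios.items():
            if dt <= 0:
                raise DomainError(f"timepoint dt={dt} must be > 0 days after t*")
            if r <= 0:
                raise DomainError(f"ratio at dt={dt} must be > 0, got {r}")

    @property
    def label(self) -> str:
        return f"{self.cell_line}-{self.dose:g}Gy" if self.dose else f"{self.cell_line}-NT"


@dataclass(frozen=True)
class CCInferenceResult:
    """Dose-indexed carrying-capacity ratio with responder call.

    ``cc_ratio_per_timepoint`` holds the per-timepoint inversions; they are
    combined by geometric mean (multiplicative error model).  ``consistency``
    is the maximum pairwise relative spread, ``max/min - 1``, across
    timepoints (0 for a single timepoint).
    """

    cell_line: str
    dose: float
    cc_ratio_per_timepoint: dict[float, float]
    cc_ratio_combined: float
    responder: bool
    consistency: float
    k_used: float


def invert_cc(ratio: float, dt: float, k: float) -> float:
    """Invert one post-treatment ratio into ``Vinf(d)/V(t*)``.

    Exact inverse of the Gompertz restart formula; the round trip through
    :func:`tumorgrowth.laws.regression_after_treatment` is the identity.
    """
    if not (ratio > 0 and dt > 0 and k > 0):
        raise DomainError("ratio, dt and k must all be > 0")
    return math.exp(math.log(ratio) / -math.expm1(-k * dt))


def infer_line(obs: DoseObservation, k: float) -> CCInferenceResult:
    """Per-timepoint CC inversion for one (line, dose), combined geometrically."""
    if not obs.ratios:
        raise ConfigurationError(f"{obs.label}: no timepoints to invert")
    per_tp = {dt: invert_cc(r, dt, k) for dt, r in sorted(obs.ratios.items())}
    values = np.array(list(per_tp.values()))
    combined = float(np.exp(np.mean(np.log(values))))
    consistency = float(values.max() / values.min() - 1.0)
    return CCInferenceResult(
        cell_line=obs.cell_line, dose=obs.dose, cc_ratio_per_timepoint=per_tp,
        cc_ratio_combined=combined, responder=bool(combined < 1.0),
        consistency=consistency, k_used=float(k),
    )


def dose_response_table(results: list[CCInferenceResult]) -> pd.DataFrame:
    """Tabulate CC ratios versus dose, one row per (line, dose).

    Rows are sorted by line then dose.  ``monotone_in_dose`` descriptively
    flags, per line, whether the combined CC ratio decreases with dose
    (NaN where a line has fewer than two doses).  Duplicated (line, dose)
    pairs are a validation error.
    """
    if not results:
        raise DomainError("no results to tabulate")
    keys = [(r.cell_line, r.dose) for r in results]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise DomainError(f"duplicated (cell_line, dose) entries: {dupes}")
    timepoints = sorted({dt for r in results for dt in r.cc_ratio_per_timepoint})
    rows = []
    for r in sorted(results, key=lambda r: (r.cell_line, r.dose)):
        row = {"cell_line": r.cell_line, "dose_gy": r.dose}
        for dt in timepoints:
            row[f"cc_ratio_d{dt:g}"] = r.cc_ratio_per_timepoint.get(dt, np.nan)
        row.update(
            cc_ratio_combined=r.cc_ratio_combined, responder=r.responder,
            consistency=r.consistency, k_used=r.k_used,
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    monotone = {}
    for line, grp in table.groupby("cell_line"):
        cc = grp.sort_values("dose_gy")["cc_ratio_combined"].to_numpy()
        monotone[line] = bool(np.all(np.diff(cc) < 0)) if len(cc) > 1 else np.nan
    table["monotone_in_dose"] = table["cell_line"].map(monotone)
    return table


def untreated_rate(obs: DoseObservation, law: str = "gompertz") -> tuple[float, GrowthCurveResults]:
    """Rate constant of an untreated (dose 0) line from its ratio series.

    Fits the growth law to ``(0, 1)`` plus the tabulated timepoints.  For
    identifiable lines the fitted rate is returned; for exponential-degenerate
    lines (bound status) the rate at the profile flatness contour is used —
    the largest rate consistent with the data — since the degenerate ridge
    carries no single point value.
    """
    if obs.dose != 0:
        raise ConfigurationError(f"{obs.label}: untreated_rate needs a dose-0 observation")
    dts = sorted(obs.ratios)
    series = VolumeSeries(obs.label, np.concatenate(([0.0], dts)),
                          np.concatenate(([1.0], [obs.ratios[dt] for dt in dts])),
                          normalization="ratio_to_first")
    res = GrowthCurveModel(series, law=law).fit()
    if res.status == "bound":
        return float(res.bound_info.rate_bound[1]), res
    return float(res.params.rate), res


def analyze_ratio_table(observations: list[DoseObservation], law: str = "gompertz",
                        k_overrides: dict[str, float] | None = None,
                        ) -> tuple[dict[str, GrowthCurveResults], list[CCInferenceResult]]:
    """Full inversion pipeline over a normalized ratio table.

    Dose-0 rows define each line's ``k`` (they are never inverted); treated
    rows are inverted with the line's shared ``k``.  ``k_overrides`` maps
    cell-line labels to rates and takes precedence over the untreated fits
    (per-dose sensitivity analyses can call :func:`infer_line` directly).
    """
    k_overrides = dict(k_overrides or {})
    nt_fits: dict[str, GrowthCurveResults] = {}
    k_by_line: dict[str, float] = {}
    for obs in observations:
        if obs.dose == 0:
            if obs.cell_line in nt_fits:
                raise ConfigurationError(f"duplicate untreated row for line {obs.cell_line}")
            k, res = untreated_rate(obs, law=law)
            nt_fits[obs.cell_line] = res
            k_by_line[obs.cell_line] = k
    k_by_line.update(k_overrides)
    results = []
    for obs in observations:
        if obs.dose == 0:
            continue
        if obs.cell_line not in k_by_line:
            raise ConfigurationError(
                f"{obs.label}: no untreated fit or k override for line {obs.cell_line}")
        results.append(infer_line(obs, k_by_line[obs.cell_line]))
    return nt_fits, results
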