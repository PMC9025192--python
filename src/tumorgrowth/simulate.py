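"""Synthetic cohorts with the statistical structure of the real studies.

Two kinds of cohort are generated:

``patient``
    Per-subject volume series mimicking daily MRI-based gross-tumor-volume
    monitoring during a ~28-day neoadjuvant radiochemotherapy course
    (default: 23 visits evenly spread over 28 days).  Archetypes:

    * ``PR`` (partial response): carrying-capacity ratio ``Vinf/V0``
      log-uniform in [0.2, 0.65], Gompertz ``k`` uniform in [0.03, 0.11]/day
      (logistic ``lambda`` uniform in [0.05, 0.13]/day).
    * ``CR`` (complete response): ``log10(Vinf/V0)`` uniform in [-9, -7]
      (a vanishing residual carrying capacity) with the identifiable
      composite rate ``k |ln(Vinf/V0)|`` uniform in [0.04, 0.1]/day; the
      series are exponential-degenerate by construction, as observed for
      complete responders.
    * ``NT``: untreated growth, ``Vinf/V0`` uniform in [2.0, 2.8], ``k``
      uniform in [0.03, 0.08]/day.

    Initial volumes are log-uniform in [20, 150] cm^3.

``xenograft``
    Per-line normalized ratio tables on the {0, 15, 30}-day schedule: an
    untreated series grown from ``V(t*) = 1`` with NT-archetype parameters,
    plus one post-treatment series per dose in ``cc_dose_map`` obtained from
    the Gompertz restart with carrying capacity ``cc_ratio * V(t*)`` and the
    line's own ``k``.  Archetypes ``responder`` / ``non_responder`` select a
    default dose map with CC ratios below / above 1.

Measurement noise is multiplicative log-normal: each observed volume is the
model value times ``exp(eps)``, ``eps ~ N(0, noise_rel)`` — percentages are
the natural error scale for volumes and positivity is automatic.  Day-0
entries of normalized xenograft series are exactly 1 (they define the
normalization).  Generation is deterministic given ``seed``; seeds are
mandatory, no global RNG state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, InvalidParameterError
from .laws import GrowthLawParams, TreatmentContext, regression_after_treatment
from .series import VolumeSeries

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticRecord",
    "generate_cohort",
    "patient_schedule",
    "ARCHETYPES",
]

ARCHETYPES = ("NT", "PR", "CR", "responder", "non_responder")

_DEFAULT_CC_MAPS = {
    "responder": {5.0: 0.75, 10.0: 0.5},
    "non_responder": {5.0: 1.4, 10.0: 1.7},
}


def patient_schedule(n_visits: int = 23, duration: float = 28.0) -> np.ndarray:
    """Near-daily visit schedule over a treatment course (days)."""
    return np.linspace(0.0, duration, n_visits)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generative settings for one synthetic cohort.

    ``vinf_ratio_range``, ``rate_range``, ``composite_range`` and ``v0_range``
    override the archetype defaults (use a zero-width range to pin a value).
    For xenograft cohorts ``n_subjects`` counts cell lines; each line yields
    an untreated record plus one record per dose in ``cc_dose_map``.
    """

    kind: str  # "patient" | "xenograft"
    n_subjects: int
    seed: int
    law: str = "gompertz"
    archetype: str = "PR"
    schedule: tuple[float, ...] | None = None
    noise_rel: float = 0.05
    cc_dose_map: dict[float, float] | None = None
    vinf_ratio_range: tuple[float, float] | None = None
    rate_range: tuple[float, float] | None = None
    composite_range: tuple[float, float] | None = None
    v0_range: tuple[float, float] = (20.0, 150.0)

    def __post_init__(self):
        if self.kind not in ("patient", "xenograft"):
            raise InvalidParameterError(f"unknown cohort kind {self.kind!r}")
        if self.archetype not in ARCHETYPES:
            raise InvalidParameterError(f"unknown archetype {self.archetype!r}")
        if self.n_subjects < 1:
            raise InvalidParameterError("n_subjects must be >= 1")
        if self.noise_rel < 0:
            raise InvalidParameterError("noise_rel must be >= 0")
        if self.schedule is not None:
            sched = tuple(float(t) for t in self.schedule)
            if len(sched) == 0:
                raise InvalidParameterError("schedule must not be empty")
            if any(b <= a for a, b in zip(sched, sched[1:])):
                raise InvalidParameterError("schedule must be strictly increasing")
            object.__setattr__(self, "schedule", sched)

    def resolved_schedule(self) -> np.ndarray:
        if self.schedule is not None:
            return np.asarray(self.schedule, dtype=float)
        if self.kind == "xenograft":
            return np.array([0.0, 15.0, 30.0])
        return patient_schedule()


@dataclass(frozen=True)
class SyntheticRecord:
    """One generated series with its ground truth."""

    subject_id: str
    true_params: GrowthLawParams
    observed: VolumeSeries
    cell_line: str | None = None
    dose: float | None = None
    true_cc_ratio: float | None = None


def _loguniform(rng, lo, hi):
    return math.exp(rng.uniform(math.log(lo), math.log(hi)))


def _draw_params(rng, spec: SyntheticCohortSpec, v0: float) -> GrowthLawParams:
    arch = "NT" if spec.archetype in ("responder", "non_responder") else spec.archetype
    if arch == "PR":
        ratio_rng = spec.vinf_ratio_range or (0.2, 0.65)
        rate_rng = spec.rate_range or ((0.03, 0.11) if spec.law == "gompertz" else (0.05, 0.13))
        ratio = _loguniform(rng, *ratio_rng)
        rate = rng.uniform(*rate_rng)
    elif arch == "CR":
        ratio_rng = spec.vinf_ratio_range or (1e-9, 1e-7)
        comp_rng = spec.composite_range or (0.04, 0.10)
        ratio = _loguniform(rng, *ratio_rng)
        comp = rng.uniform(*comp_rng)
        rate = comp / abs(math.log(ratio)) if spec.law == "gompertz" else comp
    else:  # NT
        ratio_rng = spec.vinf_ratio_range or (2.0, 2.8)
        rate_rng = spec.rate_range or (0.03, 0.08)
        ratio = rng.uniform(*ratio_rng)
        rate = rng.uniform(*rate_rng)
    return GrowthLawParams(spec.law, V0=v0, Vinf=v0 * ratio, rate=rate)


def _observe(rng, spec, times, model_volumes, skip_first=False):
    noisy = np.asarray(model_volumes, dtype=float).copy()
    if spec.noise_rel > 0:
        eps = rng.normal(0.0, spec.noise_rel, size=noisy.shape)
        if skip_first:
            eps[0] = 0.0
        noisy *= np.exp(eps)
    return noisy


def generate_cohort(spec: SyntheticCohortSpec) -> list[SyntheticRecord]:
    """Generate a cohort; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    times = spec.resolved_schedule()
    records: list[SyntheticRecord] = []
    if spec.kind == "patient":
        for i in range(spec.n_subjects):
            v0 = _loguniform(rng, *spec.v0_range)
            p = _draw_params(rng, spec, v0)
            volumes = _observe(rng, spec, times, p.volume(times))
            records.append(SyntheticRecord(
                subject_id=f"{spec.archetype}{i + 1:03d}", true_params=p,
                observed=VolumeSeries(f"{spec.archetype}{i + 1:03d}", times, volumes),
            ))
        return records

    # xenograft: per line, an untreated ratio series plus treated series per dose
    if times[0] != 0.0:
        raise ConfigurationError("xenograft schedules are days after t* and must start at 0")
    cc_map = spec.cc_dose_map or _DEFAULT_CC_MAPS.get(spec.archetype)
    if cc_map is None:
        cc_map = {}
    ctx = TreatmentContext(t_star=0.0, V_at_tstar=1.0)
    for i in range(spec.n_subjects):
        line = f"S{i + 1}L"
        p_nt = _draw_params(rng, spec, v0=1.0)
        nt_volumes = _observe(rng, spec, times, p_nt.volume(times), skip_first=True)
        records.append(SyntheticRecord(
            subject_id=f"{line}-NT", true_params=p_nt,
            observed=VolumeSeries(f"{line}-NT", times, nt_volumes,
                                  normalization="ratio_to_first"),
            cell_line=line, dose=0.0,
        ))
        for dose in sorted(cc_map):
            cc_ratio = float(cc_map[dose])
            p_d = GrowthLawParams(spec.law, V0=1.0, Vinf=cc_ratio, rate=p_nt.rate)
            ratios = regression_after_treatment(times, ctx, Vinf_d=cc_ratio, k=p_nt.rate) \
                if spec.law == "gompertz" else p_d.volume(times)
            volumes = _observe(rng, spec, times, ratios, skip_first=True)
            sid = f"{line}-{dose:g}Gy"
            records.append(SyntheticRecord(
                subject_id=sid, true_params=p_d,
                observed=VolumeSeries(sid, times, volumes, normalization="ratio_to_first"),
                cell_line=line, dose=dose, true_cc_ratio=cc_ratio,
            ))
    return records
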