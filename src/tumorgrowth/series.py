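"""The :class:`VolumeSeries` container: one subject's tumor-volume trajectory."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataValidationError

__all__ = ["VolumeSeries"]


@dataclass(frozen=True)
class VolumeSeries:
    """A timestamped tumor-volume trajectory for one subject.

    ``times`` are days from the study's own origin (first measurement = day 0
    by convention, but any non-negative, strictly increasing grid is valid);
    ``volumes`` are cm^3 for absolute series or dimensionless ratios for
    series normalized to a reference volume (``normalization="ratio_to_first"``).
    """

    subject_id: str
    times: np.ndarray
    volumes: np.ndarray
    normalization: str = "absolute"

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        volumes = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "volumes", volumes)
        if times.ndim != 1 or volumes.ndim != 1 or times.size != volumes.size:
            raise DataValidationError("times and volumes must be 1-D arrays of equal length")
        if times.size == 0:
            raise DataValidationError("empty series")
        if not np.all(np.isfinite(times)) or np.any(times < 0):
            raise DataValidationError("times must be finite and >= 0")
        if np.any(np.diff(times) <= 0):
            raise DataValidationError("times must be strictly increasing")
        if not np.all(np.isfinite(volumes)) or np.any(volumes <= 0):
            raise DataValidationError("volumes must be finite and > 0")
        if self.normalization not in ("absolute", "ratio_to_first"):
            raise DataValidationError(f"unknown normalization {self.normalization!r}")

    @property
    def nobs(self) -> int:
        return int(self.times.size)

    @property
    def ratios(self) -> np.ndarray:
        """Volumes in units of the first observation, ``V(t)/V(t_0)``."""
        return self.volumes / self.volumes[0]

    def prefix(self, cutoff_day: float) -> "VolumeSeries":
        """The sub-series with ``times <= cutoff_day`` (same origin)."""
        keep = self.times <= cutoff_day + 1e-12
        if not keep.any():
            raise DataValidationError(f"no observations at or before day {cutoff_day}")
        return replace(self, times=self.times[keep], volumes=self.volumes[keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": self.subject_id, "day": self.times, "volume_cm3": self.volumes}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, subject_id: str | None = None,
                   normalization: str = "absolute") -> "VolumeSeries":
        """Build from a ``subject_id, day, volume_cm3`` data frame (one subject)."""
        if subject_id is not None:
            df = df[df["subject_id"] == subject_id]
        ids = df["subject_id"].unique()
        if len(ids) != 1:
            raise DataValidationError(f"expected exactly one subject, got {list(ids)}")
        df = df.sort_values("day")
        return cls(str(ids[0]), df["day"].to_numpy(float), df["volume_cm3"].to_numpy(float),
                   normalization=normalization)
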