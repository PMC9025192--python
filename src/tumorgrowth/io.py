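"""CSV/JSON formats and run configuration.

Dialects:

* series CSV — header ``subject_id,day,volume_cm3``, one row per measurement,
  days counted from each study's own origin;
* ratio-table CSV — header ``cell_line,dose_gy,ratio_d15,ratio_d30`` (the
  xenograft layout; any ``ratio_d<dt>`` columns are accepted);
* cc-table CSV — the dose-response output of the inversion pipeline;
* fit-result JSON — records validated against ``schemas/fit_result.schema.json``.

Numeric output is written at full precision; rounding is a display concern.
Validation errors name the offending 1-based data row.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .cc import CCInferenceResult, DoseObservation
from .errors import ConfigurationError, DataValidationError
from .series import VolumeSeries

__all__ = [
    "read_series_csv",
    "write_series_csv",
    "read_ratio_table_csv",
    "write_cc_table_csv",
    "load_schema",
    "validate_record",
    "RunConfig",
    "load_config",
]

_SERIES_COLUMNS = ["subject_id", "day", "volume_cm3"]


def read_series_csv(path_or_buf) -> list[VolumeSeries]:
    """Read a series CSV into one :class:`VolumeSeries` per subject.

    Subjects may be interleaved; rows are sorted by day per subject.
    Non-positive volumes, unparsable cells and duplicate (subject, day)
    pairs raise :class:`DataValidationError` naming the data row.
    """
    try:
        df = pd.read_csv(path_or_buf, dtype={"subject_id": str},
                         float_precision="round_trip")
    except Exception as exc:
        raise DataValidationError(f"unreadable CSV: {exc}") from exc
    missing = [c for c in _SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"missing required column(s): {missing}")
    for col in ("day", "volume_cm3"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(parsed.isna().to_numpy() & df[col].notna().to_numpy()
                         | df[col].isna().to_numpy())[0]
        if bad.size:
            raise DataValidationError(f"unparsable {col} value {df[col].iloc[bad[0]]!r}",
                                      row=int(bad[0]) + 1)
        df[col] = parsed
    nonpos = np.nonzero((df["volume_cm3"] <= 0).to_numpy())[0]
    if nonpos.size:
        raise DataValidationError(
            f"volume must be > 0, got {df['volume_cm3'].iloc[nonpos[0]]}",
            row=int(nonpos[0]) + 1)
    dup = df.duplicated(subset=["subject_id", "day"])
    if dup.any():
        i = int(np.nonzero(dup.to_numpy())[0][0])
        raise DataValidationError(
            f"duplicate (subject_id, day)=({df['subject_id'].iloc[i]!r}, {df['day'].iloc[i]})",
            row=i + 1)
    out = []
    for sid in df["subject_id"].unique():  # preserve file order of subjects
        sub = df[df["subject_id"] == sid].sort_values("day")
        out.append(VolumeSeries(str(sid), sub["day"].to_numpy(float),
                                sub["volume_cm3"].to_numpy(float)))
    return out


def write_series_csv(series_list: list[VolumeSeries], path_or_buf) -> None:
    df = pd.concat([s.to_frame() for s in series_list], ignore_index=True)
    # %.17g round-trips float64 exactly
    df.to_csv(path_or_buf, index=False, float_format="%.17g")


_RATIO_COL = re.compile(r"^ratio_d(\d+(?:\.\d+)?)$")


def read_ratio_table_csv(path_or_buf) -> list[DoseObservation]:
    """Read a normalized ratio table (xenograft layout) into DoseObservations."""
    try:
        df = pd.read_csv(path_or_buf)
    except Exception as exc:
        raise DataValidationError(f"unreadable CSV: {exc}") from exc
    for col in ("cell_line", "dose_gy"):
        if col not in df.columns:
            raise DataValidationError(f"missing required column {col!r}")
    dt_cols = {c: float(m.group(1)) for c in df.columns if (m := _RATIO_COL.match(c))}
    if not dt_cols:
        raise DataValidationError("no ratio_d<days> columns found")
    obs = []
    for i, row in df.iterrows():
        ratios = {dt: float(row[c]) for c, dt in dt_cols.items() if pd.notna(row[c])}
        try:
            obs.append(DoseObservation(cell_line=str(row["cell_line"]),
                                       dose=float(row["dose_gy"]), ratios=ratios))
        except Exception as exc:
            raise DataValidationError(str(exc), row=int(i) + 1) from exc
    return obs


def write_cc_table_csv(table: pd.DataFrame, path_or_buf) -> None:
    table.to_csv(path_or_buf, index=False)


# -- JSON schema (structural validation; full precision floats) -------------

def load_schema(name: str) -> dict:
    """Load a schema shipped under ``tumorgrowth/schemas`` (e.g. ``fit_result``)."""
    ref = importlib.resources.files("tumorgrowth") / "schemas" / f"{name}.schema.json"
    return json.loads(ref.read_text())


_TYPES = {"string": str, "number": (int, float), "integer": int,
          "boolean": bool, "object": dict, "array": list}


def validate_record(record: dict, schema: dict, _path: str = "$") -> None:
    """Minimal structural validator (required / type / enum / properties)."""
    if "type" in schema:
        expected = _TYPES[schema["type"]]
        if isinstance(record, bool) and schema["type"] in ("number", "integer"):
            raise DataValidationError(f"{_path}: expected {schema['type']}, got bool")
        if not isinstance(record, expected):
            raise DataValidationError(
                f"{_path}: expected {schema['type']}, got {type(record).__name__}")
    if "enum" in schema and record not in schema["enum"]:
        raise DataValidationError(f"{_path}: {record!r} not in {schema['enum']}")
    if isinstance(record, dict):
        for key in schema.get("required", []):
            if key not in record:
                raise DataValidationError(f"{_path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in record:
                validate_record(record[key], sub, f"{_path}.{key}")


# -- run configuration -------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Validated knobs shared by the CLI subcommands."""

    law: str = "gompertz"
    sigma_rel: float = 0.10
    flatness_threshold: float | None = None
    k_policy: str = "shared_per_line"  # or "per_dose"
    seed: int | None = None
    output_format: str = "json"  # or "csv"

    def __post_init__(self):
        if self.law not in ("gompertz", "logistic"):
            raise ConfigurationError(f"law must be gompertz or logistic, got {self.law!r}")
        if not self.sigma_rel > 0:
            raise ConfigurationError("sigma_rel must be > 0")
        if self.flatness_threshold is not None and not self.flatness_threshold > 0:
            raise ConfigurationError("flatness_threshold must be > 0")
        if self.k_policy not in ("shared_per_line", "per_dose"):
            raise ConfigurationError(f"unknown k_policy {self.k_policy!r}")
        if self.output_format not in ("json", "csv"):
            raise ConfigurationError(f"unknown output_format {self.output_format!r}")


def load_config(path) -> RunConfig:
    """Load a YAML or JSON config file mirroring :class:`RunConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**raw)
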