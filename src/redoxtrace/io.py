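"""File formats and run configuration.

CSV is the canonical event-table format (UTF-8, header row, columns
i405, i488, chl, sytox, sample_id, dose_uM, time_min, replicate).
Image stacks travel as multi-page TIFF plus a JSON sidecar (see
:class:`redoxtrace.imaging.ImageStack`).  Calibrations are small YAML
files.  Every writer here has a matching reader so all artifacts
round-trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .imaging import FilterCriteria, ImageStack  # noqa: F401  (re-exported)
from .redox import CalibrationSet

__all__ = [
    "EVENT_COLUMNS",
    "SchemaError",
    "read_event_table",
    "write_event_table",
    "RunConfig",
]

EVENT_COLUMNS = ("i405", "i488", "chl", "sytox", "sample_id", "dose_uM", "time_min", "replicate")
_NUMERIC = ("i405", "i488", "chl", "sytox", "dose_uM", "time_min")
_REQUIRED = ("i405", "i488", "chl", "sample_id", "dose_uM", "time_min", "replicate")


class SchemaError(ValueError):
    """An input table does not match the documented event schema."""


def read_event_table(path) -> pd.DataFrame:
    """Load and validate a flow-cytometry event CSV.

    Missing required columns raise :class:`SchemaError` naming the
    column; non-numeric intensities raise with the offending rows.
    Row count is preserved exactly.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    for col in _NUMERIC:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            rows = df.index[bad].tolist()[:10]
            raise SchemaError(f"non-numeric values in '{col}' at rows {rows}")
        df[col] = coerced
    neg = [c for c in ("i405", "i488", "chl") if (df[c] < 0).any()]
    if neg:
        raise SchemaError(f"negative intensities in column(s): {', '.join(neg)}")
    return df


def write_event_table(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Parameters of a full analysis run, serializable to YAML.

    The loaded config is echoed into every output directory so a run
    can always be reproduced from its artifacts.
    """

    calibration_file: Optional[str] = None
    expr_threshold: float = 1.0           # flow gating on i405*i488 (a.u.^2)
    split_method: str = "mixture"
    channel_thresholds: dict = field(
        default_factory=lambda: {"i405": 0.02, "i488": 0.02, "chlorophyll": 0.02}
    )
    t_expr: float = 2.5e-4                # pixel-level expression product threshold
    background_roi: Optional[list] = None  # (row0, row1, col0, col1); None = auto tile
    area_min: float = 20.0
    area_max: float = 500.0
    major_axis_max: float = 40.0
    minor_axis_min: float = 2.0
    eccentricity_max: float = 0.97
    max_dist: float = 15.0
    min_track_len: int = 6
    dilation_px: int = 3
    sytox_threshold: float = 0.1
    decision_time_min: float = 40.0
    seed: int = 0

    def filter_criteria(self) -> FilterCriteria:
        return FilterCriteria(
            area_min=self.area_min,
            area_max=self.area_max,
            major_axis_max=self.major_axis_max,
            minor_axis_min=self.minor_axis_min,
            eccentricity_max=self.eccentricity_max,
        )

    def load_calibration(self) -> CalibrationSet:
        if self.calibration_file is None:
            raise ValueError("config has no calibration_file")
        if not Path(self.calibration_file).exists():
            raise FileNotFoundError(self.calibration_file)
        return CalibrationSet.from_yaml(self.calibration_file)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def echo_into(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_yaml(outdir / "run_config.yaml")


def write_json(obj, path) -> None:
    """JSON writer tolerant of numpy scalars/arrays."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=default)
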