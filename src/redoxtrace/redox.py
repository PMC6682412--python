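"""Ratiometric roGFP mathematics.

roGFP is a redox-sensitive GFP with two excitation peaks (~405 and
~488 nm) whose relative amplitudes shift with the oxidation state of
the probe's engineered cysteine pair.  The measured quantity is the
excitation ratio R = i405/i488, which rises upon oxidation.  Given
calibration measurements of the fully reduced probe (DTT treatment)
and the fully oxidized probe (H2O2 treatment), the ratio maps onto the
degree of oxidation

    OxD(R) = (R - R_red) / [ (i488_ox / i488_red) * (R_ox - R) + (R - R_red) ]

which is 0 for the fully reduced probe and 1 for the fully oxidized
probe.  The i488_ox/i488_red factor corrects for the intensity change
of the 488-excited channel between the two redox states.

This module holds the calibration container, the forward and inverse
OxD mappings, the probe dynamic range, and the out-of-range policy
used across the flow-cytometry and imaging pipelines: biologically
implausible OxD values (by default > 1.10, i.e. >110%) are flagged
``EXCLUDED`` because they typically arise from autofluorescence
leaking into the i405 channel; values in (1.0, 1.10] are retained but
flagged ``OVER_RANGE``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import yaml

__all__ = [
    "CalibrationSet",
    "OxDFlag",
    "OxDResult",
    "UndefinedRatioError",
    "compute_ratio",
    "compute_oxd",
    "oxd_to_ratio",
    "dynamic_range",
    "DEFAULT_I488_FLOOR",
    "DEFAULT_OVER_RANGE_CUTOFF",
]

#: i488 intensities at or below this floor make the ratio unreliable.
DEFAULT_I488_FLOOR = 1e-12

#: OxD values above this cutoff are excluded from summaries (110%).
DEFAULT_OVER_RANGE_CUTOFF = 1.10

ArrayLike = Union[float, np.ndarray]


class UndefinedRatioError(ValueError):
    """Raised when a scalar ratio is requested with i488 at/below the floor."""


class OxDFlag(enum.IntEnum):
    """Per-value quality flag for OxD measurements."""

    IN_RANGE = 0      # 0 <= OxD <= 1
    OVER_RANGE = 1    # 1 < OxD <= cutoff; plotted but suspicious
    EXCLUDED = 2      # OxD > cutoff (or non-positive denominator); dropped from summaries
    INVALID = 3       # undefined input (i488 at floor, non-finite ratio)


@dataclass(frozen=True)
class CalibrationSet:
    """The four scalars anchoring the ratio-to-OxD mapping.

    Parameters
    ----------
    R_red : float
        i405/i488 ratio of the fully reduced probe (DTT reference).
    R_ox : float
        i405/i488 ratio of the fully oxidized probe (H2O2 reference).
    i488_red, i488_ox : float
        i488 intensities of the two reference states (a.u.).
    provenance : str
        Free-text description of how the references were acquired.
    """

    R_red: float
    R_ox: float
    i488_red: float
    i488_ox: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if not (self.R_red > 0 and np.isfinite(self.R_red)):
            raise ValueError(f"R_red must be positive and finite, got {self.R_red}")
        if not (self.R_ox > self.R_red):
            raise ValueError(
                f"R_ox must exceed R_red (got R_ox={self.R_ox}, R_red={self.R_red})"
            )
        if not (self.i488_red > 0 and self.i488_ox > 0):
            raise ValueError("i488_red and i488_ox must be positive")

    @property
    def instrument_factor(self) -> float:
        """i488_ox / i488_red, the channel-intensity correction in the OxD map."""
        return self.i488_ox / self.i488_red

    # -- serialization ---------------------------------------------------

    def to_yaml(self, path) -> None:
        data = {
            "R_red": float(self.R_red),
            "R_ox": float(self.R_ox),
            "i488_red": float(self.i488_red),
            "i488_ox": float(self.i488_ox),
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CalibrationSet":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            R_red=float(data["R_red"]),
            R_ox=float(data["R_ox"]),
            i488_red=float(data["i488_red"]),
            i488_ox=float(data["i488_ox"]),
            provenance=str(data.get("provenance", "")),
        )


@dataclass(frozen=True)
class OxDResult:
    """OxD values with per-value flags (arrays or scalars, matching input)."""

    value: ArrayLike
    flag: ArrayLike

    def in_summary(self) -> np.ndarray:
        """Boolean mask of values eligible for summary statistics."""
        flag = np.asarray(self.flag)
        return (flag == OxDFlag.IN_RANGE) | (flag == OxDFlag.OVER_RANGE)


def compute_ratio(i405: ArrayLike, i488: ArrayLike, floor: float = DEFAULT_I488_FLOOR) -> ArrayLike:
    """i405/i488 excitation ratio.

    Scalar inputs with ``i488 <= floor`` raise :class:`UndefinedRatioError`;
    in array inputs such entries become NaN (never a silent zero).
    """
    scalar = np.isscalar(i405) and np.isscalar(i488)
    i405_a = np.asarray(i405, dtype=float)
    i488_a = np.asarray(i488, dtype=float)
    invalid = ~(i488_a > floor)
    if scalar and invalid:
        raise UndefinedRatioError(f"i488={i488} is at or below the floor {floor}")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(invalid, np.nan, i405_a) / np.where(invalid, 1.0, i488_a)
    return float(ratio) if scalar else ratio


def compute_oxd(
    R: ArrayLike,
    calib: CalibrationSet,
    over_range_cutoff: float = DEFAULT_OVER_RANGE_CUTOFF,
) -> OxDResult:
    """Degree of oxidation of the probe from the excitation ratio.

    OxD(R_red) = 0 and OxD(R_ox) = 1 exactly; the map is strictly
    increasing on [R_red, R_ox].  Values beyond the anchors can occur on
    real data; they are flagged per the over-range policy.  A
    non-positive denominator (possible for R far above R_ox when
    i488_ox > i488_red) yields NaN flagged ``EXCLUDED`` — never an
    unflagged number.
    """
    scalar = np.isscalar(R)
    R_a = np.asarray(R, dtype=float)
    k = calib.instrument_factor
    num = R_a - calib.R_red
    den = k * (calib.R_ox - R_a) + num
    bad_input = ~np.isfinite(R_a)
    bad_den = (den <= 0) & ~bad_input
    with np.errstate(divide="ignore", invalid="ignore"):
        value = np.where(bad_den | bad_input, np.nan, num) / np.where(
            bad_den | bad_input, 1.0, den
        )
    flag = np.full(R_a.shape, int(OxDFlag.IN_RANGE), dtype=np.int8)
    flag[(value > 1.0) & (value <= over_range_cutoff)] = OxDFlag.OVER_RANGE
    flag[value > over_range_cutoff] = OxDFlag.EXCLUDED
    flag[bad_den] = OxDFlag.EXCLUDED
    flag[bad_input] = OxDFlag.INVALID
    if scalar:
        return OxDResult(value=float(value), flag=OxDFlag(int(flag)))
    return OxDResult(value=value, flag=flag)


def oxd_to_ratio(oxd: ArrayLike, calib: CalibrationSet) -> ArrayLike:
    """Inverse of :func:`compute_oxd` on the domain [0, 1].

    Solving OxD = (R - R_red) / [k (R_ox - R) + (R - R_red)] for R gives

        R = [R_red (1 - OxD) + OxD k R_ox] / [1 - OxD (1 - k)]

    with k = i488_ox/i488_red; the round-trip identity holds to
    machine precision on [R_red, R_ox].
    """
    scalar = np.isscalar(oxd)
    x = np.asarray(oxd, dtype=float)
    if np.any((x < 0) | (x > 1) | ~np.isfinite(x)):
        raise ValueError("oxd must lie in [0, 1]")
    k = calib.instrument_factor
    R = (calib.R_red * (1.0 - x) + x * k * calib.R_ox) / (1.0 - x * (1.0 - k))
    return float(R) if scalar else R


def dynamic_range(calib: CalibrationSet) -> float:
    """Probe dynamic range R_ox / R_red (> 1 for any valid calibration)."""
    return calib.R_ox / calib.R_red
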