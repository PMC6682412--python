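"""Synthetic flow-cytometry and time-lapse data with known ground truth.

The generator emulates the statistical structure of a chloroplast-
targeted roGFP stress experiment in a diatom population:

* After an H2O2 dose, the population splits into a *reduced*
  subpopulation that oxidizes mildly (tens of percent OxD) and then
  recovers over hours, and an *oxidized* subpopulation that saturates
  near 100% OxD.  The oxidized fraction grows with dose.
* Death, scored by Sytox staining ~24 h later, follows the oxidized
  fraction linearly (default line y = 1.09x - 0.16, i.e. death is a
  subset of the early-oxidized cells).
* In imaging, settled cells experience global stage drift, camera
  background and noise, optional chlorophyll-to-i405 autofluorescence
  leakage, and a terminal Sytox frame whose positives are exactly the
  cells whose OxD at the decision frame crossed the fate threshold
  (default 74% OxD).

True subpopulation labels, OxD trajectories, positions, tracks and
fates are returned alongside the rendered data, so every downstream
stage can be scored against ground truth.  All randomness flows from
the config seed; a fixed seed reproduces the output bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .imaging import ImageStack
from .redox import CalibrationSet, oxd_to_ratio

__all__ = [
    "DEFAULT_CALIBRATION",
    "FlowSimConfig",
    "ImagingSimConfig",
    "simulate_flow_experiment",
    "simulate_timelapse",
    "simulate_fate_data",
    "export_ground_truth",
    "read_ground_truth",
]

#: Calibration used by the simulators: a chloroplast-type probe with a
#: flow-cytometry dynamic range of 5.57 (R_ox/R_red) and the typical
#: halving of the 488-excited channel upon oxidation.
DEFAULT_CALIBRATION = CalibrationSet(
    R_red=0.4,
    R_ox=0.4 * 5.57,
    i488_red=1.0,
    i488_ox=0.5,
    provenance="synthetic reference: DTT-reduced / H2O2-oxidized anchors",
)

# Piecewise-linear OxD trajectory of the reduced subpopulation
# (minutes, OxD fraction): mild early oxidation, then slow recovery to
# below the pre-treatment baseline.
REDUCED_TRAJECTORY: Tuple[Tuple[float, float], ...] = (
    (0.0, 0.33),
    (15.0, 0.38),
    (60.0, 0.33),
    (120.0, 0.28),
    (480.0, 0.15),
    (1440.0, 0.12),
)

OXIDIZED_TRAJECTORY: Tuple[Tuple[float, float], ...] = (
    (0.0, 0.33),
    (10.0, 0.90),
    (20.0, 1.0),
    (1440.0, 1.0),
)


def _traj_value(traj: Sequence[Tuple[float, float]], t: float) -> float:
    times = np.array([p[0] for p in traj])
    vals = np.array([p[1] for p in traj])
    return float(np.interp(t, times, vals))


# ---------------------------------------------------------------------------
# Flow cytometry simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlowSimConfig:
    """Conditions of a dose/time-course flow-cytometry experiment."""

    doses: Tuple[float, ...] = (0.0, 50.0, 80.0, 100.0)  # µM H2O2
    n_events_per_sample: int = 4000
    timepoints: Tuple[float, ...] = (0.0, 5.0, 15.0, 30.0, 60.0, 120.0, 480.0, 1440.0)
    n_replicates: int = 3
    frac_oxidized_by_dose: Dict[float, float] = field(
        default_factory=lambda: {0.0: 0.0, 50.0: 0.2, 80.0: 0.5, 100.0: 0.8}
    )
    reduced_trajectory: Tuple[Tuple[float, float], ...] = REDUCED_TRAJECTORY
    oxidized_trajectory: Tuple[Tuple[float, float], ...] = OXIDIZED_TRAJECTORY
    oxd_noise_sd: float = 0.03
    expression_mu: float = 4.0      # lognormal location of roGFP abundance (a.u.)
    expression_sigma: float = 0.4
    wt_af_fraction: float = 0.05    # autofluorescence-only events
    death_line: Tuple[float, float] = (1.09, -0.16)  # dead24h = a*frac_ox + b
    sytox_time_min: float = 1440.0
    sytox_positive_intensity: float = 500.0
    sytox_background_scale: float = 1.0
    fraction_ramp_tau_min: float = 10.0  # subpopulations stabilize within ~30-50 min
    calibration: CalibrationSet = DEFAULT_CALIBRATION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events_per_sample <= 0:
            raise ValueError("n_events_per_sample must be positive")
        for d in self.doses:
            if d not in self.frac_oxidized_by_dose:
                raise ValueError(f"dose {d} missing from frac_oxidized_by_dose")
        for f in self.frac_oxidized_by_dose.values():
            if not 0.0 <= f <= 1.0:
                raise ValueError("oxidized fractions must lie in [0, 1]")
        if not 0.0 <= self.wt_af_fraction < 1.0:
            raise ValueError("wt_af_fraction must lie in [0, 1)")


def simulate_flow_experiment(cfg: FlowSimConfig):
    """Render a flow-cytometry event table and its ground truth.

    Returns ``(events, truth)`` DataFrames sharing an ``event_id``.
    Events carry i405/i488/chl/sytox intensities and sample metadata;
    the truth carries the generating subpopulation label, true OxD and
    death outcome.  Sytox separates dead from live events only at the
    terminal staining timepoint.
    """
    rng = np.random.default_rng(cfg.seed)
    calib = cfg.calibration
    events, truths = [], []
    event_id = 0
    for dose in cfg.doses:
        frac_stable = cfg.frac_oxidized_by_dose[dose]
        for rep in range(1, cfg.n_replicates + 1):
            # death is decided by the stabilized oxidized fraction;
            # oxidized cells die first (death line lies below y = x)
            slope, intercept = cfg.death_line
            dead_frac = float(np.clip(slope * frac_stable + intercept, 0.0, 1.0))
            for t in cfg.timepoints:
                n = cfg.n_events_per_sample
                n_af = rng.binomial(n, cfg.wt_af_fraction)
                n_pos = n - n_af
                frac_t = frac_stable * (1.0 - np.exp(-t / cfg.fraction_ramp_tau_min)) if t > 0 else 0.0
                oxidized = rng.random(n_pos) < frac_t
                true_oxd = np.where(
                    oxidized,
                    _traj_value(cfg.oxidized_trajectory, t),
                    _traj_value(cfg.reduced_trajectory, t),
                )
                true_oxd = np.clip(true_oxd + rng.normal(0.0, cfg.oxd_noise_sd, n_pos), 0.0, 1.0)
                R = oxd_to_ratio(true_oxd, calib)
                expr = rng.lognormal(cfg.expression_mu, cfg.expression_sigma, n_pos)
                i488 = expr
                i405 = R * expr
                chl = rng.lognormal(cfg.expression_mu, 0.3, n_pos)
                # autofluorescence-only cloud: dim in both roGFP channels
                af_i405 = rng.lognormal(0.0, 0.5, n_af)
                af_i488 = rng.lognormal(0.0, 0.5, n_af)
                af_chl = rng.lognormal(cfg.expression_mu, 0.3, n_af)

                sytox = rng.lognormal(0.0, 0.5, n) * cfg.sytox_background_scale
                dead = np.zeros(n, dtype=bool)
                if t == cfg.sytox_time_min:
                    # rank oxidized events first so death nests inside them
                    order = np.argsort(~oxidized, kind="stable")
                    n_dead = int(round(dead_frac * n_pos))
                    dead_pos = np.zeros(n_pos, dtype=bool)
                    dead_pos[order[:n_dead]] = True
                    dead[:n_pos] = dead_pos
                    sytox[:n_pos][dead_pos] = cfg.sytox_positive_intensity * rng.lognormal(
                        0.0, 0.2, n_dead
                    )
                ids = np.arange(event_id, event_id + n)
                event_id += n
                sample_id = f"d{dose:g}_t{t:g}_r{rep}"
                events.append(
                    pd.DataFrame(
                        {
                            "event_id": ids,
                            "i405": np.concatenate([i405, af_i405]),
                            "i488": np.concatenate([i488, af_i488]),
                            "chl": np.concatenate([chl, af_chl]),
                            "sytox": sytox,
                            "sample_id": sample_id,
                            "dose_uM": dose,
                            "time_min": t,
                            "replicate": rep,
                        }
                    )
                )
                truths.append(
                    pd.DataFrame(
                        {
                            "event_id": ids,
                            "population": np.concatenate(
                                [np.where(oxidized, "oxidized", "reduced"), np.repeat("af", n_af)]
                            ),
                            "true_oxd": np.concatenate([true_oxd, np.full(n_af, np.nan)]),
                            "dead": dead,
                            "sample_id": sample_id,
                            "dose_uM": dose,
                            "time_min": t,
                            "replicate": rep,
                        }
                    )
                )
    return (
        pd.concat(events, ignore_index=True),
        pd.concat(truths, ignore_index=True),
    )


def simulate_fate_data(
    n: int = 250,
    threshold: float = 0.74,
    slope: float = 40.0,
    seed: int = 0,
):
    """Single-cell decision-OxD values with stochastic logistic fates.

    OxD is drawn from a bimodal mixture spanning the threshold (mild
    oxidation around 0.45, strong oxidation around 0.95) and death is
    Bernoulli with P(death) = logistic(slope * (OxD - threshold)).
    Returns ``(oxd, died)`` arrays; used for fate-model parameter
    recovery at the study's per-treatment cell count (n >= 250).
    """
    rng = np.random.default_rng(seed)
    comp = rng.random(n) < 0.5
    oxd = np.where(
        comp,
        rng.normal(0.45, 0.15, n),
        rng.normal(0.95, 0.10, n),
    )
    oxd = np.clip(oxd, 0.0, 1.1)
    p = 1.0 / (1.0 + np.exp(-slope * (oxd - threshold)))
    died = rng.random(n) < p
    return oxd, died


# ---------------------------------------------------------------------------
# Imaging simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImagingSimConfig:
    """Conditions of a microfluidics time-lapse experiment."""

    field_size: Tuple[int, int] = (256, 256)  # (height, width) px
    n_cells: int = 20
    n_frames: int = 30
    frame_interval_min: float = 20.0
    semi_major_range: Tuple[float, float] = (6.0, 9.0)
    semi_minor_range: Tuple[float, float] = (3.0, 5.0)
    min_center_distance: float = 30.0
    channel_gains: Dict[str, float] = field(
        default_factory=lambda: {"i405": 1.0, "i488": 1.0, "chlorophyll": 0.8, "sytox": 1.0}
    )
    cell_brightness_mu: float = -1.4   # lognormal of per-cell i488 brightness (fraction of range)
    cell_brightness_sigma: float = 0.25
    background_level: float = 0.05
    noise_sd: float = 0.005
    poisson_noise: bool = False
    drift_per_frame: Tuple[float, float] = (0.4, -0.3)  # (dy, dx) px
    frac_oxidized: float = 0.5
    oxd_noise_sd: float = 0.02
    fate_threshold_oxd: float = 0.74
    decision_time_min: float = 40.0
    sytox_frame: Optional[int] = None   # default: last frame
    division_probability: float = 0.0   # per surviving cell per frame
    af_leakage_coeff: float = 0.0       # chlorophyll -> i405 additive leakage
    bit_depth: int = 16
    calibration: CalibrationSet = DEFAULT_CALIBRATION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_frames <= 0:
            raise ValueError("n_cells and n_frames must be positive")
        if not 0.0 <= self.frac_oxidized <= 1.0:
            raise ValueError("frac_oxidized must lie in [0, 1]")


def _place_cells(cfg: ImagingSimConfig, rng: np.random.Generator):
    """Non-overlapping initial centers, away from borders so that the
    configured drift keeps cells inside the field."""
    h, w = cfg.field_size
    total_dy = abs(cfg.drift_per_frame[0]) * (cfg.n_frames - 1)
    total_dx = abs(cfg.drift_per_frame[1]) * (cfg.n_frames - 1)
    margin_y = cfg.semi_major_range[1] + total_dy + 2
    margin_x = cfg.semi_major_range[1] + total_dx + 2
    centers = []
    attempts = 0
    while len(centers) < cfg.n_cells:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError("could not place non-overlapping cells; reduce n_cells")
        y = rng.uniform(margin_y, h - margin_y)
        x = rng.uniform(margin_x, w - margin_x)
        if all((y - cy) ** 2 + (x - cx) ** 2 >= cfg.min_center_distance**2 for cy, cx in centers):
            centers.append((y, x))
    return centers


def simulate_timelapse(cfg: ImagingSimConfig):
    """Render a 4-channel drifting time-lapse and its ground truth.

    Returns ``(stack, truth)`` where ``truth`` has one row per cell per
    frame: cell_id, frame, time_min, x, y (drifted centers), true_oxd,
    fate ('dead'/'alive'), decision_oxd, truncated.  Sytox positivity at
    the Sytox frame equals ``decision_oxd > fate_threshold_oxd`` exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.field_size
    calib = cfg.calibration
    centers = _place_cells(cfg, rng)
    n = cfg.n_cells
    semi_major = rng.uniform(*cfg.semi_major_range, n)
    semi_minor = rng.uniform(*cfg.semi_minor_range, n)
    orientation = rng.uniform(0, np.pi, n)
    brightness = rng.lognormal(cfg.cell_brightness_mu, cfg.cell_brightness_sigma, n)
    chl_brightness = rng.lognormal(cfg.cell_brightness_mu, cfg.cell_brightness_sigma, n)
    oxidized = rng.random(n) < cfg.frac_oxidized
    cell_offset = rng.normal(0.0, 0.01, n)  # stable per-cell OxD offset

    times = np.arange(cfg.n_frames) * cfg.frame_interval_min
    decision_frame = int(np.argmin(np.abs(times - cfg.decision_time_min)))
    sytox_frame = cfg.sytox_frame if cfg.sytox_frame is not None else cfg.n_frames - 1

    # per-cell per-frame true OxD
    true_oxd = np.empty((n, cfg.n_frames))
    for i in range(n):
        traj = OXIDIZED_TRAJECTORY if oxidized[i] else REDUCED_TRAJECTORY
        base = np.array([_traj_value(traj, t) for t in times])
        true_oxd[i] = np.clip(
            base + cell_offset[i] + rng.normal(0.0, cfg.oxd_noise_sd, cfg.n_frames), 0.0, 1.0
        )
    decision_oxd = true_oxd[:, decision_frame]
    dead = decision_oxd > cfg.fate_threshold_oxd

    channel_names = ("i405", "i488", "chlorophyll", "sytox")
    maxval = 2**cfg.bit_depth - 1
    pixels = np.zeros((cfg.n_frames, len(channel_names), h, w), dtype=np.uint16)
    truth_rows = []
    dy, dx = cfg.drift_per_frame
    for f in range(cfg.n_frames):
        frame_f = {name: np.zeros((h, w)) for name in channel_names}
        off_y, off_x = dy * f, dx * f
        for i in range(n):
            cy = centers[i][0] + off_y
            cx = centers[i][1] + off_x
            rr, cc = draw_ellipse(
                round(cy), round(cx), semi_major[i], semi_minor[i],
                shape=(h, w), rotation=orientation[i],
            )
            a = semi_major[i]
            truncated = bool(cy - a < 0 or cy + a >= h or cx - a < 0 or cx + a >= w)
            if truncated:
                warnings.warn(
                    f"cell {i} truncated at field boundary in frame {f}", stacklevel=2
                )
            R = oxd_to_ratio(true_oxd[i, f], calib)
            # i488 tracks the probe's reduced-state brightness; oxidation
            # dims it by the instrument factor while i405 = R * i488
            k = calib.instrument_factor
            i488_val = brightness[i] * (1.0 + (k - 1.0) * true_oxd[i, f])
            frame_f["i488"][rr, cc] += i488_val * cfg.channel_gains["i488"]
            frame_f["i405"][rr, cc] += R * i488_val * cfg.channel_gains["i405"]
            frame_f["chlorophyll"][rr, cc] += chl_brightness[i] * cfg.channel_gains["chlorophyll"]
            if f == sytox_frame and dead[i]:
                nr, nc = draw_ellipse(
                    round(cy), round(cx), max(semi_major[i] * 0.5, 1.5),
                    max(semi_minor[i] * 0.5, 1.5), shape=(h, w), rotation=orientation[i],
                )
                frame_f["sytox"][nr, nc] += 0.6 * cfg.channel_gains["sytox"]
            truth_rows.append(
                {
                    "cell_id": i,
                    "frame": f,
                    "time_min": times[f],
                    "x": cx,
                    "y": cy,
                    "true_oxd": true_oxd[i, f],
                    "fate": "dead" if dead[i] else "alive",
                    "decision_oxd": decision_oxd[i],
                    "truncated": truncated,
                }
            )
        frame_f["i405"] += cfg.af_leakage_coeff * frame_f["chlorophyll"]
        for ci, name in enumerate(channel_names):
            img = frame_f[name] + cfg.background_level
            if cfg.poisson_noise:
                img = rng.poisson(np.clip(img, 0, None) * maxval) / maxval
            img = img + rng.normal(0.0, cfg.noise_sd, (h, w))
            pixels[f, ci] = np.clip(img, 0.0, 1.0) * maxval
    stack = ImageStack(
        pixels=pixels,
        channel_names=channel_names,
        frame_times=times,
        bit_depth=cfg.bit_depth,
    )
    truth = pd.DataFrame(truth_rows)
    truth.attrs["decision_frame"] = decision_frame
    truth.attrs["sytox_frame"] = sytox_frame
    return stack, truth


# ---------------------------------------------------------------------------
# Ground-truth round trip
# ---------------------------------------------------------------------------

def export_ground_truth(truth: pd.DataFrame, path) -> None:
    """Write ground truth as CSV (lossless for the columns we generate)."""
    truth.to_csv(path, index=False)


def read_ground_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)
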