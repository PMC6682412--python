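"""Flow-cytometry event processing.

Implements probe-positive gating on the i405*i488 expression product,
per-event OxD with quality flags, automatic splitting of the bimodal
OxD distribution into 'oxidized' and 'reduced' subpopulations,
dose/time courses of the oxidized fraction, Sytox dead fractions, the
death-versus-early-oxidation linear model, and CFU survival.

The subpopulation split replaces the manual gates drawn in sorting
experiments with a seeded, reproducible procedure: a two-component
Gaussian mixture on OxD whose boundary falls between the modes, with a
kernel-density valley finder as an alternative and a fixed cutoff for
full manual control.  A unimodality guard (mode separation must exceed
twice the pooled standard deviation and the minor component must carry
more than 2% of the weight) prevents spurious splits on control
samples; guarded samples return a degenerate split with the whole
population assigned to one side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .redox import (
    CalibrationSet,
    DEFAULT_I488_FLOOR,
    OxDFlag,
    compute_oxd,
    compute_ratio,
)

__all__ = [
    "SubpopulationSplit",
    "gate_rogfp_positive",
    "oxd_per_event",
    "split_subpopulations",
    "oxidized_fraction_timecourse",
    "sytox_threshold_from_control",
    "dead_fraction",
    "death_vs_oxidation_fit",
    "cfu_survival",
]

#: OxD histogram bin edges shared across all plots/summaries.
OXD_BINS = np.arange(-0.1, 1.2 + 1e-9, 0.01)


def gate_rogfp_positive(events: pd.DataFrame, expr_threshold: float) -> pd.DataFrame:
    """Keep events whose roGFP expression proxy i405*i488 exceeds the threshold.

    The product separates probe-expressing cells from the wild-type
    autofluorescence cloud.  Gated and rejected events partition the
    input exactly.
    """
    if expr_threshold <= 0:
        raise ValueError("expr_threshold must be positive")
    product = events["i405"].to_numpy() * events["i488"].to_numpy()
    return events.loc[product > expr_threshold].reset_index(drop=True)


def oxd_per_event(
    events: pd.DataFrame,
    calib: CalibrationSet,
    i488_floor: float = DEFAULT_I488_FLOOR,
) -> pd.DataFrame:
    """Append ``oxd`` and ``oxd_flag`` columns (one OxD per event).

    Events with i488 at the floor are flagged ``INVALID``; OxD above
    110% is flagged ``EXCLUDED``.  Flagged-out events stay in the table
    but are dropped from all downstream summaries.
    """
    out = events.copy()
    ratio = compute_ratio(
        events["i405"].to_numpy(dtype=float), events["i488"].to_numpy(dtype=float),
        floor=i488_floor,
    )
    res = compute_oxd(ratio, calib)
    out["oxd"] = res.value
    out["oxd_flag"] = np.asarray(res.flag, dtype=int)
    return out


def summary_oxd(events: pd.DataFrame) -> np.ndarray:
    """OxD values eligible for summaries (in-range or over-range only)."""
    flag = events["oxd_flag"].to_numpy()
    ok = (flag == int(OxDFlag.IN_RANGE)) | (flag == int(OxDFlag.OVER_RANGE))
    return events.loc[ok, "oxd"].to_numpy(dtype=float)


@dataclass(frozen=True)
class SubpopulationSplit:
    """Result of splitting an OxD distribution at a threshold."""

    threshold_oxd: float
    frac_oxidized: float
    frac_reduced: float
    method: str
    n_events: int
    unimodal: bool = False

    def __post_init__(self) -> None:
        if not np.isclose(self.frac_oxidized + self.frac_reduced, 1.0):
            raise ValueError("fractions must sum to 1")


def _degenerate_split(oxd: np.ndarray, method: str) -> SubpopulationSplit:
    # all mass on one side: call the population oxidized if its center
    # sits in the oxidized regime
    oxidized = float(np.median(oxd)) > 0.7
    return SubpopulationSplit(
        threshold_oxd=float(np.median(oxd)),
        frac_oxidized=1.0 if oxidized else 0.0,
        frac_reduced=0.0 if oxidized else 1.0,
        method=method,
        n_events=oxd.size,
        unimodal=True,
    )


def split_subpopulations(
    oxd: Sequence[float],
    method: str = "mixture",
    fixed_threshold: Optional[float] = None,
    min_events: int = 200,
    min_weight: float = 0.02,
    separation_sds: float = 2.0,
    seed: int = 0,
) -> SubpopulationSplit:
    """Locate the boundary between the 'reduced' and 'oxidized' modes.

    method='mixture': 2-component Gaussian mixture; the threshold is the
    point between the component means where posterior membership flips.
    method='valley': minimum of a Gaussian KDE between the two modes.
    method='fixed': user-supplied cutoff.

    Unimodal inputs (guard: separation <= ``separation_sds`` pooled SDs,
    or minor weight <= ``min_weight``) return a degenerate split with
    ``unimodal=True`` instead of a spurious boundary.
    """
    x = np.asarray(oxd, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_events:
        raise ValueError(f"need at least {min_events} events, got {x.size}")

    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed method requires fixed_threshold")
        thr = float(fixed_threshold)
        frac_ox = float(np.mean(x > thr))
        return SubpopulationSplit(thr, frac_ox, 1.0 - frac_ox, "fixed", x.size)

    if method == "mixture":
        gm = GaussianMixture(n_components=2, n_init=3, random_state=seed)
        gm.fit(x[:, None])
        means = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())
        weights = gm.weights_.ravel()
        lo, hi = np.argsort(means)
        pooled = np.sqrt(np.mean(sds**2))
        if (means[hi] - means[lo]) <= separation_sds * pooled or weights.min() <= min_weight:
            return _degenerate_split(x, "mixture")
        # posterior flip point between the means
        grid = np.linspace(means[lo], means[hi], 2001)
        post = gm.predict_proba(grid[:, None])
        flip = np.argmax(post[:, hi] >= 0.5)
        thr = float(grid[flip])
        frac_ox = float(np.mean(x > thr))
        return SubpopulationSplit(thr, frac_ox, 1.0 - frac_ox, "mixture", x.size)

    if method == "valley":
        kde = stats.gaussian_kde(x)
        grid = np.linspace(x.min(), x.max(), 512)
        dens = kde(grid)
        # local maxima of the density
        peaks = np.where((dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:]))[0] + 1
        if peaks.size < 2:
            return _degenerate_split(x, "valley")
        top2 = peaks[np.argsort(dens[peaks])[-2:]]
        p_lo, p_hi = np.sort(top2)
        valley = p_lo + int(np.argmin(dens[p_lo : p_hi + 1]))
        thr = float(grid[valley])
        # guard mirrors the mixture criterion
        left, right = x[x <= thr], x[x > thr]
        if left.size == 0 or right.size == 0:
            return _degenerate_split(x, "valley")
        pooled = np.sqrt((left.var() * left.size + right.var() * right.size) / x.size)
        if (right.mean() - left.mean()) <= separation_sds * pooled or min(
            left.size, right.size
        ) <= min_weight * x.size:
            return _degenerate_split(x, "valley")
        frac_ox = float(np.mean(x > thr))
        return SubpopulationSplit(thr, frac_ox, 1.0 - frac_ox, "valley", x.size)

    raise ValueError(f"unknown method {method!r}")


def oxidized_fraction_timecourse(
    events: pd.DataFrame,
    calib: CalibrationSet,
    expr_threshold: float,
    method: str = "mixture",
    fixed_threshold: Optional[float] = None,
    min_events: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Oxidized fraction per (dose, time, replicate), plus mean +- SEM.

    Gating, per-event OxD and subpopulation splitting are applied per
    sample; excluded/invalid OxD values never enter the fractions.
    Returns a tidy frame with columns dose_uM, time_min, replicate,
    frac_oxidized, threshold_oxd, unimodal, n.
    """
    if calib is None:
        raise ValueError("calibration is required")
    gated = gate_rogfp_positive(events, expr_threshold)
    gated = oxd_per_event(gated, calib)
    rows = []
    for (dose, t, rep), grp in gated.groupby(["dose_uM", "time_min", "replicate"], sort=True):
        oxd = summary_oxd(grp)
        split = split_subpopulations(
            oxd, method=method, fixed_threshold=fixed_threshold,
            min_events=min_events, seed=seed,
        )
        rows.append(
            {
                "dose_uM": dose,
                "time_min": t,
                "replicate": rep,
                "frac_oxidized": split.frac_oxidized,
                "threshold_oxd": split.threshold_oxd,
                "unimodal": split.unimodal,
                "n": split.n_events,
            }
        )
    return pd.DataFrame(rows)


def sytox_threshold_from_control(unstained_sytox: Sequence[float], q: float = 0.999) -> float:
    """Dead/alive Sytox cutoff: a high quantile of an unstained control."""
    x = np.asarray(unstained_sytox, dtype=float)
    if x.size == 0:
        raise ValueError("empty control sample")
    return float(np.quantile(x, q))


def dead_fraction(events: pd.DataFrame, sytox_threshold: float) -> float:
    """Fraction of events above the Sytox staining threshold."""
    if sytox_threshold <= 0:
        raise ValueError("sytox_threshold must be positive")
    if "sytox" not in events.columns:
        raise ValueError("events have no 'sytox' column")
    sytox = events["sytox"].to_numpy(dtype=float)
    return float(np.mean(sytox > sytox_threshold))


def death_vs_oxidation_fit(points: Sequence[Tuple[float, float]]):
    """OLS of the 24 h dead fraction on the early oxidized fraction.

    ``points`` are (frac_oxidized at ~1-2 h, frac_dead at ~24 h) pairs,
    one per sample.  Returns ``(slope, intercept, r_squared, p_value)``
    from the standard t machinery of the single regression.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.allclose(x, x[0]):
        raise ValueError("degenerate fit: zero variance in x")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)


def cfu_survival(n_colonies: int, n_sorted: int) -> float:
    """Colony-forming-unit survival: 100 * colonies / sorted cells (%)."""
    if n_sorted <= 0:
        raise ValueError("n_sorted must be positive")
    if not 0 <= n_colonies <= n_sorted:
        raise ValueError("n_colonies must lie in [0, n_sorted]")
    return 100.0 * n_colonies / n_sorted
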