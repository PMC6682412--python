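"""Time-lapse image pipeline: registration through per-cell OxD measurement.

The pipeline mirrors the standard workflow for ratiometric biosensor
microscopy of settled cells in a flow chamber:

    register -> normalize by bit depth -> subtract background -> channel
    masks -> expression mask -> pixel-wise OxD -> watershed segmentation
    -> shape filtering -> per-cell measurement

Stage drift is corrected by translation-only phase cross-correlation
against the first frame.  The roGFP expression mask keeps only pixels
that are bright in BOTH excitation channels (their product above a
threshold), which suppresses autofluorescence-only pixels before the
ratio is formed.  Per-cell OxD is summarized as the median over the
cell's expression-mask pixels (robust against leakage-inflated pixels);
the mean is reported alongside.

Coordinates are 0-based with (x, y) = (column, row), origin top-left.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian
from skimage.measure import label as cc_label, regionprops
from skimage.registration import phase_cross_correlation
from skimage.segmentation import watershed

from .redox import CalibrationSet, OxDFlag, compute_oxd, compute_ratio

__all__ = [
    "ImageStack",
    "FilterCriteria",
    "register_stack",
    "normalize_bit_depth",
    "subtract_background",
    "threshold_mask",
    "expression_mask",
    "pixel_oxd_map",
    "segment_cells",
    "filter_objects",
    "measure_cells",
    "analyze_stack",
]

VALID_BIT_DEPTHS = (8, 12, 14, 16)


@dataclass
class ImageStack:
    """Multi-channel, multi-frame pixel data plus spatial/temporal metadata.

    ``pixels`` has shape (frames, channels, height, width).
    """

    pixels: np.ndarray
    channel_names: tuple
    frame_times: np.ndarray  # minutes
    bit_depth: int = 16
    pixel_size_um: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError("pixels must be (frames, channels, height, width)")
        self.channel_names = tuple(self.channel_names)
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.pixels.shape[1] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.shape[0] != self.pixels.shape[0]:
            raise ValueError("frame_times length does not match frame axis")
        if self.bit_depth not in VALID_BIT_DEPTHS:
            raise ValueError(f"bit_depth must be one of {VALID_BIT_DEPTHS}")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    def channel(self, name: str, frame: Optional[int] = None) -> np.ndarray:
        ci = self.channel_names.index(name)
        return self.pixels[:, ci] if frame is None else self.pixels[frame, ci]

    # -- TIFF + JSON sidecar round-trip ----------------------------------

    def write(self, tiff_path, sidecar_path=None) -> None:
        """Write as a multi-page TIFF (frame-major, channel-interleaved)
        with a JSON sidecar holding channel names, frame times and depth."""
        tiff_path = str(tiff_path)
        if sidecar_path is None:
            sidecar_path = tiff_path.rsplit(".", 1)[0] + ".json"
        t, c, h, w = self.pixels.shape
        pages = self.pixels.reshape(t * c, h, w)
        tifffile.imwrite(tiff_path, pages)
        meta = {
            "channel_names": list(self.channel_names),
            "frame_times_min": [float(x) for x in self.frame_times],
            "bit_depth": int(self.bit_depth),
            "pixel_size_um": self.pixel_size_um,
            "n_frames": int(t),
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def read(cls, tiff_path, sidecar_path=None) -> "ImageStack":
        tiff_path = str(tiff_path)
        if sidecar_path is None:
            sidecar_path = tiff_path.rsplit(".", 1)[0] + ".json"
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        pages = tifffile.imread(tiff_path)
        if pages.ndim == 2:
            pages = pages[None]
        n_frames = int(meta["n_frames"])
        n_chan = len(meta["channel_names"])
        if pages.shape[0] != n_frames * n_chan:
            raise ValueError(
                f"TIFF page count mismatch: expected {n_frames * n_chan} "
                f"(frames x channels), found {pages.shape[0]}"
            )
        pixels = pages.reshape(n_frames, n_chan, *pages.shape[1:])
        return cls(
            pixels=pixels,
            channel_names=tuple(meta["channel_names"]),
            frame_times=np.asarray(meta["frame_times_min"], dtype=float),
            bit_depth=int(meta["bit_depth"]),
            pixel_size_um=meta.get("pixel_size_um"),
        )


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

def register_stack(
    stack: ImageStack,
    reference_channel: str = "chlorophyll",
    upsample_factor: int = 10,
    max_shift: Optional[float] = None,
):
    """Align every frame to frame 0 by translation (XY drift correction).

    Offsets are estimated on ``reference_channel`` with phase
    cross-correlation and the same shift is applied to all channels of
    the frame.  Returns ``(registered_stack, offsets)`` where
    ``offsets[f] = (dy, dx)`` is the shift that was applied to frame f
    (the negative of the estimated drift).  Integer drifts are recovered
    exactly.  Border pixels revealed by the shift carry no data: they
    are filled with the frame's median intensity (background) so they
    cannot masquerade as cells, and are marked invalid in the returned
    ``valid_mask`` (True where every frame has real data).
    A frame whose estimated drift reaches ``max_shift`` gets a warning.
    """
    if stack.n_frames < 2:
        return stack, np.zeros((stack.n_frames, 2))
    ref_ci = stack.channel_names.index(reference_channel)
    ref = stack.pixels[0, ref_ci].astype(float)
    out = stack.pixels.astype(float).copy()
    offsets = np.zeros((stack.n_frames, 2))
    h, w = ref.shape
    valid = np.ones((h, w), dtype=bool)
    for f in range(1, stack.n_frames):
        shift, _, _ = phase_cross_correlation(
            ref, stack.pixels[f, ref_ci].astype(float), upsample_factor=upsample_factor
        )
        if max_shift is not None and np.any(np.abs(shift) >= max_shift):
            warnings.warn(
                f"frame {f}: estimated drift {tuple(shift)} at search-range boundary",
                stacklevel=2,
            )
        offsets[f] = shift
        border = np.zeros((h, w), dtype=bool)
        if np.allclose(shift, np.round(shift)):
            sy, sx = int(round(shift[0])), int(round(shift[1]))
            for ci in range(out.shape[1]):
                frame_img = stack.pixels[f, ci].astype(float)
                fill = float(np.median(frame_img))
                rolled = np.roll(np.roll(frame_img, sy, axis=0), sx, axis=1)
                if sy > 0:
                    rolled[:sy] = fill
                elif sy < 0:
                    rolled[sy:] = fill
                if sx > 0:
                    rolled[:, :sx] = fill
                elif sx < 0:
                    rolled[:, sx:] = fill
                out[f, ci] = rolled
            if sy > 0:
                border[:sy] = True
            elif sy < 0:
                border[sy:] = True
            if sx > 0:
                border[:, :sx] = True
            elif sx < 0:
                border[:, sx:] = True
        else:
            for ci in range(out.shape[1]):
                frame_img = stack.pixels[f, ci].astype(float)
                fill = float(np.median(frame_img))
                out[f, ci] = ndi.shift(frame_img, shift, order=1, mode="constant", cval=fill)
            sy_up, sx_up = int(np.ceil(abs(shift[0]))), int(np.ceil(abs(shift[1])))
            if shift[0] > 0:
                border[:sy_up] = True
            elif shift[0] < 0 and sy_up:
                border[-sy_up:] = True
            if shift[1] > 0:
                border[:, :sx_up] = True
            elif shift[1] < 0 and sx_up:
                border[:, -sx_up:] = True
        valid &= ~border
    reg = ImageStack(
        pixels=out,
        channel_names=stack.channel_names,
        frame_times=stack.frame_times,
        bit_depth=stack.bit_depth,
        pixel_size_um=stack.pixel_size_um,
    )
    reg.valid_mask = valid
    return reg, offsets


# ---------------------------------------------------------------------------
# Normalization / background / masks
# ---------------------------------------------------------------------------

def normalize_bit_depth(image: np.ndarray, bit_depth: int):
    """Scale integer intensities into [0, 1] by the bit-depth maximum.

    Returns ``(normalized, saturated_mask)``; pixels at or above the
    maximum representable value are flagged saturated, values beyond it
    raise (they cannot come from the stated depth).
    """
    if bit_depth not in VALID_BIT_DEPTHS:
        raise ValueError(f"bit_depth must be one of {VALID_BIT_DEPTHS}")
    maxval = 2**bit_depth - 1
    image = np.asarray(image, dtype=float)
    if np.any(image > maxval):
        raise ValueError(f"intensities exceed {maxval} for bit depth {bit_depth}")
    saturated = image >= maxval
    return image / maxval, saturated


def subtract_background(image: np.ndarray, roi, cell_mask: Optional[np.ndarray] = None):
    """Subtract the mean of a user-defined cell-free ROI, flooring at 0.

    ``roi`` is ``(row0, row1, col0, col1)`` (half-open).  If a cell mask
    is supplied and the ROI overlaps it, a warning is emitted (the ROI
    is supposed to contain no cells).  Returns ``(image, background)``.
    """
    r0, r1, c0, c1 = roi
    h, w = image.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"ROI {roi} outside image bounds {(h, w)} or empty")
    if cell_mask is not None and np.any(cell_mask[r0:r1, c0:c1]):
        warnings.warn("background ROI overlaps segmented cells", stacklevel=2)
    background = float(np.mean(image[r0:r1, c0:c1]))
    return np.maximum(image - background, 0.0), background


def auto_background_roi(image: np.ndarray, tile: int = 32):
    """Fallback ROI: the lowest-mean tile on a regular grid."""
    h, w = image.shape
    best, best_roi = np.inf, None
    for r0 in range(0, h - tile + 1, tile):
        for c0 in range(0, w - tile + 1, tile):
            m = image[r0 : r0 + tile, c0 : c0 + tile].mean()
            if m < best:
                best, best_roi = m, (r0, r0 + tile, c0, c0 + tile)
    return best_roi


def threshold_mask(image: np.ndarray, t: float) -> np.ndarray:
    """Binary mask of pixels strictly above ``t`` (image normalized to [0,1])."""
    if not 0 < t < 1:
        raise ValueError("threshold must be in (0, 1) after normalization")
    return image > t


def expression_mask(
    i405: np.ndarray,
    i488: np.ndarray,
    t_expr: float,
    mask405: Optional[np.ndarray] = None,
    mask488: Optional[np.ndarray] = None,
) -> np.ndarray:
    """roGFP expression mask: pixels in BOTH channel masks whose
    i405*i488 product exceeds ``t_expr``."""
    if mask405 is None:
        mask405 = i405 > 0
    if mask488 is None:
        mask488 = i488 > 0
    return mask405 & mask488 & ((i405 * i488) > t_expr)


# ---------------------------------------------------------------------------
# Pixel OxD
# ---------------------------------------------------------------------------

def pixel_oxd_map(
    i405: np.ndarray,
    i488: np.ndarray,
    calib: CalibrationSet,
    mask: np.ndarray,
    i488_floor: float = 1e-12,
):
    """Per-pixel OxD inside ``mask``; NaN outside.

    Returns ``(oxd_image, flag_image)``.  Out-of-mask pixels carry flag
    ``INVALID``; in-mask pixels follow the over-range policy (values
    above 110% flagged ``EXCLUDED``).
    """
    if not np.any(mask):
        warnings.warn("expression mask is empty; OxD map has no defined pixels", stacklevel=2)
    oxd = np.full(i405.shape, np.nan)
    flags = np.full(i405.shape, int(OxDFlag.INVALID), dtype=np.int8)
    valid = mask & (i488 > i488_floor)
    if np.any(valid):
        ratio = compute_ratio(i405[valid], i488[valid], floor=i488_floor)
        res = compute_oxd(ratio, calib)
        oxd[valid] = res.value
        flags[valid] = res.flag
    return oxd, flags


# ---------------------------------------------------------------------------
# Segmentation / filtering / measurement
# ---------------------------------------------------------------------------

def segment_cells(
    seed_image: np.ndarray,
    mask: np.ndarray,
    smoothing_sigma: float = 1.0,
    min_distance: int = 8,
) -> np.ndarray:
    """Watershed segmentation of the mask, seeded at local intensity maxima.

    The seed channel (i405 for roGFP strains, chlorophyll otherwise) is
    smoothed, local maxima at least ``min_distance`` apart become
    markers, and the watershed of the inverted intensity splits touching
    cells along intensity saddles.  Every labeled pixel lies inside the
    mask; an empty mask yields zero labels.
    """
    if not np.any(mask):
        return np.zeros(mask.shape, dtype=np.int32)
    smooth = gaussian(seed_image.astype(float), sigma=smoothing_sigma, preserve_range=True)
    coords = peak_local_max(
        smooth, min_distance=min_distance, labels=mask, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:  # no interior maxima; fall back to connected components
        return cc_label(mask).astype(np.int32)
    labels = watershed(-smooth, markers=markers, mask=mask)
    return labels.astype(np.int32)


@dataclass(frozen=True)
class FilterCriteria:
    """Shape bounds used to reject debris, clumps and doublets."""

    area_min: float = 20.0
    area_max: float = 500.0
    major_axis_max: float = 40.0
    minor_axis_min: float = 2.0
    eccentricity_max: float = 0.97


def filter_objects(labels: np.ndarray, criteria: FilterCriteria = FilterCriteria()):
    """Keep only objects within the area/axis/eccentricity bounds.

    Returns ``(filtered_labels, removal_log)``; the log maps removed
    label -> list of violated bounds.
    """
    out = labels.copy()
    removal_log: dict = {}
    for prop in regionprops(labels):
        reasons = []
        if prop.area < criteria.area_min:
            reasons.append("area_min")
        if prop.area > criteria.area_max:
            reasons.append("area_max")
        if prop.axis_major_length > criteria.major_axis_max:
            reasons.append("major_axis_max")
        if prop.axis_minor_length < criteria.minor_axis_min:
            reasons.append("minor_axis_min")
        if prop.eccentricity > criteria.eccentricity_max:
            reasons.append("eccentricity_max")
        if reasons:
            out[labels == prop.label] = 0
            removal_log[prop.label] = reasons
    return out, removal_log


def measure_cells(
    labels: np.ndarray,
    oxd: np.ndarray,
    oxd_flags: np.ndarray,
    channels: Optional[dict] = None,
    frame: int = 0,
) -> pd.DataFrame:
    """One record per labeled object: centroid, shape, and OxD summary.

    OxD statistics use only defined, non-excluded pixels.  The median
    uses the lower-middle element on even counts (always an observed
    pixel value; ties break low).  A cell with no usable OxD pixel gets
    ``n_oxd_pixels = 0`` and NaN summaries.
    Columns: frame, label, x, y, area, major_axis, minor_axis,
    eccentricity, mean_oxd, median_oxd, n_oxd_pixels, mean_<channel>...
    """
    usable = np.isfinite(oxd) & (
        (oxd_flags == OxDFlag.IN_RANGE) | (oxd_flags == OxDFlag.OVER_RANGE)
    )
    records = []
    for prop in regionprops(labels):
        region = labels == prop.label
        vals = oxd[region & usable]
        rec = {
            "frame": frame,
            "label": prop.label,
            "x": prop.centroid[1],
            "y": prop.centroid[0],
            "area": float(prop.area),
            "major_axis": prop.axis_major_length,
            "minor_axis": prop.axis_minor_length,
            "eccentricity": prop.eccentricity,
            "n_oxd_pixels": int(vals.size),
            "mean_oxd": float(np.mean(vals)) if vals.size else np.nan,
            "median_oxd": float(np.percentile(vals, 50, method="lower")) if vals.size else np.nan,
        }
        if channels:
            for name, img in channels.items():
                rec[f"mean_{name}"] = float(np.mean(img[region]))
        records.append(rec)
    cols = [
        "frame", "label", "x", "y", "area", "major_axis", "minor_axis",
        "eccentricity", "n_oxd_pixels", "mean_oxd", "median_oxd",
    ]
    if channels:
        cols += [f"mean_{name}" for name in channels]
    return pd.DataFrame(records, columns=cols)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def analyze_stack(
    stack: ImageStack,
    calib: CalibrationSet,
    channel_thresholds: Optional[dict] = None,
    t_expr: float = 2.5e-4,
    background_roi=None,
    seed_channel: str = "i405",
    criteria: FilterCriteria = FilterCriteria(),
    register: bool = True,
    reference_channel: str = "chlorophyll",
    min_distance: int = 8,
):
    """Full per-frame pipeline; returns ``(cells_df, qc)``.

    ``cells_df`` concatenates :func:`measure_cells` across frames with a
    ``time_min`` column; ``qc`` records offsets, background levels,
    object counts and removal reasons per frame.
    """
    if channel_thresholds is None:
        channel_thresholds = {"i405": 0.02, "i488": 0.02, "chlorophyll": 0.02}
    if register:
        stack, offsets = register_stack(stack, reference_channel=reference_channel)
    else:
        offsets = np.zeros((stack.n_frames, 2))
    qc = {"offsets": offsets.tolist(), "frames": []}
    frames_out = []
    fluor = [c for c in ("i405", "i488", "chlorophyll") if c in stack.channel_names]
    for f in range(stack.n_frames):
        norm = {}
        for name in fluor:
            norm[name], _ = normalize_bit_depth(stack.channel(name, f), stack.bit_depth)
        roi = background_roi or auto_background_roi(norm[fluor[0]])
        backgrounds = {}
        for name in fluor:
            norm[name], backgrounds[name] = subtract_background(norm[name], roi)
        masks = {name: threshold_mask(norm[name], channel_thresholds[name]) for name in fluor}
        expr = expression_mask(norm["i405"], norm["i488"], t_expr, masks["i405"], masks["i488"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            oxd, flags = pixel_oxd_map(norm["i405"], norm["i488"], calib, expr)
        labels = segment_cells(norm[seed_channel], masks[seed_channel], min_distance=min_distance)
        labels, removal_log = filter_objects(labels, criteria)
        cells = measure_cells(labels, oxd, flags, channels=norm, frame=f)
        cells["time_min"] = stack.frame_times[f]
        frames_out.append(cells)
        qc["frames"].append(
            {
                "frame": f,
                "background": backgrounds,
                "n_objects": int(cells.shape[0]),
                "n_removed": len(removal_log),
                "removed": {int(k): v for k, v in removal_log.items()},
            }
        )
    cells_df = pd.concat(frames_out, ignore_index=True) if frames_out else pd.DataFrame()
    return cells_df, qc
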