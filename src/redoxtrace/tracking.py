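"""Frame-to-frame cell linking, track assembly, and fate assignment.

Segmented cells are linked between adjacent frames by globally optimal
min-cost bipartite matching on centroid distance (cells settled on the
chamber glass barely move once stage drift is corrected, so nearest-
centroid assignment with a hard distance limit is the right model).
Tracks must be strictly consecutive; a track shorter than the minimum
length (default 6 frames) or absent from the Sytox frame is marked
``unresolved`` and never enters fate statistics.  Terminal fate is
called by co-localization of thresholded Sytox signal with the cell
region extended by a small morphological dilation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy import ndimage as ndi

__all__ = [
    "Track",
    "link_frames",
    "build_tracks",
    "assign_fate",
    "extract_decision_oxd",
    "track_cells",
    "tracks_to_frame",
]

DEFAULT_MAX_DIST = 15.0
DEFAULT_MIN_LEN = 6
DEFAULT_DILATION_PX = 3


@dataclass
class Track:
    """A chain of per-frame cell records for one followed cell."""

    track_id: int
    records: pd.DataFrame  # per-frame rows with frame, label, x, y, ... (consecutive)
    fate: str = "unresolved"  # 'alive' | 'dead' | 'unresolved'
    decision_oxd: float = float("nan")

    def __post_init__(self) -> None:
        frames = self.records["frame"].to_numpy()
        if len(frames) == 0:
            raise ValueError("a track needs at least one record")
        if not np.all(np.diff(frames) == 1):
            raise ValueError("track frames must be strictly consecutive")

    @property
    def start_frame(self) -> int:
        return int(self.records["frame"].iloc[0])

    @property
    def end_frame(self) -> int:
        return int(self.records["frame"].iloc[-1])

    def __len__(self) -> int:
        return len(self.records)


def link_frames(
    cells_a: pd.DataFrame,
    cells_b: pd.DataFrame,
    max_dist: float = DEFAULT_MAX_DIST,
) -> List[Tuple[int, int]]:
    """Optimal one-to-one partial matching between two frames.

    Returns index pairs (row position in ``cells_a``, row position in
    ``cells_b``).  Among all partial matchings whose pairs lie within
    ``max_dist``, the result has maximum cardinality and, among those,
    minimum total centroid distance (min-cost bipartite assignment with
    the distance limit as an infeasibility cutoff — not greedy
    nearest-neighbour).
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    na, nb = len(cells_a), len(cells_b)
    if na == 0 or nb == 0:
        return []
    ax = cells_a[["x", "y"]].to_numpy(dtype=float)
    bx = cells_b[["x", "y"]].to_numpy(dtype=float)
    dist = np.linalg.norm(ax[:, None, :] - bx[None, :, :], axis=-1)
    feasible = dist <= max_dist
    # big-M makes the solver prefer any feasible pair over leaving it
    # unmatched, i.e. maximum cardinality first, then minimum distance
    big = max_dist * (min(na, nb) + 1) * 1e3 + 1.0
    cost = np.where(feasible, dist, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if feasible[i, j]]


def link_frames_greedy(
    cells_a: pd.DataFrame, cells_b: pd.DataFrame, max_dist: float = DEFAULT_MAX_DIST
) -> List[Tuple[int, int]]:
    """Greedy nearest-neighbour linking (comparison baseline only)."""
    na, nb = len(cells_a), len(cells_b)
    if na == 0 or nb == 0:
        return []
    ax = cells_a[["x", "y"]].to_numpy(dtype=float)
    bx = cells_b[["x", "y"]].to_numpy(dtype=float)
    dist = np.linalg.norm(ax[:, None, :] - bx[None, :, :], axis=-1)
    pairs = []
    used_a, used_b = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
    for i, j in order:
        if dist[i, j] > max_dist:
            break
        if i not in used_a and j not in used_b:
            pairs.append((int(i), int(j)))
            used_a.add(int(i))
            used_b.add(int(j))
    return pairs


def build_tracks(
    frames: Sequence[pd.DataFrame],
    max_dist: float = DEFAULT_MAX_DIST,
    min_len: int = DEFAULT_MIN_LEN,
    linker=link_frames,
) -> List[Track]:
    """Assemble tracks by chaining adjacent-frame links.

    ``frames`` is a time-ordered list of per-frame cell tables (each
    needs x, y columns; a ``frame`` column is added/overwritten from the
    position in the list).  Unmatched cells start new tracks; a broken
    link ends a track — there is no gap closing.  Tracks shorter than
    ``min_len`` keep fate='unresolved' permanently.
    """
    chains: List[List[Tuple[int, int]]] = []  # list of (frame, row position)
    open_chain_of: dict = {}  # row position in current frame -> chain index
    for f, cells in enumerate(frames):
        new_open: dict = {}
        if f == 0:
            for i in range(len(cells)):
                chains.append([(0, i)])
                new_open[i] = len(chains) - 1
        else:
            pairs = linker(frames[f - 1], cells, max_dist=max_dist)
            matched_b = set()
            for i, j in pairs:
                ci = open_chain_of.get(i)
                if ci is not None:
                    chains[ci].append((f, j))
                    new_open[j] = ci
                    matched_b.add(j)
            for j in range(len(cells)):
                if j not in matched_b:
                    chains.append([(f, j)])
                    new_open[j] = len(chains) - 1
        open_chain_of = new_open
    tracks = []
    for tid, chain in enumerate(chains):
        recs = []
        for f, j in chain:
            row = frames[f].iloc[j].to_dict()
            row["frame"] = f
            recs.append(row)
        track = Track(track_id=tid, records=pd.DataFrame(recs))
        tracks.append(track)
    return tracks


def assign_fate(
    track: Track,
    sytox_image: np.ndarray,
    labels: np.ndarray,
    sytox_threshold: float,
    dilation_px: int = DEFAULT_DILATION_PX,
    sytox_frame: Optional[int] = None,
    min_len: int = DEFAULT_MIN_LEN,
) -> str:
    """Call 'dead'/'alive' from Sytox co-localization at the Sytox frame.

    The track's segmented region in the Sytox-frame label image is
    dilated by ``dilation_px`` (the nucleus of a dying cell may sit at
    the cell edge); the fate is 'dead' iff any thresholded Sytox pixel
    falls inside that extended region.  Tracks shorter than ``min_len``
    or absent from the Sytox frame stay 'unresolved'.
    """
    if sytox_image is None:
        raise ValueError("missing Sytox channel")
    if sytox_frame is None:
        sytox_frame = int(track.records["frame"].max())
    if len(track) < min_len:
        track.fate = "unresolved"
        return track.fate
    at_frame = track.records[track.records["frame"] == sytox_frame]
    if at_frame.empty:
        track.fate = "unresolved"
        return track.fate
    lbl = int(at_frame["label"].iloc[0])
    region = labels == lbl
    if dilation_px > 0:
        region = ndi.binary_dilation(region, iterations=dilation_px)
    track.fate = "dead" if np.any((sytox_image > sytox_threshold) & region) else "alive"
    return track.fate


def extract_decision_oxd(
    track: Track,
    decision_time: float,
    time_col: str = "time_min",
    oxd_col: str = "median_oxd",
    tolerance: Optional[float] = None,
) -> float:
    """Per-cell OxD at the frame nearest the decision time.

    Ties between equally near frames break toward the earlier frame.
    Returns NaN (and leaves the track unresolved for prediction
    purposes) when no frame lies within ``tolerance`` minutes.
    """
    times = track.records[time_col].to_numpy(dtype=float)
    diffs = np.abs(times - decision_time)
    idx = int(np.argmin(diffs))  # argmin takes the first (earlier) on ties
    if tolerance is not None and diffs[idx] > tolerance:
        track.decision_oxd = float("nan")
        return track.decision_oxd
    track.decision_oxd = float(track.records[oxd_col].iloc[idx])
    return track.decision_oxd


def track_cells(
    cells_df: pd.DataFrame,
    sytox_image: Optional[np.ndarray] = None,
    labels_at_sytox: Optional[np.ndarray] = None,
    sytox_threshold: float = 0.1,
    sytox_frame: Optional[int] = None,
    decision_time: float = 40.0,
    max_dist: float = DEFAULT_MAX_DIST,
    min_len: int = DEFAULT_MIN_LEN,
    dilation_px: int = DEFAULT_DILATION_PX,
) -> List[Track]:
    """Tracks from a concatenated per-frame measurement table.

    Splits ``cells_df`` (as produced by ``imaging.analyze_stack``) by
    frame, links, assigns fates (when a Sytox frame is given) and
    extracts decision OxD for resolved tracks.
    """
    n_frames = int(cells_df["frame"].max()) + 1 if len(cells_df) else 0
    frames = [
        cells_df[cells_df["frame"] == f].reset_index(drop=True) for f in range(n_frames)
    ]
    tracks = build_tracks(frames, max_dist=max_dist, min_len=min_len)
    for track in tracks:
        if sytox_image is not None and labels_at_sytox is not None:
            assign_fate(
                track, sytox_image, labels_at_sytox, sytox_threshold,
                dilation_px=dilation_px, sytox_frame=sytox_frame, min_len=min_len,
            )
        if track.fate != "unresolved" or (sytox_image is None and len(track) >= min_len):
            extract_decision_oxd(track, decision_time)
    return tracks


def tracks_to_frame(tracks: Sequence[Track]) -> pd.DataFrame:
    """Long-form CSV-ready view: track_id, frame, label, x, y, oxd, fate."""
    rows = []
    for tr in tracks:
        for _, rec in tr.records.iterrows():
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": int(rec["frame"]),
                    "label": rec.get("label", np.nan),
                    "x": rec["x"],
                    "y": rec["y"],
                    "oxd": rec.get("median_oxd", np.nan),
                    "fate": tr.fate,
                    "decision_oxd": tr.decision_oxd,
                }
            )
    return pd.DataFrame(rows)
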