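"""Organelle mobility: object tracking and first-frame autocorrelation.

Two complementary readouts:

* **tracking** — per-frame centroids are linked frame-to-frame by a
  deterministic, distance-gated greedy nearest-pair assignment with
  optional gap closing.  Each track reports its duration, straight-line
  displacement and **mean straight velocity** (displacement / duration);
  tracks shorter than 10 s are treated as noise and dropped by default.
* **autocorrelation** — each frame is compared to frame 0 with thresholded
  Manders coefficients; moving organelles decorrelate from their starting
  positions, so the decay rate of the curve is a segmentation-free proxy
  for mobility (and, using overlap rather than intensity covariance, is
  robust to photobleaching).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmental import isodata_threshold

__all__ = [
    "Track",
    "CorrelationCurve",
    "track_organelles",
    "filter_tracks",
    "mean_straight_velocity",
    "manders_coefficients",
    "autocorrelation_curve",
    "summarize_mobility",
    "tracks_to_frame",
]


@dataclass
class Track:
    """One organelle trajectory (frames with a detection, centroids in µm)."""

    track_id: int
    frames: list[int]
    centroids_um: list[tuple[float, float]]
    frame_interval_s: float

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        return (self.frames[-1] - self.frames[0]) * self.frame_interval_s

    @property
    def displacement_um(self) -> float:
        (y0, x0), (y1, x1) = self.centroids_um[0], self.centroids_um[-1]
        return float(np.hypot(y1 - y0, x1 - x0))

    @property
    def path_length_um(self) -> float:
        c = np.asarray(self.centroids_um)
        return float(np.sum(np.hypot(*np.diff(c, axis=0).T)))


@dataclass
class CorrelationCurve:
    """First-frame correlation decay for one cell/time-lapse."""

    cell_id: str
    offsets_s: np.ndarray  # starting at one frame interval
    values: np.ndarray  # mean of M1 and M2, in [0, 1]
    m1: np.ndarray = None
    m2: np.ndarray = None


# --------------------------------------------------------------------------
# tracking
# --------------------------------------------------------------------------
def track_organelles(
    detections: list[dict[int, tuple[float, float]]] | list[list],
    frame_interval_s: float,
    max_link_um: float = 1.0,
    max_gap_frames: int = 0,
) -> list[Track]:
    """Greedy globally-nearest-pair linking of per-frame centroids.

    ``detections[t]`` maps a detection id (e.g. segmentation label) to a
    centroid in µm, or is a plain list of centroids.  At each frame all
    (open track, detection) pairs within ``max_link_um`` are linked in
    ascending distance order, ties broken by (track id, detection id) for
    determinism.  Unlinked detections open new tracks; tracks unmatched
    for more than ``max_gap_frames`` frames are closed.
    """
    if max_link_um < 0:
        raise ValueError("max_link_um must be nonnegative")
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be positive")
    tracks: list[Track] = []
    open_tracks: list[int] = []  # indices into tracks
    next_id = 1
    for t, dets in enumerate(detections):
        if isinstance(dets, dict):
            items = sorted(dets.items())
        else:
            items = list(enumerate(dets))
        cands = []
        for ti in open_tracks:
            ty, tx = tracks[ti].centroids_um[-1]
            for di, (dy, dx) in items:
                d = np.hypot(dy - ty, dx - tx)
                if d <= max_link_um:
                    cands.append((d, tracks[ti].track_id, di, ti))
        used_tracks: set[int] = set()
        used_dets: set = set()
        for d, _, di, ti in sorted(cands):
            if ti in used_tracks or di in used_dets:
                continue
            used_tracks.add(ti)
            used_dets.add(di)
            tracks[ti].frames.append(t)
            tracks[ti].centroids_um.append(dict(items)[di])
        for di, c in items:
            if di not in used_dets:
                tracks.append(
                    Track(
                        track_id=next_id,
                        frames=[t],
                        centroids_um=[tuple(c)],
                        frame_interval_s=frame_interval_s,
                    )
                )
                next_id += 1
        open_tracks = [
            i
            for i, tr in enumerate(tracks)
            if t - tr.frames[-1] <= max_gap_frames
        ]
    return tracks


def filter_tracks(tracks: list[Track], min_duration_s: float = 10.0) -> list[Track]:
    """Drop tracks shorter than ``min_duration_s`` (noise by convention)."""
    return [tr for tr in tracks if tr.duration_s >= min_duration_s]


def mean_straight_velocity(track: Track) -> float:
    """Straight-line displacement divided by track duration, µm/s."""
    if track.n_points < 2 or track.duration_s <= 0:
        raise ValueError("velocity undefined for single-point tracks")
    return track.displacement_um / track.duration_s


# --------------------------------------------------------------------------
# Manders / autocorrelation
# --------------------------------------------------------------------------
def manders_coefficients(
    image_a: np.ndarray,
    image_b: np.ndarray,
    threshold_a: float,
    threshold_b: float,
) -> tuple[float, float]:
    """Thresholded Manders colocalization coefficients (M1, M2).

    ``M1`` = fraction of A's above-threshold intensity lying where B is
    above its threshold; ``M2`` symmetrically for B.  Both lie in [0, 1].
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if threshold_a < 0 or threshold_b < 0:
        raise ValueError("thresholds must be nonnegative")
    a_sup, b_sup = a > threshold_a, b > threshold_b
    denom_a = a[a_sup].sum()
    denom_b = b[b_sup].sum()
    if denom_a <= 0 or denom_b <= 0:
        raise ValueError("no signal above threshold")
    m1 = float(a[a_sup & b_sup].sum() / denom_a)
    m2 = float(b[a_sup & b_sup].sum() / denom_b)
    return min(m1, 1.0), min(m2, 1.0)


def autocorrelation_curve(
    channel_stack: np.ndarray,
    frame_interval_s: float,
    cell_id: str = "cell",
    thresholds: np.ndarray | float | None = None,
    component: str = "mean",  # mean | m1 | m2
) -> CorrelationCurve:
    """Manders correlation of every frame against frame 0.

    Thresholds default to the per-frame IsoData level (auto-threshold
    intent); a scalar applies to all frames, an array gives one per frame.
    The curve value is the mean of M1 and M2 (both retained); a static
    stack yields 1 at every offset.
    """
    stack = np.asarray(channel_stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a (frames, rows, cols) stack with >= 2 frames")
    n = stack.shape[0]
    if thresholds is None:
        th = np.array([isodata_threshold(f) for f in stack])
    elif np.isscalar(thresholds):
        th = np.full(n, float(thresholds))
    else:
        th = np.asarray(thresholds, dtype=float)
        if th.shape != (n,):
            raise ValueError("need one threshold per frame")
    if not (stack[0] > th[0]).any():
        raise ValueError("empty first frame: no signal above threshold")
    m1s, m2s = [], []
    for t in range(1, n):
        m1, m2 = manders_coefficients(stack[0], stack[t], th[0], th[t])
        m1s.append(m1)
        m2s.append(m2)
    m1s, m2s = np.array(m1s), np.array(m2s)
    vals = {"mean": 0.5 * (m1s + m2s), "m1": m1s, "m2": m2s}[component]
    return CorrelationCurve(
        cell_id=cell_id,
        offsets_s=np.arange(1, n) * frame_interval_s,
        values=vals,
        m1=m1s,
        m2=m2s,
    )


# --------------------------------------------------------------------------
# condition summaries
# --------------------------------------------------------------------------
def summarize_mobility(
    per_cell_velocities: pd.DataFrame | None = None,
    curves_by_condition: dict[str, list[CorrelationCurve]] | None = None,
) -> dict:
    """Condition-level summaries of both mobility readouts.

    Velocities: per-cell means, then condition mean ± SD across cells
    (expects columns ``condition, cell_id, velocity_um_s``).  Curves:
    per-offset condition mean ± SEM across cells, ready for the
    chi-squared curve comparison.
    """
    out: dict = {}
    if per_cell_velocities is not None:
        from .chancestat import aggregate_per_cell

        per_cell, per_cond = aggregate_per_cell(
            per_cell_velocities, "velocity_um_s"
        )
        out["velocity_per_cell"] = per_cell
        out["velocity_per_condition"] = per_cond
    if curves_by_condition:
        rows = {}
        for cond, curves in curves_by_condition.items():
            vals = np.stack([c.values for c in curves])
            n = vals.shape[0]
            sem = (
                vals.std(axis=0, ddof=1) / np.sqrt(n)
                if n > 1
                else np.zeros(vals.shape[1])
            )
            rows[cond] = {
                "offsets_s": curves[0].offsets_s,
                "mean": vals.mean(axis=0),
                "sem": sem,
                "n_cells": n,
            }
        out["curves_per_condition"] = rows
    return out


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Tracks table: one row per track with duration, displacement and
    mean straight velocity."""
    rows = []
    for tr in tracks:
        row = {
            "track_id": tr.track_id,
            "n_points": tr.n_points,
            "duration_s": tr.duration_s,
            "displacement_um": tr.displacement_um,
            "path_length_um": tr.path_length_um,
        }
        row["velocity_um_s"] = (
            tr.displacement_um / tr.duration_s if tr.duration_s > 0 else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)
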