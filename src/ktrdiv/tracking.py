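"""Frame-to-frame linking of nuclear labels into single-cell tracks.

The linker solves, per consecutive frame pair, an optimal one-to-one
assignment on centroid distance with a hard displacement gate. Tracks are
never bridged across missed detections; the full-duration filter then
removes transiently tracked cells, mirroring a conservative live-cell
imaging workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import linear_sum_assignment

__all__ = ["CellTrack", "link_tracks", "filter_full_duration",
           "tracks_to_dataframe"]

_GATE_PENALTY = 1e9


@dataclass
class CellTrack:
    track_id: int
    frames: list[tuple[int, int, tuple[float, float]]] = field(default_factory=list)
    # per-channel C/N series aligned to `frames` (filled in by the pipeline)
    measurements: dict[str, list[float]] = field(default_factory=dict)

    @property
    def start_frame(self) -> int:
        return self.frames[0][0]

    @property
    def end_frame(self) -> int:
        return self.frames[-1][0]

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def label_at(self, frame_idx: int) -> int | None:
        for f, lab, _ in self.frames:
            if f == frame_idx:
                return lab
        return None


def _centroids(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        return labels, np.empty((0, 2))
    cents = np.asarray(ndi.center_of_mass(mask > 0, labels=mask, index=labels))
    return labels, cents


def link_tracks(masks: np.ndarray | list[np.ndarray],
                max_disp_px: float = 25.0) -> list[CellTrack]:
    """Link a label-mask series into tracks.

    Per frame pair the assignment minimising total centroid displacement
    among links within ``max_disp_px`` is kept; unmatched new labels start
    tracks, unmatched old tracks terminate. When a division places a second
    nucleus next to a track, the track continues as the nearer daughter and
    the other daughter founds a new track.
    """
    masks = list(masks)
    if len(masks) < 2:
        raise ValueError("need at least two frames to link")
    shape = np.asarray(masks[0]).shape
    for m in masks:
        if np.asarray(m).shape != shape:
            raise ValueError("mask shapes differ across frames")

    tracks: list[CellTrack] = []
    labels0, cents0 = _centroids(np.asarray(masks[0]))
    active: list[int] = []  # indices into `tracks`
    for lab, cent in zip(labels0, cents0):
        tracks.append(CellTrack(track_id=len(tracks),
                                frames=[(0, int(lab), tuple(cent))]))
        active.append(len(tracks) - 1)
    prev_cents = cents0

    for f in range(1, len(masks)):
        labels, cents = _centroids(np.asarray(masks[f]))
        matched_curr = np.zeros(len(labels), dtype=bool)
        next_active: list[int] = []
        if len(active) and len(labels):
            d = np.linalg.norm(prev_cents[:, None, :] - cents[None, :, :], axis=-1)
            cost = np.where(d <= max_disp_px, d, _GATE_PENALTY)
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if d[i, j] > max_disp_px:
                    continue
                ti = active[i]
                tracks[ti].frames.append((f, int(labels[j]), tuple(cents[j])))
                matched_curr[j] = True
                next_active.append(ti)
        new_cents = [tracks[ti].frames[-1][2] for ti in next_active]
        for j in np.flatnonzero(~matched_curr):
            tracks.append(CellTrack(track_id=len(tracks),
                                    frames=[(f, int(labels[j]), tuple(cents[j]))]))
            next_active.append(len(tracks) - 1)
            new_cents.append(tuple(cents[j]))
        active = next_active
        prev_cents = np.asarray(new_cents).reshape(-1, 2)
    return tracks


def filter_full_duration(
    tracks: list[CellTrack], n_frames_required: int,
) -> tuple[list[CellTrack], list[tuple[CellTrack, str]]]:
    """Keep only tracks spanning frames 0 .. n_frames_required - 1.

    Dropped tracks carry a reason code: LATE_START, EARLY_END or both
    (TRANSIENT).
    """
    if n_frames_required < 1:
        raise ValueError("n_frames_required must be >= 1")
    kept, dropped = [], []
    for t in tracks:
        late = t.start_frame > 0
        early = t.end_frame < n_frames_required - 1
        if not late and not early:
            kept.append(t)
        else:
            reason = "TRANSIENT" if late and early else (
                "LATE_START" if late else "EARLY_END")
            dropped.append((t, reason))
    return kept, dropped


def tracks_to_dataframe(tracks: list[CellTrack],
                        sampling_interval_h: float = 0.25) -> pd.DataFrame:
    """Long-format track table (one row per track x frame x channel)."""
    rows = []
    for t in tracks:
        channels = list(t.measurements) or [None]
        for k, (f, lab, (r, c)) in enumerate(t.frames):
            for ch in channels:
                rows.append({
                    "track_id": t.track_id, "frame": f,
                    "time_h": f * sampling_interval_h, "label": lab,
                    "row": r, "col": c, "channel": ch,
                    "cn_ratio": (t.measurements[ch][k] if ch else np.nan),
                })
    return pd.DataFrame(rows, columns=["track_id", "frame", "time_h", "label",
                                       "row", "col", "channel", "cn_ratio"])
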