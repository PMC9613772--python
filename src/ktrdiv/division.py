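"""Division-event detection from the C/N-ratio drop signature.

At mitosis the cell rounds up and the cytoplasmic ring collapses, producing
a transient steep drop in the C/N ratio. The detector finds the earliest
prominent, steep relative drop, the trace is truncated five timepoints
before the drop so only genuine kinase activity survives, and every track
is classified as dividing, non-dividing, or excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "DetectParams",
    "DivisionCall",
    "FateConfig",
    "FateRecord",
    "detect_division",
    "truncate_trace",
    "classify_fates",
]


@dataclass
class DetectParams:
    """Thresholds for the drop detector.

    ``min_drop_frac`` is the minimum relative C/N decrease over at most
    ``max_drop_span_frames`` frames; ``min_prominence`` (C/N units) is the
    prominence the inverted trace must show at the local minimum. In
    dual-reporter movies the Akt channel is used at 15-min sampling and the
    ERK channel at 5-min sampling.
    """

    min_drop_frac: float = 0.35
    max_drop_span_frames: int = 2
    min_prominence: float = 0.2
    earliest_frame: int = 0
    truncate_offset_frames: int = 5
    detection_channel: str = "akt"

    def __post_init__(self) -> None:
        if not 0.0 < self.min_drop_frac < 1.0:
            raise ValueError("min_drop_frac must lie in (0, 1)")
        if self.truncate_offset_frames < 0:
            raise ValueError("truncate_offset_frames must be >= 0")
        if self.max_drop_span_frames < 1:
            raise ValueError("max_drop_span_frames must be >= 1")


@dataclass
class DivisionCall:
    track_id: int
    peak_frame: int
    drop_frac_observed: float
    qc_flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def accepted(self) -> bool:
        return not self.qc_flags


@dataclass
class FateConfig:
    """Presence thresholds for the non-dividing definition."""

    sampling_interval_h: float = 0.25
    min_presence_h_15min: float = 48.0
    min_presence_h_5min: float = 41.67

    def __post_init__(self) -> None:
        if min(self.min_presence_h_15min, self.min_presence_h_5min) <= 0:
            raise ValueError("presence thresholds must be positive")

    @property
    def min_presence_h(self) -> float:
        # 5-min acquisitions get the relaxed threshold; everything else the
        # full-duration one
        if self.sampling_interval_h <= 5.0 / 60.0 + 1e-9:
            return self.min_presence_h_5min
        return self.min_presence_h_15min


@dataclass
class FateRecord:
    track_id: int
    fate: str                      # "dividing" | "non-dividing" | "excluded"
    reason: str = ""
    qc_flags: frozenset[str] = field(default_factory=frozenset)


def detect_division(cn_trace: np.ndarray, params: DetectParams | None = None,
                    track_id: int = -1) -> DivisionCall | None:
    """Find the earliest qualifying division drop in one C/N trace.

    A candidate frame p must show a relative drop
    ``(cn[p-s] - cn[p]) / cn[p-s] > min_drop_frac`` over some span
    ``s <= max_drop_span_frames`` and sit at (or within a span of) a local
    minimum of prominence ``>= min_prominence``. Candidates that fail
    secondary checks — the drop is not sustained for at least one further
    frame, or the drop falls within ``truncate_offset_frames`` of the trace
    start — are returned flagged for review rather than silently dropped.
    """
    params = params or DetectParams()
    cn = np.asarray(cn_trace, dtype=float)
    if cn.ndim != 1 or cn.size < params.truncate_offset_frames + 2:
        raise ValueError("trace too short for division detection")
    n = cn.size

    minima, props = find_peaks(-cn, prominence=params.min_prominence)
    minima = set(int(m) for m in minima)

    spans = range(1, params.max_drop_span_frames + 1)
    for p in range(1, n):
        if p <= params.earliest_frame:
            continue
        best_drop, best_span = 0.0, None
        for s in spans:
            if p - s < 0 or cn[p - s] <= 0:
                continue
            drop = (cn[p - s] - cn[p]) / cn[p - s]
            if drop > params.min_drop_frac and drop > best_drop:
                best_drop, best_span = drop, s
        if best_span is None:
            continue
        near_min = any(abs(p - m) <= params.max_drop_span_frames for m in minima)
        if not near_min:
            continue
        peak = min((m for m in minima
                    if abs(p - m) <= params.max_drop_span_frames),
                   key=lambda m: (abs(p - m), m))
        flags: set[str] = set()
        if peak < params.truncate_offset_frames:
            flags.add("NEAR_START")
        q = min(p + 1, n - 1)
        ref = cn[p - best_span]
        if q == p or (ref - cn[q]) / ref < params.min_drop_frac / 2.0:
            flags.add("SPURIOUS_CANDIDATE")
        return DivisionCall(track_id=track_id, peak_frame=int(peak),
                            drop_frac_observed=float(best_drop),
                            qc_flags=frozenset(flags))
    return None


def truncate_trace(trace: np.ndarray, call: DivisionCall | None,
                   params: DetectParams | None = None) -> np.ndarray:
    """Cut the trace `truncate_offset_frames` before the division drop.

    Returns frames 0 .. peak_frame - offset - 1 (length peak_frame -
    offset). With no call the trace is returned unchanged; a call too close
    to the start yields an empty trace (the cell is excluded downstream via
    its NEAR_START flag, never an exception).
    """
    params = params or DetectParams()
    trace = np.asarray(trace)
    if call is None:
        return trace.copy()
    stop = max(call.peak_frame - params.truncate_offset_frames, 0)
    return trace[:stop].copy()


def classify_fates(
    tracks,
    calls: dict[int, DivisionCall | None],
    fate: FateConfig,
    n_frames_total: int,
) -> list[FateRecord]:
    """Assign dividing / non-dividing / excluded to every track.

    Dividing requires an accepted (unflagged) call. Non-dividing requires
    no call and presence for at least the acquisition-interval-specific
    duration. Everything else is excluded with a reason; flagged calls are
    routed to review, standing in for manual curation of spurious peaks.
    """
    by_id = {t.track_id: t for t in tracks}
    for tid in calls:
        if tid not in by_id:
            raise KeyError(f"division call references unknown track {tid}")
    records = []
    for t in tracks:
        call = calls.get(t.track_id)
        if call is not None and call.accepted:
            records.append(FateRecord(t.track_id, "dividing"))
        elif call is not None:
            records.append(FateRecord(
                t.track_id, "excluded", reason="QC_REVIEW",
                qc_flags=call.qc_flags))
        else:
            presence_h = (t.end_frame - t.start_frame) * fate.sampling_interval_h
            if presence_h >= fate.min_presence_h - 1e-9:
                records.append(FateRecord(t.track_id, "non-dividing"))
            else:
                records.append(FateRecord(t.track_id, "excluded",
                                          reason="SHORT_PRESENCE"))
    return records
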